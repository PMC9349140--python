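"""Markov cohort engine.

Two hypothetical cohorts of 1000 patients (teriflunomide started first-line
in treatment-naïve patients vs. started after previous DMT exposure) are
pushed through annual cycles over a 7-year horizon.  Each cycle a patient
remains in their compartment, moves, or dies of age- and sex-specific
all-cause mortality.  Within the relapse compartment the flow order is:
death first, then remission (20% of survivors), then -- naïve strategy,
cycles >= 2 only -- switch to a second-line DMT (10% of survivors who did
not remit); the remainder stays in relapse on the current arm.  Remission
is not sticky (remitted patients face the cohort relapse probability
again) and controlled RRMS is entry-only.

Half-cycle correction: deaths are assumed to occur half-way through the
cycle, so each cycle's accrual credits survivors with a full cycle in
their end-of-cycle compartment and that cycle's decedents with half a
cycle in the compartment they died from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import states as st
from .errors import ValidationError


def _check_prob(value: float, name: str) -> float:
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must lie in [0, 1], got {value}")
    return float(value)


class MortalityTable:
    """Annual all-cause death probability keyed by (integer age, sex).

    Sex codes are ``"F"`` and ``"M"``.  No extrapolation: querying an age
    outside the table raises.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"age", "sex", "p_death"}
        if not required.issubset(frame.columns):
            raise ValidationError(
                f"mortality table needs columns {sorted(required)}, "
                f"got {list(frame.columns)}"
            )
        bad = frame[(frame["p_death"] < 0) | (frame["p_death"] > 1)]
        if len(bad):
            raise ValidationError(
                f"mortality probabilities outside [0,1] at ages "
                f"{bad['age'].tolist()}"
            )
        if frame["sex"].isin(["F", "M"]).all() is False:
            raise ValidationError("mortality sex codes must be 'F' or 'M'")
        self._table = {
            (int(r.age), str(r.sex)): float(r.p_death)
            for r in frame.itertuples()
        }
        self.frame = frame.reset_index(drop=True)

    def prob(self, age: int, sex: str) -> float:
        key = (int(age), sex)
        if key not in self._table:
            raise ValidationError(
                f"age {age} ({sex}) outside the mortality table; "
                "no extrapolation is performed"
            )
        return self._table[key]

    def blended(self, age: int, female_share: float) -> float:
        """Female-share-weighted average of the sex-specific rates."""
        _check_prob(female_share, "female_share")
        return (female_share * self.prob(age, "F")
                + (1.0 - female_share) * self.prob(age, "M"))

    def to_csv(self, path):
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MortalityTable":
        return cls(pd.read_csv(path))


@dataclass
class CohortDemographics:
    entry_age_mean: float
    entry_age_range: tuple[float, float]
    female_share: float
    years_since_diagnosis_mean: float = 0.0

    def __post_init__(self):
        _check_prob(self.female_share, "female_share")
        lo, hi = self.entry_age_range
        if not lo <= self.entry_age_mean <= hi:
            raise ValidationError(
                f"entry age range {self.entry_age_range} does not bracket "
                f"the mean {self.entry_age_mean}"
            )

    def age_at_cycle(self, cycle: int) -> int:
        """Integer cohort age during 1-based ``cycle`` (mean entry age
        advancing one year per cycle)."""
        return int(self.entry_age_mean) + (cycle - 1)


@dataclass
class TransitionParams:
    """Per-cohort transition inputs.

    ``p_relapse_by_cycle`` may be a scalar (constant risk) or a sequence of
    per-cycle probabilities.  ``adherence`` below 1 raises the effective
    relapse probability on the teriflunomide arm: non-adherent person-time
    loses the treatment effect, i.e. ``p_eff = a*p + (1-a)*min(1, p/m)``
    with treatment-effect multiplier ``m`` (default 0.7).
    """

    p_relapse_by_cycle: float | list[float]
    p_remission_given_relapse: float = 0.20
    p_switch_given_relapse: float = 0.0
    switch_first_cycle: int = 2
    switch_shares: dict[str, float] = field(default_factory=dict)
    adherence: float = 1.0
    treatment_effect_multiplier: float = 0.7

    def __post_init__(self):
        _check_prob(self.p_remission_given_relapse, "p_remission_given_relapse")
        _check_prob(self.p_switch_given_relapse, "p_switch_given_relapse")
        _check_prob(self.adherence, "adherence")
        for c, p in enumerate(np.atleast_1d(np.asarray(
                self.p_relapse_by_cycle, dtype=float)), start=1):
            _check_prob(p, f"p_relapse_by_cycle[{c}]")
        if self.switch_shares:
            total = sum(self.switch_shares.values())
            if abs(total - 1.0) > 1e-12:
                raise ValidationError(
                    f"switch_shares must sum to 1, got {total:.15g}"
                )
        if not 0.0 < self.treatment_effect_multiplier <= 1.0:
            raise ValidationError(
                "treatment_effect_multiplier must lie in (0, 1]"
            )

    def p_relapse(self, cycle: int) -> float:
        arr = np.atleast_1d(np.asarray(self.p_relapse_by_cycle, dtype=float))
        raw = float(arr[min(cycle - 1, len(arr) - 1)])
        a, m = self.adherence, self.treatment_effect_multiplier
        return a * raw + (1.0 - a) * min(1.0, raw / m)

    def p_relapse_offtreatment(self, cycle: int) -> float:
        """Relapse probability on the switched arm (same treatment effect
        assumed for second-line DMTs; adherence applies to teriflunomide only)."""
        arr = np.atleast_1d(np.asarray(self.p_relapse_by_cycle, dtype=float))
        return float(arr[min(cycle - 1, len(arr) - 1)])


@dataclass
class StrategyConfig:
    """Everything defining one cohort: demographics, transition dynamics,
    cost items and utilities (the latter two are consumed by the valuation
    layer)."""

    name: str
    demographics: CohortDemographics
    transitions: TransitionParams
    mortality: MortalityTable
    allows_switch: bool = True
    cost_items: list = field(default_factory=list)
    utilities: object = None
    wages: object = None


def build_transition_matrix(tp: TransitionParams, mort: MortalityTable,
                            demo: CohortDemographics, cycle: int,
                            allows_switch: bool = True) -> np.ndarray:
    """Row-stochastic 6x6 matrix over the expanded state space for ``cycle``.

    Death applies first to every live compartment at the cohort's current
    integer age (sex-blended); survivors are then allocated by the relapse/
    remission/switch rules in the module docstring.
    """
    if cycle < 1:
        raise ValidationError(f"cycle must be >= 1, got {cycle}")
    q = mort.blended(demo.age_at_cycle(cycle), demo.female_share)
    p_rel = _check_prob(tp.p_relapse(cycle), "effective p_relapse")
    p_rel_sw = _check_prob(tp.p_relapse_offtreatment(cycle),
                           "switched-arm p_relapse")
    p_rem = tp.p_remission_given_relapse
    p_sw = tp.p_switch_given_relapse
    switching = (allows_switch and p_sw > 0.0
                 and cycle >= tp.switch_first_cycle)

    P = np.zeros((st.N_STATES, st.N_STATES))
    s = 1.0 - q  # survival this cycle

    # CONTROLLED (teri): stay or relapse
    P[st.CONTROLLED_TERI, st.DEAD] = q
    P[st.CONTROLLED_TERI, st.RELAPSE_TERI] = s * p_rel
    P[st.CONTROLLED_TERI, st.CONTROLLED_TERI] = s * (1.0 - p_rel)

    # RELAPSE (teri): death -> remission -> (naïve, cycle>=2) switch -> stay
    P[st.RELAPSE_TERI, st.DEAD] = q
    P[st.RELAPSE_TERI, st.REMISSION_TERI] = s * p_rem
    rest = s * (1.0 - p_rem)
    if switching:
        P[st.RELAPSE_TERI, st.RELAPSE_SWITCHED] = rest * p_sw
        P[st.RELAPSE_TERI, st.RELAPSE_TERI] = rest * (1.0 - p_sw)
    else:
        P[st.RELAPSE_TERI, st.RELAPSE_TERI] = rest

    # REMISSION (teri): not sticky -- same relapse risk as CONTROLLED
    P[st.REMISSION_TERI, st.DEAD] = q
    P[st.REMISSION_TERI, st.RELAPSE_TERI] = s * p_rel
    P[st.REMISSION_TERI, st.REMISSION_TERI] = s * (1.0 - p_rel)

    # Switched arm mirrors the teri arm without further switching
    P[st.RELAPSE_SWITCHED, st.DEAD] = q
    P[st.RELAPSE_SWITCHED, st.REMISSION_SWITCHED] = s * p_rem
    P[st.RELAPSE_SWITCHED, st.RELAPSE_SWITCHED] = s * (1.0 - p_rem)

    P[st.REMISSION_SWITCHED, st.DEAD] = q
    P[st.REMISSION_SWITCHED, st.RELAPSE_SWITCHED] = s * p_rel_sw
    P[st.REMISSION_SWITCHED, st.REMISSION_SWITCHED] = s * (1.0 - p_rel_sw)

    P[st.DEAD, st.DEAD] = 1.0

    rowsum = P.sum(axis=1)
    if not np.allclose(rowsum, 1.0, atol=1e-12):
        raise ValidationError(f"transition rows do not sum to 1: {rowsum}")
    return P


@dataclass
class CohortTrace:
    """Expected occupancy and person-time credits of one cohort.

    ``occupancy[t]`` is the compartment occupancy *after* cycle ``t``
    (row 0 is the entry distribution).  ``accrual[t-1]`` holds cycle
    ``t``'s half-cycle-corrected person-time credits per compartment.
    Event flows (new relapses, new remissions, switches) are expected
    counts of within-cycle transitions, used for per-episode costing.
    """

    n0: float
    occupancy: np.ndarray          # (n_cycles+1, 6)
    accrual: np.ndarray            # (n_cycles, 6)
    deaths_by_cycle: np.ndarray    # (n_cycles,)
    relapse_onsets: np.ndarray     # (n_cycles,) inflow into RELAPSE states
    remission_onsets: np.ndarray   # (n_cycles,) inflow into REMISSION states
    switch_flows: np.ndarray       # (n_cycles,) teri -> switched arm flow

    @property
    def n_cycles(self) -> int:
        return self.accrual.shape[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in range(1, self.n_cycles + 1):
            for i, label in enumerate(st.STATE_LABELS):
                rows.append({
                    "cycle": t,
                    "state": st.health_of(i).value,
                    "arm": getattr(st.arm_of(i), "value", ""),
                    "occupancy": self.occupancy[t, i],
                    "accrual_weight": self.accrual[t - 1, i],
                })
        df = pd.DataFrame(rows)
        df["deaths_in_cycle"] = df["cycle"].map(
            {t: self.deaths_by_cycle[t - 1] for t in range(1, self.n_cycles + 1)}
        )
        return df


def run_cohort_trace(strategy: StrategyConfig, n0: float = 1000.0,
                     n_cycles: int = 7) -> CohortTrace:
    """Propagate ``n0`` patients from (CONTROLLED, TERIFLUNOMIDE) through
    ``n_cycles`` annual cycles."""
    if n_cycles < 1:
        raise ValidationError(f"n_cycles must be >= 1, got {n_cycles}")
    if n0 <= 0:
        raise ValidationError(f"n0 must be > 0, got {n0}")

    occ = np.zeros((n_cycles + 1, st.N_STATES))
    occ[0, st.CONTROLLED_TERI] = n0
    accrual = np.zeros((n_cycles, st.N_STATES))
    deaths = np.zeros(n_cycles)
    relapse_onsets = np.zeros(n_cycles)
    remission_onsets = np.zeros(n_cycles)
    switch_flows = np.zeros(n_cycles)

    relapse_states = list(st.states_of_health(st.HealthState.RELAPSE))
    remission_states = list(st.states_of_health(st.HealthState.REMISSION))

    for t in range(1, n_cycles + 1):
        P = build_transition_matrix(
            strategy.transitions, strategy.mortality, strategy.demographics,
            cycle=t, allows_switch=strategy.allows_switch,
        )
        prev = occ[t - 1]
        flows = prev[:, None] * P        # flows[i, j]: expected i -> j moves
        occ[t] = flows.sum(axis=0)

        died = flows[st.LIVE_STATES, st.DEAD]
        deaths[t - 1] = died.sum()
        # survivors: full credit in end-of-cycle compartment;
        # decedents: half credit in the compartment they died from.
        accrual[t - 1] = occ[t].copy()
        accrual[t - 1, st.DEAD] = 0.0
        for k, i in enumerate(st.LIVE_STATES):
            accrual[t - 1, i] += 0.5 * died[k]

        off = flows.copy()
        np.fill_diagonal(off, 0.0)
        relapse_onsets[t - 1] = off[:, relapse_states].sum() - flows[
            st.RELAPSE_TERI, st.RELAPSE_SWITCHED]
        remission_onsets[t - 1] = off[:, remission_states].sum()
        switch_flows[t - 1] = flows[st.RELAPSE_TERI, st.RELAPSE_SWITCHED]

        if abs(occ[t].sum() - n0) > 1e-9:
            raise ValidationError(
                f"conservation violated at cycle {t}: {occ[t].sum():.12f}"
            )

    return CohortTrace(
        n0=n0, occupancy=occ, accrual=accrual, deaths_by_cycle=deaths,
        relapse_onsets=relapse_onsets, remission_onsets=remission_onsets,
        switch_flows=switch_flows,
    )


def occupancy_summary(trace: CohortTrace) -> pd.DataFrame:
    """Mean, population SD and share-of-cohort of each compartment across
    the post-baseline cycle occupancies (the Table-1-style summary)."""
    post = trace.occupancy[1:]
    mean = post.mean(axis=0)
    sd = post.std(axis=0)  # population SD
    return pd.DataFrame({
        "state": [st.health_of(i).value for i in range(st.N_STATES)],
        "arm": [getattr(st.arm_of(i), "value", "") for i in range(st.N_STATES)],
        "mean": mean,
        "sd": sd,
        "share": mean / trace.n0,
    }, index=list(st.STATE_LABELS))


def aggregate_to_four_states(trace: CohortTrace) -> pd.DataFrame:
    """Sum the treatment-arm dimension out of the occupancy table."""
    healths = [h.value for h in st.HealthState]
    data = {h: np.zeros(trace.occupancy.shape[0]) for h in healths}
    for i in range(st.N_STATES):
        data[st.health_of(i).value] += trace.occupancy[:, i]
    df = pd.DataFrame(data)
    df.index.name = "cycle"
    return df
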