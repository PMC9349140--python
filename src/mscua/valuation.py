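"""Costing, discounting, QALYs and strategy comparison.

Costs are grouped into three blocks mirroring the usual reference-case
layout: (A) healthcare-sector costs funded by the payer, (B) patients'
out-of-pocket expenses and (C) patient time and informal care.  The
healthcare-sector perspective counts block A only; the societal
perspective counts A + B + C.

Cost items attach either to compartment *stocks* (credited with that
cycle's half-cycle-corrected person-time) or to within-cycle *events*
(new relapses, new remissions, switches, model entry), which are costed
per episode.  Administration tariffs that would double-count the
separately priced drug are halved.  Patient and caregiver time is valued
at the gross hourly wage (working time, patients under 70), the take-home
wage (leisure time: patients 70+ and all caregivers) or the home-helper
gross wage (housekeeping patients).

Accruals in cycle t are discounted by (1+r)^-(t-1): the first cycle is
undiscounted, as are one-off entry costs.  QALYs are per-compartment
person-time times utility (minus any adverse-event disutility on the
teriflunomide arm), discounted the same way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


from . import states as st
from .engine import CohortTrace
from .errors import ValidationError

HEALTHCARE_SECTOR = "HEALTHCARE_SECTOR"
OUT_OF_POCKET = "OUT_OF_POCKET"
TIME_AND_INFORMAL_CARE = "TIME_AND_INFORMAL_CARE"
CATEGORIES = (HEALTHCARE_SECTOR, OUT_OF_POCKET, TIME_AND_INFORMAL_CARE)

SOCIETAL = "SOCIETAL"
PERSPECTIVES = (HEALTHCARE_SECTOR, SOCIETAL)

#: attach_to tokens resolved against a trace
STOCK_ATTACHMENTS = {
    "state:CONTROLLED": [st.CONTROLLED_TERI],
    "state:RELAPSE": [st.RELAPSE_TERI, st.RELAPSE_SWITCHED],
    "state:REMISSION": [st.REMISSION_TERI, st.REMISSION_SWITCHED],
    "arm:TERIFLUNOMIDE": list(st.TERI_ARM_STATES),
    "arm:SWITCHED_DMT": list(st.SWITCHED_ARM_STATES),
    "alive": list(st.LIVE_STATES),
}
EVENT_ATTACHMENTS = ("event:entry", "event:relapse_onset",
                     "event:remission_onset", "event:switch")
TIME_ROLES = ("patient", "caregiver", "housekeeper-patient")


@dataclass
class WageParams:
    gross_hourly_wage: float
    take_home_hourly_wage: float
    homehelper_gross_wage: float
    age_threshold: float = 70.0

    def __post_init__(self):
        if not self.gross_hourly_wage >= self.take_home_hourly_wage > 0:
            raise ValidationError(
                "wages must satisfy gross >= take-home > 0, got "
                f"gross={self.gross_hourly_wage}, "
                f"take_home={self.take_home_hourly_wage}"
            )


@dataclass
class UtilityParams:
    """State utilities plus an adverse-event disutility on the drug arm."""

    utility_controlled: float
    utility_relapse: float
    utility_remission: float
    ae_disutility: float = 0.0

    def __post_init__(self):
        for nm in ("utility_controlled", "utility_relapse", "utility_remission"):
            u = getattr(self, nm)
            if not 0.0 <= u <= 1.0:
                raise ValidationError(f"{nm} must lie in [0, 1], got {u}")
        if self.ae_disutility < 0:
            raise ValidationError("ae_disutility must be >= 0")
        if self.utility_relapse > self.utility_controlled:
            raise ValidationError(
                "utility(RELAPSE) must not exceed utility(CONTROLLED)"
            )

    def by_state(self) -> np.ndarray:
        u = np.zeros(st.N_STATES)
        u[st.CONTROLLED_TERI] = self.utility_controlled
        u[st.RELAPSE_TERI] = u[st.RELAPSE_SWITCHED] = self.utility_relapse
        u[st.REMISSION_TERI] = u[st.REMISSION_SWITCHED] = self.utility_remission
        return u


@dataclass
class CostItem:
    """One costed resource.

    ``attach_to`` is a stock token (see :data:`STOCK_ATTACHMENTS`), an
    event token, or ``event:entry`` for one-off baseline assessments.
    ``kind="time"`` items are hour volumes valued through
    :func:`value_time_loss` with the given ``role``; ``unit_cost`` is then
    ignored.  ``weight`` scales the contribution (used for the DMT split
    across switch destinations) and ``scales_with_adherence`` multiplies
    the quantity by the cohort's adherence (drug acquisition only).
    """

    name: str
    category: str
    attach_to: str
    unit_cost: float = 0.0
    quantity_per_cycle: float = 1.0
    is_admin_tariff: bool = False
    sa_excluded: bool = False
    kind: str = "cost"
    role: str | None = None
    weight: float = 1.0
    scales_with_adherence: bool = False

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"cost item {self.name!r}: unknown category {self.category!r}"
            )
        if (self.attach_to not in STOCK_ATTACHMENTS
                and self.attach_to not in EVENT_ATTACHMENTS):
            raise ValidationError(
                f"cost item {self.name!r}: unknown attachment "
                f"{self.attach_to!r}"
            )
        if self.unit_cost < 0:
            raise ValidationError(
                f"cost item {self.name!r}: unit_cost must be >= 0"
            )
        if self.quantity_per_cycle < 0:
            raise ValidationError(
                f"cost item {self.name!r}: quantity must be >= 0"
            )
        if self.kind == "time" and self.role not in TIME_ROLES:
            raise ValidationError(
                f"cost item {self.name!r}: time items need a role in "
                f"{TIME_ROLES}"
            )


def discount_factors(rate: float, n_cycles: int) -> np.ndarray:
    """Per-cycle factors (1+r)^-(t-1) for t = 1..n_cycles."""
    if rate < 0:
        raise ValidationError(f"discount rate must be >= 0, got {rate}")
    t = np.arange(n_cycles)
    return (1.0 + rate) ** (-t.astype(float))


def discount_total(values_by_cycle, rate: float, times=None) -> float:
    """Present value sum(v_t / (1+rate)^t).

    ``times`` defaults to 0, 1, ... (first value undiscounted), matching
    the engine's accrual convention; pass explicit exponents for other
    conventions.
    """
    if rate < 0:
        raise ValidationError(f"discount rate must be >= 0, got {rate}")
    v = np.asarray(values_by_cycle, dtype=float)
    t = np.arange(len(v)) if times is None else np.asarray(times, dtype=float)
    return float(np.sum(v * (1.0 + rate) ** (-t)))


def value_time_loss(hours: float, person_age: float, role: str,
                    wages: WageParams) -> float:
    """Monetary value of lost time under the human-capital rules."""
    if hours < 0:
        raise ValidationError(f"hours must be >= 0, got {hours}")
    if role not in TIME_ROLES:
        raise ValidationError(f"unknown time role {role!r}")
    if role == "housekeeper-patient":
        return hours * wages.homehelper_gross_wage
    if role == "caregiver" or person_age >= wages.age_threshold:
        return hours * wages.take_home_hourly_wage
    return hours * wages.gross_hourly_wage


@dataclass
class EconOutcome:
    """Discounted per-patient costs (by block), LYS and QALYs for one
    strategy under one perspective."""

    strategy: str
    perspective: str
    cost_by_category: dict[str, float]
    lys: float
    qalys: float
    cost_by_item: dict[str, float] = field(default_factory=dict)

    @property
    def total_cost(self) -> float:
        if self.perspective == HEALTHCARE_SECTOR:
            return self.cost_by_category[HEALTHCARE_SECTOR]
        return sum(self.cost_by_category.values())


def _event_stream(trace: CohortTrace, token: str) -> np.ndarray:
    if token == "event:relapse_onset":
        return trace.relapse_onsets
    if token == "event:remission_onset":
        return trace.remission_onsets
    if token == "event:switch":
        return trace.switch_flows
    raise ValidationError(f"unknown event token {token!r}")


def accrue_costs(trace: CohortTrace, items: list[CostItem], rate: float,
                 wages: WageParams | None = None,
                 person_age: float = 0.0,
                 adherence: float = 1.0) -> tuple[dict[str, float], dict[str, float]]:
    """Discounted per-patient cost by category (and by item).

    Stock items accrue ``quantity x unit cost`` per person-cycle of
    half-cycle-corrected person-time; event items per expected episode;
    ``event:entry`` items once per starting patient, undiscounted.
    """
    disc = discount_factors(rate, trace.n_cycles)
    by_cat = {c: 0.0 for c in CATEGORIES}
    by_item: dict[str, float] = {}
    for item in items:
        if item.kind == "time":
            if wages is None:
                raise ValidationError(
                    f"time item {item.name!r} needs wage parameters"
                )
            unit = value_time_loss(1.0, person_age, item.role, wages)
        else:
            unit = item.unit_cost
        if item.is_admin_tariff:
            unit *= 0.5
        qty = item.quantity_per_cycle * item.weight
        if item.scales_with_adherence:
            qty *= adherence

        if item.attach_to == "event:entry":
            total = unit * qty  # once per starting patient, undiscounted
        else:
            if item.attach_to in STOCK_ATTACHMENTS:
                idx = STOCK_ATTACHMENTS[item.attach_to]
                stream = trace.accrual[:, idx].sum(axis=1)
            else:
                stream = _event_stream(trace, item.attach_to)
            total = unit * qty * float(stream @ disc) / trace.n0
        by_cat[item.category] += total
        by_item[item.name] = by_item.get(item.name, 0.0) + total
    return by_cat, by_item


def compute_lys_qalys(trace: CohortTrace, up: UtilityParams,
                      rate: float = 0.03) -> tuple[float, float]:
    """Discounted per-patient life-years and QALYs from the accrual table."""
    disc = discount_factors(rate, trace.n_cycles)
    live = trace.accrual[:, st.LIVE_STATES].sum(axis=1)
    lys = float(live @ disc) / trace.n0
    u = up.by_state()
    u_eff = u.copy()
    for i in st.TERI_ARM_STATES:
        u_eff[i] = max(0.0, u_eff[i] - up.ae_disutility)
    qaly_stream = trace.accrual[:, st.LIVE_STATES] @ u_eff[list(st.LIVE_STATES)]
    qalys = float(qaly_stream @ disc) / trace.n0
    return lys, qalys


STRONGLY_DOMINANT = "STRONGLY_DOMINANT"
DOMINATED = "DOMINATED"
ICUR_REPORTED = "ICUR_REPORTED"


@dataclass
class CUAResult:
    """Incremental comparison of a new strategy against a comparator."""

    delta_cost: float
    delta_qalys: float
    icur: float          # signed ratio; nan when delta_qalys == 0
    verdict: str
    perspective: str = SOCIETAL

    @property
    def icur_defined(self) -> bool:
        return not math.isnan(self.icur)


def compare_strategies(new: EconOutcome, ref: EconOutcome) -> CUAResult:
    """ΔC, ΔQALYs and the ICUR/dominance verdict of ``new`` vs ``ref``."""
    if new.perspective != ref.perspective:
        raise ValidationError(
            f"cannot compare across perspectives: {new.perspective} vs "
            f"{ref.perspective}"
        )
    dc = new.total_cost - ref.total_cost
    dq = new.qalys - ref.qalys
    if dc < 0 and dq > 0:
        verdict = STRONGLY_DOMINANT
    elif dc > 0 and dq < 0:
        verdict = DOMINATED
    else:
        verdict = ICUR_REPORTED
    icur = dc / dq if dq != 0 else float("nan")
    return CUAResult(delta_cost=dc, delta_qalys=dq, icur=icur,
                     verdict=verdict, perspective=new.perspective)


def net_monetary_benefit(wtp: float, cost: float, qalys: float) -> float:
    """NMB = wtp * QALYs - cost."""
    if wtp < 0:
        raise ValidationError(f"willingness to pay must be >= 0, got {wtp}")
    return wtp * qalys - cost
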