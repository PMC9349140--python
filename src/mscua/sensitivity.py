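"""One-way, scenario and probabilistic sensitivity analyses.

* **OWSA**: every sensitivity-eligible parameter is replaced, one at a
  time, by the limits of its 95% CI (distributed parameters) or of its
  stated range (fixed parameters, including the discount rate), the model
  re-solved, and the signed percentage departure from the base-case ICUR
  recorded: ``pct = 100 * (ICUR_scenario - ICUR_base) / |ICUR_base|``
  with signed ICURs, so a dominant (negative-ICUR) base case keeps its
  sign; dominance changes are flagged separately.  Drug prices, posology
  and administration counts are excluded by convention.
* **Scenario analyses**: yearly ICUR over truncated horizons, an
  adherence grid, and a remission-probability grid, each applied to both
  cohorts symmetrically.
* **PSA**: a Monte Carlo simulation drawing every distributed parameter
  jointly per iteration (parameters shared between cohorts are drawn
  once), solving both strategies, and summarising cost-effectiveness as
  CEAC/CEAF over a willingness-to-pay grid via the net monetary benefit.
  NMB ties are broken toward the comparator; infeasible draws are
  resampled and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import ParameterRegistry, ParameterSpec
from .errors import ValidationError
from .valuation import HEALTHCARE_SECTOR, PERSPECTIVES, SOCIETAL

NEW, REF = "naive", "experienced"


def _clamp_to_support(spec: ParameterSpec, value: float) -> tuple[float, bool]:
    """Clamp an OWSA replacement to the parameter's support."""
    lo, hi = -np.inf, np.inf
    if spec.family in ("BETA", "DIRICHLET"):
        lo, hi = 1e-9, 1.0 - 1e-9
    elif spec.family == "GAMMA":
        lo = 1e-12
    clamped = min(max(value, lo), hi)
    return clamped, clamped != value


def owsa_parameters(registry: ParameterRegistry) -> list[ParameterSpec]:
    """Parameters entering OWSA: eligible and varyable (distributed, or
    fixed with a stated range)."""
    out = []
    for spec in registry:
        if not spec.sa_eligible:
            continue
        if spec.family == "FIXED" and spec.range is None:
            continue
        out.append(spec)
    return out


def run_owsa(model, perspective: str = HEALTHCARE_SECTOR) -> pd.DataFrame:
    """Tornado table: one row per parameter, sorted by largest absolute
    percentage departure from the base-case ICUR."""
    base = model.solve()
    base_icur = base.cua[perspective].icur
    base_verdict = base.cua[perspective].verdict
    rows = []
    for spec in owsa_parameters(model.registry):
        lo, hi = spec.ci95()
        entry = {"parameter": spec.name, "family": spec.family,
                 "low": lo, "high": hi, "clamped": False}
        for tag, replacement in (("low", lo), ("high", hi)):
            val, was_clamped = _clamp_to_support(spec, replacement)
            entry["clamped"] |= was_clamped
            sol = model.solve(model.registry.with_overrides({spec.name: val}))
            r = sol.cua[perspective]
            entry[f"icur_at_{tag}"] = r.icur
            entry[f"pct_departure_{tag}"] = (
                100.0 * (r.icur - base_icur) / abs(base_icur)
                if base_icur not in (0.0,) and np.isfinite(r.icur)
                and np.isfinite(base_icur) else np.nan)
            entry[f"verdict_at_{tag}"] = r.verdict
        entry["dominance_flip"] = (entry["verdict_at_low"] != base_verdict
                                   or entry["verdict_at_high"] != base_verdict)
        entry["max_abs_departure"] = np.nanmax(
            [abs(entry["pct_departure_low"]),
             abs(entry["pct_departure_high"])])
        rows.append(entry)
    df = pd.DataFrame(rows).sort_values(
        "max_abs_departure", ascending=False, ignore_index=True)
    return df


def scenario_yearly_icur(model, perspective: str = HEALTHCARE_SECTOR
                         ) -> pd.DataFrame:
    """Point estimate of the ICUR at each truncated horizon 1..n_cycles."""
    rows = []
    for horizon in range(1, model.n_cycles + 1):
        sol = model.solve(horizon=horizon)
        r = sol.cua[perspective]
        rows.append({"horizon": horizon, "delta_cost": r.delta_cost,
                     "delta_qalys": r.delta_qalys, "icur": r.icur,
                     "verdict": r.verdict})
    return pd.DataFrame(rows)


def scenario_override(model, overrides: dict[str, float],
                      perspective: str = HEALTHCARE_SECTOR):
    """Re-solve with named parameter overrides; returns the incremental
    result and its % change vs the base-case ICUR (signed convention)."""
    base = model.solve().cua[perspective]
    sol = model.solve(model.registry.with_overrides(overrides))
    r = sol.cua[perspective]
    pct = (100.0 * (r.icur - base.icur) / abs(base.icur)
           if np.isfinite(r.icur) and np.isfinite(base.icur)
           and base.icur != 0 else np.nan)
    return r, pct


def scenario_adherence(model, grid=(0.9, 0.8, 0.7, 0.6, 0.5, 0.4),
                       perspective: str = HEALTHCARE_SECTOR) -> pd.DataFrame:
    """Adherence lowered symmetrically for both cohorts over a grid."""
    rows = []
    for a in grid:
        r, pct = scenario_override(
            model, {"naive.adherence": a, "experienced.adherence": a},
            perspective=perspective)
        rows.append({"adherence": a, "delta_cost": r.delta_cost,
                     "delta_qalys": r.delta_qalys, "icur": r.icur,
                     "verdict": r.verdict, "pct_vs_base": pct})
    return pd.DataFrame(rows)


def scenario_remission(model, grid=(0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
                       perspective: str = HEALTHCARE_SECTOR) -> pd.DataFrame:
    """Recovery probability after relapse raised for both cohorts."""
    rows = []
    for p in grid:
        r, pct = scenario_override(
            model, {"naive.p_remission": p, "experienced.p_remission": p},
            perspective=perspective)
        rows.append({"p_remission": p, "delta_cost": r.delta_cost,
                     "delta_qalys": r.delta_qalys, "icur": r.icur,
                     "verdict": r.verdict, "pct_vs_base": pct})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ----------------------------------------------------------------------

@dataclass
class PSASampleSet:
    """Per-iteration (cost, QALY) pairs per strategy and perspective."""

    n_iter: int
    seed: int
    strategies: tuple[str, ...]
    costs: dict[tuple[str, str], np.ndarray]   # (strategy, perspective)
    qalys: dict[str, np.ndarray]
    n_resampled: int = 0

    def to_frame(self) -> pd.DataFrame:
        data = {"iteration": np.arange(self.n_iter)}
        for s in self.strategies:
            for p in PERSPECTIVES:
                data[f"cost_{s}_{p}"] = self.costs[(s, p)]
            data[f"qalys_{s}"] = self.qalys[s]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, seed: int = -1) -> "PSASampleSet":
        strategies = tuple(sorted({c[len("qalys_"):] for c in df.columns
                                   if c.startswith("qalys_")}))
        costs = {}
        qalys = {}
        for s in strategies:
            for p in PERSPECTIVES:
                costs[(s, p)] = df[f"cost_{s}_{p}"].to_numpy()
            qalys[s] = df[f"qalys_{s}"].to_numpy()
        return cls(n_iter=len(df), seed=seed, strategies=strategies,
                   costs=costs, qalys=qalys)


def run_psa(model, n_iter: int = 10000, seed: int = 0) -> PSASampleSet:
    """Monte Carlo simulation: one joint draw of all distributed
    parameters per iteration (fixed parameters at their base case),
    both strategies solved on the shared draw."""
    rng = np.random.default_rng(seed)
    draws = model.registry.sample_matrix(n_iter, rng)
    base = model.registry.point_values()
    strategies = (NEW, REF)
    costs = {(s, p): np.empty(n_iter) for s in strategies
             for p in PERSPECTIVES}
    qalys = {s: np.empty(n_iter) for s in strategies}
    n_resampled = 0
    for i in range(n_iter):
        values = dict(base)
        for name, col in draws.items():
            values[name] = float(col[i])
        while True:
            try:
                sol = model.solve(values)
                break
            except ValidationError:
                n_resampled += 1
                redraw = model.registry.sample_matrix(1, rng)
                values = dict(base)
                for name, col in redraw.items():
                    values[name] = float(col[0])
        for s in strategies:
            for p in PERSPECTIVES:
                costs[(s, p)][i] = sol.outcome(s, p).total_cost
            qalys[s][i] = sol.outcome(s, SOCIETAL).qalys
    return PSASampleSet(n_iter=n_iter, seed=seed, strategies=strategies,
                        costs=costs, qalys=qalys, n_resampled=n_resampled)


def default_wtp_grid(wtp_max: float = 99900.0, n_points: int = 1000
                     ) -> np.ndarray:
    """1000 equally spaced willingness-to-pay thresholds from €0."""
    return np.linspace(0.0, wtp_max, n_points)


def ceac(psa: PSASampleSet, wtp_grid=None,
         perspective: str = HEALTHCARE_SECTOR) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    CEAC(s, λ) is the fraction of iterations in which strategy ``s`` has
    the (strictly, for the new strategy) highest NMB at threshold λ; at
    λ = 0 this is the probability of having the lower cost.  Ties go to
    the comparator.
    """
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    wtp = np.asarray(wtp_grid, dtype=float)
    dq = psa.qalys[NEW] - psa.qalys[REF]
    dc = psa.costs[(NEW, perspective)] - psa.costs[(REF, perspective)]
    dnmb = wtp[:, None] * dq[None, :] - dc[None, :]
    p_new = (dnmb > 0).mean(axis=1)
    n_ties = int((dnmb == 0).sum())
    df = pd.DataFrame({"wtp": wtp, NEW: p_new, REF: 1.0 - p_new})
    df.attrs["n_ties"] = n_ties
    df.attrs["perspective"] = perspective
    return df


def ceaf(psa: PSASampleSet, wtp_grid=None,
         perspective: str = HEALTHCARE_SECTOR) -> pd.DataFrame:
    """Cost-effectiveness acceptability frontier: the strategy with the
    highest *expected* NMB at each threshold, with its CEAC value."""
    curves = ceac(psa, wtp_grid, perspective)
    wtp = curves["wtp"].to_numpy()
    mean_dq = float(np.mean(psa.qalys[NEW] - psa.qalys[REF]))
    mean_dc = float(np.mean(psa.costs[(NEW, perspective)]
                            - psa.costs[(REF, perspective)]))
    mean_dnmb = wtp * mean_dq - mean_dc
    optimal = np.where(mean_dnmb > 0, NEW, REF)
    prob = np.where(mean_dnmb > 0, curves[NEW], curves[REF])
    return pd.DataFrame({"wtp": wtp, "optimal": optimal,
                         "probability": prob})
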