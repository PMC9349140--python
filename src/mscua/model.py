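"""Model and results objects.

:class:`CostUtilityModel` wraps a parameter registry plus a model
structure; ``fit()`` solves the deterministic base case for both cohorts
and returns a :class:`CUAResults` carrying the traces, the discounted
cost/LYS/QALY outcomes under both perspectives, the incremental
comparison, and entry points to the sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass


import pandas as pd

from . import sensitivity as sa
from .distributions import ParameterRegistry
from .engine import (CohortTrace, aggregate_to_four_states, occupancy_summary,
                     run_cohort_trace)
from .errors import ValidationError
from .structure import ModelStructure
from .valuation import (CATEGORIES, HEALTHCARE_SECTOR, PERSPECTIVES, SOCIETAL,
                        CUAResult, EconOutcome, accrue_costs, compare_strategies,
                        compute_lys_qalys)

NEW_STRATEGY = "naive"          # teriflunomide started first-line
REF_STRATEGY = "experienced"    # teriflunomide after previous DMTs


@dataclass
class ModelSolution:
    """One deterministic solve: traces and outcomes for both strategies."""

    values: dict[str, float]
    traces: dict[str, CohortTrace]
    outcomes: dict[tuple[str, str], EconOutcome]  # (strategy, perspective)
    cua: dict[str, CUAResult]                     # by perspective

    def outcome(self, strategy: str, perspective: str) -> EconOutcome:
        return self.outcomes[(strategy, perspective)]


class CostUtilityModel:
    """Markov cohort cost-utility model of teriflunomide sequencing.

    Parameters
    ----------
    registry
        The parameter registry (point estimates + distributions).
    structure
        Wiring from registry names to the two cohort configurations.
    """

    def __init__(self, registry: ParameterRegistry,
                 structure: ModelStructure):
        self.registry = registry
        self.structure = structure
        # fail early if any structural reference is dangling
        structure.build(registry.point_values())

    # -- constructors --------------------------------------------------
    @classmethod
    def from_synthetic(cls, spec=None, seed: int = 0) -> "CostUtilityModel":
        from .synthetic import SyntheticScenarioSpec, generate_registry
        if spec is None:
            spec = SyntheticScenarioSpec(seed=seed)
        bundle = generate_registry(spec)
        return cls(bundle.registry, bundle.structure)

    @classmethod
    def from_files(cls, registry_path, structure_path,
                   mortality_path) -> "CostUtilityModel":
        from .engine import MortalityTable
        registry = ParameterRegistry.from_csv(registry_path)
        mortality = MortalityTable.from_csv(mortality_path)
        structure = ModelStructure.from_yaml(structure_path, mortality)
        return cls(registry, structure)

    # -- solving -------------------------------------------------------
    @property
    def n0(self) -> float:
        return self.structure.n0

    @property
    def n_cycles(self) -> int:
        return self.structure.n_cycles

    def solve(self, values: dict[str, float] | None = None,
              horizon: int | None = None) -> ModelSolution:
        """Deterministic solve at ``values`` (default: point estimates)."""
        if values is None:
            values = self.registry.point_values()
        horizon = horizon or self.n_cycles
        rate = self.structure.discount_rate(values)
        strategies = self.structure.build(values)
        traces, outcomes = {}, {}
        for name, strat in strategies.items():
            trace = run_cohort_trace(strat, n0=self.n0, n_cycles=horizon)
            traces[name] = trace
            by_cat, by_item = accrue_costs(
                trace, strat.cost_items, rate, wages=strat.wages,
                person_age=strat.demographics.entry_age_mean,
                adherence=strat.transitions.adherence,
            )
            lys, qalys = compute_lys_qalys(trace, strat.utilities, rate)
            for persp in PERSPECTIVES:
                outcomes[(name, persp)] = EconOutcome(
                    strategy=name, perspective=persp,
                    cost_by_category=dict(by_cat), lys=lys, qalys=qalys,
                    cost_by_item=dict(by_item),
                )
        cua = {
            persp: compare_strategies(outcomes[(NEW_STRATEGY, persp)],
                                      outcomes[(REF_STRATEGY, persp)])
            for persp in PERSPECTIVES
        }
        return ModelSolution(values=dict(values), traces=traces,
                             outcomes=outcomes, cua=cua)

    def fit(self) -> "CUAResults":
        """Solve the base case and return the results object."""
        return CUAResults(self, self.solve())


class CUAResults:
    """Base-case results with summary tables and sensitivity entry points."""

    def __init__(self, model: CostUtilityModel, solution: ModelSolution):
        self.model = model
        self.solution = solution

    # -- accessors -----------------------------------------------------
    @property
    def cua(self) -> dict[str, CUAResult]:
        return self.solution.cua

    def outcome(self, strategy: str, perspective: str = SOCIETAL) -> EconOutcome:
        return self.solution.outcome(strategy, perspective)

    def trace(self, strategy: str) -> CohortTrace:
        return self.solution.traces[strategy]

    # -- tables --------------------------------------------------------
    def occupancy_table(self, strategy: str) -> pd.DataFrame:
        """Mean (SD) compartment occupancy over the cycles."""
        return occupancy_summary(self.trace(strategy))

    def four_state_table(self, strategy: str) -> pd.DataFrame:
        return aggregate_to_four_states(self.trace(strategy))

    def cost_table(self) -> pd.DataFrame:
        """Per-item discounted cost per patient, with A/B/C block totals."""
        rows = []
        for strat in (NEW_STRATEGY, REF_STRATEGY):
            out = self.outcome(strat, SOCIETAL)
            for item, val in out.cost_by_item.items():
                rows.append({"strategy": strat, "item": item, "cost": val})
        df = pd.DataFrame(rows).pivot(index="item", columns="strategy",
                                      values="cost").fillna(0.0)
        blocks = {}
        for strat in (NEW_STRATEGY, REF_STRATEGY):
            cats = self.outcome(strat, SOCIETAL).cost_by_category
            blocks[strat] = {
                "Total (A) healthcare sector": cats[CATEGORIES[0]],
                "Total (B) out-of-pocket": cats[CATEGORIES[1]],
                "Total (C) time and informal care": cats[CATEGORIES[2]],
                "Overall (A + B + C)": sum(cats.values()),
            }
        totals = pd.DataFrame(blocks)
        totals.index.name = "item"
        return pd.concat([df, totals])

    def cua_table(self) -> pd.DataFrame:
        rows = []
        for persp in PERSPECTIVES:
            for strat in (REF_STRATEGY, NEW_STRATEGY):
                out = self.outcome(strat, persp)
                rows.append({
                    "perspective": persp, "strategy": strat,
                    "cost": out.total_cost, "lys": out.lys,
                    "qalys": out.qalys,
                })
            r = self.cua[persp]
            rows[-1].update({"delta_cost": r.delta_cost,
                             "delta_qalys": r.delta_qalys,
                             "icur": r.icur, "verdict": r.verdict})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable base-case summary."""
        lines = ["Cost-utility analysis -- base case",
                 "=" * 60,
                 f"cohorts: {self.model.n0:.0f} patients, "
                 f"{self.model.n_cycles} annual cycles, discount rate "
                 f"{self.model.structure.discount_rate(self.solution.values):.1%}",
                 ""]
        for persp in PERSPECTIVES:
            r = self.cua[persp]
            lines.append(f"[{persp}]")
            for strat in (REF_STRATEGY, NEW_STRATEGY):
                o = self.outcome(strat, persp)
                lines.append(
                    f"  {strat:<12} cost €{o.total_cost:>12,.2f}   "
                    f"LYS {o.lys:6.3f}   QALYs {o.qalys:6.3f}")
            icur = "undefined" if not r.icur_defined else f"€{r.icur:,.2f}/QALY"
            lines.append(
                f"  ΔC €{r.delta_cost:,.2f}   ΔQALYs {r.delta_qalys:+.3f}   "
                f"ICUR {icur}   [{r.verdict}]")
            lines.append("")
        return "\n".join(lines)

    # -- sensitivity analyses ------------------------------------------
    def run_owsa(self, perspective: str = HEALTHCARE_SECTOR) -> pd.DataFrame:
        return sa.run_owsa(self.model, perspective=perspective)

    def yearly_icur(self, perspective: str = HEALTHCARE_SECTOR) -> pd.DataFrame:
        return sa.scenario_yearly_icur(self.model, perspective=perspective)

    def scenario(self, overrides: dict[str, float],
                 perspective: str = HEALTHCARE_SECTOR):
        return sa.scenario_override(self.model, overrides,
                                    perspective=perspective)

    def run_psa(self, n_iter: int = 10000, seed: int = 0) -> "sa.PSASampleSet":
        return sa.run_psa(self.model, n_iter=n_iter, seed=seed)
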