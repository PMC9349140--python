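"""Model structure: the wiring between the parameter registry and the
cohort model.

The registry stores *numbers*; a :class:`ModelStructure` stores *where
each number goes*: which parameter drives each cohort's EDSS-based
relapse risk, which unit-cost and volume parameters feed each cost item,
which compartment or event each item attaches to, and the cohort
demographics.  ``build(values)`` resolves a name->value mapping (base
case points, a PSA draw, or an OWSA override) into fully-formed
:class:`~mscua.engine.StrategyConfig` objects ready to solve.

References inside templates are either a registry parameter name (str)
or a literal number, so the same structure serves deterministic and
probabilistic runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .engine import (CohortDemographics, MortalityTable, StrategyConfig,
                     TransitionParams)
from .errors import ValidationError
from .valuation import CostItem, UtilityParams, WageParams



def resolve(ref, values: dict[str, float]) -> float:
    if isinstance(ref, str):
        try:
            return float(values[ref])
        except KeyError:
            raise ValidationError(f"unresolved parameter reference {ref!r}")
    return float(ref)


def relapse_probability_from_edss(edss: float, intercept: float,
                                  slope: float) -> float:
    """Logistic link from the EDSS disability score to the annual
    probability of clinical relapse."""
    return 1.0 / (1.0 + math.exp(-(intercept + slope * edss)))


@dataclass
class CostItemTemplate:
    """A cost item with its inputs expressed as registry references."""

    name: str
    category: str
    attach_to: str
    cost_ref: object = 0.0
    qty_ref: object = 1.0
    weight_ref: object = 1.0
    is_admin_tariff: bool = False
    sa_excluded: bool = False
    kind: str = "cost"
    role: str | None = None
    scales_with_adherence: bool = False

    def build(self, values) -> CostItem:
        return CostItem(
            name=self.name,
            category=self.category,
            attach_to=self.attach_to,
            unit_cost=resolve(self.cost_ref, values) if self.kind == "cost" else 0.0,
            quantity_per_cycle=resolve(self.qty_ref, values),
            weight=resolve(self.weight_ref, values),
            is_admin_tariff=self.is_admin_tariff,
            sa_excluded=self.sa_excluded,
            kind=self.kind,
            role=self.role,
            scales_with_adherence=self.scales_with_adherence,
        )


@dataclass
class CohortStructure:
    """Parameter wiring for one cohort."""

    name: str
    entry_age_ref: object
    entry_age_range: tuple[float, float]
    female_share_ref: object
    years_since_diagnosis: float
    edss_ref: object
    relapse_intercept: float
    relapse_slope: float
    remission_ref: object
    adherence_ref: object
    switch_ref: object = 0.0           # probability of switching given relapse
    switch_first_cycle: int = 2
    switch_share_refs: dict[str, object] = field(default_factory=dict)
    allows_switch: bool = False
    utility_refs: dict[str, object] = field(default_factory=dict)
    ae_disutility_ref: object = 0.0
    treatment_effect_multiplier: float = 0.7
    items: list[CostItemTemplate] = field(default_factory=list)

    def build(self, values, mortality: MortalityTable,
              wages: WageParams) -> StrategyConfig:
        demo = CohortDemographics(
            entry_age_mean=resolve(self.entry_age_ref, values),
            entry_age_range=tuple(self.entry_age_range),
            female_share=resolve(self.female_share_ref, values),
            years_since_diagnosis_mean=self.years_since_diagnosis,
        )
        p_relapse = relapse_probability_from_edss(
            resolve(self.edss_ref, values),
            self.relapse_intercept, self.relapse_slope,
        )
        shares = {drug: resolve(ref, values)
                  for drug, ref in self.switch_share_refs.items()}
        if shares:
            total = sum(shares.values())
            if total > 0:  # renormalise clamped OWSA replacements
                shares = {d: v / total for d, v in shares.items()}
        tp = TransitionParams(
            p_relapse_by_cycle=p_relapse,
            p_remission_given_relapse=resolve(self.remission_ref, values),
            p_switch_given_relapse=(resolve(self.switch_ref, values)
                                    if self.allows_switch else 0.0),
            switch_first_cycle=self.switch_first_cycle,
            switch_shares=shares,
            adherence=resolve(self.adherence_ref, values),
            treatment_effect_multiplier=self.treatment_effect_multiplier,
        )
        up = UtilityParams(
            utility_controlled=resolve(self.utility_refs["controlled"], values),
            utility_relapse=resolve(self.utility_refs["relapse"], values),
            utility_remission=resolve(self.utility_refs["remission"], values),
            ae_disutility=resolve(self.ae_disutility_ref, values),
        )
        items = [t.build(values) for t in self.items]
        return StrategyConfig(
            name=self.name, demographics=demo, transitions=tp,
            mortality=mortality, allows_switch=self.allows_switch,
            cost_items=items, utilities=up, wages=wages,
        )


@dataclass
class ModelStructure:
    """Full wiring for the two-strategy comparison."""

    cohorts: dict[str, CohortStructure]
    mortality: MortalityTable
    wage_refs: dict[str, object]
    discount_ref: object = "discount_rate"
    n0: float = 1000.0
    n_cycles: int = 7

    def build_wages(self, values) -> WageParams:
        return WageParams(
            gross_hourly_wage=resolve(self.wage_refs["gross"], values),
            take_home_hourly_wage=resolve(self.wage_refs["take_home"], values),
            homehelper_gross_wage=resolve(self.wage_refs["homehelper"], values),
        )

    def build(self, values) -> dict[str, StrategyConfig]:
        wages = self.build_wages(values)
        return {name: c.build(values, self.mortality, wages)
                for name, c in self.cohorts.items()}

    def discount_rate(self, values) -> float:
        return resolve(self.discount_ref, values)

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        def _item(t: CostItemTemplate) -> dict:
            return asdict(t)

        def _cohort(c: CohortStructure) -> dict:
            d = asdict(c)
            d["entry_age_range"] = list(c.entry_age_range)
            d["items"] = [_item(t) for t in c.items]
            return d

        return {
            "n0": self.n0,
            "n_cycles": self.n_cycles,
            "discount_ref": self.discount_ref,
            "wage_refs": dict(self.wage_refs),
            "cohorts": {name: _cohort(c) for name, c in self.cohorts.items()},
        }

    @classmethod
    def from_dict(cls, d: dict, mortality: MortalityTable) -> "ModelStructure":
        cohorts = {}
        for name, cd in d["cohorts"].items():
            cd = dict(cd)
            cd["entry_age_range"] = tuple(cd["entry_age_range"])
            cd["items"] = [CostItemTemplate(**it) for it in cd["items"]]
            cohorts[name] = CohortStructure(**cd)
        return cls(
            cohorts=cohorts,
            mortality=mortality,
            wage_refs=dict(d["wage_refs"]),
            discount_ref=d.get("discount_ref", "discount_rate"),
            n0=float(d.get("n0", 1000.0)),
            n_cycles=int(d.get("n_cycles", 7)),
        )

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path, mortality: MortalityTable) -> "ModelStructure":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh), mortality)
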