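"""Synthetic parameter registries at the study conditions.

The full analysis is driven by a 721-parameter registry (438 assigned a
theoretical probability distribution, 283 fixed).  Only a subset of those
values is printed in the main text of the study this package models
(remission probability 20%, switch probability 10% from the second cycle,
100% adherence, 3% discounting, 1000-patient cohorts, 7 annual cycles,
entry ages 33/37, female shares 78.71%/77.08%, the five switch-destination
DMTs); the remainder lives in a supplementary workbook.  This module
generates complete, internally consistent registries that (a) carry the
printed values exactly, (b) reproduce the registry's *statistical
structure* -- beta for probabilities and utilities, Dirichlet for the
switch split, gamma for resource volumes and EDSS scores, normal for
non-drug unit costs, fixed for drug prices and posology -- and (c) are
loosely calibrated so that cost-category shares and outcome magnitudes
resemble the published base case.  They are synthetic stand-ins, not a
transcription of the supplementary values.

Relapse risk is a logistic function of a gamma-distributed EDSS score, so
one-way sensitivity analysis over EDSS is exercisable.  All-cause
mortality is a Gompertz-like table by age and sex, ages 25-60.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .distributions import ParameterRegistry, ParameterSpec
from .engine import MortalityTable
from .errors import UnspecifiedInputError, ValidationError
from .structure import CohortStructure, CostItemTemplate, ModelStructure
from .valuation import (HEALTHCARE_SECTOR, OUT_OF_POCKET,
                        TIME_AND_INFORMAL_CARE)

COHORTS = ("naive", "experienced")
SWITCH_DMTS = ("alemtuzumab", "cladribine", "fingolimod", "natalizumab",
               "ocrelizumab")
INFUSION_DMTS = ("alemtuzumab", "natalizumab", "ocrelizumab")

#: logistic link EDSS -> annual relapse probability, calibrated once so the
#: cohort EDSS means (2.0 naïve, 3.0 experienced) map to relapse
#: probabilities (~0.305, ~0.325) that reproduce the published occupancy
#: structure (mean controlled ~29%/28% of the cohort over 7 cycles).
RELAPSE_INTERCEPT = -1.00866
RELAPSE_SLOPE = 0.09259


@dataclass
class SyntheticScenarioSpec:
    """Knobs of the synthetic registry generator.

    Defaults are the study conditions; ``edss_mean`` drives the
    naïve/experienced relapse-probability gap through the logistic link.
    """

    seed: int = 0
    n_total_params: int = 721
    distributed_fraction: float = 438.0 / 721.0
    edss_mean: dict = field(default_factory=lambda: {
        "naive": 2.0, "experienced": 3.0})
    utility: dict = field(default_factory=lambda: {
        "naive": {"controlled": 0.80, "relapse": 0.43, "remission": 0.61},
        "experienced": {"controlled": 0.78, "relapse": 0.33,
                        "remission": 0.58}})
    teriflunomide_annual_price: float = 11700.0
    cost_scale: dict = field(default_factory=lambda: {
        HEALTHCARE_SECTOR: 1.0, OUT_OF_POCKET: 1.0,
        TIME_AND_INFORMAL_CARE: 1.0})
    dirichlet_precision: float = 100.0


@dataclass
class SyntheticBundle:
    registry: ParameterRegistry
    structure: ModelStructure
    spec: SyntheticScenarioSpec


def gompertz_mortality(ages=range(25, 61)) -> MortalityTable:
    """Synthetic all-cause mortality: exponential in age, constant sex
    ratio, anchored near Italian adult magnitudes (q ~ 4-9 per 10,000 in
    the 30s, females lower)."""
    rows = []
    for age in ages:
        q_m = 9.0e-4 * math.exp(0.085 * (age - 33))
        q_f = 4.0e-4 * math.exp(0.085 * (age - 33))
        rows.append({"age": age, "sex": "M", "p_death": min(q_m, 1.0)})
        rows.append({"age": age, "sex": "F", "p_death": min(q_f, 1.0)})
    return MortalityTable(pd.DataFrame(rows))


def _beta(name, point, cv, eligible=True):
    return ParameterSpec(name=name, point=point, family="BETA", cv=cv,
                         sa_eligible=eligible)


def _gamma(name, point, cv, eligible=True):
    return ParameterSpec(name=name, point=point, family="GAMMA", cv=cv,
                         sa_eligible=eligible)


def _normal(name, point, cv, eligible=True):
    return ParameterSpec(name=name, point=point, family="NORMAL", cv=cv,
                         sa_eligible=eligible)


def _fixed(name, point, rng=None, eligible=False):
    return ParameterSpec(name=name, point=point, family="FIXED", range=rng,
                         sa_eligible=eligible)


def _core_specs(spec: SyntheticScenarioSpec) -> list[ParameterSpec]:
    s: list[ParameterSpec] = []
    # transition structure -------------------------------------------------
    for c in COHORTS:
        s.append(_gamma(f"{c}.edss_score", spec.edss_mean[c], cv=0.2))
        s.append(_beta(f"{c}.p_remission", 0.20, cv=0.2))
    s.append(_beta("naive.p_switch", 0.10, cv=0.25))
    shares = dict(zip(SWITCH_DMTS, (0.15, 0.15, 0.25, 0.15, 0.30)))
    for drug, share in shares.items():
        s.append(ParameterSpec(
            name=f"naive.switch_share.{drug}", point=share,
            family="DIRICHLET", dirichlet_group="naive.switch_shares",
            dirichlet_precision=spec.dirichlet_precision))
    s.append(_fixed("naive.adherence", 1.0, rng=(0.4, 1.0), eligible=True))
    s.append(_fixed("experienced.adherence", 1.0, rng=(0.4, 1.0),
                    eligible=True))
    s.append(_fixed("naive.entry_age", 33.0, rng=(25.0, 49.0), eligible=True))
    s.append(_fixed("experienced.entry_age", 37.0, rng=(25.0, 48.0),
                    eligible=True))
    s.append(_fixed("naive.female_share", 0.7871, rng=(0.5, 1.0),
                    eligible=True))
    s.append(_fixed("experienced.female_share", 0.7708, rng=(0.5, 1.0),
                    eligible=True))
    s.append(_fixed("discount_rate", 0.03, rng=(0.0, 0.05), eligible=True))
    # utilities ------------------------------------------------------------
    for c in COHORTS:
        u = spec.utility[c]
        s.append(_beta(f"{c}.utility.controlled", u["controlled"], cv=0.05))
        s.append(_beta(f"{c}.utility.relapse", u["relapse"], cv=0.10))
        s.append(_beta(f"{c}.utility.remission", u["remission"], cv=0.08))
        s.append(_beta(f"{c}.disutility.ae", 0.012, cv=0.30))
    # wages ----------------------------------------------------------------
    s.append(_normal("wage.gross_hourly", 34.7, cv=0.10))
    s.append(_normal("wage.take_home_hourly", 14.7, cv=0.10))
    s.append(_normal("wage.homehelper_hourly", 11.0, cv=0.10))
    # time volumes (hours per cycle) ---------------------------------------
    s.append(_gamma("naive.hours.work_loss", 29.349, cv=0.10))
    s.append(_gamma("experienced.hours.work_loss", 25.989, cv=0.10))
    s.append(_gamma("naive.hours.informal_care", 5.314, cv=0.25))
    s.append(_gamma("experienced.hours.informal_care", 11.897, cv=0.25))
    # drug prices and posology: fixed, excluded from sensitivity analysis --
    s.append(_fixed("price.teriflunomide.annual",
                    spec.teriflunomide_annual_price))
    dmt_prices = dict(zip(SWITCH_DMTS, (16000.0, 13000.0, 12500.0,
                                        14000.0, 15000.0)))
    for drug, price in dmt_prices.items():
        s.append(_fixed(f"price.{drug}.annual", price))
    for drug in ("teriflunomide",) + SWITCH_DMTS:
        s.append(_fixed(f"posology.{drug}.courses_per_year", 1.0))
    # administration tariffs (infusion DMTs; halved at costing time) --------
    s.append(_normal("cost.admin.alemtuzumab", 1100.0, cv=0.10))
    s.append(_normal("cost.admin.natalizumab", 1000.0, cv=0.10))
    s.append(_normal("cost.admin.ocrelizumab", 1200.0, cv=0.10))
    # shared unit costs ------------------------------------------------------
    k = spec.cost_scale
    unit_costs = {
        "cost.pretx_assessment": (113.34, k[HEALTHCARE_SECTOR]),
        "cost.liver_test": (9.0, k[HEALTHCARE_SECTOR]),
        "cost.ae_mgmt": (10.0, k[HEALTHCARE_SECTOR]),
        "cost.switch_pretx": (20.0, k[HEALTHCARE_SECTOR]),
        "cost.switch_ontx": (60.0, k[HEALTHCARE_SECTOR]),
        "cost.premedication": (70.0, k[HEALTHCARE_SECTOR]),
        "cost.postmedication": (60.0, k[HEALTHCARE_SECTOR]),
        "cost.followup_visit": (255.0, k[HEALTHCARE_SECTOR]),
        "cost.relapse_mgmt": (900.0, k[HEALTHCARE_SECTOR]),
        "cost.post_relapse_fu": (900.0, k[HEALTHCARE_SECTOR]),
        "cost.mobility_aid_pub": (830.0, k[HEALTHCARE_SECTOR]),
        "cost.mobility_aid_oop": (490.0, k[OUT_OF_POCKET]),
        "cost.other_aid": (490.0, k[OUT_OF_POCKET]),
        "cost.transport_trip": (25.2, k[OUT_OF_POCKET]),
        "cost.parking": (9.0, k[OUT_OF_POCKET]),
        "cost.ae_otc": (0.06, k[OUT_OF_POCKET]),
    }
    for name, (point, scale) in unit_costs.items():
        s.append(_normal(name, point * scale, cv=0.10))
    # cohort-specific resource volumes (per cycle) ---------------------------
    volumes = {
        "liver_tests": (2.0, 2.0, 0.15),
        "ae_mgmt": (1.14, 0.96, 0.20),
        "followup_visits": (2.61, 2.02, 0.15),
        "relapse_mgmt": (1.0, 1.0, 0.20),
        "post_relapse_fu": (1.0, 1.0, 0.20),
        "mobility_aid_pub": (1.0, 1.96, 0.20),
        "mobility_aid_oop": (1.0, 1.94, 0.20),
        "other_aid": (1.0, 1.94, 0.20),
        "transport_trips": (30.0, 28.3, 0.10),
        "parking": (5.04, 5.05, 0.10),
        "ae_otc": (1.0, 1.15, 0.25),
    }
    for nm, (v_n, v_e, cv) in volumes.items():
        s.append(_gamma(f"qty.naive.{nm}", v_n, cv=cv))
        s.append(_gamma(f"qty.experienced.{nm}", v_e, cv=cv))
    # one-off switch procedures: unit volumes, fixed -------------------------
    for nm in ("switch_pretx", "premedication", "pretx_assessment"):
        s.append(_fixed(f"qty.{nm}", 1.0))
    s.append(_fixed("qty.switch_ontx", 2.0))
    s.append(_fixed("qty.postmedication", 1.0))
    return s


_PAD_ATTACH = ("alive", "state:RELAPSE", "state:CONTROLLED",
               "arm:TERIFLUNOMIDE", "state:REMISSION")


def _pad_specs_and_items(spec, n_dist_pad, n_fixed_pad, rng):
    """Micro resource items padding the registry to the requested counts.

    Distributed pads come in (gamma volume, normal unit cost) pairs; an
    odd remainder yields one gamma-volume item with a fixed unit cost.
    Fixed pads are posology-like fixed unit costs, alternately flagged
    eligible (with an OWSA range) and excluded.
    """
    specs, items = [], []
    n_pairs, odd = divmod(n_dist_pad, 2)
    for i in range(n_pairs + odd):
        cat = HEALTHCARE_SECTOR if i % 3 < 2 else OUT_OF_POCKET
        base = 1.2 if cat == HEALTHCARE_SECTOR else 0.5
        qty = float(rng.uniform(0.5, 2.0))
        specs.append(_gamma(f"qty.pad{i:03d}", qty, cv=0.2))
        last_odd = odd and i == n_pairs
        if last_odd:
            specs.append(_fixed(f"cost.pad{i:03d}", base))
            n_fixed_pad -= 1
        else:
            specs.append(_normal(f"cost.pad{i:03d}", base, cv=0.1))
        items.append(CostItemTemplate(
            name=f"pad.item{i:03d}", category=cat,
            attach_to=_PAD_ATTACH[i % len(_PAD_ATTACH)],
            cost_ref=f"cost.pad{i:03d}", qty_ref=f"qty.pad{i:03d}",
            sa_excluded=last_odd,
        ))
    for j in range(n_fixed_pad):
        cat = HEALTHCARE_SECTOR if j % 3 < 2 else OUT_OF_POCKET
        base = 0.6 if cat == HEALTHCARE_SECTOR else 0.25
        eligible = j % 2 == 0
        specs.append(_fixed(
            f"cost.fixpad{j:03d}", base,
            rng=(0.5 * base, 1.5 * base) if eligible else None,
            eligible=eligible))
        items.append(CostItemTemplate(
            name=f"pad.fixitem{j:03d}", category=cat,
            attach_to=_PAD_ATTACH[j % len(_PAD_ATTACH)],
            cost_ref=f"cost.fixpad{j:03d}", qty_ref=1.0,
            sa_excluded=not eligible,
        ))
    return specs, items


def _cohort_items(c: str) -> list[CostItemTemplate]:
    """Cost-item wiring shared by both cohorts (the experienced cohort
    never populates the switched arm, so its switch items accrue zero)."""
    A, B, C = HEALTHCARE_SECTOR, OUT_OF_POCKET, TIME_AND_INFORMAL_CARE
    T = CostItemTemplate
    items = [
        T("pretx_assessment", A, "event:entry",
          cost_ref="cost.pretx_assessment", qty_ref="qty.pretx_assessment"),
        T("teriflunomide", A, "arm:TERIFLUNOMIDE",
          cost_ref="price.teriflunomide.annual",
          qty_ref="posology.teriflunomide.courses_per_year",
          sa_excluded=True, scales_with_adherence=True),
        T("liver_monitoring", A, "arm:TERIFLUNOMIDE",
          cost_ref="cost.liver_test", qty_ref=f"qty.{c}.liver_tests"),
        T("ae_management", A, "arm:TERIFLUNOMIDE",
          cost_ref="cost.ae_mgmt", qty_ref=f"qty.{c}.ae_mgmt"),
        T("switch_pretx_assessment", A, "event:switch",
          cost_ref="cost.switch_pretx", qty_ref="qty.switch_pretx"),
        T("switch_ontx_assessment", A, "arm:SWITCHED_DMT",
          cost_ref="cost.switch_ontx", qty_ref="qty.switch_ontx"),
        T("premedication", A, "event:switch",
          cost_ref="cost.premedication", qty_ref="qty.premedication"),
        T("postmedication", A, "arm:SWITCHED_DMT",
          cost_ref="cost.postmedication", qty_ref="qty.postmedication"),
        T("followup_no_relapse", A, "state:CONTROLLED",
          cost_ref="cost.followup_visit", qty_ref=f"qty.{c}.followup_visits"),
        T("relapse_management", A, "event:relapse_onset",
          cost_ref="cost.relapse_mgmt", qty_ref=f"qty.{c}.relapse_mgmt"),
        T("post_relapse_followup", A, "event:remission_onset",
          cost_ref="cost.post_relapse_fu", qty_ref=f"qty.{c}.post_relapse_fu"),
        T("mobility_aids", A, "alive",
          cost_ref="cost.mobility_aid_pub", qty_ref=f"qty.{c}.mobility_aid_pub"),
        T("ae_management_oop", B, "arm:TERIFLUNOMIDE",
          cost_ref="cost.ae_otc", qty_ref=f"qty.{c}.ae_otc"),
        T("mobility_aids_oop", B, "alive",
          cost_ref="cost.mobility_aid_oop", qty_ref=f"qty.{c}.mobility_aid_oop"),
        T("other_aids", B, "alive",
          cost_ref="cost.other_aid", qty_ref=f"qty.{c}.other_aid"),
        T("transportation", B, "alive",
          cost_ref="cost.transport_trip", qty_ref=f"qty.{c}.transport_trips"),
        T("parking", B, "alive",
          cost_ref="cost.parking", qty_ref=f"qty.{c}.parking"),
        T("work_time_loss", C, "alive",
          qty_ref=f"{c}.hours.work_loss", kind="time", role="patient"),
        T("informal_care", C, "alive",
          qty_ref=f"{c}.hours.informal_care", kind="time", role="caregiver"),
    ]
    for drug in SWITCH_DMTS:
        items.append(T(
            f"dmt_{drug}", A, "arm:SWITCHED_DMT",
            cost_ref=f"price.{drug}.annual",
            qty_ref=f"posology.{drug}.courses_per_year",
            weight_ref=f"naive.switch_share.{drug}", sa_excluded=True))
    for drug in INFUSION_DMTS:
        items.append(T(
            f"admin_{drug}", A, "arm:SWITCHED_DMT",
            cost_ref=f"cost.admin.{drug}",
            qty_ref=f"posology.{drug}.courses_per_year",
            weight_ref=f"naive.switch_share.{drug}", is_admin_tariff=True))
    return items


def generate_registry(spec: SyntheticScenarioSpec | None = None) -> SyntheticBundle:
    """Build a complete synthetic registry + model structure.

    Deterministic under ``spec.seed``; the registry satisfies the count
    invariant ``distributed + fixed = total`` with the requested
    distributed fraction (the default reproduces 721 = 438 + 283).
    """
    spec = spec or SyntheticScenarioSpec()
    rng = np.random.default_rng(spec.seed)

    core = _core_specs(spec)
    n_dist_core = sum(1 for p in core if p.distributed)
    n_fixed_core = len(core) - n_dist_core
    n_dist_target = int(round(spec.n_total_params * spec.distributed_fraction))
    if not 0 <= n_dist_target <= spec.n_total_params:
        raise ValidationError("distributed_fraction must lie in [0, 1]")

    if n_dist_target < n_dist_core:
        # demote core distributed parameters to their point estimates
        demoted = 0
        for i, p in enumerate(core):
            if demoted >= n_dist_core - n_dist_target:
                break
            if p.distributed:
                core[i] = ParameterSpec(
                    name=p.name, point=p.point, family="FIXED",
                    sa_eligible=p.sa_eligible,
                )
                demoted += 1
        n_dist_core = sum(1 for p in core if p.distributed)
        n_fixed_core = len(core) - n_dist_core

    n_dist_pad = n_dist_target - n_dist_core
    n_fixed_pad = (spec.n_total_params - n_dist_target) - n_fixed_core
    if n_fixed_pad < 0 or spec.n_total_params < len(core):
        raise ValidationError(
            f"n_total_params={spec.n_total_params} too small for the "
            f"{len(core)} structural parameters"
        )
    pad_specs, pad_items = _pad_specs_and_items(spec, n_dist_pad,
                                                n_fixed_pad, rng)
    registry = ParameterRegistry(core + pad_specs)

    cohorts = {}
    for c in COHORTS:
        cohorts[c] = CohortStructure(
            name=c,
            entry_age_ref=f"{c}.entry_age",
            entry_age_range=(25.0, 49.0) if c == "naive" else (25.0, 48.0),
            female_share_ref=f"{c}.female_share",
            years_since_diagnosis=6.0 if c == "naive" else 11.0,
            edss_ref=f"{c}.edss_score",
            relapse_intercept=RELAPSE_INTERCEPT,
            relapse_slope=RELAPSE_SLOPE,
            remission_ref=f"{c}.p_remission",
            adherence_ref=f"{c}.adherence",
            switch_ref="naive.p_switch" if c == "naive" else 0.0,
            switch_first_cycle=2,
            switch_share_refs={d: f"naive.switch_share.{d}"
                               for d in SWITCH_DMTS},
            allows_switch=(c == "naive"),
            utility_refs={k: f"{c}.utility.{k}"
                          for k in ("controlled", "relapse", "remission")},
            ae_disutility_ref=f"{c}.disutility.ae",
            items=_cohort_items(c) + list(pad_items),
        )
    structure = ModelStructure(
        cohorts=cohorts, mortality=gompertz_mortality(),
        wage_refs={"gross": "wage.gross_hourly",
                   "take_home": "wage.take_home_hourly",
                   "homehelper": "wage.homehelper_hourly"},
        discount_ref="discount_rate", n0=1000.0, n_cycles=7,
    )
    return SyntheticBundle(registry=registry, structure=structure, spec=spec)


# ----------------------------------------------------------------------
# Main-text study inputs
# ----------------------------------------------------------------------

class _Unspecified:
    """Sentinel for study inputs that are not printed in the main text."""

    def __repr__(self):
        return "UNSPECIFIED"

    def __bool__(self):
        return False


UNSPECIFIED = _Unspecified()


@dataclass
class StudyInputs:
    """The study settings printed in the main text, field by field.

    Fields holding :data:`UNSPECIFIED` (relapse risks, utilities, unit
    costs, mortality) are only available from the study's supplementary
    workbook; :meth:`to_bundle` either fills them with the synthetic
    defaults or raises listing every unfilled field.
    """

    n0: int = 1000
    n_cycles: int = 7
    discount_rate: float = 0.03
    remission_probability: float = 0.20
    switch_probability: float = 0.10
    switch_first_cycle: int = 2
    adherence: float = 1.0
    psa_iterations: int = 10000
    entry_age: dict = field(default_factory=lambda: {
        "naive": (33.0, (25.0, 49.0)), "experienced": (37.0, (25.0, 48.0))})
    female_share: dict = field(default_factory=lambda: {
        "naive": 0.7871, "experienced": 0.7708})
    switch_dmts: tuple = SWITCH_DMTS
    relapse_probability: object = UNSPECIFIED
    utilities: object = UNSPECIFIED
    unit_costs: object = UNSPECIFIED
    mortality: object = UNSPECIFIED

    def switch_probability_at(self, cycle: int) -> float:
        """Effective switch probability in a given 1-based cycle."""
        return self.switch_probability if cycle >= self.switch_first_cycle \
            else 0.0

    def unspecified_fields(self) -> list[str]:
        return [f.name for f in fields(self)
                if getattr(self, f.name) is UNSPECIFIED]

    def to_bundle(self, seed: int = 0,
                  fill_synthetic: bool = True) -> SyntheticBundle:
        missing = self.unspecified_fields()
        if missing and not fill_synthetic:
            raise UnspecifiedInputError(
                "cannot solve: unfilled study inputs "
                + ", ".join(missing), errors=missing)
        bundle = generate_registry(SyntheticScenarioSpec(seed=seed))
        # stamp the printed values over the synthetic registry
        reg = bundle.registry
        reg["naive.p_remission"].point = self.remission_probability
        reg["experienced.p_remission"].point = self.remission_probability
        reg["naive.p_switch"].point = self.switch_probability
        for c in COHORTS:
            reg[f"{c}.adherence"].point = self.adherence
            reg[f"{c}.entry_age"].point = self.entry_age[c][0]
            reg[f"{c}.female_share"].point = self.female_share[c]
        reg["discount_rate"].point = self.discount_rate
        bundle.structure.n0 = float(self.n0)
        bundle.structure.n_cycles = self.n_cycles
        for c in COHORTS:
            bundle.structure.cohorts[c].switch_first_cycle = \
                self.switch_first_cycle
        return bundle


def study_inputs() -> StudyInputs:
    """The main-text study settings (see :class:`StudyInputs`)."""
    return StudyInputs()
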