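"""One-way, scenario and probabilistic sensitivity analyses."""

import numpy as np
import pandas as pd
import pytest

import mscua.sensitivity as sa
from mscua import (CostItem, CostUtilityModel, StrategyConfig, ValidationError,
                   WageParams, net_monetary_benefit)
from mscua.sensitivity import PSASampleSet
from mscua.valuation import HEALTHCARE_SECTOR, SOCIETAL


@pytest.fixture(scope="module")
def owsa_table(model):
    return sa.run_owsa(model, perspective=HEALTHCARE_SECTOR)


class TestOWSA:
    def test_drug_prices_and_posology_are_absent(self, owsa_table):
        names = set(owsa_table["parameter"])
        assert not any(n.startswith("price.") for n in names)
        assert not any(n.startswith("posology.") for n in names)

    def test_discount_rate_varied_to_its_range_limits(self, owsa_table):
        row = owsa_table.set_index("parameter").loc["discount_rate"]
        assert row["low"] == 0.0
        assert row["high"] == 0.05

    def test_null_variation_reproduces_base_icur(self, model):
        base = model.solve().cua[HEALTHCARE_SECTOR].icur
        r, pct = sa.scenario_override(
            model, {"naive.p_remission":
                    model.registry["naive.p_remission"].point})
        assert r.icur == pytest.approx(base, abs=1e-9)
        assert pct == pytest.approx(0.0, abs=1e-9)

    def test_departures_are_finite_and_sorted(self, owsa_table):
        dep = owsa_table["max_abs_departure"]
        assert (dep.to_numpy()[:-1] >= dep.to_numpy()[1:]).all()
        assert np.isfinite(owsa_table["icur_at_low"]).all()


class TestScenarios:
    def test_full_horizon_reproduces_base_case(self, model):
        yearly = sa.scenario_yearly_icur(model, HEALTHCARE_SECTOR)
        base = model.solve().cua[HEALTHCARE_SECTOR]
        last = yearly.iloc[-1]
        assert last["horizon"] == model.n_cycles
        assert last["delta_cost"] == pytest.approx(base.delta_cost)
        assert last["verdict"] == base.verdict

    def test_identical_strategies_have_zero_increments(self):
        """A registry in which both cohorts share every input yields
        ΔC = ΔQ = 0 at every horizon."""
        from mscua import generate_registry
        bundle = generate_registry()
        reg = bundle.registry
        values = reg.point_values()
        for name in list(values):
            twin = name.replace("experienced.", "naive.", 1).replace(
                "qty.experienced.", "qty.naive.", 1)
            if twin != name and twin in reg:
                values[name] = values[twin]
        values["naive.p_switch"] = 0.0  # align the switch structure too
        model = CostUtilityModel(bundle.registry, bundle.structure)
        sol = model.solve(values)
        assert sol.cua[SOCIETAL].delta_cost == pytest.approx(0.0, abs=1e-9)
        assert sol.cua[SOCIETAL].delta_qalys == pytest.approx(0.0, abs=1e-9)

    def test_remission_scenario_keeps_strong_dominance(self, model):
        df = sa.scenario_remission(model, grid=(0.9,),
                                   perspective=HEALTHCARE_SECTOR)
        assert df.iloc[0]["verdict"] == "STRONGLY_DOMINANT"

    def test_adherence_grid_includes_published_extremes(self, model):
        df = sa.scenario_adherence(model, perspective=HEALTHCARE_SECTOR)
        assert {0.9, 0.5, 0.4}.issubset(set(df["adherence"]))

    def test_adherence_toy_closed_form(self):
        """On a 1-cycle no-event cohort, the drug cost scales linearly with
        adherence: cost = price * adherence (full person-year accrual)."""
        from conftest import make_strategy
        from mscua import accrue_costs, run_cohort_trace
        strat = make_strategy(q=0.0, p_relapse=0.0, adherence=0.6)
        trace = run_cohort_trace(strat, n0=1000, n_cycles=1)
        drug = CostItem(name="drug", category=HEALTHCARE_SECTOR,
                        attach_to="arm:TERIFLUNOMIDE", unit_cost=1000.0,
                        scales_with_adherence=True)
        by_cat, _ = accrue_costs(trace, [drug], rate=0.0, adherence=0.6)
        assert by_cat[HEALTHCARE_SECTOR] == pytest.approx(600.0)

    def test_unknown_override_name_rejected(self, model):
        with pytest.raises(KeyError):
            sa.scenario_override(model, {"no.such.parameter": 1.0})


@pytest.fixture(scope="module")
def psa_small(model):
    return sa.run_psa(model, n_iter=150, seed=7)


class TestPSA:
    def test_seeded_determinism_is_bitwise(self, model, psa_small):
        again = sa.run_psa(model, n_iter=150, seed=7)
        for key in psa_small.costs:
            assert np.array_equal(psa_small.costs[key], again.costs[key])
        for s in psa_small.qalys:
            assert np.array_equal(psa_small.qalys[s], again.qalys[s])

    def test_mean_cost_near_base_case(self, model, psa_small):
        """Near-linearity: PSA mean cost within 3 Monte-Carlo standard
        errors of the deterministic base case."""
        base = model.solve()
        for s in ("naive", "experienced"):
            draws = psa_small.costs[(s, SOCIETAL)]
            mc_se = draws.std(ddof=1) / np.sqrt(len(draws))
            assert abs(draws.mean() - base.outcome(s, SOCIETAL).total_cost) \
                < 3 * mc_se + 1e-9

    def test_resample_fraction_below_one_percent(self, psa_small):
        assert psa_small.n_resampled < 0.01 * psa_small.n_iter + 1

    def test_sample_frame_round_trip(self, psa_small):
        df = psa_small.to_frame()
        back = PSASampleSet.from_frame(df)
        assert back.n_iter == psa_small.n_iter
        assert np.array_equal(back.qalys["naive"], psa_small.qalys["naive"])


def _toy_psa(dc, dq):
    n = len(dc)
    return PSASampleSet(
        n_iter=n, seed=0, strategies=("naive", "experienced"),
        costs={("naive", HEALTHCARE_SECTOR): np.asarray(dc, float),
               ("naive", SOCIETAL): np.asarray(dc, float),
               ("experienced", HEALTHCARE_SECTOR): np.zeros(n),
               ("experienced", SOCIETAL): np.zeros(n)},
        qalys={"naive": np.asarray(dq, float),
               "experienced": np.zeros(n)},
    )


class TestCEAC:
    def test_at_zero_wtp_equals_probability_of_lower_cost(self):
        rng = np.random.default_rng(0)
        dc = rng.normal(-100, 500, size=400)
        dq = rng.normal(0.3, 0.2, size=400)
        curves = sa.ceac(_toy_psa(dc, dq), wtp_grid=[0.0])
        assert curves.loc[0, "naive"] == pytest.approx(np.mean(dc < 0))

    def test_large_wtp_limit_is_probability_of_higher_qalys(self):
        rng = np.random.default_rng(1)
        dc = rng.normal(0, 500, size=400)
        dq = rng.normal(0.1, 0.3, size=400)
        curves = sa.ceac(_toy_psa(dc, dq), wtp_grid=[1e12])
        assert curves.loc[0, "naive"] == pytest.approx(np.mean(dq > 0))

    def test_probabilities_sum_to_one_and_stay_bounded(self, psa_small):
        curves = sa.ceac(psa_small, perspective=HEALTHCARE_SECTOR)
        probs = curves[["naive", "experienced"]]
        assert ((probs >= 0) & (probs <= 1)).all().all()
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_identical_strategies_resolve_ties_to_comparator(self):
        curves = sa.ceac(_toy_psa(np.zeros(50), np.zeros(50)),
                         wtp_grid=[0.0, 1e4])
        assert (curves["naive"] == 0.0).all()
        assert (curves["experienced"] == 1.0).all()


class TestCEAF:
    def test_frontier_is_expected_nmb_argmax(self, psa_small):
        wtp = sa.default_wtp_grid(50000, 51)
        frontier = sa.ceaf(psa_small, wtp, perspective=HEALTHCARE_SECTOR)
        for _, row in frontier.sample(10, random_state=0).iterrows():
            nmb = {}
            for s in ("naive", "experienced"):
                nmb[s] = np.mean([
                    net_monetary_benefit(row["wtp"], c, q)
                    for c, q in zip(psa_small.costs[(s, HEALTHCARE_SECTOR)],
                                    psa_small.qalys[s])])
            best = max(nmb, key=nmb.get)
            assert row["optimal"] == best

    def test_frontier_overlaps_winning_ceac(self, psa_small):
        """Wherever the frontier strategy also has CEAC > 0.5, the CEAF
        probability coincides with that strategy's CEAC."""
        wtp = sa.default_wtp_grid(99900, 200)
        curves = sa.ceac(psa_small, wtp, perspective=HEALTHCARE_SECTOR)
        frontier = sa.ceaf(psa_small, wtp, perspective=HEALTHCARE_SECTOR)
        checked = 0
        for i in range(len(frontier)):
            s = frontier.loc[i, "optimal"]
            if curves.loc[i, s] > 0.5:
                assert frontier.loc[i, "probability"] == curves.loc[i, s]
                checked += 1
        assert checked > 0

    def test_wtp_grid_shape(self):
        grid = sa.default_wtp_grid()
        assert len(grid) == 1000
        assert grid[0] == 0.0
        assert grid[-1] == 99900.0
        assert np.allclose(np.diff(grid), 100.0)
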