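import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("repro", derandomize=True)
hyp_settings.load_profile("repro")

from mscua import (CohortDemographics, CostUtilityModel, MortalityTable,
                   StrategyConfig, TransitionParams, UtilityParams,
                   WageParams, generate_registry)


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic registry at the study conditions (seed 0)."""
    return generate_registry()


@pytest.fixture(scope="session")
def model(bundle):
    return CostUtilityModel(bundle.registry, bundle.structure)


@pytest.fixture(scope="session")
def results(model):
    return model.fit()


def flat_mortality(q: float, ages=range(20, 80)) -> MortalityTable:
    rows = [{"age": a, "sex": s, "p_death": q}
            for a in ages for s in ("F", "M")]
    return MortalityTable(pd.DataFrame(rows))


@pytest.fixture
def demo():
    return CohortDemographics(entry_age_mean=33.0,
                              entry_age_range=(25.0, 49.0),
                              female_share=0.7871)


def make_strategy(q=0.0, p_relapse=0.0, p_remission=0.2, p_switch=0.0,
                  allows_switch=True, adherence=1.0, name="toy",
                  entry_age=33.0):
    """Minimal strategy for engine-level tests (no cost items)."""
    return StrategyConfig(
        name=name,
        demographics=CohortDemographics(
            entry_age_mean=entry_age, entry_age_range=(20.0, 60.0),
            female_share=0.5),
        transitions=TransitionParams(
            p_relapse_by_cycle=p_relapse,
            p_remission_given_relapse=p_remission,
            p_switch_given_relapse=p_switch,
            adherence=adherence),
        mortality=flat_mortality(q),
        allows_switch=allows_switch,
        utilities=UtilityParams(utility_controlled=1.0, utility_relapse=1.0,
                                utility_remission=1.0),
        wages=WageParams(gross_hourly_wage=20.0, take_home_hourly_wage=12.0,
                         homehelper_gross_wage=10.0),
    )
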