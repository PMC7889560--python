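import numpy as np
import pytest

from surrofrax import (
    FractureModel,
    HazardTable,
    RatioTable,
    RelativeRiskSpec,
    SexPair,
    SyntheticSpec,
    build_surrogate,
    default_banding,
    impute_mof_incidence,
    make_demo_pair,
)

BANDS = default_banding()


@pytest.fixture(scope="session")
def spec():
    return SyntheticSpec()


@pytest.fixture(scope="session")
def demo_pair(spec):
    return make_demo_pair(spec)


@pytest.fixture(scope="session")
def reference_model(demo_pair):
    return demo_pair[0]


@pytest.fixture(scope="session")
def surrogate_model(demo_pair):
    ref, idx_mort = demo_pair
    return build_surrogate(ref, idx_mort, "surrogate")


def hazard_pair(rates_male, rates_female, kind, bands=BANDS):
    return SexPair(
        male=HazardTable(sex="male", bands=bands, rate=np.asarray(rates_male), kind=kind),
        female=HazardTable(sex="female", bands=bands, rate=np.asarray(rates_female), kind=kind),
    )


def flat_model(hip=0.002, mof=0.006, mortality=0.02, name="flat", bands=BANDS):
    """Minimal valid model with age-constant rates, equal for both sexes."""
    n = len(bands)
    return FractureModel(
        name=name,
        hip_incidence=hazard_pair([hip] * n, [hip] * n, "hip_incidence", bands),
        mof_incidence=hazard_pair([mof] * n, [mof] * n, "mof_incidence", bands),
        mortality=hazard_pair([mortality] * n, [mortality] * n, "mortality", bands),
        risk_coefficients=RelativeRiskSpec.synthetic_default(),
    )


def random_hazard_pair(rng, kind, scale=0.01, bands=BANDS):
    n = len(bands)
    return hazard_pair(rng.uniform(0, scale, n), rng.uniform(0, scale, n), kind, bands)


def random_ratio_pair(rng, bands=BANDS):
    n = len(bands)
    return SexPair(
        male=RatioTable(sex="male", bands=bands, multiplier=rng.uniform(1, 6, n)),
        female=RatioTable(sex="female", bands=bands, multiplier=rng.uniform(1, 6, n)),
    )
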