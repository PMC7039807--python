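import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from pmburden import (
    DistributionSpec,
    Microenvironment,
    MicroenvironmentSpecs,
    ExposureProfile,
    PopulationInputs,
    ScenarioConfig,
    EffectEstimate,
)
from pmburden.distributions import point


NHAPS = {
    Microenvironment.RESIDENCE: 0.687,
    Microenvironment.OTHER_INDOOR: 0.182,
    Microenvironment.VEHICLE: 0.055,
    Microenvironment.OUTDOOR: 0.076,
}


@pytest.fixture
def nhaps():
    return dict(NHAPS)


@pytest.fixture
def national_population():
    return PopulationInputs(y0=0.01463, pop=166_516_716)


def point_mass_profile(c_out=10.0, f_inf=0.5, ig_res=0.0):
    """All-point-mass exposure profile; E_AG is exactly computable."""
    micro = {
        Microenvironment.RESIDENCE: MicroenvironmentSpecs(
            outdoor=point(c_out), infiltration=point(f_inf),
            ig_concentration=point(ig_res),
        ),
        Microenvironment.OTHER_INDOOR: MicroenvironmentSpecs(
            outdoor=point(c_out), infiltration=point(f_inf),
        ),
        Microenvironment.VEHICLE: MicroenvironmentSpecs(
            outdoor=point(c_out), infiltration=point(f_inf),
        ),
        Microenvironment.OUTDOOR: MicroenvironmentSpecs(
            ag_concentration=point(c_out),
        ),
    }
    return ExposureProfile(time_activity=dict(NHAPS), microenvironments=micro)


@pytest.fixture
def degenerate_config(national_population):
    """Point-mass national config: beta_AG = 0.00702/0.6 = 0.0117, E_AG = 5.38."""
    effect = EffectEstimate(
        beta=0.00702, ci_low=0.00702, ci_high=0.00702, sampling=point(0.00702)
    )
    return ScenarioConfig(
        population=national_population,
        effect=effect,
        exposure=point_mass_profile(),
        sum_ft=0.6,
        n_iterations=50,
        master_seed=7,
    )
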