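import pytest

from viscnet import KineticParams, StudyDesign, generate_cohort, simulate_tracer_kinetics


@pytest.fixture(scope="session")
def default_sim():
    """Noise-free simulation at the default calibrated rates, 3.7 MBq."""
    return simulate_tracer_kinetics(KineticParams(), dose_MBq=3.7)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Default design with jitter and measurement noise switched off."""
    return generate_cohort(StudyDesign(seed=7).noise_free())


@pytest.fixture(scope="session")
def default_cohort():
    """Default stochastic design (jitter + 5% measurement noise)."""
    return generate_cohort(StudyDesign(seed=11))
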