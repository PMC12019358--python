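import warnings

import pytest

from switchscope.synthetic import NoiseRates, SimConfig, generate_cohort

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", message=".*n_jobs value 1 overridden.*")


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free synthetic cohort: every planted record survives filtering."""
    cfg = SimConfig(
        n_patients=600,
        switch_probability=0.3,
        noise_rates=NoiseRates().all_zero(),
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_sim():
    """Default-noise synthetic cohort exercising every attrition filter."""
    return generate_cohort(SimConfig(n_patients=500, seed=1))
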