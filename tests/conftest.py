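import numpy as np
import pytest

from liftkin import biomech, config, pipeline, synth
from liftkin.frames import nominal_mounting


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """One subject, LL only, every random component off: draws equal the
    condition means and sensor streams are exact forward kinematics."""
    spec = synth.CohortSpec.noise_free(n_subjects=1, tasks=("LL",), seed=7)
    return synth.simulate_cohort(spec)


@pytest.fixture(scope="session")
def zero_noise_fmap(zero_noise_cohort):
    standing, sitting = next(iter(zero_noise_cohort.calibrations.values()))
    return biomech.functional_calibration(standing, sitting, nominal=nominal_mounting())


@pytest.fixture(scope="session")
def default_result():
    """Full default cohort (26 subjects, both tasks, realistic noise) run
    end-to-end once and shared across tests."""
    cfg = config.load_config({"seed": 1})
    return pipeline.run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
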