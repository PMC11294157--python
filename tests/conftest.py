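import warnings

import numpy as np
import pytest

import trunktrack as tt


@pytest.fixture
def box_markers():
    """Symmetric trunk box aligned with the laboratory axes."""
    return {
        "CLAV": np.array([50.0, 0.0, 100.0]),
        "XP": np.array([50.0, 0.0, 0.0]),
        "T1": np.array([-50.0, 0.0, 100.0]),
        "T10": np.array([-50.0, 0.0, 0.0]),
        "M-STRN": np.array([50.0, 0.0, 50.0]),
    }


@pytest.fixture(scope="session")
def rigid_cohort():
    """Noise-free, artifact-free cohort: every model should agree exactly."""
    return tt.generate_cohort(n=8, artifact=tt.ArtifactConfig.none(), seed=11)


@pytest.fixture(scope="session")
def rigid_table(rigid_cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, _ = tt.analyze_cohort(rigid_cohort, predicted_mse=None)
    return table


@pytest.fixture(scope="session")
def noisy_trial_pair():
    """Static + noisy DVJ trial of one female subject, with ground truth."""
    template = tt.SubjectTemplate.default(sex="F")
    static, _ = tt.generate_trial(
        template, tt.MotionProfile.static(), tt.ArtifactConfig.none(), rng=1)
    dvj, truth = tt.generate_trial(
        template, tt.MotionProfile.dvj(peak_flexion_deg=45.0),
        tt.ArtifactConfig(noise_sigma_mm=0.5, sta_amplitude_mm=0.0,
                          bra_shift_mm=0.0), rng=3)
    return template, static, dvj, truth
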