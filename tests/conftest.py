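import numpy as np
import pytest

from aosdetect.config import PipelineConfig
from aosdetect.io import PatientMeta
from aosdetect.simulate import (
    BeatTemplateParams,
    HemodynamicCouplings,
    simulate_recording,
)


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def control_params():
    """Median beat-template parameters of the no-stenosis group."""
    return BeatTemplateParams()


@pytest.fixture(scope="session")
def aos_params():
    """Median beat-template parameters of the stenosis group."""
    return BeatTemplateParams(
        dap=75.0, pp=84.0, t_peak=0.20, t_max_up=0.075, lvet=0.345,
        notch_depth=44.0, dicrotic_wave_amp=5.0,
    )


@pytest.fixture(scope="session")
def control_meta():
    return PatientMeta(patient_id="ctl", age=73, sex="male",
                       height_cm=176, weight_kg=83, label="noAoS")


@pytest.fixture(scope="session")
def aos_meta():
    return PatientMeta(patient_id="aos", age=78, sex="female",
                       height_cm=170, weight_kg=76, label="AoS")


@pytest.fixture(scope="session")
def control_recording(control_params):
    """A 240-s noisy control recording with its ground-truth beat log."""
    return simulate_recording(control_params, HemodynamicCouplings(),
                              duration=240.0, seed=101, patient_id="ctl")


@pytest.fixture(scope="session")
def aos_recording(aos_params):
    return simulate_recording(aos_params, HemodynamicCouplings(),
                              duration=240.0, seed=202, patient_id="aos")


def match_truth(onsets: np.ndarray, truth_onsets: np.ndarray, tol: float = 0.05):
    """Indices pairing detected onsets with their nearest ground-truth beat."""
    idx = np.clip(np.searchsorted(truth_onsets, onsets), 1, len(truth_onsets) - 1)
    nearer = np.where(
        np.abs(truth_onsets[idx] - onsets) < np.abs(truth_onsets[idx - 1] - onsets),
        idx, idx - 1,
    )
    ok = np.abs(truth_onsets[nearer] - onsets) < tol
    return nearer, ok
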