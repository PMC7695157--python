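import numpy as np
import pytest

import vigistate as vg


@pytest.fixture(scope="session")
def calib() -> vg.CalibrationProfile:
    """Calibration profile from a simulated eyes-closed alpha segment."""
    return vg.calibrate(vg.simulate_calibration_segment(30, seed=99))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240830)


def random_stage_sequence(
    rng: np.random.Generator, n_minutes: int = 4, p_artifact: float = 0.05
) -> vg.StageSequence:
    """Random per-second sequence over all seven stages with sparse artifacts."""
    scores = rng.integers(1, 8, size=n_minutes * 60)
    mask = rng.random(n_minutes * 60) < p_artifact
    if mask.all():
        mask[0] = False
    return vg.StageSequence(scores=scores, artifact_mask=mask)
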