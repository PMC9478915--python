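import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from eodtrack import Detection, ErrorCalibration


@pytest.fixture
def rng():
    return np.random.default_rng(20220902)


def make_detection(time_index, eodf, powers, step=3.0):
    """Detection on a regular time grid with the given power vector."""
    return Detection(time_index=time_index, time=time_index * step, eodf=eodf,
                     powers=np.asarray(powers, dtype=float))


def random_detections(rng, n, n_steps=8, n_electrodes=4, step=3.0,
                      band=(698.0, 703.0)):
    """Random detection set: at most one shared grid, arbitrary freq/powers."""
    dets = []
    for _ in range(n):
        dets.append(make_detection(
            int(rng.integers(0, n_steps)),
            float(rng.uniform(*band)),
            rng.uniform(-90.0, -50.0, size=n_electrodes),
            step=step,
        ))
    dets.sort(key=lambda d: (d.time, d.eodf))
    return dets


def random_calibration(rng, m=25):
    return ErrorCalibration(np.sort(rng.uniform(0.0, 2.5, size=m)))


@pytest.fixture
def two_fish_detections():
    """Two well-separated synthetic frequency traces over 6 time steps.

    Fish A at ~700 Hz strongest on electrode 0, fish B at ~702 Hz strongest
    on electrode 3.
    """
    dets = []
    for i in range(6):
        dets.append(make_detection(i, 700.0 + 0.02 * i, [-50, -70, -80, -90]))
        dets.append(make_detection(i, 702.0 - 0.02 * i, [-90, -80, -70, -50]))
    return dets
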