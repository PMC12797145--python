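import numpy as np
import pytest

from eegfmri.fmri_metrics import VolumeSeries
from eegfmri.synth import SimulationConfig, make_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def make_volume(series_by_voxel, grid=(4, 4, 4), tr=1.0, baseline=0.0,
                masks=None, fbv=None, fill_rng=None):
    """Tiny VolumeSeries helper: ``series_by_voxel`` maps (x, y, z) -> 1-D
    series; remaining voxels get baseline (plus optional noise)."""
    t = len(next(iter(series_by_voxel.values())))
    data = np.full((*grid, t), float(baseline))
    if fill_rng is not None:
        data += 0.01 * fill_rng.standard_normal(data.shape)
    for c, s in series_by_voxel.items():
        data[c] = np.asarray(s, dtype=float)
    return VolumeSeries(data=data, tr_seconds=tr, masks=masks or {}, fbv=fbv)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down cohort (shorter scan, fewer participants) for pipeline
    smoke tests; metric-relevant structure is unchanged."""
    return SimulationConfig(n_participants=4, n_volumes=26, eeg_duration_s=120.0,
                            master_seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return make_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-design cohort (20 participants x 7 networks) shared across
    tests that need the study geometry."""
    return make_cohort(SimulationConfig(master_seed=11))
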