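import numpy as np
import pytest

from rehoscope import BoldSeries, BrainMask, RoiBox, SimulationSpec

AFF3 = np.diag([3.0, 3.0, 3.0, 1.0])


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def full_mask():
    def _make(shape=(12, 12, 12)):
        return BrainMask(data=np.ones(shape, dtype=bool), affine=AFF3.copy())
    return _make


@pytest.fixture
def noise_bold(rng):
    """Factory for i.i.d. Gaussian BOLD series on a 3 mm grid."""
    def _make(shape=(12, 12, 12), t_len=60, tr=2.0, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        return BoldSeries(data=r.standard_normal(shape + (t_len,)),
                          affine=AFF3.copy(), tr=tr)
    return _make


@pytest.fixture
def tiny_spec():
    """A fast, small cohort spec with one planted deficit ROI."""
    return SimulationSpec(
        n_per_group=8, grid=(12, 12, 12), n_volumes=60,
        rois={"roi_a": RoiBox((2, 2, 2), (6, 6, 6)),
              "roi_b": RoiBox((7, 7, 7), (11, 11, 11))},
        coherence_control={"roi_a": 0.5, "roi_b": 0.3},
        coherence_patient={"roi_a": 0.2, "roi_b": 0.3},
        behav_corr={"bis_total": ("roi_a", -0.5)},
        gm_deficit_roi="roi_a",
        seed=7,
    )
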