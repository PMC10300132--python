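import numpy as np
import pytest

from froipipe import synthdata as synth
from froipipe.glm import DOG_HRF


@pytest.fixture(scope="session")
def stimset5():
    return synth.generate_stimulus_set(5, seed=42, image_size=64)


@pytest.fixture(scope="session")
def stimset30():
    return synth.generate_stimulus_set(30, seed=42, image_size=64)


def make_simple_truth(
    shape=(8, 8, 6),
    region_slice=(slice(2, 5), slice(2, 5), slice(1, 4)),
    amplitudes=None,
    noise_sd=0.0,
    drift_amplitude=0.0,
    block_jitter_sd=0.0,
    tr=1.0,
):
    """Minimal ground truth: one planted region on a small grid."""
    region = np.zeros(shape, dtype=bool)
    region[region_slice] = True
    if amplitudes is None:
        amplitudes = {"dog_body": 2.0}
    return synth.GroundTruth(
        shape=shape,
        affine=np.eye(4),
        regions={"planted": region},
        amplitudes={"planted": amplitudes},
        noise_sd=noise_sd,
        drift_amplitude=drift_amplitude,
        tr=tr,
        hrf=DOG_HRF,
        block_jitter_sd=block_jitter_sd,
        block_jitter_region="planted" if block_jitter_sd > 0 else None,
    )


@pytest.fixture()
def simple_truth():
    return make_simple_truth()


@pytest.fixture()
def small_design(stimset5):
    """One run, 6 conditions x 1 block, fixed 5-s baselines."""
    order = synth.randomize_block_order(list(synth.CONDITIONS), 1, seed=1)
    return synth.build_run_design(order, stimset5, seed=1, jitter_range=(5.0, 5.0))
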