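import pytest

from spcl.augment import AugmentConfig, make_augmenter
from spcl.pipeline import run_desk_experiment
from spcl.synthetic import generate_slide, make_class_library


@pytest.fixture(scope="session")
def library4():
    return make_class_library(4, seed=0)


@pytest.fixture(scope="session")
def small_slide(library4):
    """A 256 px slide with 6 contiguous regions and a white border."""
    return generate_slide(256, 256, 6, library4, seed=7, background_border=24)


@pytest.fixture(scope="session")
def tissue_slide(library4):
    """A slide with no background border (all tissue)."""
    return generate_slide(256, 256, 6, library4, seed=11)


def noop_augmenter(out_size=32):
    return make_augmenter(AugmentConfig(
        crop_scale_range=(1.0, 1.0), hflip_p=0, vflip_p=0,
        color_jitter=(0, 0, 0, 0), color_jitter_p=0, grayscale_p=0,
        blur_p=0, out_size=out_size, seed=0))


@pytest.fixture(scope="session")
def five_seed_runs():
    """The reference experiment on seeds 1-5, with the random-init control.

    Session-scoped: several end-to-end checks (recovery level, pretraining
    benefit) read from the same replicates.
    """
    return {seed: run_desk_experiment(seed, include_random_baseline=True)
            for seed in range(1, 6)}


@pytest.fixture(scope="session")
def desk_run(five_seed_runs):
    """One representative trained pipeline for downstream-analysis tests."""
    return five_seed_runs[1]
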