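"""Shared fixtures: scaled-down synthetic scenes used across the suite."""

import numpy as np
import pytest

import mitoloc as ml

#: Manual transfection gate for full-scale (512x512) synthetic cells: sits
#: between the untransfected noise-residual mode (~1.5e5) and the low tail
#: of the transfected lognormal (~5e5).
DEFAULT_GATE = 3e5
#: The same manual choice rescaled for the small test cells below.
SMALL_GATE = 1.2e5


def small_synth(**overrides) -> ml.SynthParams:
    """Small but fully featured scene parameters for fast unit tests."""
    base = dict(
        image_height=160,
        image_width=160,
        n_fields=2,
        cells_per_field=(2, 3),
        nucleus_radius_range=(7.0, 9.0),
        cell_radius_range=(22.0, 30.0),
        mito_filament_count=5,
        mito_filament_length=40,
        golgi_offset_px=3.0,
        golgi_thickness_px=5.0,
        seed=5,
    )
    base.update(overrides)
    return ml.SynthParams(**base)


def tiny_synth(**overrides) -> ml.SynthParams:
    """Smallest usable scene (for replicate-heavy studies)."""
    base = dict(
        image_height=128,
        image_width=128,
        n_fields=4,
        cells_per_field=(3, 4),
        nucleus_radius_range=(5.0, 7.0),
        cell_radius_range=(16.0, 20.0),
        mito_filament_count=4,
        mito_filament_length=30,
        golgi_offset_px=2.0,
        golgi_thickness_px=4.0,
        transfected_prob=1.0,
        seed=0,
    )
    base.update(overrides)
    return ml.SynthParams(**base)


NOISE_FREE = dict(shot_noise=False, read_noise_sd=0.0, background_plane_coeffs=(0.0, 0.0, 0.0))


def small_seg(**overrides) -> ml.SegmentationParams:
    # guidance blur scaled down with the smaller test cells
    base = dict(marker_gate_threshold=SMALL_GATE, guidance_smooth_sigma=4.0)
    base.update(overrides)
    return ml.SegmentationParams(**base)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_condition():
    """Two rendered small fields with truths (default noise)."""
    pairs, manifest = ml.generate_condition(small_synth(), "small")
    return pairs, manifest


@pytest.fixture(scope="session")
def small_condition_clean():
    """Noise-free, background-free version of the small condition."""
    pairs, manifest = ml.generate_condition(small_synth(**NOISE_FREE), "small_clean")
    return pairs, manifest
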