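"""Synthetic scene generator: validation, determinism, mask algebra, noise."""

import numpy as np
import pytest
from pydantic import ValidationError

import mitoloc as ml
from mitoloc.benchmark import reporter_mito_fraction
from mitoloc.synth import (
    background_plane,
    field_rng,
    render_clean_field,
    sample_cell_geometry,
    sample_field_truths,
)

from conftest import NOISE_FREE, small_synth


class TestParamValidation:
    def test_degenerate_nucleus_radius_rejected(self):
        with pytest.raises(ValidationError):
            small_synth(nucleus_radius_range=(0.0, 0.0))

    @pytest.mark.parametrize(
        "field,value",
        [
            ("misloc_fraction", 1.5),
            ("misloc_fraction", -0.1),
            ("transfected_prob", 2.0),
            ("image_height", 32),
            ("mito_filament_count", 0),
            ("cell_radius_range", (30.0, 20.0)),
        ],
    )
    def test_invariant_violations_rejected(self, field, value):
        with pytest.raises(ValidationError):
            small_synth(**{field: value})


class TestCellGeometry:
    def test_masks_satisfy_invariants(self, small_condition):
        for _field, truths in small_condition[0]:
            for t in truths:
                t.check_invariants()

    def test_nucleus_and_mito_disjoint_and_area_bounded(self):
        params = small_synth(seed=1)
        truth = sample_cell_geometry(params, field_rng(params, 0))
        assert int(np.count_nonzero(truth.nucleus_mask & truth.mito_mask)) == 0
        area = int(truth.cell_mask.sum())
        lo, hi = params.cell_radius_range
        # ellipse with axis ratio in [0.8, 0.95]
        assert 0.8 * np.pi * lo**2 * 0.9 <= area <= np.pi * hi**2 * 1.1

    def test_theta_zero_puts_no_reporter_mass_on_mito(self):
        params = small_synth(misloc_fraction=0.0, **NOISE_FREE)
        truths = sample_field_truths(params, field_rng(params, 0))
        clean = render_clean_field(truths, params)
        for t in truths:
            assert clean["reporter"][t.mito_mask].sum() == 0.0

    def test_crowded_field_raises_placement_error(self):
        params = small_synth(cells_per_field=(30, 30))
        with pytest.raises(ml.errors.PlacementError, match="field"):
            sample_field_truths(params, field_rng(params, 0), field_id="crowded")

    def test_distinct_cells_are_disjoint(self, small_condition):
        for _field, truths in small_condition[0]:
            count = np.zeros(truths[0].cell_mask.shape, dtype=int)
            for t in truths:
                count += t.cell_mask
            assert count.max() <= 1


class TestRenderField:
    def test_zero_cells_noise_off_equals_background(self):
        params = small_synth(
            shot_noise=False, read_noise_sd=0.0, background_plane_coeffs=(25.0, 4.0, 2.0)
        )
        field = ml.render_field([], params, field_rng(params, 0))
        bg = background_plane(params)
        for role in ml.CHANNEL_ORDER:
            np.testing.assert_array_equal(field.channels[role], bg)

    def test_theta_one_reporter_proportional_to_mito(self):
        params = small_synth(misloc_fraction=1.0, **NOISE_FREE)
        truths = sample_field_truths(params, field_rng(params, 0))
        field = ml.render_field(truths, params, field_rng(params, 0))
        for t in truths:
            rep = field.channels["reporter"][t.cell_mask]
            mito = field.channels["mito"][t.cell_mask]
            # both are flat on the mito mask and zero elsewhere in the cell
            ratio = rep[mito > 0] / mito[mito > 0]
            assert np.allclose(ratio, ratio[0])
            assert np.all(rep[mito == 0] == 0)

    def test_nuclei_channel_contains_no_cytoplasmic_signal(self, small_condition_clean):
        for field, truths in small_condition_clean[0]:
            nuc = field.channels["nuclei"]
            for t in truths:
                assert np.all(nuc[t.mito_mask | t.golgi_mask] == 0)

    def test_shot_noise_mean_converges_to_clean_image(self):
        """Monte-Carlo oracle: averaging repeated noisy renders recovers the
        expectation image to within 3 standard errors per pixel."""
        params = small_synth(
            image_height=64, image_width=64, cells_per_field=(1, 1),
            cell_radius_range=(18.0, 22.0), nucleus_radius_range=(6.0, 8.0),
            read_noise_sd=0.0,
        )
        truths = sample_field_truths(params, field_rng(params, 0))
        expect = render_clean_field(truths, params)["reporter"] + background_plane(params)
        n_rep = 400
        acc = np.zeros_like(expect)
        acc2 = np.zeros_like(expect)
        for k in range(n_rep):
            f = ml.render_field(truths, params, field_rng(params, k + 1))
            acc += f.channels["reporter"]
            acc2 += f.channels["reporter"] ** 2
        mean = acc / n_rep
        se = np.sqrt(np.maximum(acc2 / n_rep - mean**2, 1e-9) / n_rep)
        frac_outside = np.mean(np.abs(mean - expect) > 3 * se + 1e-9)
        assert frac_outside < 0.01


class TestGenerateCondition:
    def test_zero_fields_yields_empty_list_and_manifest(self):
        pairs, manifest = ml.generate_condition(small_synth(n_fields=0), "empty")
        assert pairs == []
        assert manifest["condition"] == "empty"
        assert manifest["n_cells"] == 0

    def test_same_seed_is_byte_identical(self):
        params = small_synth(seed=9)
        a, _ = ml.generate_condition(params, "rep")
        b, _ = ml.generate_condition(params, "rep")
        for (fa, ta), (fb, tb) in zip(a, b):
            for role in ml.CHANNEL_ORDER:
                np.testing.assert_array_equal(fa.channels[role], fb.channels[role])
            assert [t.theta for t in ta] == [t.theta for t in tb]

    def test_default_condition_yields_about_fifty_cells(self):
        """15 default fields of 3-4 cells emulate ~50 cells per condition."""
        params = ml.SynthParams(seed=2)
        total = 0
        for i in range(params.n_fields):
            total += len(sample_field_truths(params, field_rng(params, i)))
        assert 40 <= total <= 60


class TestSignalPartition:
    def test_mito_fraction_equals_theta(self):
        for theta in (0.0, 0.3, 0.7, 1.0):
            params = small_synth(misloc_fraction=theta, **NOISE_FREE)
            truths = sample_field_truths(params, field_rng(params, 0))
            clean = render_clean_field(truths, params)
            for t in truths:
                assert abs(reporter_mito_fraction(t, clean["reporter"]) - theta) <= 0.02

    def test_theta_coupling_is_monotone_in_expression(self):
        params = small_synth(theta_coupling=(0.1, 0.9), transfected_prob=1.0, n_fields=4)
        cells = []
        for i in range(params.n_fields):
            cells.extend(sample_field_truths(params, field_rng(params, i)))
        cells.sort(key=lambda t: t.expression_level)
        thetas = [t.theta for t in cells]
        assert thetas == sorted(thetas)
        assert all(0.1 <= th <= 0.9 for th in thetas)
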