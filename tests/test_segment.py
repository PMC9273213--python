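"""Nucleus detection, seeded propagation, transfection gating, pseudo-cell mask."""

import heapq
import math

import numpy as np
import pytest

import mitoloc as ml
from mitoloc.benchmark import segmentation_recovery
from mitoloc.errors import ConfigError, MitolocError, ShapeMismatchError
from mitoloc.pipeline import preprocess_field, quantify_field
from mitoloc.segment import (
    gate_transfected,
    make_pseudo_cell_mask,
    propagate_cell_masks,
    segment_nuclei,
)
from mitoloc.synth import field_rng, sample_field_truths

from conftest import NOISE_FREE, small_seg, small_synth, SMALL_GATE


class TestSegmentNuclei:
    def test_blank_image_yields_no_labels(self):
        out = segment_nuclei(np.zeros((64, 64)), small_seg())
        assert out.n_labels == 0

    def test_noise_free_field_recovers_all_nuclei_centroids(self):
        params = small_synth(**NOISE_FREE, cells_per_field=(3, 3), seed=21)
        truths = sample_field_truths(params, field_rng(params, 0))
        field = ml.render_field(truths, params, field_rng(params, 0))
        out = segment_nuclei(field.channels["nuclei"], small_seg())
        assert out.n_labels == len(truths)
        found = list(out.centroids().values())
        for t in truths:
            ty, tx = t.centroid
            best = min(math.hypot(ty - fy, tx - fx) for fy, fx in found)
            assert best <= 2.0

    def test_object_below_min_area_is_dropped(self):
        img = np.zeros((64, 64))
        img[30:33, 30:33] = 100.0  # 9 px << min area
        out = segment_nuclei(img, small_seg(nucleus_min_area=120))
        assert out.n_labels == 0


def _dijkstra_oracle(fg, gn, lam, seed_pixels):
    """Independent single-source shortest path over the 8-connected grid."""
    h, w = fg.shape
    dist = np.full((h, w), np.inf)
    heap = []
    for (r, c) in seed_pixels:
        dist[r, c] = 0.0
        heapq.heappush(heap, (0.0, r, c))
    while heap:
        d, r, c = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                nr, nc = r + dr, c + dc
                if not (0 <= nr < h and 0 <= nc < w and fg[nr, nc]):
                    continue
                step = math.sqrt(2) if dr and dc else 1.0
                nd = d + abs(gn[r, c] - gn[nr, nc]) + lam * step
                if nd < dist[nr, nc]:
                    dist[nr, nc] = nd
                    heapq.heappush(heap, (nd, nr, nc))
    return dist


class TestPropagation:
    def test_no_seeds_gives_empty_mask(self):
        out = propagate_cell_masks(
            ml.LabelMask.empty((32, 32)), np.ones((32, 32)), small_seg()
        )
        assert out.n_labels == 0

    def test_single_seed_claims_entire_uniform_foreground(self):
        seeds = np.zeros((32, 32), dtype=np.int32)
        seeds[16, 16] = 1
        params = small_seg(guidance_smooth_sigma=0.0, guidance_threshold=0.5)
        out = propagate_cell_masks(ml.LabelMask(seeds), np.ones((32, 32)), params)
        assert np.all(out.labels == 1)

    def test_two_point_seeds_split_at_euclidean_bisector(self):
        """Seeds in the same row on a flat image: assignment is nearest-seed
        by Euclidean distance, ties to the lower label."""
        h = w = 31
        seeds = np.zeros((h, w), dtype=np.int32)
        seeds[15, 10] = 1
        seeds[15, 20] = 2
        params = small_seg(guidance_smooth_sigma=0.0, guidance_threshold=0.5)
        out = propagate_cell_masks(ml.LabelMask(seeds), np.ones((h, w)), params)
        cols = np.arange(w)
        d1, d2 = np.abs(cols - 10), np.abs(cols - 20)
        expected_col = np.where(d1 < d2, 1, np.where(d2 < d1, 2, 1))
        np.testing.assert_array_equal(out.labels, np.tile(expected_col, (h, 1)))

    def test_matches_brute_force_shortest_path_oracle(self, rng):
        h = w = 40
        gn_img = rng.uniform(0, 1, (h, w))
        fg = np.ones((h, w), dtype=bool)
        fg[rng.uniform(size=(h, w)) < 0.1] = False
        seeds = np.zeros((h, w), dtype=np.int32)
        seed_px = {1: (8, 8), 2: (30, 25), 3: (12, 33)}
        for lab, (r, c) in seed_px.items():
            seeds[r, c] = lab
            fg[r, c] = True
        lam = 0.05
        params = small_seg(
            guidance_smooth_sigma=0.0, guidance_threshold=0.5, propagation_lambda=lam
        )
        guide = np.where(fg, 1.0 + gn_img, 0.0)
        span = guide.max() - guide.min()
        gn = (guide - guide.min()) / span
        out = propagate_cell_masks(ml.LabelMask(seeds), guide, params)

        dists = {lab: _dijkstra_oracle(fg, gn, lam, [px]) for lab, px in seed_px.items()}
        labs = sorted(dists)
        stacked = np.stack([dists[lab] for lab in labs])
        for r in range(h):
            for c in range(w):
                if not fg[r, c]:
                    assert out.labels[r, c] == 0
                    continue
                vals = stacked[:, r, c]
                if not np.isfinite(vals).any():
                    assert out.labels[r, c] == 0
                    continue
                got = out.labels[r, c]
                assert got in labs
                # assigned label must achieve the minimum (within float slack)
                assert dists[got][r, c] <= vals.min() + 1e-9

    def test_cell_masks_disjoint_and_contain_their_seed(self, small_condition):
        field, _truths = small_condition[0][0]
        imgs = preprocess_field(field, ml.PreprocessParams())
        nuclei = segment_nuclei(imgs["nuclei"], small_seg())
        cells = propagate_cell_masks(nuclei, imgs["mito"], small_seg())
        for lab in nuclei.label_ids:
            assert np.all(cells.labels[nuclei.labels == lab] == lab)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeMismatchError):
            propagate_cell_masks(
                ml.LabelMask.empty((16, 16)), np.ones((8, 8)), small_seg()
            )


class TestGating:
    def _labels_and_marker(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[2:8, 2:8] = 1
        labels[12:18, 12:18] = 2
        marker = np.zeros((20, 20))
        marker[2:8, 2:8] = 5.0
        marker[12:18, 12:18] = 1.0
        return ml.LabelMask(labels), marker

    def test_zero_threshold_selects_every_positive_cell(self):
        labels, marker = self._labels_and_marker()
        selected, integrated = gate_transfected(labels, marker, 0.0)
        assert sorted(selected) == [1, 2]
        assert integrated[1] == pytest.approx(5.0 * 36)

    def test_impossible_threshold_selects_nothing(self):
        labels, marker = self._labels_and_marker()
        selected, _ = gate_transfected(labels, marker, 1e9)
        assert selected == []

    def test_negative_threshold_rejected(self):
        labels, marker = self._labels_and_marker()
        with pytest.raises(MitolocError):
            gate_transfected(labels, marker, -1.0)

    def test_missing_threshold_is_config_error(self):
        labels, marker = self._labels_and_marker()
        with pytest.raises(ConfigError, match="marker_gate_threshold"):
            gate_transfected(labels, marker, None)

    def test_raising_threshold_never_adds_cells(self, rng):
        labels, marker = self._labels_and_marker()
        prev = None
        for thr in [0.0, 10.0, 50.0, 200.0, 1e4]:
            sel, _ = gate_transfected(labels, marker, thr)
            sel = set(sel)
            if prev is not None:
                assert sel <= prev
            prev = sel

    def test_bimodal_expression_gate_matches_truth_flags(self):
        """Gate at the manual threshold recovers the transfected flags of
        >= 95% of matched cells."""
        pairs, _ = ml.generate_condition(small_synth(n_fields=5, seed=17), "gate")
        hits = total = 0
        for field, truths in pairs:
            res = quantify_field(
                field, ml.PreprocessParams(), small_seg(), ml.ColocParams()
            )
            rec = segmentation_recovery(truths, res.cells)
            by_id = {t.cell_id: t for t in truths}
            for tid, (lab, _score) in rec.matches.items():
                total += 1
                hits += (res.integrated_marker[lab] > SMALL_GATE) == by_id[tid].transfected
        assert total >= 8
        assert hits / total >= 0.95


class TestPseudoCellMask:
    def test_ring_is_closed_and_filled(self):
        """One-pixel ring on a 7x7 grid -> solid ring + interior."""
        mito = np.zeros((9, 9))
        mito[1:8, 1] = mito[1:8, 7] = 1.0
        mito[1, 1:8] = mito[7, 1:8] = 1.0
        cells = ml.LabelMask(np.ones((9, 9), dtype=np.int32))
        expected = np.zeros((9, 9), dtype=np.int32)
        expected[1:8, 1:8] = 1  # hand-executed closing + hole fill
        params = small_seg(mito_threshold=0.5, closing_radius_px=1)
        out, flags = make_pseudo_cell_mask(mito, cells, params)
        np.testing.assert_array_equal(out.labels, expected)
        assert flags == {}

    def test_solid_blob_is_unchanged(self):
        mito = np.zeros((20, 20))
        mito[5:15, 5:15] = 1.0
        cells = ml.LabelMask(np.ones((20, 20), dtype=np.int32))
        params = small_seg(mito_threshold=0.5, closing_radius_px=3)
        out, _ = make_pseudo_cell_mask(mito, cells, params)
        np.testing.assert_array_equal(out.labels == 1, mito > 0)

    def test_cell_without_mito_signal_is_flagged(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[2:8, 2:8] = 1
        labels[12:18, 12:18] = 2
        mito = np.zeros((20, 20))
        mito[3:7, 3:7] = 10.0  # only cell 1 has signal
        params = small_seg(mito_threshold=0.5, closing_radius_px=2)
        out, flags = make_pseudo_cell_mask(mito, ml.LabelMask(labels), params)
        assert 1 in out.label_ids and 2 not in out.label_ids
        assert flags == {2: "no_mito_mask"}

    def test_pseudo_mask_subset_of_parent_cell(self, small_condition):
        field, _ = small_condition[0][1]
        res = quantify_field(field, ml.PreprocessParams(), small_seg(), ml.ColocParams())
        for lab in res.pseudo.label_ids:
            assert np.all(res.cells.labels[res.pseudo.labels == lab] == lab)


class TestRecovery:
    def test_noise_free_fields_recover_all_cells(self):
        """Spot check at the study scale (512x512, default geometry): every
        cell of two noise-free fields is recovered at IoU >= 0.5."""
        params = ml.SynthParams(**NOISE_FREE, n_fields=2, seed=31)
        pairs, _ = ml.generate_condition(params, "clean")
        seg = ml.SegmentationParams(marker_gate_threshold=3e5)
        tot = hit = 0
        for field, truths in pairs:
            res = quantify_field(field, ml.PreprocessParams(), seg, ml.ColocParams())
            rec = segmentation_recovery(truths, res.cells, iou_threshold=0.5)
            tot += rec.n_true
            hit += rec.n_matched
        assert tot >= 5
        assert hit == tot
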