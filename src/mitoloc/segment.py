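"""Segmentation: nuclei, propagated cell bodies, transfection gate, pseudo-cell mask.

The stage mirrors a nucleus-seeded high-content workflow: nuclei are
detected in the DNA channel and used as seeds for a regularized propagation
that partitions the cytoplasmic foreground into per-cell masks; cells are
gated on integrated transfection-marker intensity; and within each gated
cell the mitochondrial stain is closed and hole-filled into one solid
"pseudo-cell" measurement region (the mitochondrial network being a good
proxy for cell area when it is spread throughout the cytoplasm).

Propagation assigns each foreground pixel to the seed with the smallest
accumulated cost along 8-connected paths, where one step from pixel p to
neighbor q costs ``|I(p) - I(q)| + lambda * steplength`` on the normalized
guidance image: pure image-geodesic growth at lambda=0, pure (chamfer)
Euclidean growth for a flat image. Ties go to the lower seed label.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import dilation, disk
from skimage.segmentation import relabel_sequential, watershed

from .config import SegmentationParams
from .containers import LabelMask
from .errors import ConfigError, MitolocError, ShapeMismatchError


def _resolve_threshold(image: np.ndarray, spec) -> Optional[float]:
    """Return the cut value, or None when the image carries no contrast."""
    if isinstance(spec, (int, float)):
        return float(spec)
    if image.max() <= image.min():
        return None
    return float(threshold_otsu(image))


def segment_nuclei(nuclei_image: np.ndarray, params: SegmentationParams) -> LabelMask:
    """Threshold, fill holes, size-filter and (optionally) declump nuclei."""
    img = np.asarray(nuclei_image, dtype=float)
    thr = _resolve_threshold(img, params.nucleus_threshold)
    if thr is None:
        return LabelMask.empty(img.shape)
    mask = img > thr
    if not mask.any():
        return LabelMask.empty(img.shape)
    mask = ndi.binary_fill_holes(mask)

    if params.declump:
        distance = ndi.distance_transform_edt(mask)
        peaks = peak_local_max(
            distance, min_distance=params.declump_min_distance, labels=mask
        )
        markers = np.zeros(img.shape, dtype=np.int32)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        labels = watershed(-distance, markers, mask=mask)
    else:
        labels, _ = ndi.label(mask)

    counts = np.bincount(labels.ravel())
    bad = np.flatnonzero(
        (counts < params.nucleus_min_area) | (counts > params.nucleus_max_area)
    )
    labels[np.isin(labels, bad[bad > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    return LabelMask(labels.astype(np.int32))


def _neighbor_edges(
    fg: np.ndarray, gn: np.ndarray, lam: float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """8-connected edges between foreground pixels with propagation costs."""
    h, w = fg.shape
    node = -np.ones((h, w), dtype=np.int64)
    node[fg] = np.arange(int(fg.sum()))
    rows, cols, weights = [], [], []
    offsets = ((0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2)), (1, -1, np.sqrt(2)))
    for dy, dx, steplen in offsets:
        src_y = slice(0, h - dy)
        dst_y = slice(dy, h)
        if dx >= 0:
            src_x, dst_x = slice(0, w - dx), slice(dx, w)
        else:
            src_x, dst_x = slice(-dx, w), slice(0, w + dx)
        src = (src_y, src_x)
        dst = (dst_y, dst_x)
        both = fg[src] & fg[dst]
        a = node[src][both]
        b = node[dst][both]
        wgt = np.abs(gn[src][both] - gn[dst][both]) + lam * steplen
        rows.append(a)
        cols.append(b)
        weights.append(wgt)
    return (
        np.concatenate(rows),
        np.concatenate(cols),
        np.concatenate(weights),
        node,
    )


def propagate_cell_masks(
    nuclei_labels: LabelMask,
    guidance_image: np.ndarray,
    params: SegmentationParams,
) -> LabelMask:
    """Grow per-cell masks from nucleus seeds over the guidance foreground.

    The guidance image is Gaussian-smoothed (``guidance_smooth_sigma``) so a
    filamentous cytoplasmic stain fills out to cell-body support, then
    thresholded (scaled Otsu or fixed value). Seed pixels are always
    foreground. Every labeled mask is connected and contains its seed; masks
    of distinct seeds are disjoint by construction.
    """
    guide = np.asarray(guidance_image, dtype=float)
    if guide.shape != nuclei_labels.shape:
        raise ShapeMismatchError(
            f"guidance image {guide.shape} vs nuclei labels {nuclei_labels.shape}"
        )
    seeds = nuclei_labels.labels
    seed_ids = nuclei_labels.label_ids
    if seed_ids.size == 0:
        return LabelMask.empty(guide.shape)

    if params.guidance_smooth_sigma > 0:
        guide = gaussian(guide, sigma=params.guidance_smooth_sigma, preserve_range=True)
    thr = _resolve_threshold(guide, params.guidance_threshold)
    if thr is None:
        fg = np.ones_like(guide, dtype=bool)
    else:
        if not isinstance(params.guidance_threshold, (int, float)):
            thr *= params.guidance_threshold_scale
        fg = guide > thr
    fg |= seeds > 0

    span = guide.max() - guide.min()
    gn = (guide - guide.min()) / span if span > 0 else np.zeros_like(guide)

    rows, cols, weights, node = _neighbor_edges(fg, gn, params.propagation_lambda)
    n_nodes = int(fg.sum())
    graph = coo_matrix((weights, (rows, cols)), shape=(n_nodes, n_nodes)).tocsr()

    dists = np.empty((seed_ids.size, n_nodes), dtype=float)
    for k, lab in enumerate(seed_ids):
        seed_nodes = node[seeds == lab]
        dists[k] = dijkstra(
            graph, directed=False, indices=seed_nodes, min_only=True
        )
    nearest = np.argmin(dists, axis=0)  # ties resolve to the lower label
    best = dists[nearest, np.arange(n_nodes)]

    out = np.zeros(guide.shape, dtype=np.int32)
    flat_assign = np.where(np.isfinite(best), seed_ids[nearest], 0)
    out[fg] = flat_assign
    return LabelMask(out)


def gate_transfected(
    cell_labels: LabelMask,
    marker_image: np.ndarray,
    threshold: Optional[float],
) -> Tuple[List[int], Dict[int, float]]:
    """Select cells whose integrated marker intensity exceeds the gate.

    Returns the selected label list and the integrated intensity of every
    cell (kept for downstream expression-correlation analysis). The gate is
    a manually chosen value; ``suggest_marker_threshold`` can propose one.
    """
    marker = np.asarray(marker_image, dtype=float)
    if marker.shape != cell_labels.shape:
        raise ShapeMismatchError(
            f"marker image {marker.shape} vs cell labels {cell_labels.shape}"
        )
    if threshold is None:
        raise ConfigError(
            "marker_gate_threshold is not set; the transfection gate is a manual "
            "choice (see suggest_marker_threshold / marker_intensity_histogram)"
        )
    if threshold < 0:
        raise MitolocError("marker gate threshold must be >= 0")

    ids = cell_labels.label_ids
    sums = ndi.sum_labels(marker, cell_labels.labels, index=ids)
    integrated = {int(lab): float(s) for lab, s in zip(ids, sums)}
    selected = [lab for lab, s in integrated.items() if s > threshold]
    return selected, integrated


def marker_intensity_histogram(
    integrated: Dict[int, float], bins: int = 32
) -> Tuple[np.ndarray, np.ndarray]:
    """Histogram of per-cell integrated marker intensities (gate-choosing aid)."""
    values = np.asarray(list(integrated.values()), dtype=float)
    return np.histogram(values, bins=bins)


def suggest_marker_threshold(integrated: Dict[int, float]) -> float:
    """Otsu cut on log-intensities: a starting point for the manual gate."""
    values = np.asarray(list(integrated.values()), dtype=float)
    if values.size < 2 or values.max() <= values.min():
        raise MitolocError("need at least two distinct integrated intensities")
    logs = np.log10(values + 1.0)
    return float(10 ** threshold_otsu(logs) - 1.0)


def make_pseudo_cell_mask(
    mito_image: np.ndarray,
    cell_labels: LabelMask,
    params: SegmentationParams,
    selected: Optional[Sequence[int]] = None,
) -> Tuple[LabelMask, Dict[int, str]]:
    """Close and fill the mitochondrial stain into solid per-cell regions.

    Within each (selected) cell label the thresholded mito signal is
    morphologically closed with ``closing_radius_px`` and hole-filled; the
    result is restricted to its parent cell mask. Cells without any mito
    foreground are flagged ``no_mito_mask`` instead of failing the run.
    """
    mito = np.asarray(mito_image, dtype=float)
    if mito.shape != cell_labels.shape:
        raise ShapeMismatchError(
            f"mito image {mito.shape} vs cell labels {cell_labels.shape}"
        )
    thr = _resolve_threshold(mito, params.mito_threshold)
    mito_fg = np.zeros(mito.shape, dtype=bool) if thr is None else mito > thr

    labels = cell_labels.labels
    ids = list(selected) if selected is not None else [int(i) for i in cell_labels.label_ids]
    out = np.zeros(mito.shape, dtype=np.int32)
    flags: Dict[int, str] = {}
    pad = params.closing_radius_px + 1
    slices = ndi.find_objects(labels)
    footprint = disk(params.closing_radius_px)

    for lab in sorted(ids):
        sl = slices[lab - 1] if lab - 1 < len(slices) else None
        if sl is None:
            flags[lab] = "no_mito_mask"
            continue
        ry = slice(max(0, sl[0].start - pad), min(mito.shape[0], sl[0].stop + pad))
        rx = slice(max(0, sl[1].start - pad), min(mito.shape[1], sl[1].stop + pad))
        cell_sub = labels[ry, rx] == lab
        src = mito_fg[ry, rx] & cell_sub
        if not src.any():
            flags[lab] = "no_mito_mask"
            continue
        # zero-padded binary closing: no spill beyond the dilation envelope
        closed = ndi.binary_closing(src, structure=footprint)
        filled = ndi.binary_fill_holes(closed)
        region = filled & cell_sub
        out[ry, rx][region] = lab
    return LabelMask(out), flags


def dilate_labels(mask: LabelMask, radius_px: int) -> LabelMask:
    """Binary-dilate each label independently (used for nucleus exclusion)."""
    if radius_px <= 0:
        return LabelMask(mask.labels.copy())
    out = np.zeros_like(mask.labels)
    fp = disk(radius_px)
    for lab in mask.label_ids:
        out[dilation(mask.labels == lab, fp)] = lab
    return LabelMask(out)
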