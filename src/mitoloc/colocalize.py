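"""Per-cell Pearson colocalization between reporter and mitochondrial channels.

The mislocalization metric is the plain Pearson correlation coefficient

    r = sum((x_i - xbar)(y_i - ybar)) / sqrt(sum((x_i - xbar)^2) sum((y_i - ybar)^2))

computed pixel-wise over each cell's measurement region: the pseudo-cell
mask minus the nucleus. No Costes-style thresholding variant is applied.
Cells whose region is too small, or where either channel has zero variance,
are flagged as excluded rather than dropped or imputed.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional

import numpy as np

from .containers import CellRecord, LabelMask
from .errors import ShapeMismatchError, UndefinedCorrelationError


def pearson_cc(x, y) -> float:
    """Pearson correlation of two equal-length intensity vectors.

    Raises :class:`UndefinedCorrelationError` when either vector is constant
    (the caller converts this into a ``zero_variance`` exclusion) and
    :class:`ShapeMismatchError` on length mismatch or fewer than 2 samples.
    """
    xv = np.asarray(x, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    if xv.size != yv.size:
        raise ShapeMismatchError(f"length mismatch: {xv.size} vs {yv.size}")
    if xv.size < 2:
        raise ShapeMismatchError("need at least 2 samples for a correlation")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        raise UndefinedCorrelationError("zero variance in at least one vector")
    return float((xc @ yc) / math.sqrt(sxx * syy))


def per_cell_colocalization(
    reporter_image: np.ndarray,
    mito_image: np.ndarray,
    pseudo_cell_mask: LabelMask,
    nucleus_labels: LabelMask,
    *,
    min_pixels: int = 50,
    integrated_marker: Optional[Dict[int, float]] = None,
    condition: str = "",
    field_id: str = "",
) -> List[CellRecord]:
    """One :class:`CellRecord` per label of the pseudo-cell mask.

    The measurement pixel set of a cell is its pseudo-cell region minus all
    nucleus pixels. Records failing ``min_pixels`` or with an undefined
    correlation are emitted with the corresponding exclusion flag.
    """
    rep = np.asarray(reporter_image, dtype=float)
    mito = np.asarray(mito_image, dtype=float)
    for name, arr in (("reporter", rep), ("mito", mito)):
        if arr.shape != pseudo_cell_mask.shape:
            raise ShapeMismatchError(
                f"{name} image {arr.shape} vs pseudo-cell mask {pseudo_cell_mask.shape}"
            )
    if nucleus_labels.shape != pseudo_cell_mask.shape:
        raise ShapeMismatchError("nucleus labels and pseudo-cell mask differ in shape")

    marker_of = integrated_marker or {}
    nucleus_fg = nucleus_labels.labels > 0
    records: List[CellRecord] = []
    for lab in sorted(int(i) for i in pseudo_cell_mask.label_ids):
        sel = (pseudo_cell_mask.labels == lab) & ~nucleus_fg
        n = int(sel.sum())
        marker_sum = float(marker_of.get(lab, float("nan")))
        mean_rep = float(rep[sel].mean()) if n else float("nan")
        mean_mito = float(mito[sel].mean()) if n else float("nan")
        common = dict(
            cell_id=lab,
            field_id=field_id,
            condition=condition,
            n_pixels=n,
            integrated_marker=marker_sum,
            mean_reporter=mean_rep,
            mean_mito=mean_mito,
        )
        if n < min_pixels:
            records.append(CellRecord(pcc=float("nan"), excluded="too_few_pixels", **common))
            continue
        try:
            r = pearson_cc(rep[sel], mito[sel])
        except UndefinedCorrelationError:
            records.append(CellRecord(pcc=float("nan"), excluded="zero_variance", **common))
            continue
        records.append(CellRecord(pcc=r, excluded="none", **common))
    return records
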