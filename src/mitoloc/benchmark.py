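"""Ground-truth-based validation utilities for the synthetic assay.

These helpers compare pipeline output against the generator's per-cell
truth: segmentation recovery (IoU matching) and direct PCC measurement on
the true masks, which serves both as the independent oracle for the
segmentation-based measurement and as a fast path for large replicate
studies (e.g. null-calibration of the group test).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .colocalize import pearson_cc
from .containers import CellRecord, FieldStack, LabelMask, SceneTruth
from .errors import UndefinedCorrelationError
from .preprocess import average_projection


def iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = int(np.count_nonzero(a & b))
    union = int(np.count_nonzero(a | b))
    return inter / union if union else 0.0


@dataclass
class RecoveryResult:
    n_true: int
    n_matched: int
    matches: Dict[int, Tuple[int, float]] = field(default_factory=dict)

    @property
    def fraction(self) -> float:
        return self.n_matched / self.n_true if self.n_true else float("nan")


def segmentation_recovery(
    truths: Sequence[SceneTruth],
    cell_labels: LabelMask,
    iou_threshold: float = 0.5,
) -> RecoveryResult:
    """Greedy one-to-one matching of true cells to predicted labels by IoU."""
    pred_ids = [int(i) for i in cell_labels.label_ids]
    pairs = []  # (iou, truth_idx, pred_label)
    for ti, t in enumerate(truths):
        overlapping = np.unique(cell_labels.labels[t.cell_mask])
        for lab in overlapping[overlapping > 0]:
            pairs.append((iou(t.cell_mask, cell_labels.labels == lab), ti, int(lab)))
    pairs.sort(reverse=True)
    used_t, used_p = set(), set()
    matches: Dict[int, Tuple[int, float]] = {}
    for score, ti, lab in pairs:
        if score < iou_threshold:
            break
        if ti in used_t or lab in used_p:
            continue
        used_t.add(ti)
        used_p.add(lab)
        matches[truths[ti].cell_id] = (lab, score)
    _ = pred_ids
    return RecoveryResult(n_true=len(truths), n_matched=len(matches), matches=matches)


def measure_with_truth_masks(
    field: FieldStack,
    truths: Sequence[SceneTruth],
    min_pixels: int = 20,
    transfected_only: bool = True,
) -> List[CellRecord]:
    """Per-cell PCC measured on ground-truth masks (cell minus nucleus).

    Bypasses segmentation entirely; the measurement region is the true cell
    mask outside the true nucleus, mirroring the pipeline's pseudo-cell
    convention on perfect masks.
    """
    rep = average_projection(field.channels["reporter"])
    mito = average_projection(field.channels["mito"])
    records: List[CellRecord] = []
    for t in truths:
        if transfected_only and not t.transfected:
            continue
        sel = t.cell_mask & ~t.nucleus_mask
        n = int(sel.sum())
        common = dict(
            cell_id=t.cell_id,
            field_id=field.field_id,
            condition=field.condition,
            n_pixels=n,
            integrated_marker=float(t.expression_level * t.cell_mask.sum()),
            mean_reporter=float(rep[sel].mean()) if n else float("nan"),
            mean_mito=float(mito[sel].mean()) if n else float("nan"),
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


def reporter_mito_fraction(truth: SceneTruth, reporter_clean: np.ndarray) -> float:
    """Fraction of a cell's reporter photon mass on its mitochondrial mask."""
    total = float(reporter_clean[truth.cell_mask].sum())
    on_mito = float(reporter_clean[truth.mito_mask].sum())
    return on_mito / total if total > 0 else float("nan")
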