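"""In-memory data model shared by all pipeline stages.

Pixel grid convention (used uniformly): row-major arrays, 0-based indices,
origin at the top-left corner. Channel roles are the four stains of the
mislocalization assay: ``nuclei`` (DNA stain), ``reporter`` (EGFP-tagged
tail-anchored protein), ``marker`` (transfection/expression marker) and
``mito`` (mitochondrial stain).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import ShapeMismatchError

#: Fixed channel order used when serializing multi-channel TIFFs.
CHANNEL_ORDER: Tuple[str, ...] = ("nuclei", "reporter", "marker", "mito")

#: Exclusion reasons a CellRecord may carry.
EXCLUSION_REASONS = (
    "none",
    "too_few_pixels",
    "zero_variance",
    "no_mito_mask",
    "not_transfected",
)


@dataclass
class FieldStack:
    """One imaged field: named channels, each a 2D plane or a (z, y, x) stack."""

    channels: Dict[str, np.ndarray]
    field_id: str
    condition: str = ""

    def __post_init__(self) -> None:
        shapes = {role: self.plane_shape(role) for role in self.channels}
        uniq = set(shapes.values())
        if len(uniq) > 1:
            raise ShapeMismatchError(
                f"channel planes of field {self.field_id!r} disagree in shape: {shapes}"
            )

    def plane_shape(self, role: str) -> Tuple[int, int]:
        arr = self.channels[role]
        if arr.ndim == 2:
            return arr.shape  # type: ignore[return-value]
        if arr.ndim == 3:
            return arr.shape[1:]  # type: ignore[return-value]
        raise ShapeMismatchError(
            f"channel {role!r} of field {self.field_id!r} has ndim={arr.ndim}, expected 2 or 3"
        )

    @property
    def shape(self) -> Tuple[int, int]:
        role = next(iter(self.channels))
        return self.plane_shape(role)

    def require_roles(self, roles=CHANNEL_ORDER) -> None:
        missing = [r for r in roles if r not in self.channels]
        if missing:
            raise ShapeMismatchError(
                f"field {self.field_id!r} is missing channel role(s) {missing}"
            )


@dataclass
class LabelMask:
    """Integer-labeled segmentation map; 0 is background."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ShapeMismatchError("label mask must be 2D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int32)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_labels(self) -> int:
        return int(self.label_ids.size)

    def mask_of(self, label: int) -> np.ndarray:
        return self.labels == label

    def pixel_counts(self) -> Dict[int, int]:
        ids, counts = np.unique(self.labels, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts) if i > 0}

    def centroids(self) -> Dict[int, Tuple[float, float]]:
        """(row, col) centroid per label."""
        out: Dict[int, Tuple[float, float]] = {}
        for lab in self.label_ids:
            rr, cc = np.nonzero(self.labels == lab)
            out[int(lab)] = (float(rr.mean()), float(cc.mean()))
        return out

    @classmethod
    def empty(cls, shape: Tuple[int, int]) -> "LabelMask":
        return cls(np.zeros(shape, dtype=np.int32))


@dataclass
class SceneTruth:
    """Ground truth for one simulated cell.

    Masks are full-field boolean arrays. Invariants: the nucleus lies inside
    the cell; mitochondrial and Golgi masks lie in the cytoplasm (cell minus
    nucleus) and are mutually disjoint; cells of one field never overlap.
    """

    cell_id: int
    nucleus_mask: np.ndarray
    cell_mask: np.ndarray
    mito_mask: np.ndarray
    golgi_mask: np.ndarray
    theta: float
    expression_level: float
    transfected: bool

    def check_invariants(self) -> None:
        if not np.all(self.cell_mask[self.nucleus_mask]):
            raise AssertionError(f"cell {self.cell_id}: nucleus escapes cell mask")
        cyto = self.cell_mask & ~self.nucleus_mask
        if not np.all(cyto[self.mito_mask]):
            raise AssertionError(f"cell {self.cell_id}: mito mask escapes cytoplasm")
        if not np.all(cyto[self.golgi_mask]):
            raise AssertionError(f"cell {self.cell_id}: golgi mask escapes cytoplasm")
        if np.any(self.mito_mask & self.golgi_mask):
            raise AssertionError(f"cell {self.cell_id}: mito and golgi masks overlap")
        if not 0.0 <= self.theta <= 1.0:
            raise AssertionError(f"cell {self.cell_id}: theta out of [0,1]")

    @property
    def centroid(self) -> Tuple[float, float]:
        rr, cc = np.nonzero(self.nucleus_mask)
        return (float(rr.mean()), float(cc.mean()))


@dataclass
class CellRecord:
    """Per-cell measurement row emitted by the colocalization stage."""

    cell_id: int
    field_id: str
    condition: str
    pcc: float  # NaN when excluded
    n_pixels: int
    integrated_marker: float
    mean_reporter: float
    mean_mito: float
    excluded: str = "none"

    def __post_init__(self) -> None:
        if self.excluded not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.excluded!r}")
        defined = self.excluded == "none"
        if defined and not math.isfinite(self.pcc):
            raise ValueError("non-excluded record must carry a finite PCC")
        if not defined and math.isfinite(self.pcc):
            raise ValueError("excluded record must not carry a PCC")

    @property
    def is_excluded(self) -> bool:
        return self.excluded != "none"


@dataclass
class ConditionSummary:
    """Condition-level mean PCC and its standard error."""

    condition: str
    n_cells: int
    mean_pcc: float
    sem_pcc: float  # NaN when n_cells < 2
    values: List[float] = field(default_factory=list)


@dataclass
class GroupComparison:
    """Two-group Mann-Whitney comparison of per-cell PCC distributions."""

    condition_a: str
    condition_b: str
    u_statistic: float
    p_two_sided: float
    method: str  # "exact" | "normal_tie_corrected"
    n_a: int
    n_b: int


@dataclass
class ExpressionCorrelation:
    """Rank correlation between marker expression and per-cell PCC."""

    rho: float
    p_value: float
    n: int
    method: str
    approximate: bool  # True when n is too small for a reliable p-value
    defined: bool = True
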