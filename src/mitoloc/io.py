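"""TIFF / CSV / YAML / JSON input-output.

Fields are written as one multi-channel TIFF per field in the fixed channel
order (nuclei, reporter, marker, mito), with a JSON description tag
recording axes, channel names, field id and condition. Label masks go to
16-bit TIFFs; tables are comma-separated UTF-8 CSVs with a header row and
'.' decimals.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .containers import (
    CHANNEL_ORDER,
    CellRecord,
    ConditionSummary,
    FieldStack,
    GroupComparison,
    LabelMask,
    SceneTruth,
)
from .errors import MitolocError, ShapeMismatchError

PER_CELL_COLUMNS = [
    "condition",
    "field_id",
    "cell_id",
    "pcc",
    "n_pixels",
    "integrated_marker",
    "mean_reporter",
    "mean_mito",
    "excluded",
]


def write_field(field: FieldStack, path: Union[str, Path]) -> Path:
    """Write a field as a multi-channel (optionally multi-z) TIFF."""
    field.require_roles()
    path = Path(path)
    arrs = [np.asarray(field.channels[r], dtype=np.float32) for r in CHANNEL_ORDER]
    ndim = {a.ndim for a in arrs}
    if len(ndim) != 1:
        raise ShapeMismatchError("all channels must share z-dimensionality")
    stack = np.stack(arrs)  # (C, Y, X) or (C, Z, Y, X)
    meta = {
        "axes": "CYX" if stack.ndim == 3 else "CZYX",
        "channels": list(CHANNEL_ORDER),
        "field_id": field.field_id,
        "condition": field.condition,
    }
    tifffile.imwrite(path, stack, photometric="minisblack", description=json.dumps(meta))
    return path


def _read_tiff(path: Path) -> Tuple[np.ndarray, dict]:
    if not path.exists():
        raise MitolocError(f"unreadable or missing file: {path}")
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description or ""
    meta: dict = {}
    if desc:
        try:
            parsed = json.loads(desc)
            if isinstance(parsed, dict):
                meta = parsed
        except (json.JSONDecodeError, TypeError):
            pass
    return arr, meta


def read_field(
    source: Union[str, Path, Dict[str, Union[str, Path]]],
    field_id: Optional[str] = None,
    condition: str = "",
) -> FieldStack:
    """Load a field from one multi-channel TIFF or a role -> path mapping."""
    if isinstance(source, (str, Path)):
        arr, meta = _read_tiff(Path(source))
        names = meta.get("channels", list(CHANNEL_ORDER))
        if arr.ndim not in (3, 4) or arr.shape[0] != len(names):
            raise ShapeMismatchError(
                f"{source}: expected a leading channel axis of size {len(names)}, "
                f"got array shape {arr.shape}"
            )
        channels = {name: np.asarray(arr[i], dtype=float) for i, name in enumerate(names)}
        fid = field_id or meta.get("field_id") or Path(source).stem
        cond = condition or meta.get("condition", "")
        fs = FieldStack(channels=channels, field_id=fid, condition=cond)
    else:
        channels = {}
        shapes = {}
        for role, p in source.items():
            arr, _ = _read_tiff(Path(p))
            channels[role] = np.asarray(arr, dtype=float)
            shapes[str(p)] = arr.shape[-2:]
        if len(set(shapes.values())) > 1:
            raise ShapeMismatchError(f"channel files disagree in shape: {shapes}")
        fid = field_id or "field"
        fs = FieldStack(channels=channels, field_id=fid, condition=condition)
    fs.require_roles()
    return fs


def write_label_mask(mask: LabelMask, path: Union[str, Path]) -> Path:
    if mask.labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise MitolocError("more than 65535 labels cannot go to a 16-bit TIFF")
    path = Path(path)
    tifffile.imwrite(path, mask.labels.astype(np.uint16))
    return path


def read_label_mask(path: Union[str, Path]) -> LabelMask:
    arr, _ = _read_tiff(Path(path))
    return LabelMask(arr.astype(np.int32))


def truths_to_dataframe(truths: Sequence[SceneTruth], field_id: str = "") -> pd.DataFrame:
    rows = []
    for t in truths:
        cy, cx = t.centroid
        rows.append(
            {
                "field_id": field_id,
                "cell_id": t.cell_id,
                "theta": t.theta,
                "expression_level": t.expression_level,
                "transfected": t.transfected,
                "cell_area_px": int(t.cell_mask.sum()),
                "nucleus_area_px": int(t.nucleus_mask.sum()),
                "mito_area_px": int(t.mito_mask.sum()),
                "golgi_area_px": int(t.golgi_mask.sum()),
                "nucleus_centroid_y": cy,
                "nucleus_centroid_x": cx,
            }
        )
    return pd.DataFrame(rows)


def records_to_dataframe(records: Sequence[CellRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=PER_CELL_COLUMNS if not rows else None)
    return df[PER_CELL_COLUMNS] if len(df) else pd.DataFrame(columns=PER_CELL_COLUMNS)


def summaries_to_dataframe(summaries: Sequence[ConditionSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "condition": s.condition,
                "n_cells": s.n_cells,
                "mean_pcc": s.mean_pcc,
                "sem_pcc": s.sem_pcc,
            }
            for s in summaries
        ]
    )


def comparisons_to_dataframe(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "condition_a": c.condition_a,
                "condition_b": c.condition_b,
                "u_statistic": c.u_statistic,
                "p_two_sided": c.p_two_sided,
                "method": c.method,
                "n_a": c.n_a,
                "n_b": c.n_b,
            }
            for c in comparisons
        ]
    )


def write_csv(df: pd.DataFrame, path: Union[str, Path]) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, encoding="utf-8")
    return path


def write_manifest(manifest: dict, path: Union[str, Path]) -> Path:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    else:
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def write_condition(
    outdir: Union[str, Path],
    fields_truths: Sequence[Tuple[FieldStack, List[SceneTruth]]],
    manifest: dict,
) -> Path:
    """Persist a simulated condition: TIFFs, truth CSV, mask TIFFs, manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_frames = []
    for field, truths in fields_truths:
        write_field(field, outdir / f"{field.field_id}.tif")
        truth_frames.append(truths_to_dataframe(truths, field.field_id))
        for kind in ("nucleus", "cell", "mito", "golgi"):
            label_img = np.zeros(field.shape, dtype=np.int32)
            for t in truths:
                label_img[getattr(t, f"{kind}_mask")] = t.cell_id
            write_label_mask(
                LabelMask(label_img), outdir / f"{field.field_id}_{kind}_labels.tif"
            )
    truth_df = (
        pd.concat(truth_frames, ignore_index=True) if truth_frames else truths_to_dataframe([])
    )
    write_csv(truth_df, outdir / "truth.csv")
    write_manifest(manifest, outdir / "manifest.yaml")
    return outdir
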