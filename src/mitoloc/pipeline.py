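"""End-to-end workflow: preprocess -> segment -> gate -> pseudo-cell -> PCC -> stats.

`quantify_field` turns one four-channel field into per-cell records;
`run_pipeline` executes a full multi-condition experiment from a
:class:`~mitoloc.config.PipelineConfig`, writing the per-cell, condition
and comparison CSV tables plus a JSON run manifest. All randomness derives
from the single config seed; outputs are byte-deterministic for fixed
config and inputs, and every excluded cell appears in the per-cell table
with its reason.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import __version__
from .colocalize import per_cell_colocalization
from .config import (
    ColocParams,
    PipelineConfig,
    PreprocessParams,
    SegmentationParams,
    config_hash,
)
from .containers import (
    CellRecord,
    ConditionSummary,
    FieldStack,
    GroupComparison,
    LabelMask,
    SceneTruth,
)
from .errors import EmptyConditionError, MitolocError
from .io import (
    comparisons_to_dataframe,
    read_field,
    records_to_dataframe,
    summaries_to_dataframe,
    write_csv,
    write_manifest,
)
from .preprocess import average_projection, correct_background
from .segment import (
    dilate_labels,
    gate_transfected,
    make_pseudo_cell_mask,
    propagate_cell_masks,
    segment_nuclei,
)
from .stats import compare_conditions, summarize_condition
from .synth import generate_condition

log = logging.getLogger("mitoloc")


@dataclass
class FieldResult:
    """Per-field quantification output with intermediate masks."""

    records: List[CellRecord]
    nuclei: LabelMask
    cells: LabelMask
    pseudo: LabelMask
    integrated_marker: Dict[int, float]
    selected: List[int]


def preprocess_field(field: FieldStack, params: PreprocessParams) -> Dict[str, np.ndarray]:
    """Average-project then background-correct every channel identically."""
    field.require_roles()
    out = {}
    for role, chan in field.channels.items():
        img = average_projection(chan)
        out[role] = correct_background(
            img,
            method=params.background_method,
            radius_px=params.background_radius_px,
            poly_order=params.background_poly_order,
        )
    return out


def quantify_field(
    field: FieldStack,
    preprocess_params: PreprocessParams,
    seg_params: SegmentationParams,
    coloc_params: ColocParams,
) -> FieldResult:
    """Quantify one field; emits a record (possibly excluded) for every cell."""
    imgs = preprocess_field(field, preprocess_params)

    nuclei = segment_nuclei(imgs["nuclei"], seg_params)
    cells = propagate_cell_masks(nuclei, imgs[seg_params.guidance_channel], seg_params)
    selected, integrated = gate_transfected(
        cells, imgs["marker"], seg_params.marker_gate_threshold
    )
    pseudo, mito_flags = make_pseudo_cell_mask(imgs["mito"], cells, seg_params, selected)

    nuc_for_exclusion = (
        dilate_labels(nuclei, seg_params.nucleus_dilation_px)
        if seg_params.nucleus_dilation_px
        else nuclei
    )
    records = per_cell_colocalization(
        imgs["reporter"],
        imgs["mito"],
        pseudo,
        nuc_for_exclusion,
        min_pixels=coloc_params.min_pixels,
        integrated_marker=integrated,
        condition=field.condition,
        field_id=field.field_id,
    )
    # cells that never reached the measurement stage still get a row
    covered = {r.cell_id for r in records}
    for lab in sorted(int(i) for i in cells.label_ids):
        if lab in covered:
            continue
        reason = "no_mito_mask" if mito_flags.get(lab) else "not_transfected"
        if lab in selected and lab not in mito_flags:
            reason = "no_mito_mask"
        records.append(
            CellRecord(
                cell_id=lab,
                field_id=field.field_id,
                condition=field.condition,
                pcc=float("nan"),
                n_pixels=0,
                integrated_marker=float(integrated.get(lab, float("nan"))),
                mean_reporter=float("nan"),
                mean_mito=float("nan"),
                excluded=reason,
            )
        )
    records.sort(key=lambda r: r.cell_id)
    return FieldResult(
        records=records,
        nuclei=nuclei,
        cells=cells,
        pseudo=pseudo,
        integrated_marker=integrated,
        selected=selected,
    )


@dataclass
class PipelineResult:
    records: List[CellRecord]
    summaries: List[ConditionSummary]
    comparisons: List[GroupComparison]
    config_hash: str
    output_dir: Optional[Path] = None
    truths: Dict[str, List[List[SceneTruth]]] = dc_field(default_factory=dict)
    field_results: Dict[str, List[FieldResult]] = dc_field(default_factory=dict)


def _condition_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(1000 + index,))
    return int(ss.generate_state(1)[0] % (2**31))


def load_condition_fields(
    config: PipelineConfig, index: int
) -> Tuple[List[FieldStack], List[List[SceneTruth]]]:
    """Materialize one condition's fields (simulate or read from disk)."""
    spec = config.conditions[index]
    if spec.synth is not None:
        params = spec.synth.model_copy(
            update={"seed": _condition_seed(config.seed, index)}
        )
        pairs, _manifest = generate_condition(params, spec.name)
        return [f for f, _t in pairs], [t for _f, t in pairs]
    fields = []
    for i, mapping in enumerate(spec.fields or []):
        if len(mapping) == 1 and next(iter(mapping.keys())) in ("file", "path"):
            src: object = next(iter(mapping.values()))
        else:
            src = mapping
        fields.append(
            read_field(src, field_id=f"{spec.name}_f{i:02d}", condition=spec.name)
        )
    if not fields:
        raise MitolocError(f"condition {spec.name!r} lists no input fields")
    return fields, []


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> PipelineResult:
    """Execute the full experiment described by ``config``."""
    chash = config_hash(config)
    outdir = Path(config.output_dir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(outdir / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)
    log.setLevel(config.log_level.upper())
    log.info("mitoloc %s run, config hash %s, seed %d", __version__, chash, config.seed)

    all_records: List[CellRecord] = []
    summaries: List[ConditionSummary] = []
    truths_by_cond: Dict[str, List[List[SceneTruth]]] = {}
    field_results: Dict[str, List[FieldResult]] = {}
    try:
        for idx, spec in enumerate(config.conditions):
            fields, truths = load_condition_fields(config, idx)
            truths_by_cond[spec.name] = truths
            cond_records: List[CellRecord] = []
            results: List[FieldResult] = []
            for fld in fields:
                res = quantify_field(
                    fld, config.preprocess, config.segmentation, config.colocalization
                )
                results.append(res)
                cond_records.extend(res.records)
            field_results[spec.name] = results
            n_ok = sum(not r.is_excluded for r in cond_records)
            log.info(
                "condition %s: %d cells, %d analyzable", spec.name, len(cond_records), n_ok
            )
            if n_ok == 0:
                raise EmptyConditionError(spec.name)
            summaries.append(summarize_condition(cond_records, spec.name))
            all_records.extend(cond_records)

        comparisons = [
            compare_conditions(
                sa, sb, exact_max_total=config.statistics.exact_max_total
            )
            for sa, sb in itertools.combinations(summaries, 2)
        ]

        if write_outputs:
            write_csv(records_to_dataframe(all_records), outdir / "per_cell.csv")
            write_csv(summaries_to_dataframe(summaries), outdir / "condition_summary.csv")
            write_csv(comparisons_to_dataframe(comparisons), outdir / "comparisons.csv")
            write_manifest(
                {
                    "package_version": __version__,
                    "config_hash": chash,
                    "seed": config.seed,
                    "conditions": [c.name for c in config.conditions],
                    "n_records": len(all_records),
                },
                outdir / "run_manifest.json",
            )
    finally:
        if write_outputs:
            log.removeHandler(handler)
            handler.close()

    return PipelineResult(
        records=all_records,
        summaries=summaries,
        comparisons=comparisons,
        config_hash=chash,
        output_dir=outdir if write_outputs else None,
        truths=truths_by_cond,
        field_results=field_results,
    )
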