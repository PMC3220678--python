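"""End-to-end orchestration: field in, per-cell traces and classes out.

The stages follow the retrospective design: register the live series to the
fixed reference, segment nuclei from the fixed nuclear stain, assign
cytoplasm on the first registered frame, erode the nuclei for measurement,
exclude edge cells, measure every frame, classify masks against a
stationary-cell control fit, and build per-cell kinetic traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from retrotrack.io import Field, IntensityImage, PipelineConfig, MEASUREMENT_COLUMNS
from retrotrack.mask_qc import (
    MaskClass,
    MaskStats,
    RobustFit,
    classify_masks,
    fit_robust_line,
    measure_mask_stats,
)
from retrotrack.quantify import CellTrace, build_traces
from retrotrack.registration import ShiftTransform, register_series
from retrotrack.segmentation import (
    LabelMap,
    assign_cytoplasm,
    erode_nuclei,
    exclude_edge_cells,
    segment_nuclei,
)

__all__ = ["FieldResult", "analyze_field", "control_fit_from_field", "measure_frames"]


@dataclass
class FieldResult:
    """Everything the pipeline derives from one field."""

    field: Field
    registered: list[IntensityImage]
    shifts: list[ShiftTransform]
    nuclei: LabelMap
    cytoplasm: LabelMap
    eroded_nuclei: LabelMap
    edge_excluded: dict[int, bool]
    measurements: pd.DataFrame
    traces: list[CellTrace] = dc_field(default_factory=list)
    classes: list[MaskClass] = dc_field(default_factory=list)
    fit: RobustFit | None = None

    def class_of(self) -> dict[int, str]:
        return {c.cell_id: c.label for c in self.classes}

    def retained_cell_ids(self) -> list[int]:
        return [int(k) for k in self.nuclei.cell_ids if not self.edge_excluded.get(int(k), False)]


def measure_frames(
    registered: list[IntensityImage],
    eroded_nuclei: LabelMap,
    cytoplasm: LabelMap,
    times_min: np.ndarray,
    keep_ids: list[int] | None = None,
) -> pd.DataFrame:
    """Per-(cell, frame) nuclear mean/s.d./area and cytoplasmic mean table."""
    rows = []
    cyto = cytoplasm.labels
    for j, frame in enumerate(registered):
        stats, flagged = measure_mask_stats(frame, eroded_nuclei)
        by_id: dict[int, MaskStats] = {s.cell_id: s for s in stats}
        ids = keep_ids if keep_ids is not None else [int(k) for k in eroded_nuclei.cell_ids]
        for k in ids:
            sel = (cyto == k) & frame.valid_mask
            cmean = float(frame.pixels[sel].mean()) if sel.any() else np.nan
            s = by_id.get(k)
            rows.append(
                {
                    "cell_id": k,
                    "frame": j + 1,
                    "t_min": float(times_min[j]),
                    "nuclear_mean": s.mean_fi if s else np.nan,
                    "nuclear_sd": s.sd_fi if s else np.nan,
                    "nuclear_area_px": s.area_px if s else 0,
                    "cyto_mean": cmean,
                    "valid": s is not None and np.isfinite(cmean),
                    "flag": "" if s else "too_few_valid_pixels",
                }
            )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def _segment_and_measure(field: Field, config: PipelineConfig):
    registered, shifts = register_series(field, config.max_shift)
    nuclei = segment_nuclei(
        field.fixed_nuclear,
        config.min_area_fraction,
        log_sigma=config.log_sigma,
        min_seed_distance=config.min_seed_distance,
    )
    cytoplasm, _empty = assign_cytoplasm(registered[0], nuclei, config.d)
    eroded, _extinct = erode_nuclei(nuclei, config.e)
    edge = exclude_edge_cells(nuclei, cytoplasm, registered)
    keep = [k for k, excl in edge.items() if not excl]
    meas = measure_frames(registered, eroded, cytoplasm, field.times_min, keep_ids=keep)
    return registered, shifts, nuclei, cytoplasm, eroded, edge, meas


def analyze_field(
    field: Field, config: PipelineConfig, control_fit: RobustFit | None = None
) -> FieldResult:
    """Run the full retrospective pipeline on one field.

    When ``control_fit`` (a robust s.d.-vs-mean fit from a cell-movement
    control population) is given, masks are classified matched vs
    mismatched/false from their first-frame statistics.
    """
    registered, shifts, nuclei, cytoplasm, eroded, edge, meas = _segment_and_measure(field, config)
    result = FieldResult(
        field=field,
        registered=registered,
        shifts=shifts,
        nuclei=nuclei,
        cytoplasm=cytoplasm,
        eroded_nuclei=eroded,
        edge_excluded=edge,
        measurements=meas,
    )
    result.traces = build_traces(meas, field.frame_interval_min)
    if control_fit is not None:
        keep = set(result.retained_cell_ids())
        stats, flagged = measure_mask_stats(registered[0], eroded)
        stats = [s for s in stats if s.cell_id in keep]
        flagged = [k for k in flagged if k in keep]
        result.classes = classify_masks(stats, control_fit, missing_ids=flagged)
        result.fit = control_fit
    return result


def control_first_frame_stats(field: Field, config: PipelineConfig) -> list[MaskStats]:
    """Stationary-cell (mean, s.d.) pairs from a cell-movement control field."""
    registered, _, nuclei, cytoplasm, eroded, edge, _ = _segment_and_measure(field, config)
    keep = {k for k, excl in edge.items() if not excl}
    stats, _ = measure_mask_stats(registered[0], eroded)
    return [s for s in stats if s.cell_id in keep]


def control_fit_from_field(
    fields: Field | list[Field], config: PipelineConfig
) -> RobustFit:
    """Build the classifier's robust fit from one or more control fields.

    Control populations may be pooled across fields/experiments; the fit
    accepts any population with at least 3 nuclei.
    """
    if isinstance(fields, Field):
        fields = [fields]
    stats: list[MaskStats] = []
    for f in fields:
        stats.extend(control_first_frame_stats(f, config))
    return fit_robust_line(stats, alpha=config.alpha)
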