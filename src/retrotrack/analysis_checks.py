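"""Reusable validation procedures built on the pipeline.

These reproduce, on synthetic fields with known ground truth, the method's
own validation experiments: pooling stationary-cell control statistics,
generating artificially mismatched masks and measuring how their CV and
mean respond to the mismatch, and quantifying how often shifted masks land
over cytoplasm.  Shared by the test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from retrotrack.io import Field, PipelineConfig
from retrotrack.mask_qc import MaskStats, make_mismatch
from retrotrack.pipeline import _segment_and_measure, control_first_frame_stats
from retrotrack.simgen import GroundTruth

__all__ = [
    "pooled_control_stats",
    "mismatched_mask_stats",
    "cv_vs_shift_profile",
]


def pooled_control_stats(fields: list[Field], config: PipelineConfig) -> list[MaskStats]:
    """First-frame (mean, s.d.) stats pooled over control fields."""
    stats: list[MaskStats] = []
    for f in fields:
        stats.extend(control_first_frame_stats(f, config))
    return stats


def _retained_masks(field: Field, config: PipelineConfig):
    """First registered frame plus the retained eroded nuclear masks."""
    registered, _, nuclei, _, eroded, edge, _ = _segment_and_measure(field, config)
    keep = {k for k, excl in edge.items() if not excl}
    masks = [
        (int(k), eroded.mask(int(k)))
        for k in eroded.cell_ids
        if int(k) in keep
    ]
    return registered[0], masks


def mismatched_mask_stats(
    field: Field,
    truth: GroundTruth,
    config: PipelineConfig,
    dr: int,
    dc: int,
    theta_deg: float = 0.0,
) -> tuple[list[MaskStats], np.ndarray]:
    """Stats of rigidly displaced nuclear masks plus their cytoplasm overlap.

    Each retained eroded mask is displaced by (dr, dc, theta); the returned
    fractions give, per mask, the share of its pixels lying over true
    cytoplasm (ground-truth cell territory minus the true nucleus), so
    callers can select masks with a required degree of mismatch.
    """
    frame, masks = _retained_masks(field, config)
    true_cyto = (truth.cell_labels > 0) & (truth.nuclei_labels == 0)
    stats: list[MaskStats] = []
    fracs: list[float] = []
    for cell_id, mask in masks:
        moved, _ = make_mismatch(mask, dr, dc, theta_deg)
        sel = moved & frame.valid_mask
        if sel.sum() < 2:
            continue
        vals = frame.pixels[sel]
        stats.append(MaskStats(cell_id, float(vals.mean()), float(vals.std(ddof=0)), int(sel.sum())))
        fracs.append(float((moved & true_cyto).sum() / moved.sum()))
    return stats, np.asarray(fracs)


def cv_vs_shift_profile(
    fields: list[Field],
    config: PipelineConfig,
    shift_levels: list[int],
    seed: int = 0,
) -> dict:
    """Mismatched-mask CV and intersected-mask stability versus shift size.

    For every retained mask and every shift magnitude, the mask is displaced
    in a random direction; the displaced ("mismatched") mask's CV and the
    intersection's ("shrunken" mask's) mean/CV are expressed relative to the
    undisplaced mask.  Returns per-level medians of the relative CV and a
    table of intersected-mask records restricted to intersections covering
    at least half the original area.
    """
    rng = np.random.default_rng(seed)
    items = []
    for field in fields:
        frame, masks = _retained_masks(field, config)
        for _, mask in masks:
            sel = mask & frame.valid_mask
            if sel.sum() < 2:
                continue
            vals = frame.pixels[sel]
            m0, sd0 = float(vals.mean()), float(vals.std(ddof=0))
            if m0 <= 0 or sd0 <= 0:
                continue
            items.append((frame, mask, m0, sd0))

    cv_rel_median = []
    inter_rows = []
    for s in shift_levels:
        cvs = []
        for frame, mask, m0, sd0 in items:
            ang = rng.uniform(0.0, 2 * np.pi)
            dr = int(round(s * np.sin(ang)))
            dc = int(round(s * np.cos(ang)))
            moved, inter = make_mismatch(mask, dr, dc)
            sel = moved & frame.valid_mask
            if sel.sum() >= 2:
                v = frame.pixels[sel]
                cvs.append((v.std(ddof=0) / v.mean()) / (sd0 / m0))
            isel = inter & frame.valid_mask
            if inter.sum() >= 0.5 * mask.sum() and isel.sum() >= 2:
                v = frame.pixels[isel]
                inter_rows.append(
                    {
                        "shift": s,
                        "area_fraction": inter.sum() / mask.sum(),
                        "mean_rel": v.mean() / m0,
                        "cv_rel": (v.std(ddof=0) / v.mean()) / (sd0 / m0),
                    }
                )
        cv_rel_median.append(float(np.median(cvs)))
    return {
        "cv_rel_median": np.asarray(cv_rel_median),
        "intersected": pd.DataFrame(inter_rows),
        "n_masks": len(items),
    }
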