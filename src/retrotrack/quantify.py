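"""Per-cell translocation descriptors and kinetic summaries.

Three descriptors quantify nuclear import per cell:

* **N:C ratio** — nuclear over cytoplasmic mean intensity, normalized to 1
  at time 0.  Informative about the fluorescence distribution within a cell
  but sensitive to cytoplasmic segmentation.
* **NA (nuclear accumulation)** — nuclear mean divided by the same nucleus's
  mean at time 0; normalizes away per-cell expression level and needs no
  cytoplasmic mask.
* **NI (nuclear increment)** — frame-to-frame change of the nuclear mean
  normalized by the first frame's mean, a direct proxy for import speed:
  ``dI_i = (I_i - I_{i-1}) / I_1`` for i = 2..n.

``difference_variation`` (|v1 - v2| / (v1 + v2)) compares two measurements
of the same quantity produced by two mask settings and is the tool for
judging which descriptor is more reliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CellTrace",
    "nc_ratio",
    "nuclear_accumulation",
    "nuclear_increment",
    "difference_variation",
    "build_traces",
    "call_responders",
    "time_to_max_speed",
    "summarize_population",
    "rank_correlation",
    "wilcoxon_signed_rank",
    "jarque_bera",
]


def nc_ratio(nuclear_mean: float, cytoplasmic_mean: float, baseline_ratio: float) -> float:
    """Nuclear:cytoplasmic mean-intensity ratio, normalized by the time-0 ratio."""
    if cytoplasmic_mean <= 0:
        raise ValueError("cytoplasmic mean must be positive")
    if baseline_ratio <= 0:
        raise ValueError("baseline ratio must be positive")
    return (nuclear_mean / cytoplasmic_mean) / baseline_ratio


def nuclear_accumulation(nuclear_mean_t: float, nuclear_mean_t0: float) -> float:
    """Nuclear mean at time t over the same nucleus's mean at time 0."""
    if nuclear_mean_t0 <= 0:
        raise ValueError("time-0 nuclear mean must be positive")
    return nuclear_mean_t / nuclear_mean_t0


def nuclear_increment(mean_i: float, mean_prev: float, mean_first: float) -> float:
    """Frame-to-frame nuclear mean change over the first frame's mean."""
    if mean_first <= 0:
        raise ValueError("first-frame nuclear mean must be positive")
    return (mean_i - mean_prev) / mean_first


def difference_variation(value1: float, value2: float) -> float:
    """Normalized disagreement |v1 - v2| / (v1 + v2), in [0, 1]."""
    if value1 < 0 or value2 < 0:
        raise ValueError("values must be non-negative")
    s = value1 + value2
    if s <= 0:
        raise ValueError("difference variation undefined for zero sum")
    return abs(value1 - value2) / s


@dataclass
class CellTrace:
    """Per-cell time series of the translocation descriptors.

    ``ni`` has length n - 1 (entry j is dI for the step ending at frame
    j + 2, 1-based).  ``raw_nc`` keeps the un-normalized N:C ratio used for
    responder calling.  ``na[0] == nc_ratio[0] == 1`` exactly by
    construction.
    """

    cell_id: int
    times_min: np.ndarray
    na: np.ndarray
    nc_ratio: np.ndarray
    ni: np.ndarray
    raw_nc: np.ndarray
    valid: bool = True
    flags: list[str] = dc_field(default_factory=list)
    responder: bool | None = None
    t_max_speed_min: float | None = None

    @property
    def n_frames(self) -> int:
        return len(self.times_min)


def build_traces(measurements: pd.DataFrame, frame_interval_min: float = 10.0) -> list[CellTrace]:
    """Assemble per-cell traces from a per-(cell, frame) measurement table.

    ``measurements`` needs columns ``cell_id, frame, t_min, nuclear_mean,
    cyto_mean``.  Cells with a non-positive baseline nuclear or cytoplasmic
    mean cannot be normalized and come back flagged invalid.
    """
    traces: list[CellTrace] = []
    for cid, grp in measurements.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        t = grp["t_min"].to_numpy(dtype=float)
        nmean = grp["nuclear_mean"].to_numpy(dtype=float)
        cmean = grp["cyto_mean"].to_numpy(dtype=float)
        flags: list[str] = []
        valid = True
        if nmean[0] <= 0 or not np.isfinite(nmean[0]):
            flags.append("nonpositive_baseline_nuclear_mean")
            valid = False
        if np.any(cmean <= 0) or not np.all(np.isfinite(cmean)):
            flags.append("nonpositive_cytoplasmic_mean")
            valid = False
        if valid:
            na = nmean / nmean[0]
            raw = nmean / cmean
            ncr = raw / raw[0]
            ni = np.diff(nmean) / nmean[0]
        else:
            n = len(t)
            na = np.full(n, np.nan)
            ncr = np.full(n, np.nan)
            raw = np.full(n, np.nan)
            ni = np.full(max(n - 1, 0), np.nan)
        traces.append(CellTrace(int(cid), t, na, ncr, ni, raw, valid=valid, flags=flags))
    return traces


def call_responders(
    pre_ratios: np.ndarray, post_ratios: np.ndarray
) -> tuple[np.ndarray, float]:
    """Responder call: end-point raw N:C ratio above the pre-treatment 95th pct.

    The threshold is the 95th percentile (linear interpolation between order
    statistics) of the *un-normalized* pre-treatment N:C ratios — by
    construction fewer than 5% of unstimulated cells exceed it.  Returns the
    boolean flags and the threshold.
    """
    pre = np.asarray(pre_ratios, dtype=float)
    post = np.asarray(post_ratios, dtype=float)
    pre = pre[np.isfinite(pre)]
    if pre.size < 20:
        warnings.warn(
            f"only {pre.size} pre-treatment cells; 95th percentile is unstable", stacklevel=2
        )
    if pre.size == 0:
        raise ValueError("no finite pre-treatment ratios")
    threshold = float(np.percentile(pre, 95.0))
    return post > threshold, threshold


def time_to_max_speed(trace: CellTrace, interval_min: float = 20.0) -> float:
    """Time (min) at which NI, recomputed on a coarser grid, is maximal.

    NI is noisier than NA, so the increment is evaluated over
    ``interval_min`` steps (default 20 min, i.e. every other frame for a
    10-min series) with the usual first-frame denominator.  The returned
    time labels the *end* of the winning interval; ties go to the earliest
    interval.  Returns NaN (and does not raise) if the trace is invalid.
    """
    if trace.n_frames < 3:
        raise ValueError("need at least 3 frames")
    dt = float(trace.times_min[1] - trace.times_min[0])
    step = interval_min / dt
    if abs(step - round(step)) > 1e-9 or step < 1:
        raise ValueError(
            f"interval {interval_min} min is not a multiple of frame spacing {dt} min"
        )
    step = int(round(step))
    if not trace.valid or np.all(~np.isfinite(trace.na)):
        return float("nan")
    idx = np.arange(0, trace.n_frames, step)
    if idx.size < 2:
        raise ValueError("trace too short for the requested interval")
    # na = I / I_1, so increments of na ARE dI with the first-frame denominator
    ni_coarse = np.diff(trace.na[idx])
    if np.all(~np.isfinite(ni_coarse)):
        return float("nan")
    best = np.nanmax(ni_coarse)
    tol = 1e-9 * max(1.0, abs(best))  # near-ties resolve to the earliest interval
    j = int(np.flatnonzero(ni_coarse >= best - tol)[0])
    return float(trace.times_min[idx[j + 1]])


def summarize_population(
    traces: list[CellTrace],
    classes: dict[int, str] | None = None,
    descriptor: str = "na",
) -> pd.DataFrame:
    """Per-frame, per-stratum summary of a descriptor across cells.

    Strata are ``all``, ``matched_only`` and ``mismatched_or_false`` (the
    latter two only when ``classes`` maps cell_id to a class label).  Empty
    strata are omitted.  Columns: stratum, frame, t_min, median, p5, p95,
    mean, sd, n_cells.
    """
    if descriptor not in ("na", "nc_ratio", "ni"):
        raise ValueError(f"unknown descriptor {descriptor!r}")
    strata: dict[str, list[CellTrace]] = {"all": [t for t in traces if t.valid]}
    if classes is not None:
        strata["matched_only"] = [
            t for t in traces if t.valid and classes.get(t.cell_id) == "matched"
        ]
        strata["mismatched_or_false"] = [
            t for t in traces if t.valid and classes.get(t.cell_id) == "mismatched_or_false"
        ]
    rows = []
    for name, sub in strata.items():
        if not sub:
            continue
        values = np.array([getattr(t, descriptor) for t in sub])  # cells x frames
        times = sub[0].times_min if descriptor != "ni" else sub[0].times_min[1:]
        for j in range(values.shape[1]):
            v = values[:, j]
            v = v[np.isfinite(v)]
            if v.size == 0:
                continue
            rows.append(
                {
                    "stratum": name,
                    "frame": j + 1 if descriptor != "ni" else j + 2,
                    "t_min": float(times[j]),
                    "median": float(np.median(v)),
                    "p5": float(np.percentile(v, 5)),
                    "p95": float(np.percentile(v, 95)),
                    "mean": float(v.mean()),
                    "sd": float(v.std(ddof=0)),
                    "n_cells": int(v.size),
                }
            )
    return pd.DataFrame(rows)


def rank_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (tie-corrected) with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need equal-length inputs with n >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def wilcoxon_signed_rank(a, b, alternative: str = "two-sided"):
    """Paired Wilcoxon signed-rank test (thin wrapper, standard definition)."""
    return sps.wilcoxon(a, b, alternative=alternative)


def jarque_bera(a):
    """Jarque-Bera normality test (thin wrapper, standard definition)."""
    return sps.jarque_bera(a)
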