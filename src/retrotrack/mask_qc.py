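"""Mask quality control: the robust s.d.-vs-mean mask classifier.

For a cytoplasm-dominant shuttle protein, a nuclear mask that has slipped
onto the cytoplasm mixes two intensity populations and inflates the pixel
s.d. far more than the mean.  Across stationary cells (the cell-movement
control: cells imaged live once, then immediately fixed) the per-nucleus
s.d. is close to linear in the mean, so a robust line fitted to the control
population, together with a pointwise prediction band, separates matched
masks (inside/below the upper band boundary) from mismatched or false masks
(above it).  Classification uses the first registered frame of a series,
which best represents the degree of mask/nucleus match for masks derived
from the end-point image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage as ndi
from scipy.stats import t as t_dist
from skimage.measure import regionprops

from retrotrack.io import IntensityImage
from retrotrack.segmentation import LabelMap

__all__ = [
    "MaskStats",
    "RobustFit",
    "MaskClass",
    "measure_mask_stats",
    "fit_robust_line",
    "band_upper",
    "classify_masks",
    "make_mismatch",
    "shape_qc",
]

MATCHED = "matched"
MISMATCHED = "mismatched_or_false"


@dataclass(frozen=True)
class MaskStats:
    """Per-nucleus target-protein intensity statistics over the eroded mask."""

    cell_id: int
    mean_fi: float
    sd_fi: float  # population s.d. (ddof=0)
    area_px: int

    @property
    def cv(self) -> float:
        """Coefficient of variation, s.d. / mean; defined for mean > 0."""
        if self.mean_fi <= 0:
            return float("nan")
        return self.sd_fi / self.mean_fi


@dataclass(frozen=True)
class MaskClass:
    cell_id: int
    label: str  # MATCHED or MISMATCHED
    reason: str = ""


@dataclass(frozen=True)
class RobustFit:
    """Robust line s.d. = slope * mean + intercept with band geometry.

    ``residual_scale`` is the RMSE of the robust (weighted) residuals;
    ``x_mean`` and ``s_xx`` fix the hyperbolic widening of the prediction
    band away from the centre of the control population.
    """

    slope: float
    intercept: float
    residual_scale: float
    n: int
    x_mean: float
    s_xx: float
    alpha: float = 0.005

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("robust fit needs n >= 3")
        if self.residual_scale < 0 or self.s_xx <= 0:
            raise ValueError("invalid fit geometry")
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")

    def line(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def upper(self, x):
        return band_upper(self, x)


def measure_mask_stats(
    frame: IntensityImage, eroded_nuclei: LabelMap
) -> tuple[list[MaskStats], list[int]]:
    """Mean/population-s.d. of frame intensity over each eroded nuclear mask.

    Only valid pixels enter the statistics; regions with fewer than 2 valid
    pixels are flagged (second return value) and yield no stats.
    """
    stats: list[MaskStats] = []
    flagged: list[int] = []
    lab = eroded_nuclei.labels
    for k in eroded_nuclei.cell_ids:
        sel = (lab == k) & frame.valid_mask
        n = int(sel.sum())
        if n < 2:
            flagged.append(int(k))
            continue
        vals = frame.pixels[sel]
        stats.append(
            MaskStats(int(k), float(vals.mean()), float(vals.std(ddof=0)), n)
        )
    return stats, flagged


def fit_robust_line(points: list[MaskStats] | np.ndarray, alpha: float = 0.005) -> RobustFit:
    """IRLS robust fit of s.d. on mean (Tukey bisquare, c = 4.685, MAD scale).

    ``points`` is either a list of :class:`MaskStats` or an (n, 2) array of
    (mean, sd) pairs.  The iteration runs to a relative coefficient change of
    1e-8 or 50 iterations.  Raises on degenerate x (all means equal) or
    n < 3.
    """
    if isinstance(points, np.ndarray):
        arr = np.asarray(points, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    else:
        x = np.array([p.mean_fi for p in points], dtype=float)
        y = np.array([p.sd_fi for p in points], dtype=float)
    if x.size < 3:
        raise ValueError("robust fit needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: all means equal")

    exog = sm.add_constant(x)
    model = sm.RLM(y, exog, M=sm.robust.norms.TukeyBiweight(c=4.685))
    res = model.fit(scale_est="mad", maxiter=50, tol=1e-8, conv="coefs")
    intercept, slope = (float(v) for v in res.params)
    resid = y - (slope * x + intercept)
    w = np.asarray(res.weights, dtype=float)
    dof = max(x.size - 2, 1)
    rmse = float(np.sqrt(np.sum(w * resid**2) / dof))
    return RobustFit(
        slope=slope,
        intercept=intercept,
        residual_scale=rmse,
        n=int(x.size),
        x_mean=float(x.mean()),
        s_xx=float(np.sum((x - x.mean()) ** 2)),
        alpha=alpha,
    )


def band_upper(fit: RobustFit, x):
    """Upper limit of the pointwise prediction band at mean intensity ``x``.

    line(x) + t(1 - alpha/2, n - 2) * s * sqrt(1 + 1/n + (x - x_mean)^2 / s_xx),
    i.e. the band for a new single observation; it widens hyperbolically away
    from the control population's centre.  With ``alpha = 0.005`` this is the
    upper boundary of the 99.5% band.
    """
    x = np.asarray(x, dtype=float)
    q = t_dist.ppf(1.0 - fit.alpha / 2.0, fit.n - 2)
    half = q * fit.residual_scale * np.sqrt(1.0 + 1.0 / fit.n + (x - fit.x_mean) ** 2 / fit.s_xx)
    out = fit.slope * x + fit.intercept + half
    return float(out) if out.ndim == 0 else out


def classify_masks(
    stats: list[MaskStats],
    fit: RobustFit,
    missing_ids: list[int] | None = None,
) -> list[MaskClass]:
    """Label each mask matched vs mismatched/false by the upper band boundary.

    A mask is matched iff its first-frame (mean, sd) pair lies at or below
    the upper prediction-band limit; only the upper boundary gates the call
    (low-s.d. masks are always matched).  Cells with no measurable stats are
    labelled mismatched/false with a reason code.
    """
    out = [
        MaskClass(s.cell_id, MATCHED if s.sd_fi <= band_upper(fit, s.mean_fi) else MISMATCHED)
        for s in stats
    ]
    for k in missing_ids or []:
        out.append(MaskClass(int(k), MISMATCHED, reason="no_stats"))
    return out


def make_mismatch(
    mask: np.ndarray, dr: int, dc: int, theta_deg: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Rigidly displace a boolean mask region and intersect with the original.

    Emulates the artificial-mismatch validation: the region is rotated by
    ``theta_deg`` about its centroid and translated by (dr, dc).  Returns
    ``(mismatched, intersection)``; the intersection mimics a mask smaller
    than the real nucleus.  An empty intersection is legal (caller flags it).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty input region")
    if theta_deg == 0.0:
        moved = np.zeros_like(mask)
        h, w = mask.shape
        src_r = slice(max(0, -dr), min(h, h - dr))
        src_c = slice(max(0, -dc), min(w, w - dc))
        dst_r = slice(max(0, dr), min(h, h + dr))
        dst_c = slice(max(0, dc), min(w, w + dc))
        moved[dst_r, dst_c] = mask[src_r, src_c]
    else:
        com = ndi.center_of_mass(mask)
        th = np.deg2rad(theta_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        center_out = np.asarray(com) + np.array([dr, dc], dtype=float)
        # affine_transform maps output coords -> input coords
        offset = np.asarray(com) - rot @ center_out
        moved = (
            ndi.affine_transform(
                mask.astype(np.float64), rot, offset=offset, order=1, mode="constant"
            )
            >= 0.5
        )
    return moved, moved & mask


_QC_PARAMS = [
    "nuclear_perimeter",
    "nuclear_solidity",
    "cell_perimeter",
    "nuclear_stain_mean",
    "nuclear_stain_sd",
    "target_mean",
    "target_sd",
]


def shape_qc(
    nuclei: LabelMap,
    cytoplasm: LabelMap,
    target_image: IntensityImage,
    nuclear_image: IntensityImage,
    n_mads: float = 3.0,
) -> pd.DataFrame:
    """Shape/intensity quality control flags per cell.

    Computes nuclear perimeter, nuclear solidity, whole-cell perimeter and
    the mean/s.d. of the nuclear-stain and target-protein intensities over
    the nucleus, then flags any cell whose value on any parameter deviates
    from the population median by more than ``n_mads`` robust standard
    deviations (1.4826 x MAD).  Deviated values indicate segmentation errors.
    """
    rows = []
    nuc = nuclei.labels
    cell_lab = np.where(cytoplasm.labels > 0, cytoplasm.labels, nuc)
    nuc_props = {p.label: p for p in regionprops(nuc)}
    cell_props = {p.label: p for p in regionprops(cell_lab)}
    for k in nuclei.cell_ids:
        k = int(k)
        sel = (nuc == k) & target_image.valid_mask & nuclear_image.valid_mask
        if not sel.any():
            continue
        tvals = target_image.pixels[sel]
        hvals = nuclear_image.pixels[sel]
        rows.append(
            {
                "cell_id": k,
                "nuclear_perimeter": float(nuc_props[k].perimeter),
                "nuclear_solidity": float(nuc_props[k].solidity),
                "cell_perimeter": float(cell_props[k].perimeter) if k in cell_props else np.nan,
                "nuclear_stain_mean": float(hvals.mean()),
                "nuclear_stain_sd": float(hvals.std(ddof=0)),
                "target_mean": float(tvals.mean()),
                "target_sd": float(tvals.std(ddof=0)),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        df["qc_flag"] = pd.Series(dtype=bool)
        return df
    flag = np.zeros(len(df), dtype=bool)
    for p in _QC_PARAMS:
        vals = df[p].to_numpy(dtype=float)
        med = np.nanmedian(vals)
        sigma = 1.4826 * np.nanmedian(np.abs(vals - med))
        flag |= np.abs(vals - med) > n_mads * sigma
    df["qc_flag"] = flag
    return df
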