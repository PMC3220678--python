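"""Rigid-translation registration by normalized cross-correlation (NCC).

The live series is aligned to the end-point fixed-cell reference: the last
live frame is registered against the fixed target-protein image, then each
earlier frame is registered against the already-registered next frame
(adjacent frames are most similar, so chaining is more reliable than
registering every frame directly against the distant reference).  Because
every reference in the chain already sits in the fixed image's coordinate
system, each chained shift is the cumulative shift of that frame.

Correlation is evaluated only over mutually valid pixels at each candidate
integer shift, which makes the score exact in the presence of border pixels
introduced by earlier shifts.  The search is exhaustive over the
``(2*max_shift + 1)^2`` grid, computed with FFT cross-correlations of masked
moment images (the masked-NCC identity), so the result is identical to the
brute-force definition up to floating-point rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from retrotrack.io import Field, IntensityImage

__all__ = ["ShiftTransform", "ncc_shift", "apply_shift", "register_series"]

# relative tolerance used to group near-equal correlation peaks before
# deterministic tie-breaking
_TIE_TOL = 1e-9


@dataclass(frozen=True)
class ShiftTransform:
    """Integer-pixel translation; positive (dr, dc) moves content down/right."""

    dr: int
    dc: int
    peak_correlation: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.peak_correlation <= 1.0:
            raise ValueError("peak_correlation must lie in [-1, 1]")


def _xcorr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # full cross-correlation: out[H-1+dr, W-1+dc] = sum a[r,c] * b[r-dr, c-dc]
    return fftconvolve(a, b[::-1, ::-1], mode="full")


def ncc_shift(
    moving: IntensityImage, reference: IntensityImage, max_shift: int = 20
) -> ShiftTransform:
    """Find the integer shift aligning ``moving`` to ``reference``.

    Returns the shift ``t`` maximizing the normalized cross-correlation over
    the mutual valid-pixel overlap, such that ``apply_shift(moving, t)``
    matches ``reference``.  Candidate shifts whose overlap covers less than
    25% of the image are excluded.  Ties within floating-point tolerance are
    broken by smallest ``|dr| + |dc|``, then row-major order; the result is
    deterministic.

    Raises
    ------
    ValueError
        If either image is constant over every admissible overlap (NCC is
        undefined for zero variance) or the images differ in shape.
    """
    if moving.shape != reference.shape:
        raise ValueError(f"shape mismatch: {moving.shape} vs {reference.shape}")
    if max_shift < 1:
        raise ValueError("max_shift must be >= 1")

    f = reference.pixels * reference.valid_mask
    g = moving.pixels * moving.valid_mask
    mf = reference.valid_mask.astype(np.float64)
    mg = moving.valid_mask.astype(np.float64)

    n_ov = _xcorr(mf, mg)
    sf = _xcorr(f, mg)
    sg = _xcorr(mf, g)
    sfg = _xcorr(f, g)
    sff = _xcorr(f * reference.pixels, mg)
    sgg = _xcorr(mf, g * moving.pixels)

    h, w = moving.shape
    r0, c0 = h - 1, w - 1
    sl = (slice(r0 - max_shift, r0 + max_shift + 1), slice(c0 - max_shift, c0 + max_shift + 1))
    n_ov, sf, sg, sfg, sff, sgg = (a[sl] for a in (n_ov, sf, sg, sfg, sff, sgg))
    n_ov = np.round(n_ov)  # overlap counts are integers; remove FFT noise

    min_overlap = 0.25 * h * w
    ok = n_ov >= max(min_overlap, 2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sfg - sf * sg / n_ov
        var_f = sff - sf**2 / n_ov
        var_g = sgg - sg**2 / n_ov
    # FFT rounding can leave tiny negative variances on constant regions
    scale = np.maximum(sff, sgg) + 1.0
    var_f[var_f < 1e-9 * scale] = 0.0
    var_g[var_g < 1e-9 * scale] = 0.0
    defined = ok & (var_f > 0) & (var_g > 0)
    if not defined.any():
        raise ValueError("normalized cross-correlation undefined: constant image or no overlap")
    ncc = np.full(n_ov.shape, -np.inf)
    ncc[defined] = cov[defined] / np.sqrt(var_f[defined] * var_g[defined])

    best = ncc.max()
    cand = np.argwhere(ncc >= best - _TIE_TOL * max(1.0, abs(best)))
    shifts = cand - max_shift  # row index max_shift <-> shift 0
    order = np.lexsort((shifts[:, 1], shifts[:, 0], np.abs(shifts).sum(axis=1)))
    dr, dc = (int(v) for v in shifts[order[0]])
    return ShiftTransform(dr, dc, float(np.clip(best, -1.0, 1.0)))


def apply_shift(image: IntensityImage, t: ShiftTransform) -> IntensityImage:
    """Translate image content by (dr, dc); exposed borders become invalid.

    Positive ``dr`` moves content down, positive ``dc`` moves it right.  The
    input's valid mask is translated along with the pixels, so invalidity is
    never lost (the mask is monotonically non-increasing along the pipeline).
    """
    h, w = image.shape
    dr, dc = int(t.dr), int(t.dc)
    if abs(dr) >= h or abs(dc) >= w:
        raise ValueError(f"shift ({dr}, {dc}) >= image size {image.shape}")
    out = np.zeros_like(image.pixels)
    mask = np.zeros_like(image.valid_mask)
    src_r = slice(max(0, -dr), min(h, h - dr))
    src_c = slice(max(0, -dc), min(w, w - dc))
    dst_r = slice(max(0, dr), min(h, h + dr))
    dst_c = slice(max(0, dc), min(w, w + dc))
    out[dst_r, dst_c] = image.pixels[src_r, src_c]
    mask[dst_r, dst_c] = image.valid_mask[src_r, src_c]
    return IntensityImage(out, mask)


def register_series(
    field: Field, max_shift: int = 20
) -> tuple[list[IntensityImage], list[ShiftTransform]]:
    """Register the live series to the fixed target-protein reference.

    The last frame is registered against ``fixed_target``; each earlier frame
    is registered against the already-registered next frame.  Returns the
    registered frames (in acquisition order) and the cumulative shift of each
    frame relative to the fixed reference.
    """
    n = field.n_frames
    registered: list[IntensityImage | None] = [None] * n
    shifts: list[ShiftTransform | None] = [None] * n

    t = ncc_shift(field.live_frames[n - 1], field.fixed_target, max_shift)
    shifts[n - 1] = t
    registered[n - 1] = apply_shift(field.live_frames[n - 1], t)
    for i in range(n - 2, -1, -1):
        t = ncc_shift(field.live_frames[i], registered[i + 1], max_shift)
        shifts[i] = t
        registered[i] = apply_shift(field.live_frames[i], t)
    return registered, shifts
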