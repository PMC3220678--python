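"""Ground-truthed synthetic fields emulating the retrospective imaging design.

The generator renders what the acquisition produces for one field: a series
of single-channel live frames of a cytoplasm-dominant shuttle protein
(12-bit, 512x672 px, one frame per 10 min, 13 frames) followed by an
end-point fixed pair — the target-protein channel, unevenly dimmed by
fixation, and a high-contrast nuclear stain — plus the per-cell ground
truth needed to score every pipeline stage.

Cells are non-overlapping ellipses (nucleus inside cytoplasm) with
log-normal per-cell expression.  Responders follow a delayed-logistic
nuclear-accumulation curve — a lag, an acceleration to maximum import speed,
then a plateau — with the cytoplasm depleted conservatively so total cell
fluorescence is constant over time.  A configurable fraction of cells move
(translate/rotate per frame), the stage may drift globally, and pixel noise
has an additive Gaussian plus a signal-proportional component.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from retrotrack.io import Field, IntensityImage

__all__ = ["KineticsConfig", "SimConfig", "GroundTruth", "simulate_field", "simulate_control"]


@dataclass(frozen=True)
class KineticsConfig:
    """Per-cell import kinetics: NA(t) = 1 + (F-1) * scaled logistic.

    ``lag_min`` and ``t_half_min`` are (mean, sd) of the lag before any
    detectable import and of the additional time to the inflection (maximum
    speed), so the inflection sits at lag + t_half.  ``plateau_fold`` is the
    (mean, sd) of the plateau fold-change F; ``rate_per_min`` the logistic
    steepness.
    """

    lag_min: tuple[float, float] = (20.0, 5.0)
    t_half_min: tuple[float, float] = (40.0, 10.0)
    plateau_fold: tuple[float, float] = (3.0, 0.5)
    rate_per_min: float = 0.15


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic field.

    Defaults emulate the validation experiment: 12-bit 512x672 frames every
    10 min for 120 min (13 frames), tens of cells per field, cytoplasm
    brighter than the nucleus before stimulation (baseline N:C 0.6), ~3.5%
    motile cells, and fixation dimming the target channel unevenly to ~70%.
    Radii are in pixels at ~0.31 um/px.
    """

    n_cells: int = 60
    image_shape: tuple[int, int] = (512, 672)
    n_frames: int = 13
    frame_interval_min: float = 10.0
    nuclear_radius_px: tuple[float, float] = (10.0, 1.0)
    cyto_radius_px: tuple[float, float] = (18.0, 2.0)
    expression_median: float = 600.0
    expression_sigma_log: float = 0.4
    baseline_nc_ratio: float = 0.6
    responder_fraction: float = 0.8
    kinetics: KineticsConfig = dc_field(default_factory=KineticsConfig)
    mover_fraction: float = 0.035
    mover_drift_px_per_frame: float = 1.5
    rotation_deg_per_frame: float = 2.0
    noise_gaussian_sd: float = 8.0
    noise_cv: float = 0.08
    background: float = 100.0
    cyto_gradient: float = 0.3
    cyto_depletion_tilt: float = 0.8
    fixation_dim_factor: float = 0.7
    fixation_unevenness: float = 0.15
    fixation_dim_smoothing_px: float = 48.0
    stage_drift_px_per_frame: tuple[int, int] = (0, 0)
    fixation_shift_px: tuple[int, int] = (0, 0)
    nuclear_stain_level: float = 2000.0
    nuclear_stain_background: float = 50.0
    bit_depth: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("responder_fraction", "mover_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nuclear_radius_px[0] <= 0 or self.cyto_radius_px[0] <= 0:
            raise ValueError("radii must be positive")
        if self.cyto_radius_px[0] <= self.nuclear_radius_px[0]:
            raise ValueError("cytoplasmic radius must exceed nuclear radius")
        if self.kinetics.plateau_fold[0] < 1.0:
            raise ValueError("plateau fold-change must be >= 1")
        if self.n_frames < 1 or self.n_cells < 1:
            raise ValueError("n_frames and n_cells must be >= 1")


@dataclass
class GroundTruth:
    """Per-cell truth for scoring the pipeline.

    ``nuclei_labels`` / ``cell_labels`` are label images at the fixed
    (end-point) geometry; ``nuclear_mean_traj`` / ``cyto_mean_traj`` are the
    noise-free per-cell mean-intensity trajectories (cells x frames);
    ``stage_shifts`` holds the true cumulative registration shift of each
    live frame relative to the fixed reference.
    """

    cells: pd.DataFrame
    nuclei_labels: np.ndarray
    cell_labels: np.ndarray
    nuclear_mean_traj: np.ndarray
    cyto_mean_traj: np.ndarray
    stage_shifts: list[tuple[int, int]]
    config: SimConfig

    @property
    def na_traj(self) -> np.ndarray:
        return self.nuclear_mean_traj / self.nuclear_mean_traj[:, :1]


def _ellipse_q(shape, center, r1, r2, angle, pad):
    """Bounding-box slices and the elliptical quadratic form on the box."""
    rmax = max(r1, r2) + pad
    r0 = max(0, int(np.floor(center[0] - rmax)))
    r1e = min(shape[0], int(np.ceil(center[0] + rmax)) + 1)
    c0 = max(0, int(np.floor(center[1] - rmax)))
    c1e = min(shape[1], int(np.ceil(center[1] + rmax)) + 1)
    rr, cc = np.mgrid[r0:r1e, c0:c1e]
    dr, dc = rr - center[0], cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    q = (u / r1) ** 2 + (v / r2) ** 2
    return (slice(r0, r1e), slice(c0, c1e)), q


def _na_curve(t, lag, t_half, fold, rate):
    """Delayed logistic normalized to exactly 1 at t = 0 and -> fold at large t."""
    s = 1.0 / (1.0 + np.exp(-rate * (t - lag - t_half)))
    s0 = 1.0 / (1.0 + np.exp(rate * (lag + t_half)))
    return 1.0 + (fold - 1.0) * (s - s0) / (1.0 - s0)


def _place_cells(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    h, w = cfg.image_shape
    n_total = cfg.n_frames - 1
    drift_budget = (
        max(abs(cfg.stage_drift_px_per_frame[0]), abs(cfg.stage_drift_px_per_frame[1])) * n_total
        + max(abs(cfg.fixation_shift_px[0]), abs(cfg.fixation_shift_px[1]))
        + (cfg.mover_drift_px_per_frame * n_total if cfg.mover_fraction > 0 else 0.0)
    )
    rows = []
    centers: list[tuple[float, float, float]] = []  # (r, c, cyto_rmax)
    attempts = 0
    max_attempts = 400 * cfg.n_cells
    while len(rows) < cfg.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {cfg.n_cells} non-overlapping cells in {cfg.image_shape}; "
                "reduce n_cells or enlarge the image"
            )
        nr = max(3.0, rng.normal(*cfg.nuclear_radius_px))
        ecc = rng.uniform(1.0, 1.15)
        nr1, nr2 = nr * ecc, nr / ecc
        cr = max(1.8 * nr, rng.normal(*cfg.cyto_radius_px))
        cr1, cr2 = cr * ecc, cr / ecc
        margin = max(cr1, cr2) + 3.0 + drift_budget
        if 2 * margin >= min(h, w):
            raise RuntimeError("image too small for the configured cell size and drift")
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        rmax = max(cr1, cr2)
        if any((r - pr) ** 2 + (c - pc) ** 2 < (rmax + prm + 4.0) ** 2 for pr, pc, prm in centers):
            continue
        centers.append((r, c, rmax))
        rows.append(
            {
                "cell_id": len(rows) + 1,
                "row": r,
                "col": c,
                "nuc_r1": nr1,
                "nuc_r2": nr2,
                "cyto_r1": cr1,
                "cyto_r2": cr2,
                "angle": rng.uniform(0.0, np.pi),
            }
        )
    df = pd.DataFrame(rows)

    n = cfg.n_cells
    df["expression"] = cfg.expression_median * np.exp(
        rng.normal(0.0, cfg.expression_sigma_log, size=n)
    )
    df["responder"] = rng.random(n) < cfg.responder_fraction
    df["mover"] = rng.random(n) < cfg.mover_fraction
    kin = cfg.kinetics
    df["lag_min"] = np.clip(rng.normal(*kin.lag_min, size=n), 0.0, None)
    df["t_half_min"] = np.clip(rng.normal(*kin.t_half_min, size=n), 5.0, None)
    # a cell cannot import more protein than its cytoplasm holds: cap the
    # plateau so the cytoplasm keeps >= 10% of its baseline (analytic areas)
    area_ratio = (df["cyto_r1"] * df["cyto_r2"] - df["nuc_r1"] * df["nuc_r2"]) / (
        df["nuc_r1"] * df["nuc_r2"]
    )
    fold_cap = 1.0 + 0.9 * area_ratio.to_numpy() / cfg.baseline_nc_ratio
    df["plateau_fold"] = np.clip(rng.normal(*kin.plateau_fold, size=n), 1.0, fold_cap)
    df["rate_per_min"] = kin.rate_per_min
    theta = rng.uniform(0.0, 2 * np.pi, size=n)
    df["mover_dr"] = np.where(df["mover"], np.sin(theta) * cfg.mover_drift_px_per_frame, 0.0)
    df["mover_dc"] = np.where(df["mover"], np.cos(theta) * cfg.mover_drift_px_per_frame, 0.0)
    return df


def _render_cells(cfg: SimConfig, cells: pd.DataFrame, frame_idx: int, offset, n_vals, c_vals, c0_vals):
    """Noise-free render of all cells at the geometry of one frame.

    The cytoplasmic profile is brighter near the nucleus (``cyto_gradient``,
    cells are thicker there) and, as import depletes the cytoplasm, the
    depletion is weighted toward the perinuclear region where the protein
    exits (``cyto_depletion_tilt``), so the spatial profile changes shape
    over time while the region mean stays exactly the conserved value.
    """
    h, w = cfg.image_shape
    img = np.full((h, w), cfg.background, dtype=np.float64)
    n = cfg.n_frames
    back = n - frame_idx  # frames before the end point (0 for the last frame)
    for i, cell in enumerate(cells.itertuples()):
        center = (
            cell.row + offset[0] - cell.mover_dr * back,
            cell.col + offset[1] - cell.mover_dc * back,
        )
        angle = cell.angle - np.deg2rad(cfg.rotation_deg_per_frame) * back * cell.mover
        sl, qc = _ellipse_q(cfg.image_shape, center, cell.cyto_r1, cell.cyto_r2, angle, 1.0)
        _, qn = _ellipse_q(cfg.image_shape, center, cell.nuc_r1, cell.nuc_r2, angle, 1.0 + cell.cyto_r1 - cell.nuc_r1)
        # evaluate both forms on the cytoplasmic bbox
        nuc = qn <= 1.0
        cyto = (qc <= 1.0) & ~nuc
        patch = img[sl]
        if cyto.any():
            rho = np.sqrt(qc[cyto])
            wgt = 1.0 + cfg.cyto_gradient * (1.0 - rho)
            dep_frac = (c0_vals[i] - c_vals[i]) / c0_vals[i]
            wgt = wgt + cfg.cyto_depletion_tilt * dep_frac * (rho - rho.mean())
            patch[cyto] = c_vals[i] * wgt / wgt.mean()
        patch[nuc] = n_vals[i]
    return img


def _add_noise(img: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.noise_gaussian_sd == 0 and cfg.noise_cv == 0:
        return img
    sd = np.sqrt(cfg.noise_gaussian_sd**2 + (cfg.noise_cv * img) ** 2)
    out = img + rng.standard_normal(img.shape) * sd
    return np.clip(out, 0.0, (1 << cfg.bit_depth) - 1)


def simulate_field(cfg: SimConfig) -> tuple[Field, GroundTruth]:
    """Render one synthetic field and its ground truth; deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    cells = _place_cells(cfg, rng)
    h, w = cfg.image_shape
    n = cfg.n_frames

    # label images at the fixed (end-point) geometry
    nuclei_labels = np.zeros((h, w), dtype=np.int32)
    cell_labels = np.zeros((h, w), dtype=np.int32)
    nuc_area = np.zeros(cfg.n_cells)
    cyto_area = np.zeros(cfg.n_cells)
    for i, cell in enumerate(cells.itertuples()):
        center = (cell.row, cell.col)
        sl, qc = _ellipse_q(cfg.image_shape, center, cell.cyto_r1, cell.cyto_r2, cell.angle, 1.0)
        _, qn = _ellipse_q(
            cfg.image_shape, center, cell.nuc_r1, cell.nuc_r2, cell.angle, 1.0 + cell.cyto_r1 - cell.nuc_r1
        )
        nuc = qn <= 1.0
        cyto = (qc <= 1.0) & ~nuc
        nuclei_labels[sl][nuc] = cell.cell_id
        cell_labels[sl][nuc | cyto] = cell.cell_id
        nuc_area[i] = nuc.sum()
        cyto_area[i] = cyto.sum()

    # noise-free intensity trajectories with conservative cytoplasm depletion
    times = np.arange(n, dtype=float) * cfg.frame_interval_min
    c0 = cells["expression"].to_numpy()
    n0 = cfg.baseline_nc_ratio * c0
    na = np.ones((cfg.n_cells, n))
    for i, cell in enumerate(cells.itertuples()):
        if cell.responder and n > 1:
            na[i] = _na_curve(times, cell.lag_min, cell.t_half_min, cell.plateau_fold, cell.rate_per_min)
    n_traj = n0[:, None] * na
    c_traj = c0[:, None] - (n_traj - n0[:, None]) * (nuc_area / np.maximum(cyto_area, 1.0))[:, None]
    if np.any(c_traj <= 0):
        raise ValueError(
            "cytoplasm depleted below zero; lower plateau_fold or baseline_nc_ratio, "
            "or enlarge the cytoplasm"
        )

    drift = np.asarray(cfg.stage_drift_px_per_frame, dtype=int)
    fix_shift = np.asarray(cfg.fixation_shift_px, dtype=int)
    stage_shifts = [tuple(int(v) for v in drift * (n - i) + fix_shift) for i in range(1, n + 1)]

    frames = []
    for i in range(1, n + 1):
        offset = -np.asarray(stage_shifts[i - 1], dtype=float)
        img = _render_cells(cfg, cells, i, offset, n_traj[:, i - 1], c_traj[:, i - 1], c_traj[:, 0])
        frames.append(IntensityImage(_add_noise(img, cfg, rng)))

    # fixed target-protein channel: end-point geometry, unevenly dimmed
    fixed_clean = _render_cells(cfg, cells, n, (0.0, 0.0), n_traj[:, -1], c_traj[:, -1], c_traj[:, 0])
    dim = np.full((h, w), cfg.fixation_dim_factor)
    if cfg.fixation_unevenness > 0:
        rough = rng.standard_normal((h, w))
        smooth = ndi.gaussian_filter(rough, cfg.fixation_dim_smoothing_px)
        smooth /= max(smooth.std(), 1e-12)
        dim = cfg.fixation_dim_factor * np.clip(1.0 + cfg.fixation_unevenness * smooth, 0.2, 1.8)
    fixed_target = IntensityImage(_add_noise(fixed_clean * dim, cfg, rng))

    # fixed nuclear stain: high-contrast nuclei at end-point geometry
    stain = np.full((h, w), cfg.nuclear_stain_background)
    per_cell_stain = cfg.nuclear_stain_level * (1.0 + 0.1 * rng.standard_normal(cfg.n_cells))
    for i, cell in enumerate(cells.itertuples()):
        stain[nuclei_labels == cell.cell_id] = per_cell_stain[i]
    fixed_nuclear = IntensityImage(_add_noise(stain, cfg, rng))

    field = Field(
        field_id=f"sim_{cfg.seed}",
        live_frames=frames,
        fixed_target=fixed_target,
        fixed_nuclear=fixed_nuclear,
        frame_interval_min=cfg.frame_interval_min,
        bit_depth=cfg.bit_depth,
    )
    cells = cells.assign(nuclear_area_px=nuc_area.astype(int), cyto_area_px=cyto_area.astype(int))
    truth = GroundTruth(
        cells=cells,
        nuclei_labels=nuclei_labels,
        cell_labels=cell_labels,
        nuclear_mean_traj=n_traj,
        cyto_mean_traj=c_traj,
        stage_shifts=stage_shifts,
        config=cfg,
    )
    return field, truth


def simulate_control(cfg: SimConfig) -> tuple[Field, GroundTruth]:
    """Cell-movement control: one live frame at time 0, then immediate fixation.

    Untreated cells: no import kinetics.  Used to build the stationary-cell
    s.d.-vs-mean control population for the mask classifier.
    """
    ctrl = dataclasses.replace(cfg, n_frames=1, responder_fraction=0.0)
    return simulate_field(ctrl)
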