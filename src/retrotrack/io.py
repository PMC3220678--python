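"""Image/table I/O, field assembly and pipeline configuration.

A *field* is one imaging position: an ordered series of live-cell frames of
the target-protein channel plus two end-point fixed-cell images (target
protein and nuclear stain) of the same position.  Images are single-channel
grayscale TIFFs; the acquisition convention is 12-bit data in 16-bit
containers, one frame every ``frame_interval_min`` minutes with frame 1 at
time 0 (pre-stimulation).

Pixels invalidated by registration shifts are tracked in a boolean
``valid_mask`` rather than filled with a sentinel intensity, so that border
pixels never enter any downstream statistic.
"""

from __future__ import annotations

import dataclasses
import glob
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "IntensityImage",
    "Field",
    "PipelineConfig",
    "load_field",
    "load_field_dir",
    "write_field_dir",
    "write_measurements",
    "read_measurements",
    "MEASUREMENT_COLUMNS",
]


@dataclass
class IntensityImage:
    """A 2-D grayscale image with a validity mask.

    Parameters
    ----------
    pixels:
        Non-negative intensities, row-major, 0-based ``(row, col)`` indexing.
    valid_mask:
        Boolean grid of the same shape; ``False`` marks pixels that carry no
        real data (e.g. borders exposed by registration shifts).  Invalid
        pixels are excluded from every statistic computed downstream.
    """

    pixels: np.ndarray
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.pixels.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.pixels.shape:
                raise ValueError(
                    f"valid_mask shape {self.valid_mask.shape} != pixels shape {self.pixels.shape}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def valid_pixels(self) -> np.ndarray:
        """Return the 1-D array of intensities at valid positions."""
        return self.pixels[self.valid_mask]

    def copy(self) -> "IntensityImage":
        return IntensityImage(self.pixels.copy(), self.valid_mask.copy())


@dataclass
class Field:
    """One imaging position: live frame series plus fixed reference pair.

    Frame ``i`` (1-based) is taken at ``(i - 1) * frame_interval_min``
    minutes; frame 1 is the pre-stimulation baseline.  ``n_frames = 1``
    corresponds to the cell-movement control design (one live image, then
    immediate fixation).
    """

    field_id: str
    live_frames: list[IntensityImage]
    fixed_target: IntensityImage
    fixed_nuclear: IntensityImage
    frame_interval_min: float = 10.0
    bit_depth: int = 12

    def __post_init__(self) -> None:
        if len(self.live_frames) < 1:
            raise ValueError("a field needs at least one live frame")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")
        shapes = [f.shape for f in self.live_frames] + [
            self.fixed_target.shape,
            self.fixed_nuclear.shape,
        ]
        if len(set(shapes)) != 1:
            raise ValueError(f"all images in a field must share one shape, got {shapes}")

    @property
    def n_frames(self) -> int:
        return len(self.live_frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.live_frames[0].shape

    @property
    def times_min(self) -> np.ndarray:
        """Acquisition time of each live frame in minutes (frame 1 = 0)."""
        return np.arange(self.n_frames, dtype=float) * self.frame_interval_min

    @property
    def max_intensity(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass
class PipelineConfig:
    """Tunable parameters of the analysis pipeline.

    ``d`` is the cytoplasm dilation distance in pixels and ``e`` the nuclear
    erosion distance; both operate with a Euclidean disk structuring element.
    ``alpha`` is the tail probability of the mask classifier's prediction
    band (0.005 gives the 99.5% band).  ``min_area_fraction`` is the fraction
    of the mean candidate nuclear area below which masks are discarded.
    """

    d: int = 8
    e: int = 3
    alpha: float = 0.005
    max_shift: int = 20
    min_area_fraction: float = 0.5
    log_sigma: float = 3.0
    min_seed_distance: int = 5
    frame_interval_min: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 6 <= int(self.d) <= 20:
            raise ValueError(f"d must be in [6, 20], got {self.d}")
        if not 2 <= int(self.e) <= 6:
            raise ValueError(f"e must be in [2, 6], got {self.e}")
        if not 0 < self.alpha < 0.5:
            raise ValueError(f"alpha must be in (0, 0.5), got {self.alpha}")
        if self.max_shift < 1:
            raise ValueError("max_shift must be >= 1")
        if not 0 < self.min_area_fraction < 1:
            raise ValueError("min_area_fraction must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _read_tiff(path: str) -> np.ndarray:
    if not os.path.exists(path):
        raise FileNotFoundError(f"image file not found: {path}")
    return tifffile.imread(path)


def load_field(
    live: str | Sequence[str],
    fixed_target: str,
    fixed_nuclear: str,
    *,
    field_id: str = "field",
    frame_interval_min: float = 10.0,
    bit_depth: int = 12,
) -> Field:
    """Assemble a :class:`Field` from TIFF files.

    ``live`` is either a single multi-page TIFF (pages in acquisition order)
    or an ordered sequence of single-page TIFF paths.
    """
    if isinstance(live, (str, os.PathLike)):
        stack = _read_tiff(str(live))
        if stack.ndim == 2:
            stack = stack[None]
        frames = [IntensityImage(p) for p in stack]
    else:
        frames = [IntensityImage(_read_tiff(str(p))) for p in live]
    ft = IntensityImage(_read_tiff(fixed_target))
    fn = IntensityImage(_read_tiff(fixed_nuclear))
    shapes = sorted({f.shape for f in frames} | {ft.shape, fn.shape})
    if len(shapes) != 1:
        raise ValueError(f"frame shapes differ: {shapes}")
    return Field(field_id, frames, ft, fn, frame_interval_min, bit_depth)


def load_field_dir(field_dir: str, **kwargs) -> Field:
    """Load a field from a directory in the pipeline's standard layout.

    Layout: ``live_###.tif`` (zero-padded acquisition index) plus
    ``fixed_target.tif`` and ``fixed_nuclear.tif``.
    """
    live = sorted(glob.glob(os.path.join(field_dir, "live_*.tif")))
    if not live:
        raise FileNotFoundError(f"no live_*.tif frames in {field_dir}")
    kwargs.setdefault("field_id", os.path.basename(os.path.normpath(field_dir)))
    return load_field(
        live,
        os.path.join(field_dir, "fixed_target.tif"),
        os.path.join(field_dir, "fixed_nuclear.tif"),
        **kwargs,
    )


def write_field_dir(field: Field, field_dir: str) -> None:
    """Write a field as 16-bit TIFFs in the standard directory layout."""
    os.makedirs(field_dir, exist_ok=True)
    for i, frame in enumerate(field.live_frames, start=1):
        arr = np.clip(np.round(frame.pixels), 0, 65535).astype(np.uint16)
        tifffile.imwrite(os.path.join(field_dir, f"live_{i:03d}.tif"), arr)
    for name, img in [("fixed_target", field.fixed_target), ("fixed_nuclear", field.fixed_nuclear)]:
        arr = np.clip(np.round(img.pixels), 0, 65535).astype(np.uint16)
        tifffile.imwrite(os.path.join(field_dir, f"{name}.tif"), arr)


MEASUREMENT_COLUMNS = [
    "cell_id",
    "frame",
    "t_min",
    "nuclear_mean",
    "nuclear_sd",
    "nuclear_area_px",
    "cyto_mean",
    "valid",
    "flag",
]


def write_measurements(rows: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write per-cell per-frame measurements as CSV with a stable column order.

    An empty frame yields a header-only CSV.  Round-trips losslessly through
    :func:`read_measurements` (floats via repr-precision formatting).
    """
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def read_measurements(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table at {path} lacks columns {missing}")
    return df[MEASUREMENT_COLUMNS]
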