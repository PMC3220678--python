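"""Nuclear and cytoplasmic segmentation from the end-point fixed images.

Nuclei are segmented from the fixed nuclear-stain image: Laplacian-of-
Gaussian edge detection closes each nucleus in a contour, flood-filling the
contour interiors yields candidate masks, intersection with the Otsu
foreground suppresses noise-driven false contours, touching nuclei are split
by a distance-transform watershed, and undersized fragments (below a
fraction of the mean candidate area) are discarded.

The cytoplasm is assigned on the first registered live frame, which has the
strongest cytoplasmic signal for a cytoplasm-dominant protein: the Otsu
foreground is partitioned among the nuclei by seeded watershed, and each
cell's cytoplasmic mask is the intersection of its watershed territory with
a disk dilation of its nucleus (radius ``d``), minus the nucleus itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.segmentation import watershed

from retrotrack.io import IntensityImage

__all__ = [
    "LabelMap",
    "otsu_threshold",
    "segment_nuclei",
    "filter_undersized",
    "assign_cytoplasm",
    "erode_nuclei",
    "exclude_edge_cells",
]


@dataclass
class LabelMap:
    """Integer-labelled pixel regions; 0 = background, k > 0 = cell k.

    Nuclear and cytoplasmic maps of one field share the label space: label k
    in both maps refers to the same cell, and the two compartments of a cell
    are disjoint.
    """

    labels: np.ndarray
    kind: str  # "nuclear" or "cytoplasmic"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.kind not in ("nuclear", "cytoplasmic"):
            raise ValueError(f"kind must be 'nuclear' or 'cytoplasmic', got {self.kind!r}")

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def mask(self, cell_id: int) -> np.ndarray:
        return self.labels == cell_id

    def areas(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))


def otsu_threshold(image: IntensityImage) -> float:
    """Between-class-variance-maximizing threshold over valid pixels."""
    vals = image.valid_pixels()
    if np.unique(vals).size < 2:
        raise ValueError("Otsu threshold undefined for a constant image")
    return float(threshold_otsu(vals))


def _log_contours(pixels: np.ndarray, sigma: float) -> np.ndarray:
    """Closed contours at the zero crossings of the LoG response.

    Bright blobs have a negative LoG interior; the contour is the 1-px ring
    of negative-response pixels adjacent to non-negative response.  Crossings
    whose local LoG amplitude is at the background noise level are dropped.
    """
    log = ndi.gaussian_laplace(pixels, sigma)
    pos = log > 0
    zc = ndi.binary_dilation(pos, disk(1)) & ~pos
    amp = ndi.maximum_filter(log, size=3) - ndi.minimum_filter(log, size=3)
    floor = 4.0 * float(np.median(amp))
    if floor > 0:
        zc &= amp > floor
    return zc


def segment_nuclei(
    nuclear_image: IntensityImage,
    min_area_fraction: float = 0.5,
    *,
    log_sigma: float = 3.0,
    min_seed_distance: int = 5,
) -> LabelMap:
    """Segment nuclei from the fixed nuclear-stain image.

    Returns an empty label map (with a warning) when no candidate nuclei are
    found; that is not an error, since downstream code treats an empty field
    gracefully.
    """
    px = np.where(nuclear_image.valid_mask, nuclear_image.pixels, 0.0)

    edges = _log_contours(px, log_sigma)
    closed = ndi.binary_dilation(edges, disk(1))
    filled = ndi.binary_fill_holes(closed)
    candidates = ndi.binary_erosion(filled, disk(1))

    try:
        fg = px > otsu_threshold(nuclear_image)
    except ValueError:
        fg = np.zeros_like(candidates)
    candidates &= fg
    candidates &= nuclear_image.valid_mask

    if not candidates.any():
        warnings.warn("no candidate nuclei found", stacklevel=2)
        return LabelMap(np.zeros(px.shape, dtype=np.int32), "nuclear")

    dist = ndi.distance_transform_edt(candidates)
    blobs, _ = ndi.label(candidates)
    peaks = peak_local_max(
        dist, min_distance=min_seed_distance, labels=blobs, exclude_border=False
    )
    markers = np.zeros(px.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    markers, _ = ndi.label(markers > 0)
    labels = watershed(-dist, markers, mask=candidates)

    labels, _removed = filter_undersized(labels, min_area_fraction)
    if labels.max() == 0:
        warnings.warn("no nuclei survived the size filter", stacklevel=2)
    return LabelMap(labels.astype(np.int32), "nuclear")


def filter_undersized(labels: np.ndarray, min_area_fraction: float) -> tuple[np.ndarray, list[int]]:
    """Drop labelled regions smaller than ``min_area_fraction`` x mean area.

    The mean is taken over all candidate regions (before removal), matching
    the rule "masks covering less than half of an average nuclear area were
    removed".  Surviving regions are relabelled densely 1..k in scan order.
    Returns the filtered label image and the removed original label ids.
    """
    labels = np.asarray(labels)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    if ids.size == 0:
        return labels.astype(np.int32), []
    cutoff = min_area_fraction * counts.mean()
    keep = ids[counts >= cutoff]
    removed = [int(i) for i in ids[counts < cutoff]]
    out = np.where(np.isin(labels, keep), labels, 0)
    # dense relabel, preserving scan order of first occurrence
    remap = {int(k): i + 1 for i, k in enumerate(sorted(keep.tolist()))}
    relab = np.zeros_like(out, dtype=np.int32)
    for old, new in remap.items():
        relab[out == old] = new
    return relab, removed


def _per_label_dilation(labels: np.ndarray, cell_id: int, radius: int) -> np.ndarray:
    """Disk dilation of one label's region, computed on a padded bounding box."""
    mask = labels == cell_id
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    if rows.size == 0:
        return np.zeros_like(mask)
    r0, r1 = max(0, rows[0] - radius), min(mask.shape[0], rows[-1] + radius + 1)
    c0, c1 = max(0, cols[0] - radius), min(mask.shape[1], cols[-1] + radius + 1)
    out = np.zeros_like(mask)
    out[r0:r1, c0:c1] = ndi.binary_dilation(mask[r0:r1, c0:c1], disk(radius))
    return out


def assign_cytoplasm(
    first_frame: IntensityImage, nuclei: LabelMap, d: int
) -> tuple[LabelMap, list[int]]:
    """Assign per-cell cytoplasmic masks from the first registered frame.

    The final cytoplasm of cell k is
    ``dilate(nucleus_k, d) & watershed_territory_k & foreground - nuclei``.
    Returns the cytoplasmic label map and the ids of cells whose cytoplasm
    came out empty (flagged, not fatal).
    """
    if not 6 <= int(d) <= 20:
        raise ValueError(f"dilation distance d must be in [6, 20], got {d}")
    if nuclei.kind != "nuclear":
        raise ValueError("nuclei LabelMap must have kind 'nuclear'")
    px = np.where(first_frame.valid_mask, first_frame.pixels, 0.0)
    fg = px > otsu_threshold(first_frame)
    fg &= first_frame.valid_mask
    nuc = nuclei.labels
    # smooth the elevation so watershed ridges follow the dim inter-cell gaps
    elevation = -ndi.gaussian_filter(px, 2.0)
    territory = watershed(elevation, nuc, mask=fg | (nuc > 0))

    cyto = np.zeros_like(nuc, dtype=np.int32)
    empty: list[int] = []
    for k in nuclei.cell_ids:
        region = _per_label_dilation(nuc, int(k), int(d))
        region &= territory == k
        region &= fg
        region &= nuc == 0
        if not region.any():
            empty.append(int(k))
        cyto[region] = k
    return LabelMap(cyto, "cytoplasmic"), empty


def erode_nuclei(nuclei: LabelMap, e: int) -> tuple[LabelMap, list[int]]:
    """Erode each nuclear region by a disk of radius ``e``, keeping labels.

    Erosion strips the pixels adjacent to the nuclear boundary so that
    nuclear statistics are not cross-contaminated by cytoplasmic signal.
    Returns the eroded map and the ids of regions eroded to extinction.
    """
    if not 2 <= int(e) <= 6:
        raise ValueError(f"erosion distance e must be in [2, 6], got {e}")
    out = np.zeros_like(nuclei.labels, dtype=np.int32)
    extinct: list[int] = []
    se = disk(int(e))
    for k in nuclei.cell_ids:
        eroded = ndi.binary_erosion(nuclei.mask(int(k)), se)
        if eroded.any():
            out[eroded] = k
        else:
            extinct.append(int(k))
    return LabelMap(out, nuclei.kind), extinct


def exclude_edge_cells(
    nuclei: LabelMap,
    cytoplasm: LabelMap | None,
    registered_frames: list[IntensityImage],
) -> dict[int, bool]:
    """Flag cells that touch the image border or any frame's invalid region.

    Cells at the edge of any image in the time course are excluded from
    quantification, as are cells overlapping border pixels created by
    registration shifts.  Returns ``{cell_id: excluded}``.
    """
    shape = nuclei.labels.shape
    bad = np.zeros(shape, dtype=bool)
    bad[0, :] = bad[-1, :] = True
    bad[:, 0] = bad[:, -1] = True
    for frame in registered_frames:
        if frame.shape != shape:
            raise ValueError("frame shape does not match label map shape")
        bad |= ~frame.valid_mask

    flags: dict[int, bool] = {}
    for k in nuclei.cell_ids:
        cell = nuclei.mask(int(k))
        if cytoplasm is not None:
            cell = cell | cytoplasm.mask(int(k))
        flags[int(k)] = bool((cell & bad).any())
    if flags and all(flags.values()):
        warnings.warn("all cells touch an edge or invalid region; none retained", stacklevel=2)
    return flags
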