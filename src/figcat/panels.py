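"""Multi-panel figure segmentation along blank scanlines.

Compound figures (several sub-panels in one raster) are split before
feature extraction, since text-layout statistics computed across panel
boundaries are ambiguous.  The procedure:

1. optionally smooth with a small Gaussian and binarize (dark = foreground);
2. count foreground pixels ``N_p`` on every horizontal and vertical
   scanline (the projection profile);
3. scanlines with ``N_p <= np_threshold`` (default 5) are candidate
   separators; runs of consecutive candidates are collapsed to a single
   cut at the run's midline;
4. the cartesian grid of horizontal and vertical cuts induces cells; cells
   whose area is below ``min_area_frac`` (default 1/20) of the *original*
   image area are dropped.

If no cut is found the whole image is returned as a single region.  Runs
of candidate lines spanning an entire axis (a blank or near-blank image)
carry no separation evidence and yield no cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

NP_THRESHOLD = 5
MIN_AREA_FRAC = 1.0 / 20.0
GAUSSIAN_SIGMA = 0.8


@dataclass(frozen=True)
class PanelRegion:
    """Grid cell ``[r0, r1) x [c0, c1)`` retained as a panel."""

    r0: int
    c0: int
    r1: int
    c1: int

    @property
    def area(self) -> int:
        return (self.r1 - self.r0) * (self.c1 - self.c0)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.r1 - self.r0, self.c1 - self.c0)

    def crop(self, image: np.ndarray) -> np.ndarray:
        return image[self.r0 : self.r1, self.c0 : self.c1]


def binarize(
    image: np.ndarray, smooth: bool = True, threshold: float | None = None
) -> np.ndarray:
    """Binarize a grayscale image; True = foreground (dark ink).

    With ``smooth``, a 3x3 Gaussian kernel (sigma 0.8) is applied first.
    The threshold defaults to Otsu's on the (smoothed) image; a fixed
    ``threshold`` overrides it.  Constant images have no Otsu valley and
    fall back to a mid-scale cut at 128.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    img = image.astype(np.float64)
    if smooth:
        # truncate=1.25 limits the kernel to a 3x3 footprint at sigma 0.8
        img = ndimage.gaussian_filter(img, sigma=GAUSSIAN_SIGMA, truncate=1.25)
    if threshold is None:
        if np.ptp(img) == 0:
            threshold = 128.0
        else:
            threshold = float(threshold_otsu(img))
    return img < threshold


def scanline_counts(mask: np.ndarray, axis: str) -> np.ndarray:
    """Projection profile: foreground count per scanline.

    ``axis="horizontal"`` counts along each row (one entry per row);
    ``axis="vertical"`` counts along each column.
    """
    mask = np.asarray(mask, dtype=bool)
    if axis == "horizontal":
        return mask.sum(axis=1)
    if axis == "vertical":
        return mask.sum(axis=0)
    raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")


def candidate_cut_lines(counts: np.ndarray, threshold: int = NP_THRESHOLD) -> np.ndarray:
    """Indices of scanlines with at most ``threshold`` foreground pixels."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return np.flatnonzero(np.asarray(counts) <= threshold)


def _collapse_cuts(candidates: np.ndarray, n_lines: int) -> list[int]:
    """Collapse runs of consecutive candidate lines to their midlines.

    A run covering the whole axis means there is nothing to separate and
    produces no cut.
    """
    cuts = []
    if candidates.size == 0:
        return cuts
    breaks = np.flatnonzero(np.diff(candidates) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [candidates.size - 1]))
    for s, e in zip(starts, ends):
        lo, hi = int(candidates[s]), int(candidates[e])
        if lo == 0 and hi == n_lines - 1:
            continue
        cut = (lo + hi + 1) // 2
        if 0 < cut < n_lines:
            cuts.append(cut)
    return cuts


def segment(
    image: np.ndarray,
    np_threshold: int = NP_THRESHOLD,
    min_area_frac: float = MIN_AREA_FRAC,
    smooth: bool = True,
    threshold: float | None = None,
) -> list[PanelRegion]:
    """Split a figure into panel regions along blank scanlines.

    Returns the retained grid cells ordered row-major.  See the module
    docstring for the procedure; the area floor is measured against the
    original image area.
    """
    image = np.asarray(image)
    if image.ndim != 2 or min(image.shape) < 20:
        raise ValueError("image must be 2-D and at least 20x20")
    H, W = image.shape
    mask = binarize(image, smooth=smooth, threshold=threshold)
    row_cuts = _collapse_cuts(
        candidate_cut_lines(scanline_counts(mask, "horizontal"), np_threshold), H
    )
    col_cuts = _collapse_cuts(
        candidate_cut_lines(scanline_counts(mask, "vertical"), np_threshold), W
    )
    if not row_cuts and not col_cuts:
        return [PanelRegion(0, 0, H, W)]
    row_edges = [0, *row_cuts, H]
    col_edges = [0, *col_cuts, W]
    floor = min_area_frac * H * W
    regions = []
    for r0, r1 in zip(row_edges, row_edges[1:]):
        for c0, c1 in zip(col_edges, col_edges[1:]):
            cell = PanelRegion(r0, c0, r1, c1)
            if cell.area >= floor:
                regions.append(cell)
    return regions
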