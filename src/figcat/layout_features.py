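"""100-dimensional text-layout descriptor of a figure.

The descriptor characterizes how annotation text is spatially arranged
inside a figure, and consists of three blocks (dimensions 20 + 60 + 20):

entropy block (20)
    Per scanline, the Shannon entropy (base 2) of the retained foreground
    run-length proportions; a 10-bin histogram of those entropies per
    direction (horizontal scanlines, then vertical).  Runs shorter than
    5 px are discarded as noise before any run statistic is computed.

structure block (60)
    (a) For each scanline, the magnitudes of Fourier coefficients 1-5 of
    the raw 0/1 line signal, normalized by line length; per coefficient
    and direction the (lower quartile, mean, median, upper quartile) over
    scanlines — 2 directions x 5 coefficients x 4 = 40 values.
    (b) Per scanline, a regularity score in [0, 1]: the gap lengths
    between retained runs are clustered by greedy centroid merging until
    no two cluster means are within ``tau`` px; the score is the largest
    cluster's share of the gaps.  A 10-bin histogram over [0, 1] per
    direction — 20 values.  Tables and other grid-like layouts concentrate
    mass in high-regularity bins.

distance block (20)
    Pairwise rectangle gap distances between text regions; a five-band
    histogram of each region's k nearest-neighbour distances
    (k = max(1, floor(n/3))), bands spanning [0, d_max] in equal fifths;
    per band the (LQ, mean, median, HQ) over regions.

All blocks are computed on the *text-region mask* (region rectangles
filled), not on the raw ink mask, so the descriptor depends only on text
geometry and is identical whichever detector supplied the rectangles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from figcat.textmap import TextRegion

MIN_RUN = 5  # noise rule: foreground runs shorter than this are discarded
DEFAULT_TAU = 3.0
N_BINS = 10
N_BANDS = 5
N_COEFFS = 5
FEATURE_DIM = 100

#: block layout of the flat 100-vector
BLOCK_SLICES = {
    "entropy_h": slice(0, 10),
    "entropy_v": slice(10, 20),
    "freq_h": slice(20, 40),
    "freq_v": slice(40, 60),
    "structure_h": slice(60, 70),
    "structure_v": slice(70, 80),
    "distance": slice(80, 100),
}


@dataclass
class ScanlineProfile:
    """Run/gap decomposition of one scanline after the 5 px noise rule."""

    index: int
    runs: list[tuple[int, int]]  # (start, length), every length >= MIN_RUN
    gaps: list[int]  # gaps between consecutive retained runs
    n_p: int  # raw foreground count (before the noise rule)


def scanline_profile(line: np.ndarray, index: int = 0, min_run: int = MIN_RUN) -> ScanlineProfile:
    """Decompose a 0/1 scanline into retained runs and inter-run gaps."""
    line = np.asarray(line, dtype=bool)
    padded = np.concatenate(([False], line, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    runs = [(int(s), int(e - s)) for s, e in zip(starts, ends) if e - s >= min_run]
    gaps = [runs[i + 1][0] - (runs[i][0] + runs[i][1]) for i in range(len(runs) - 1)]
    return ScanlineProfile(index=index, runs=runs, gaps=gaps, n_p=int(line.sum()))


def scanline_entropy(profile: ScanlineProfile) -> float:
    """Shannon entropy (bits) of the retained run-length proportions."""
    lengths = np.array([l for _, l in profile.runs], dtype=np.float64)
    if lengths.size <= 1:
        return 0.0
    p = lengths / lengths.sum()
    return float(-(p * np.log2(p)).sum())


def _hist10(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """10-bin histogram over [lo, hi], upper edge in the last bin, sum 1."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        return np.zeros(N_BINS)
    if hi <= lo:
        out = np.zeros(N_BINS)
        out[0] = 1.0
        return out
    counts, _ = np.histogram(values, bins=N_BINS, range=(lo, hi))
    return counts / values.size


def _quartile_quad(values: np.ndarray) -> np.ndarray:
    """(LQ, mean, median, HQ) with linear-interpolation quartiles."""
    values = np.asarray(values, dtype=np.float64)
    return np.array(
        [
            np.percentile(values, 25),
            values.mean(),
            np.percentile(values, 50),
            np.percentile(values, 75),
        ]
    )


def entropy_histograms(mask: np.ndarray, min_run: int = MIN_RUN) -> np.ndarray:
    """20-dim entropy block: horizontal then vertical 10-bin histograms.

    Each direction's histogram spans [0, max entropy in that direction];
    if every scanline has zero entropy, all mass sits in bin 0.
    """
    mask = np.asarray(mask, dtype=bool)
    blocks = []
    for axis_mask in (mask, mask.T):
        ents = np.array(
            [scanline_entropy(scanline_profile(line, i, min_run)) for i, line in enumerate(axis_mask)]
        )
        blocks.append(_hist10(ents, 0.0, float(ents.max(initial=0.0))))
    return np.concatenate(blocks)


def fourier_structure(mask: np.ndarray) -> np.ndarray:
    """40-dim block: quartile quads of per-scanline Fourier magnitudes.

    Coefficients 1..5 (DC excluded) of the raw 0/1 signal, magnitudes
    normalized by line length so the block is resolution-comparable.
    Order: horizontal j=1..5, then vertical j=1..5, each as
    (LQ, mean, median, HQ).
    """
    mask = np.asarray(mask, dtype=np.float64)
    blocks = []
    for axis_mask in (mask, mask.T):
        n = axis_mask.shape[1]
        spectrum = np.fft.rfft(axis_mask, axis=1)
        mags = np.zeros((axis_mask.shape[0], N_COEFFS))
        avail = min(N_COEFFS, spectrum.shape[1] - 1)
        mags[:, :avail] = np.abs(spectrum[:, 1 : 1 + avail]) / n
        for j in range(N_COEFFS):
            blocks.append(_quartile_quad(mags[:, j]))
    return np.concatenate(blocks)


def regularity(profile: ScanlineProfile, tau: float = DEFAULT_TAU) -> float:
    """Regularity score in [0, 1] of the scanline's gap structure.

    Greedy centroid clustering of the 1-D gap-length multiset: repeatedly
    merge the two clusters whose means are closest, while that distance is
    at most ``tau``.  The score is the largest cluster's share of the
    gaps; scanlines with fewer than two gaps score 0.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    gaps = profile.gaps
    if len(gaps) < 2:
        return 0.0
    clusters = [(float(g), 1) for g in gaps]  # (mean, size)
    while len(clusters) > 1:
        best, pair = None, None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = abs(clusters[i][0] - clusters[j][0])
                if best is None or d < best:
                    best, pair = d, (i, j)
        if best > tau:
            break
        i, j = pair
        (m1, s1), (m2, s2) = clusters[i], clusters[j]
        merged = ((m1 * s1 + m2 * s2) / (s1 + s2), s1 + s2)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return max(s for _, s in clusters) / len(gaps)


def structure_histograms(
    mask: np.ndarray, tau: float = DEFAULT_TAU, min_run: int = MIN_RUN
) -> np.ndarray:
    """20-dim block: 10-bin histograms over [0, 1] of per-scanline regularity."""
    mask = np.asarray(mask, dtype=bool)
    blocks = []
    for axis_mask in (mask, mask.T):
        scores = np.array(
            [regularity(scanline_profile(line, i, min_run), tau) for i, line in enumerate(axis_mask)]
        )
        blocks.append(_hist10(scores, 0.0, 1.0))
    return np.concatenate(blocks)


def region_distance(a: TextRegion, b: TextRegion) -> float:
    """Minimum boundary distance between two rectangles (0 if they overlap)."""
    dx = max(a.x0 - b.x1, b.x0 - a.x1, 0)
    dy = max(a.y0 - b.y1, b.y0 - a.y1, 0)
    return float(np.hypot(dx, dy))


def neighbor_distance_features(regions: list[TextRegion]) -> np.ndarray:
    """20-dim block from nearest-neighbour distance band histograms.

    Degenerate inputs (< 2 regions, or all pairwise distances zero) yield
    the all-zero block.
    """
    n = len(regions)
    if n < 2:
        return np.zeros(4 * N_BANDS)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = region_distance(regions[i], regions[j])
    d_max = dmat.max()
    if d_max == 0:
        return np.zeros(4 * N_BANDS)
    k = max(1, n // 3)
    hists = np.zeros((n, N_BANDS))
    for i in range(n):
        others = np.delete(dmat[i], i)
        nearest = np.sort(others, kind="stable")[:k]
        bands = np.minimum((nearest * N_BANDS / d_max).astype(int), N_BANDS - 1)
        hists[i] = np.bincount(bands, minlength=N_BANDS) / k
    return np.concatenate([_quartile_quad(hists[:, j]) for j in range(N_BANDS)])


@dataclass
class FeatureVector:
    """Flat 100-vector with named block views (see ``BLOCK_SLICES``)."""

    values: np.ndarray = field(default_factory=lambda: np.zeros(FEATURE_DIM))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (FEATURE_DIM,):
            raise ValueError(f"feature vector must have length {FEATURE_DIM}")

    def block(self, name: str) -> np.ndarray:
        return self.values[BLOCK_SLICES[name]]

    def __len__(self) -> int:
        return FEATURE_DIM


def regions_mask(shape: tuple[int, int], regions: list[TextRegion]) -> np.ndarray:
    """Rasterize text regions into a boolean mask of the given shape."""
    mask = np.zeros(shape, dtype=bool)
    H, W = shape
    for r in regions:
        if not r.within(H, W):
            raise ValueError(f"region {r} outside image bounds {shape}")
        mask[r.y0 : r.y1, r.x0 : r.x1] = True
    return mask


def extract_features(
    image: np.ndarray,
    regions: list[TextRegion],
    tau: float = DEFAULT_TAU,
    min_run: int = MIN_RUN,
) -> FeatureVector:
    """Extract the 100-dim layout descriptor of a figure.

    The entropy and structure blocks are computed on the rasterized
    text-region mask; the distance block directly on the rectangles.
    Block order: entropy-h, entropy-v, freq-h (j=1..5), freq-v (j=1..5),
    structure-h, structure-v, distance bands 0..4.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    mask = regions_mask(image.shape[:2], regions)
    vec = np.concatenate(
        [
            entropy_histograms(mask, min_run),
            fourier_structure(mask),
            structure_histograms(mask, tau, min_run),
            neighbor_distance_features(regions),
        ]
    )
    return FeatureVector(vec)
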