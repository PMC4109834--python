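"""Deterministic synthetic figure generator.

Produces labeled raster figures whose *text layout* is characteristic of
each leaf class of the taxonomy, together with ground-truth text-region
rectangles.  Text is simulated as filled dark rectangles: the layout
features downstream depend only on text-region geometry, never on glyphs,
so no font rendering is needed.

Conventions
-----------
* Background is white (255); ink is dark (<= 60), so "foreground" always
  means dark pixels.
* Rectangles are 0-based, half-open ``[x0, x1) x [y0, y1)`` with ``x`` the
  column and ``y`` the row.
* ``generate_figure(label, seed, w, h)`` is bit-deterministic in all of its
  arguments.

The ``"multipanel"`` pseudo-label produces a composite of two panels of
distinct content classes separated by a fully blank gutter at least 8 px
wide; each panel is framed by a 3 px border so that no blank scanline
crosses a panel interior (the gutter is the only separator the panel
segmenter can find).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from figcat.taxonomy import LEAF_CLASSES, top_level
from figcat.textmap import TextRegion

INK = 30  # default ink intensity
LABEL_INK = 20  # text-region fill intensity
GUTTER = 12  # blank gutter width in multi-panel composites, px
MIN_SIZE = 64

#: labels accepted by :func:`generate_figure`
GENERATOR_LABELS: tuple[str, ...] = LEAF_CLASSES + ("multipanel",)


@dataclass
class SyntheticFigure:
    """A generated figure with its ground-truth annotation.

    Attributes
    ----------
    image:
        ``(H, W)`` uint8 intensity raster, white background.
    label:
        leaf class label, or ``"multipanel"`` for composites.
    regions:
        ground-truth text regions, all within image bounds.
    seed:
        the seed the figure was generated from.
    """

    image: np.ndarray
    label: str
    regions: list[TextRegion] = field(default_factory=list)
    seed: int = 0

    @property
    def top_label(self) -> str:
        return top_level(self.label)


def _fill(img: np.ndarray, x0: int, y0: int, x1: int, y1: int, val: int = INK) -> None:
    img[y0:y1, x0:x1] = val


def _frame(img, x0, y0, x1, y1, t=1, val=INK):
    img[y0 : y0 + t, x0:x1] = val
    img[y1 - t : y1, x0:x1] = val
    img[y0:y1, x0 : x0 + t] = val
    img[y0:y1, x1 - t : x1] = val


def _text(img, regions, x0, y0, w, h) -> None:
    """Place one simulated text block and record it as a ground-truth region."""
    x0, y0 = int(x0), int(y0)
    x1, y1 = x0 + max(1, int(w)), y0 + max(1, int(h))
    H, W = img.shape
    x0 = max(0, min(x0, W - 1))
    y0 = max(0, min(y0, H - 1))
    x1 = max(x0 + 1, min(x1, W))
    y1 = max(y0 + 1, min(y1, H))
    img[y0:y1, x0:x1] = LABEL_INK
    regions.append(TextRegion(x0, y0, x1, y1, source="ground-truth"))


# ---------------------------------------------------------------------------
# per-class renderers: draw into the box [bx0, bx1) x [by0, by1)


def _render_table(img, regions, rng, bx0, by0, bx1, by1):
    w, h = bx1 - bx0, by1 - by0
    rows = int(rng.integers(4, 7))
    cols = int(rng.integers(3, 6))
    px, py = w // cols, h // rows  # integer pitch -> exactly regular grid
    tw = max(6, int(px * rng.uniform(0.5, 0.7)))
    th = max(5, min(py - 3, int(py * rng.uniform(0.35, 0.55))))
    for r in range(rows):
        for c in range(cols):
            _text(img, regions, bx0 + c * px + 2, by0 + r * py + 1, tw, th)
        # horizontal rule under each row
        yr = by0 + (r + 1) * py - 1
        if yr < by1:
            img[yr, bx0 : bx0 + cols * px] = INK


def _render_flow_chart(img, regions, rng, bx0, by0, bx1, by1):
    w, h = bx1 - bx0, by1 - by0
    n = int(rng.integers(5, 8))
    # jittered 2x4 slot grid keeps boxes disjoint
    slots = [(r, c) for r in range(4) for c in range(2)]
    idx = rng.permutation(len(slots))[:n]
    bw, bh = int(w * 0.32), int(h * 0.16)
    centers = []
    for si in sorted(idx):
        r, c = slots[si]
        cx = bx0 + int((c + 0.5) * w / 2 + rng.integers(-w // 12, w // 12 + 1))
        cy = by0 + int((r + 0.5) * h / 4 + rng.integers(-h // 24, h // 24 + 1))
        x0 = max(bx0, min(cx - bw // 2, bx1 - bw))
        y0 = max(by0, min(cy - bh // 2, by1 - bh))
        _frame(img, x0, y0, x0 + bw, y0 + bh, t=1)
        _text(img, regions, x0 + 3, y0 + 3, bw - 6, max(5, bh - 6))
        centers.append((x0 + bw // 2, y0 + bh // 2))
    # connect consecutive boxes with L-shaped arrows
    for (x1c, y1c), (x2c, y2c) in zip(centers, centers[1:]):
        img[min(y1c, y2c) : max(y1c, y2c) + 1, x1c] = INK
        img[y2c, min(x1c, x2c) : max(x1c, x2c) + 1] = INK


def _axes(img, rng, bx0, by0, bx1, by1):
    """Draw an L-shaped axis pair; return (axis_x, axis_y)."""
    w, h = bx1 - bx0, by1 - by0
    ax = bx0 + int(w * 0.18)
    ay = by1 - int(h * 0.16)
    img[by0 + int(h * 0.08) : ay + 1, ax] = INK
    img[ay, ax : bx1 - int(w * 0.05)] = INK
    return ax, ay


def _tick_labels(img, regions, rng, ax, ay, bx0, by0, bx1, by1):
    w, h = bx1 - bx0, by1 - by0
    ny = int(rng.integers(4, 7))
    th = max(5, h // 36)
    for i in range(ny):
        y = by0 + int(h * 0.10) + int(i * (ay - by0 - int(h * 0.12)) / ny)
        _text(img, regions, bx0 + 1, y, max(6, int(w * 0.10)), th)
    nx = int(rng.integers(4, 7))
    for i in range(nx):
        x = ax + 4 + int(i * (bx1 - ax - int(w * 0.10)) / nx)
        _text(img, regions, x, min(ay + 3, by1 - th - 1), max(6, int(w * 0.08)), th)
    # title, top centre
    _text(img, regions, bx0 + int(w * 0.35), by0 + 1, int(w * 0.3), max(5, h // 30))


def _render_line_chart(img, regions, rng, bx0, by0, bx1, by1):
    w, h = bx1 - bx0, by1 - by0
    ax, ay = _axes(img, rng, bx0, by0, bx1, by1)
    _tick_labels(img, regions, rng, ax, ay, bx0, by0, bx1, by1)
    # smooth random-walk polyline inside the plot box
    top = by0 + int(h * 0.12)
    y = rng.uniform(0.2, 0.8)
    for x in range(ax + 2, bx1 - int(w * 0.05)):
        y = min(0.95, max(0.05, y + rng.uniform(-0.04, 0.04)))
        yy = int(top + y * (ay - 2 - top))
        img[yy : yy + 2, x] = INK


def _render_bar_chart(img, regions, rng, bx0, by0, bx1, by1):
    w, h = bx1 - bx0, by1 - by0
    ax, ay = _axes(img, rng, bx0, by0, bx1, by1)
    _tick_labels(img, regions, rng, ax, ay, bx0, by0, bx1, by1)
    nb = int(rng.integers(4, 7))
    pitch = (bx1 - int(w * 0.06) - ax - 4) // nb
    bw = max(4, int(pitch * 0.6))
    top = by0 + int(h * 0.14)
    for i in range(nb):
        x0 = ax + 4 + i * pitch + (pitch - bw) // 2
        bh = int(rng.uniform(0.25, 0.95) * (ay - top))
        _frame(img, x0, ay - bh, x0 + bw, ay, t=2)
        # value annotation above each bar
        _text(img, regions, x0, max(by0, ay - bh - 8), max(5, bw - 2), 5)


def _render_spot_chart(img, regions, rng, bx0, by0, bx1, by1):
    w, h = bx1 - bx0, by1 - by0
    ax, ay = _axes(img, rng, bx0, by0, bx1, by1)
    _tick_labels(img, regions, rng, ax, ay, bx0, by0, bx1, by1)
    top = by0 + int(h * 0.14)
    for _ in range(int(rng.integers(15, 31))):
        x = int(rng.integers(ax + 4, bx1 - int(w * 0.06) - 3))
        y = int(rng.integers(top, ay - 4))
        img[y : y + 3, x : x + 3] = INK
    # small legend block, upper right
    lx = bx1 - int(w * 0.22)
    _text(img, regions, lx, top, int(w * 0.15), 5)
    _text(img, regions, lx, top + 8, int(w * 0.15), 5)


def _render_microscopy(img, regions, rng, bx0, by0, bx1, by1):
    w, h = bx1 - bx0, by1 - by0
    # dense mid-tone speckle texture, no blank scanline inside the box
    speck = rng.random((h, w)) < 0.30
    tex = rng.integers(70, 170, size=(h, w)).astype(np.uint8)
    sub = img[by0:by1, bx0:bx1]
    sub[speck] = tex[speck]
    # a few annotation labels near the corners + a scale bar
    nlab = int(rng.integers(2, 5))
    corners = [
        (bx0 + 3, by0 + 3),
        (bx1 - int(w * 0.15) - 3, by0 + 3),
        (bx0 + 3, by1 - 12),
        (bx1 - int(w * 0.15) - 3, by1 - 20),
    ]
    for cx, cy in corners[:nlab]:
        _text(img, regions, cx, cy, int(w * 0.13), 6)
    _fill(img, bx1 - int(w * 0.18), by1 - 6, bx1 - 4, by1 - 3, INK)  # scale bar


def _render_gel(img, regions, rng, bx0, by0, bx1, by1):
    w, h = bx1 - bx0, by1 - by0
    nl = int(rng.integers(5, 9))
    pitch = w // nl
    lane_w = max(5, int(pitch * 0.55))
    top = by0 + 12
    for i in range(nl):
        x0 = bx0 + i * pitch + (pitch - lane_w) // 2
        # lane label (the only text annotation)
        _text(img, regions, x0, by0 + 2, max(5, lane_w - 1), 6)
        # faint lane background + dark bands
        img[top:by1, x0 : x0 + lane_w] = 210
        for _ in range(int(rng.integers(2, 6))):
            y = int(rng.integers(top + 2, by1 - 8))
            img[y : y + int(rng.integers(4, 8)), x0 : x0 + lane_w] = INK


def _render_others(img, regions, rng, bx0, by0, bx1, by1):
    """Caption-like paragraph: stacked long text lines."""
    w, h = bx1 - bx0, by1 - by0
    lh = int(rng.integers(5, 8))
    pitch = 2 * lh
    nl = min(int(rng.integers(6, 11)), (h - 4) // pitch)
    for i in range(nl):
        frac = 0.85 if rng.random() > 0.25 else rng.uniform(0.4, 0.8)
        _text(img, regions, bx0 + 2, by0 + 2 + i * pitch, int(w * frac), lh)


_RENDERERS = {
    "table": _render_table,
    "flow chart": _render_flow_chart,
    "line chart": _render_line_chart,
    "bar chart": _render_bar_chart,
    "spot chart": _render_spot_chart,
    "microscopy": _render_microscopy,
    "gel electrophoresis": _render_gel,
    "others": _render_others,
}


def _render_multipanel(img, regions, rng, bx0, by0, bx1, by1):
    """Two framed panels of distinct content classes, blank gutter between."""
    w, h = bx1 - bx0, by1 - by0
    vertical_gutter = w >= h  # side-by-side panels when the figure is wide
    choices = [l for l in LEAF_CLASSES if l not in ("microscopy",)]
    labels = list(rng.choice(choices, size=2, replace=False))
    if vertical_gutter:
        mid = bx0 + w // 2
        boxes = [(bx0, by0, mid - GUTTER // 2, by1), (mid + GUTTER // 2, by0, bx1, by1)]
    else:
        mid = by0 + h // 2
        boxes = [(bx0, by0, bx1, mid - GUTTER // 2), (bx0, mid + GUTTER // 2, bx1, by1)]
    for lab, (px0, py0, px1, py1) in zip(labels, boxes):
        # 3 px frame: every scanline crossing the panel carries > 5 ink px,
        # so the gutter stays the only candidate separator
        _frame(img, px0, py0, px1, py1, t=3)
        _RENDERERS[lab](img, regions, rng, px0 + 5, py0 + 5, px1 - 5, py1 - 5)


def generate_figure(
    label: str,
    seed: int,
    width: int = 256,
    height: int = 256,
    noise: float = 0.0,
) -> SyntheticFigure:
    """Generate one synthetic figure of class ``label``.

    Parameters
    ----------
    label:
        one of the eight leaf classes or ``"multipanel"``.
    seed:
        any integer; same ``(label, seed, width, height)`` gives a
        bit-identical figure.
    width, height:
        image size in pixels, each at least 64.
    noise:
        salt-and-pepper pixel-flip rate in ``[0, 1]`` (default 0); used to
        exercise the 5 px noise-run filter downstream.

    Returns
    -------
    SyntheticFigure
        image, label, ground-truth text regions and the seed used.
    """
    if label not in GENERATOR_LABELS:
        raise ValueError(
            f"unknown class label: {label!r}; expected one of {GENERATOR_LABELS}"
        )
    if width < MIN_SIZE or height < MIN_SIZE:
        raise ValueError(f"degenerate size {width}x{height}: minimum is {MIN_SIZE}")
    if not 0.0 <= noise <= 1.0:
        raise ValueError(f"noise rate must be in [0, 1], got {noise}")

    label_idx = GENERATOR_LABELS.index(label)
    rng = np.random.default_rng([label_idx, seed & 0x7FFFFFFF, width, height])
    img = np.full((height, width), 255, dtype=np.uint8)
    regions: list[TextRegion] = []
    margin = 4
    if label == "multipanel":
        _render_multipanel(img, regions, rng, margin, margin, width - margin, height - margin)
    else:
        _RENDERERS[label](img, regions, rng, margin, margin, width - margin, height - margin)
    if noise > 0:
        flip = rng.random(img.shape) < noise
        img[flip] = np.where(rng.random(img.shape) < 0.5, 0, 255)[flip]
    return SyntheticFigure(image=img, label=label, regions=regions, seed=seed)


def generate_dataset(
    n_per_class: int,
    seed: int,
    classes: tuple[str, ...] = LEAF_CLASSES,
    width: int = 256,
    height: int = 256,
    noise: float = 0.0,
) -> list[SyntheticFigure]:
    """Generate a balanced dataset of ``n_per_class`` figures per class.

    Per-figure seeds are derived deterministically from the master ``seed``,
    so two calls with identical arguments yield identical datasets.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    figures = []
    for ci, label in enumerate(classes):
        for i in range(n_per_class):
            fig_seed = (seed * 1000003 + ci * 7919 + i) % (2**31)
            figures.append(generate_figure(label, fig_seed, width, height, noise))
    return figures


#: leaf labels available per top-level class for balanced sampling
_TOP_POOLS: dict[str, tuple[str, ...]] = {
    "flow chart": ("flow chart",),
    "experiment": ("microscopy", "gel electrophoresis"),
    "graph": ("line chart", "bar chart", "spot chart", "table"),
    "mix": ("multipanel",),
    "others": ("others",),
}


def generate_top_level_dataset(
    n_per_class: int,
    seed: int,
    width: int = 256,
    height: int = 256,
    noise: float = 0.0,
) -> list[SyntheticFigure]:
    """Balanced dataset over the five top-level classes.

    Within a top-level class the leaf labels are cycled round-robin
    (e.g. ``experiment`` alternates microscopy and gel figures), so every
    leaf is represented whenever ``n_per_class`` permits.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    figures = []
    for ci, (top, pool) in enumerate(sorted(_TOP_POOLS.items())):
        for i in range(n_per_class):
            fig_seed = (seed * 1000003 + ci * 7919 + i) % (2**31)
            figures.append(
                generate_figure(pool[i % len(pool)], fig_seed, width, height, noise)
            )
    return figures


def dataset_manifest(figures: list[SyntheticFigure]) -> dict:
    """JSON-serializable manifest: per figure id, label and region rectangles."""
    return {
        "figures": [
            {
                "id": f"{fig.label.replace(' ', '_')}_{fig.seed}_{i:04d}",
                "label": fig.label,
                "seed": fig.seed,
                "regions": [[r.x0, r.y0, r.x1, r.y1] for r in fig.regions],
            }
            for i, fig in enumerate(figures)
        ]
    }
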