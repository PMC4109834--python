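"""Text-region mapping: supplied ground truth or a baseline detector.

The layout features are defined over axis-aligned text-region rectangles.
Those rectangles can come from two sources:

* a JSON manifest of ground-truth (or externally detected) rectangles, via
  :func:`load_regions`;
* the baseline connected-component detector :func:`detect_text_regions`.

The detector interface is pluggable: any callable mapping a binary mask to
a list of :class:`TextRegion` can stand in for the baseline, so a dedicated
text-detection algorithm can be dropped in without touching the rest of the
pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import measure

GROUND_TRUTH = "ground-truth"
DETECTED = "detected"


@dataclass(frozen=True)
class TextRegion:
    """Axis-aligned rectangle ``[x0, x1) x [y0, y1)``, 0-based, x = column."""

    x0: int
    y0: int
    x1: int
    y1: int
    source: str = GROUND_TRUTH

    def __post_init__(self):
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(
                f"degenerate rectangle [{self.x0},{self.x1})x[{self.y0},{self.y1})"
            )

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    def within(self, height: int, width: int) -> bool:
        return 0 <= self.x0 and self.x1 <= width and 0 <= self.y0 and self.y1 <= height


def _mergeable(a: TextRegion, b: TextRegion, merge_gap: int) -> bool:
    """Word -> line rule: small horizontal gap and >= 50% vertical overlap."""
    gap = max(a.x0 - b.x1, b.x0 - a.x1)
    if gap > merge_gap:
        return False
    overlap = min(a.y1, b.y1) - max(a.y0, b.y0)
    return overlap >= 0.5 * min(a.height, b.height)


def detect_text_regions(
    mask: np.ndarray, min_area: int = 9, merge_gap: int = 4
) -> list[TextRegion]:
    """Baseline text detector on a binary foreground mask.

    Connected foreground components become bounding boxes; boxes separated
    horizontally by at most ``merge_gap`` px whose vertical overlap is at
    least half the shorter box's height are merged (grouping words into
    lines); merged boxes with area below ``min_area`` are discarded.

    Non-text ink (axis lines, frames) also produces boxes; the baseline
    favours recall over precision.
    """
    mask = np.asarray(mask, dtype=bool)
    labeled = measure.label(mask, connectivity=2)
    boxes = [
        TextRegion(int(c0), int(r0), int(c1), int(r1), source=DETECTED)
        for r0, c0, r1, c1 in (p.bbox for p in measure.regionprops(labeled))
    ]
    # iterate the merge rule to a fixed point
    merged = True
    while merged:
        merged = False
        boxes.sort(key=lambda b: (b.x0, b.y0))
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                if _mergeable(boxes[i], boxes[j], merge_gap):
                    a, b = boxes[i], boxes[j]
                    boxes[i] = TextRegion(
                        min(a.x0, b.x0),
                        min(a.y0, b.y0),
                        max(a.x1, b.x1),
                        max(a.y1, b.y1),
                        source=DETECTED,
                    )
                    del boxes[j]
                    merged = True
                    break
            if merged:
                break
    return [b for b in boxes if b.area >= min_area]


def load_regions(manifest: str | Path | dict, image_id: str) -> list[TextRegion]:
    """Load ground-truth regions for ``image_id`` from a JSON manifest.

    The manifest holds a ``"figures"`` list of entries with ``"id"`` and
    ``"regions"`` (rectangles as ``[x0, y0, x1, y1]``).  A present entry
    with zero regions yields an empty list; a missing id is an error.
    """
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    for entry in manifest.get("figures", []):
        if entry.get("id") == image_id:
            return [
                TextRegion(int(x0), int(y0), int(x1), int(y1), source=GROUND_TRUTH)
                for x0, y0, x1, y1 in entry.get("regions", [])
            ]
    raise KeyError(f"image id {image_id!r} not found in manifest")
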