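"""Two-level taxonomy for figures embedded in biomedical publications.

Figures are organized in a class hierarchy with five top-level categories
and eight leaf categories:

========================  ==============================================
top-level category        leaf categories
========================  ==============================================
``flow chart``            ``flow chart``
``experiment``            ``microscopy``, ``gel electrophoresis``
``graph``                 ``line chart``, ``bar chart``, ``spot chart``,
                          ``table``
``mix``                   (multi-panel composites of distinct content)
``others``                ``others``
========================  ==============================================

The ``mix`` category has no leaf of its own: a figure is mixed when its
panels, taken individually, belong to at least two distinct top-level
categories.  The synthetic label ``multipanel`` is used by the fixture
generator for such composites.
"""

from __future__ import annotations

#: Leaf (bottom-level) class labels, in canonical order.
LEAF_CLASSES: tuple[str, ...] = (
    "microscopy",
    "gel electrophoresis",
    "line chart",
    "bar chart",
    "spot chart",
    "table",
    "flow chart",
    "others",
)

#: Top-level class labels, in canonical order.
TOP_CLASSES: tuple[str, ...] = ("flow chart", "experiment", "graph", "mix", "others")

_LEAF_TO_TOP: dict[str, str] = {
    "microscopy": "experiment",
    "gel electrophoresis": "experiment",
    "line chart": "graph",
    "bar chart": "graph",
    "spot chart": "graph",
    "table": "graph",
    "flow chart": "flow chart",
    "others": "others",
    "multipanel": "mix",
}


def top_level(label: str) -> str:
    """Map a leaf label (or ``multipanel``) to its top-level category.

    Top-level labels map to themselves, so the function is idempotent.
    """
    if label in TOP_CLASSES:
        return label
    try:
        return _LEAF_TO_TOP[label]
    except KeyError:
        raise ValueError(f"unknown class label: {label!r}") from None
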