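"""The stomatocyte-discocyte-echinocyte (SDE) morphology scale.

Seven canonical shape classes are placed at equal spacing on a linear
score axis running from -1 (spherocyte) through 0 (discocyte) to +1
(echinocyte III).  Everything downstream (regression targets, the
class-matching tolerance, report axes) derives from the constants here.
"""

from __future__ import annotations

import numpy as np

#: The seven SDE classes in ladder order, spherocyte first.
SDE_CLASSES: tuple[str, ...] = (
    "spherocyte",
    "stomatocyte_II",
    "stomatocyte_I",
    "discocyte",
    "echinocyte_I",
    "echinocyte_II",
    "echinocyte_III",
)

#: Non-SDE shape classes recognised by the first classifier stage.
NON_SDE_CLASSES: tuple[str, ...] = (
    "knizocyte",
    "keratocyte",
    "acanthocyte",
    "multilobate",
    "cell_cluster",
)

#: All concrete shape classes the synthetic generator can produce.
ALL_SHAPE_CLASSES: tuple[str, ...] = SDE_CLASSES + NON_SDE_CLASSES

#: Output labels of the first-stage classifier: the whole SDE family is
#: collapsed into one class, plus five distinct classes and "unknown".
STAGE1_LABELS: tuple[str, ...] = (
    "sde",
    "knizocyte",
    "keratocyte",
    "acanthocyte",
    "multilobate",
    "cell_cluster",
    "unknown",
)

_SCORES = {cls: s for cls, s in zip(SDE_CLASSES, np.linspace(-1.0, 1.0, len(SDE_CLASSES)))}


def is_sde(shape_class: str) -> bool:
    """True if *shape_class* belongs to the SDE ladder."""
    return shape_class in _SCORES


def canonical_score(shape_class: str) -> float:
    """Canonical score of an SDE class on the [-1, +1] scale."""
    try:
        return float(_SCORES[shape_class])
    except KeyError:
        raise ValueError(f"not an SDE class: {shape_class!r}") from None


def score_spacing() -> float:
    """Spacing between adjacent canonical SDE scores (2 / 6)."""
    return 2.0 / (len(SDE_CLASSES) - 1)


def match_half_interval(decimals: int = 2) -> float:
    """Half the spacing between adjacent perfect shapes, rounded as printed.

    This is the tolerance used when deciding whether a regression score
    matches a canonical class.
    """
    return round(score_spacing() / 2.0, decimals)


def stage1_label(shape_class: str) -> str:
    """Map a concrete shape class onto the first-stage label space."""
    if is_sde(shape_class):
        return "sde"
    if shape_class in STAGE1_LABELS:
        return shape_class
    if shape_class in NON_SDE_CLASSES:
        return shape_class
    return "unknown"


def nearest_sde_class(score: float) -> str:
    """SDE class whose canonical score is closest to *score*."""
    classes = list(SDE_CLASSES)
    diffs = [abs(score - _SCORES[c]) for c in classes]
    return classes[int(np.argmin(diffs))]
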