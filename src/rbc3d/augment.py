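"""Leakage-safe splitting and linear spectrum interpolation.

Training and validation are split *before* any augmentation, so no
augmented sample ever has a parent in the other partition.  First-stage
(classification) augmentation interpolates pairs within the same class;
second-stage (regression) augmentation interpolates within or between
adjacent classes of the SDE ladder, carrying a linearly interpolated
score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .descriptor import normalize_descriptor
from .sde import SDE_CLASSES, canonical_score, is_sde, nearest_sde_class, stage1_label


class StratificationError(ValueError):
    """Raised when a class has too few members to split."""


class CoverageError(ValueError):
    """Raised when the SDE ladder is not fully represented."""


@dataclass
class LabeledSpectrum:
    vector: np.ndarray
    shape_class: str
    sde_score: float | None = None
    origin: str = "measured"  # or "augmented"
    parents: tuple[str, str] | None = None
    uid: str = ""

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if is_sde(self.shape_class) and self.sde_score is None:
            self.sde_score = canonical_score(self.shape_class)

    @property
    def label(self) -> str:
        """First-stage label (SDE family collapsed to 'sde')."""
        return stage1_label(self.shape_class)


@dataclass
class SplitDataset:
    train: list[LabeledSpectrum]
    validation: list[LabeledSpectrum]
    seed: int = 0
    fraction: float = 0.8

    def parent_ids(self, partition: str) -> set[str]:
        items = self.train if partition == "train" else self.validation
        ids = set()
        for s in items:
            if s.parents:
                ids.update(s.parents)
            elif s.origin == "measured":
                ids.add(s.uid)
        return ids


def split_before_augmentation(
    spectra: list[LabeledSpectrum], fraction: float = 0.8, seed: int = 0
) -> SplitDataset:
    """Stratified random split of measured spectra, performed before any
    augmentation so the partitions share no parents."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    by_class: dict[str, list[LabeledSpectrum]] = {}
    for s in spectra:
        by_class.setdefault(s.shape_class, []).append(s)
    for cls, members in by_class.items():
        if len(members) < 2:
            raise StratificationError(f"class {cls!r} has fewer than 2 spectra")
    rng = np.random.default_rng(seed)
    train, val = [], []
    for cls in sorted(by_class):
        members = by_class[cls]
        order = rng.permutation(len(members))
        n_train = int(round(fraction * len(members)))
        n_train = min(max(n_train, 1), len(members))
        for k, i in enumerate(order):
            (train if k < n_train else val).append(members[i])
    if not val:
        warnings.warn("validation partition is empty (fraction too high)", stacklevel=2)
    return SplitDataset(train=train, validation=val, seed=seed, fraction=fraction)


def _interpolate(u: LabeledSpectrum, v: LabeledSpectrum, t: float) -> np.ndarray:
    vec = (1.0 - t) * u.vector + t * v.vector
    return normalize_descriptor(vec)


def _partition_targets(split: SplitDataset, n_train_target: int) -> dict[str, int]:
    """Scale the per-class budget of each partition by its measured size."""
    n_train = max(len(split.train), 1)
    n_val = len(split.validation)
    return {
        "train": n_train_target,
        "validation": int(round(n_train_target * n_val / n_train)),
    }


def augment_classification(
    split: SplitDataset, n_per_class: int = 2000, seed: int = 0
) -> SplitDataset:
    """Balance every first-stage class to ``n_per_class`` samples per
    partition (train; validation scaled by its relative size) by linear
    interpolation between random same-class pairs, re-normalized to [0, 1].

    Originals count toward the per-class total.
    """
    rng = np.random.default_rng(seed)
    targets = _partition_targets(split, n_per_class)
    out = {"train": [], "validation": []}
    for name, items in (("train", split.train), ("validation", split.validation)):
        by_label: dict[str, list[LabeledSpectrum]] = {}
        for s in items:
            by_label.setdefault(s.label, []).append(s)
        target = targets[name]
        for label in sorted(by_label):
            members = by_label[label]
            out[name].extend(members)
            n_new = max(target - len(members), 0)
            idx_u = rng.integers(0, len(members), size=n_new)
            idx_v = rng.integers(0, len(members), size=n_new)
            ts = rng.uniform(0.0, 1.0, size=n_new)
            for k in range(n_new):
                u, v = members[idx_u[k]], members[idx_v[k]]
                out[name].append(
                    LabeledSpectrum(
                        vector=_interpolate(u, v, ts[k]),
                        shape_class=u.shape_class if u.shape_class == v.shape_class else label,
                        sde_score=None,
                        origin="augmented",
                        parents=(u.uid, v.uid),
                        uid=f"{name}-{label}-aug{k}",
                    )
                )
    return SplitDataset(out["train"], out["validation"], seed=split.seed, fraction=split.fraction)


def augment_regression(split: SplitDataset, n_total: int = 14000, seed: int = 0) -> SplitDataset:
    """SDE-only augmentation for the regression stage.

    Pairs are drawn from the same or adjacent classes on the SDE ladder;
    the target score is the linear interpolation of the parents' scores.
    Train receives ``n_total`` samples (originals included); validation
    is scaled by its relative measured size.
    """
    rng = np.random.default_rng(seed)
    targets = _partition_targets(split, n_total)
    out = {"train": [], "validation": []}
    ladder = list(SDE_CLASSES)
    for name, items in (("train", split.train), ("validation", split.validation)):
        sde_items = [s for s in items if is_sde(s.shape_class)]
        by_class = {c: [s for s in sde_items if s.shape_class == c] for c in ladder}
        missing = [c for c, mem in by_class.items() if not mem]
        if missing:
            if name == "validation" and not split.validation:
                continue
            raise CoverageError(f"SDE ladder not covered in {name}: missing {missing}")
        out[name].extend(sde_items)
        n_new = max(targets[name] - len(sde_items), 0)
        ci = rng.integers(0, len(ladder), size=n_new)
        step = rng.integers(-1, 2, size=n_new)  # same or adjacent class
        cj = np.clip(ci + step, 0, len(ladder) - 1)
        ts = rng.uniform(0.0, 1.0, size=n_new)
        for k in range(n_new):
            u = by_class[ladder[ci[k]]][rng.integers(0, len(by_class[ladder[ci[k]]]))]
            v = by_class[ladder[cj[k]]][rng.integers(0, len(by_class[ladder[cj[k]]]))]
            t = float(ts[k])
            score = (1.0 - t) * u.sde_score + t * v.sde_score
            out[name].append(
                LabeledSpectrum(
                    vector=_interpolate(u, v, t),
                    shape_class=u.shape_class if u.shape_class == v.shape_class else nearest_sde_class(score),
                    sde_score=score,
                    origin="augmented",
                    parents=(u.uid, v.uid),
                    uid=f"{name}-sde-aug{k}",
                )
            )
    return SplitDataset(out["train"], out["validation"], seed=split.seed, fraction=split.fraction)
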