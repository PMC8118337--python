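"""Sample-level aggregation: class fractions, SDE score distributions and
confusion matrices against manual labels.

The score-matching rule follows the printed convention: a prediction for
an SDE cell counts as correct when it lies within +/- 0.17 (half the
spacing between adjacent perfect shapes, rounded to two decimals) of the
canonical score of its manually assigned class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ann import CellResult
from .sde import (
    ALL_SHAPE_CLASSES,
    SDE_CLASSES,
    canonical_score,
    is_sde,
    match_half_interval,
    nearest_sde_class,
)

#: Row/column order of confusion matrices: SDE ladder, specific classes, unknown.
CONFUSION_LABELS: tuple[str, ...] = ALL_SHAPE_CLASSES + ("unknown",)


class JoinError(KeyError):
    """Raised when manual labels are missing for some cell ids."""


@dataclass
class SampleReport:
    sample_id: str
    n_cells: int
    class_fractions: dict[str, float]
    sde_scores: np.ndarray
    mu: float | None
    ci95: tuple[float, float] | None
    density_grid: np.ndarray | None = None
    density: np.ndarray | None = None


@dataclass
class ConfusionMatrix:
    labels: tuple[str, ...]
    counts: np.ndarray  # rows: actual, cols: predicted
    empty_rows: tuple[str, ...] = ()

    def percentages(self) -> np.ndarray:
        """Row-normalized percentages; all-zero rows stay at zero."""
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(sums > 0, 100.0 * self.counts / sums, 0.0)
        return pct

    def accuracy_per_class(self) -> dict[str, float]:
        pct = self.percentages()
        return {lab: float(pct[i, i]) for i, lab in enumerate(self.labels)}

    def to_dataframe(self, percent: bool = True) -> pd.DataFrame:
        data = self.percentages() if percent else self.counts
        return pd.DataFrame(data, index=list(self.labels), columns=list(self.labels))


# ------------------------------------------------------------------ sample report


def build_sample_report(
    results: list[CellResult],
    sample_id: str = "sample",
    kde_bandwidth: float | None = None,
    density_points: int = 201,
) -> SampleReport:
    """Class fractions, mean SDE score and central 95% interval of a sample.

    mu is the expected value of the per-cell scores; ci95 the [2.5th,
    97.5th] percentile interval of the score distribution.  The density
    curve is a Gaussian KDE (Silverman bandwidth unless given) on a
    fixed grid over [-1, 1].
    """
    if not results:
        raise ValueError("empty result list")
    n = len(results)
    fractions: dict[str, float] = {}
    for r in results:
        fractions[r.predicted_class] = fractions.get(r.predicted_class, 0.0) + 1.0
    fractions = {k: v / n for k, v in fractions.items()}
    scores = np.array([r.sde_score for r in results if r.sde_score is not None])
    if scores.size == 0:
        warnings.warn(f"sample {sample_id}: no SDE-scored cells; mu/ci95 absent", stacklevel=2)
        return SampleReport(sample_id, n, fractions, scores, None, None)
    mu = float(scores.mean())
    ci = (float(np.percentile(scores, 2.5)), float(np.percentile(scores, 97.5)))
    grid = np.linspace(-1.0, 1.0, density_points)
    density = None
    if scores.size > 1 and scores.std() > 0:
        kde = stats.gaussian_kde(scores, bw_method=kde_bandwidth)
        density = kde(grid)
    return SampleReport(sample_id, n, fractions, scores, mu, ci, grid, density)


# ------------------------------------------------------------------ matching


def sde_match(predicted_score: float, actual_class: str) -> bool:
    """True iff the score lies within the printed +/- 0.17 half-interval
    of the canonical score of *actual_class*."""
    if not is_sde(actual_class):
        raise ValueError(f"{actual_class!r} is not an SDE class")
    if not -1.0 <= predicted_score <= 1.0:
        raise ValueError("score must lie in [-1, 1]")
    return abs(predicted_score - canonical_score(actual_class)) <= match_half_interval()


def _predicted_column(result: CellResult, actual_class: str) -> str:
    """Column a prediction falls into, resolving SDE scores to classes."""
    if result.predicted_class == "sde":
        if result.sde_score is None:
            return "unknown"
        if is_sde(actual_class) and sde_match(result.sde_score, actual_class):
            return actual_class
        return nearest_sde_class(result.sde_score)
    return result.predicted_class


def build_confusion(
    results: list[CellResult], manual_labels: dict[str, str]
) -> ConfusionMatrix:
    """Confusion matrix of predictions against manual shape labels.

    SDE rows credit a prediction as correct when the cell was routed to
    the regression stage and its score matches the manual class within
    +/- 0.17; non-SDE rows require label equality.  Rows for classes
    absent from the evaluation set are kept (all zero) and flagged.
    """
    missing = [r.cell_id for r in results if r.cell_id not in manual_labels]
    if missing:
        raise JoinError(f"manual label missing for cells: {missing[:10]}")
    labels = CONFUSION_LABELS
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for r in results:
        actual = manual_labels[r.cell_id]
        if actual not in index:
            raise ValueError(f"unrecognised manual label {actual!r} for {r.cell_id}")
        col = _predicted_column(r, actual)
        counts[index[actual], index.get(col, index["unknown"])] += 1
    empty = tuple(lab for i, lab in enumerate(labels) if counts[i].sum() == 0)
    return ConfusionMatrix(labels=labels, counts=counts, empty_rows=empty)


# ------------------------------------------------------------------ output


def results_to_frame(results: list[CellResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "cell_id": r.cell_id,
                "predicted_class": r.predicted_class,
                "sde_score": r.sde_score if r.sde_score is not None else np.nan,
                "max_probability": float(np.max(r.class_probabilities)),
            }
        )
    return pd.DataFrame(rows).set_index("cell_id")


def write_report(report: SampleReport, out_dir, confusion: ConfusionMatrix | None = None) -> None:
    """Write the per-sample TSVs and the bar/density plots."""
    from pathlib import Path

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frac = pd.Series(report.class_fractions, name="fraction")
    frac.to_csv(out / f"{report.sample_id}_fractions.tsv", sep="\t")
    summary = pd.DataFrame(
        {
            "n_cells": [report.n_cells],
            "mu": [report.mu],
            "ci95_low": [report.ci95[0] if report.ci95 else None],
            "ci95_high": [report.ci95[1] if report.ci95 else None],
        },
        index=[report.sample_id],
    )
    summary.to_csv(out / f"{report.sample_id}_summary.tsv", sep="\t")
    if confusion is not None:
        confusion.to_dataframe().to_csv(out / f"{report.sample_id}_confusion.tsv", sep="\t")

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    frac.sort_index().plot.bar(ax=axes[0], color="steelblue")
    axes[0].set_ylabel("fraction of cells")
    axes[0].set_title(f"{report.sample_id} (n={report.n_cells})")
    if report.density is not None:
        axes[1].fill_between(report.density_grid, report.density, color="lightgrey")
        if report.ci95 is not None:
            lo, hi = report.ci95
            sel = (report.density_grid >= lo) & (report.density_grid <= hi)
            axes[1].fill_between(report.density_grid[sel], report.density[sel], color="dimgrey")
    if report.mu is not None:
        axes[1].axvline(report.mu, linestyle="--", color="red")
    axes[1].set_xlim(-1, 1)
    axes[1].set_xlabel("SDE score")
    axes[1].set_ylabel("density")
    fig.tight_layout()
    fig.savefig(out / f"{report.sample_id}_report.png", dpi=120)
    plt.close(fig)
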