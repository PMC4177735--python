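"""Per-protein ROC and recall-precision evaluation with curve averaging.

Evaluation follows the per-protein protocol: one curve per protein from its
ranked residue scores and catalytic/noncatalytic labels, then vertical
averaging across proteins on a fixed 101-point x grid; the dataset AUC is
the trapezoidal area of the averaged curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm

from .errors import UndefinedCurveError

logger = logging.getLogger(__name__)

#: number of x grid points used for vertical curve averaging
AVERAGING_GRID_POINTS = 101


@dataclass
class LabeledRanking:
    """Scores plus binary labels (True = catalytic) for one protein."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have equal length")


@dataclass
class Curve:
    """A monotone-x curve — (FPR, TPR) for ROC, (recall, precision) for RP —
    with its trapezoidal AUC."""

    x: np.ndarray
    y: np.ndarray
    auc: float


def roc_curve(ranking: LabeledRanking) -> Curve:
    """ROC curve by descending-score threshold sweep (ties merged).

    Starts at (0,0), ends at (1,1); AUC by the trapezoid rule.  Raises
    :class:`UndefinedCurveError` unless both classes are present.
    """
    labels = ranking.labels
    if labels.all() or (~labels).all():
        raise UndefinedCurveError("ROC needs at least one positive and one negative")
    fpr, tpr, _ = _skm.roc_curve(labels, ranking.scores, drop_intermediate=False)
    return Curve(x=fpr, y=tpr, auc=float(_skm.auc(fpr, tpr)))


def recall_precision_curve(ranking: LabeledRanking) -> Curve:
    """Recall-precision curve over the same descending threshold sweep.

    Tied scores are processed together.  The point at recall 0 carries the
    precision of the top-ranked prediction group, so the curve starts at
    x = 0 and ends at recall 1.  AUC by the trapezoid rule over recall.
    """
    labels = ranking.labels
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise UndefinedCurveError("recall-precision needs at least one positive")
    order = np.argsort(-ranking.scores, kind="stable")
    sorted_scores = ranking.scores[order]
    sorted_labels = labels[order]
    cum_tp = np.cumsum(sorted_labels)
    k = np.arange(1, len(sorted_labels) + 1)
    # last index of each tied-score group
    last_of_group = np.nonzero(np.append(np.diff(sorted_scores) != 0, True))[0]
    recall = cum_tp[last_of_group] / n_pos
    precision = cum_tp[last_of_group] / k[last_of_group]
    x = np.concatenate([[0.0], recall])
    y = np.concatenate([[precision[0]], precision])
    return Curve(x=x, y=y, auc=float(np.trapezoid(y, x)))


def average_curves(curves: list[Curve],
                   grid_points: int = AVERAGING_GRID_POINTS) -> Curve:
    """Vertical averaging: interpolate every curve's y on a fixed x grid of
    evenly spaced points in [0, 1] and average per grid point."""
    if not curves:
        raise UndefinedCurveError("cannot average an empty list of curves")
    grid = np.linspace(0.0, 1.0, grid_points)
    ys = np.array([np.interp(grid, c.x, c.y) for c in curves])
    mean_y = ys.mean(axis=0)
    return Curve(x=grid, y=mean_y, auc=float(np.trapezoid(mean_y, grid)))


def evaluate_dataset(
    rankings: dict[str, LabeledRanking],
) -> tuple[Curve, Curve, dict[str, float]]:
    """Average ROC and RP curves over a dataset of per-protein rankings.

    Proteins without a positive label are excluded with a warning; returns
    (mean ROC, mean RP, per-protein ROC AUC map).
    """
    roc_curves, rp_curves, aucs = [], [], {}
    for name, ranking in rankings.items():
        if not ranking.labels.any():
            logger.warning("%s: no catalytic residue labeled; excluded", name)
            continue
        if ranking.labels.all():
            logger.warning("%s: no noncatalytic residue labeled; excluded", name)
            continue
        rc = roc_curve(ranking)
        roc_curves.append(rc)
        rp_curves.append(recall_precision_curve(ranking))
        aucs[name] = rc.auc
    if not roc_curves:
        raise UndefinedCurveError("no protein with both classes labeled")
    return average_curves(roc_curves), average_curves(rp_curves), aucs


def write_curve_tsv(curve: Curve, path, x_name: str = "x", y_name: str = "y") -> None:
    """Write a curve as a two-column TSV."""
    import pandas as pd

    pd.DataFrame({x_name: curve.x, y_name: curve.y}).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def plot_curve(curve: Curve, path, x_label: str, y_label: str) -> None:
    """Optional matplotlib plot of a curve (requires the ``plot`` extra)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(curve.x, curve.y)
    ax.set_xlabel(x_label)
    ax.set_ylabel(y_label)
    ax.set_title(f"AUC = {curve.auc:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
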