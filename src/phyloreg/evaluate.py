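"""Scoring predicted networks against the truth; ROC sweeps; edge sharing.

Sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP) are counted over
adjacency entries that are not ``x`` in *both* matrices, so entries of
absent genes never mix content inference into edge scoring.  Counts are
pooled (micro-averaged) over all organisms per grid value to draw one ROC
curve per experiment; a per-leaf macro mode is available.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .networks import TernaryNet, WeightedNet, X

__all__ = [
    "RocPoint",
    "sens_spec",
    "roc_sweep",
    "threshold_sweep",
    "default_threshold_grid",
    "edge_sharing_table",
    "balanced_accuracy",
]


@dataclass(frozen=True)
class RocPoint:
    """Pooled confusion counts at one grid value (k_p or threshold)."""

    grid_value: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def balanced_accuracy(self) -> float:
        return 0.5 * (self.sensitivity + self.specificity)

    def __add__(self, other: "RocPoint") -> "RocPoint":
        return RocPoint(
            self.grid_value,
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


def sens_spec(
    pred: TernaryNet, truth: TernaryNet, grid_value: float = 0.0
) -> RocPoint:
    """Confusion counts over entries that are not x in both matrices."""
    if pred.genes != truth.genes:
        raise ValueError("prediction and truth must share one gene list")
    mask = (pred.matrix != X) & (truth.matrix != X)
    p = pred.matrix[mask] == 1
    t = truth.matrix[mask] == 1
    return RocPoint(
        grid_value,
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def roc_sweep(
    grid_outputs: dict[float, dict[str, TernaryNet]],
    truths: dict[str, TernaryNet],
    macro: bool = False,
) -> list[RocPoint] | pd.DataFrame:
    """One pooled ROC point per grid value (11 for the default k_p grid).

    ``grid_outputs`` maps grid value -> per-organism predictions.  With
    ``macro=True`` a DataFrame of per-organism points is returned instead
    of pooling.
    """
    organisms = set(truths)
    for g, nets in grid_outputs.items():
        if set(nets) != organisms:
            raise ValueError(f"grid value {g}: missing organisms")
    if macro:
        rows = [
            {
                "grid_value": g,
                "organism": org,
                "sensitivity": sens_spec(nets[org], truths[org], g).sensitivity,
                "specificity": sens_spec(nets[org], truths[org], g).specificity,
            }
            for g, nets in sorted(grid_outputs.items())
            for org in sorted(organisms)
        ]
        return pd.DataFrame(rows)
    points = []
    for g, nets in sorted(grid_outputs.items()):
        total = RocPoint(g, 0, 0, 0, 0)
        for org in organisms:
            total = total + sens_spec(nets[org], truths[org], g)
        points.append(total)
    return points


def default_threshold_grid(net: WeightedNet, k: int = 11) -> np.ndarray:
    """k evenly spaced |weight| thresholds from 0 up to just under max|w|."""
    top = float(np.abs(net.matrix).max())
    return np.linspace(0.0, top, k, endpoint=False)


def threshold_sweep(
    net: WeightedNet, thresholds
) -> list[TernaryNet]:
    """Binarize a weighted net at each threshold: edge iff |w| > threshold.

    Higher thresholds give nested (sparser) edge sets.
    """
    thresholds = np.asarray(thresholds, float)
    if not np.all(np.diff(thresholds) >= 0):
        raise ValueError("thresholds must be sorted ascending")
    return [
        TernaryNet(list(net.genes), (np.abs(net.matrix) > t).astype(np.int8))
        for t in thresholds
    ]


def edge_sharing_table(nets: list[TernaryNet]) -> pd.DataFrame:
    """How widely each union edge is shared across a set of networks.

    Takes the union of edges over all K networks, classifies each edge by
    the number of networks containing it, and tabulates the proportion per
    category 1..K plus the cumulative fraction (which ends at 1.0).
    Networks may live in different gene spaces; edges are matched by gene
    id pairs.
    """
    if len(nets) < 2:
        raise ValueError("need at least 2 networks")
    counts: dict[tuple[str, str], int] = {}
    for net in nets:
        for e in net.edges():
            counts[e] = counts.get(e, 0) + 1
    if not counts:
        raise ValueError("the union of edges is empty")
    K = len(nets)
    total = len(counts)
    proportions = [
        sum(1 for v in counts.values() if v == k) / total for k in range(1, K + 1)
    ]
    return pd.DataFrame(
        {
            "n_networks": np.arange(1, K + 1),
            "proportion": proportions,
            "cumulative": np.cumsum(proportions),
        }
    )


def balanced_accuracy(points: list[RocPoint]) -> float:
    """Mean (sensitivity + specificity)/2 across a sweep's points."""
    return float(np.mean([p.balanced_accuracy for p in points]))


def plot_roc(curves: dict[str, list[RocPoint]], path: str) -> None:
    """Plot ROC curves (1 - specificity vs. sensitivity), one per label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for label, points in curves.items():
        xs = [1.0 - p.specificity for p in points]
        ys = [p.sensitivity for p in points]
        order = np.argsort(xs)
        ax.plot(np.array(xs)[order], np.array(ys)[order], "o-", label=label)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
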