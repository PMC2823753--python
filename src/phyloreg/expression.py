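"""Time-series gene-expression simulators for "true" leaf networks.

Two generators are provided:

* :func:`dbnsim` — binary expression sampled from a first-order dynamic
  Bayesian network whose conditional distributions derive from the signed
  edge weights through a logistic link;
* :func:`genesim` — continuous expression following the linear update
  ``x(t+1) = x(t) + k_e (x(t) - z) C + eps`` with Gaussian noise, where
  ``C`` is the weighted adjacency matrix and ``z`` the constitutive level.

:func:`discretize` converts continuous data to binary by a per-gene median
split, for use with the binary DBN learner.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .networks import WeightedNet

__all__ = [
    "ExpressionDataset",
    "DbnSimParams",
    "GeneSimParams",
    "dbnsim",
    "genesim",
    "discretize",
    "read_expression",
    "write_expression",
]


@dataclass
class ExpressionDataset:
    """Genes x time-points expression matrix for one organism."""

    organism: str
    genes: list[str]
    values: np.ndarray  # shape (n_genes, T)
    kind: str  # "binary" | "continuous"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape[0] != len(self.genes):
            raise ValueError("values rows must match genes")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 time points")
        if self.kind not in ("binary", "continuous"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "binary" and not np.isin(self.values, (0, 1)).all():
            raise ValueError("binary dataset contains values outside {0, 1}")

    @property
    def T(self) -> int:
        return self.values.shape[1]

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class DbnSimParams:
    """Binary simulator parameters; T defaults to 13 * n_genes."""

    T: int | None = None
    beta: float = 3.0  # logistic gain on the weighted parent sum
    bias: float = 0.0
    q0: float = 0.5  # Bernoulli rate for parent-free genes / t = 0

    def __post_init__(self):
        if self.T is not None and self.T < 2:
            raise ValueError("T must be >= 2")
        if not 0.0 <= self.q0 <= 1.0:
            raise ValueError("q0 must be in [0, 1]")


@dataclass(frozen=True)
class GeneSimParams:
    """Continuous simulator parameters (amplification k_e, level z, noise)."""

    T: int = 75
    k_e: float = 7.0
    z: float = 50.0
    init_low: float = 0.0
    init_high: float = 100.0
    sigma: float = 10.0

    def __post_init__(self):
        if self.T < 2:
            raise ValueError("T must be >= 2")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def dbnsim(
    net: WeightedNet,
    params: DbnSimParams = DbnSimParams(),
    rng: np.random.Generator | int | None = None,
    organism: str = "",
) -> ExpressionDataset:
    """Sample a binary time series from the network's DBN.

    A regulated gene i is on at time t with probability
    ``sigmoid(beta * sum_j w_ji (2 x_j(t-1) - 1) + bias)`` over its
    regulators j; parent-free genes are redrawn from Bernoulli(q0) at every
    step, and every gene starts from Bernoulli(q0) at t = 0.
    """
    rng = np.random.default_rng(rng)
    n = net.n
    T = params.T if params.T is not None else 13 * n
    W = net.matrix  # W[j, i]: weight of regulator j on target i
    has_parents = (W != 0).any(axis=0)
    x = np.empty((n, T), dtype=np.int8)
    x[:, 0] = rng.random(n) < params.q0
    for t in range(1, T):
        signed = 2.0 * x[:, t - 1] - 1.0
        drive = params.beta * (signed @ W) + params.bias
        p_on = 1.0 / (1.0 + np.exp(-drive))
        p_on = np.where(has_parents, p_on, params.q0)
        x[:, t] = rng.random(n) < p_on
    return ExpressionDataset(organism, list(net.genes), x, "binary")


def genesim(
    net: WeightedNet,
    params: GeneSimParams = GeneSimParams(),
    rng: np.random.Generator | int | None = None,
    organism: str = "",
    x0: np.ndarray | None = None,
) -> ExpressionDataset:
    """Continuous linear time series: x(t+1) = x(t) + k_e (x(t) - z) C + eps.

    Expression is a row vector, so regulators of gene i act through column
    i of the weighted adjacency matrix C.  Parent-free genes (and every
    gene at t = 0, unless ``x0`` pins the initial state) are drawn
    uniformly from [init_low, init_high] at each step.  The linear map can
    be unstable; an overflow raises with advice to reduce ``k_e`` or the
    weights.
    """
    rng = np.random.default_rng(rng)
    n = net.n
    C = net.matrix
    has_parents = (C != 0).any(axis=0)
    x = np.empty((n, params.T))
    x[:, 0] = (
        np.asarray(x0, float)
        if x0 is not None
        else rng.uniform(params.init_low, params.init_high, n)
    )
    for t in range(1, params.T):
        prev = x[:, t - 1]
        eps = rng.normal(0.0, params.sigma, n) if params.sigma > 0 else 0.0
        nxt = prev + params.k_e * ((prev - params.z) @ C) + eps
        nxt = np.where(
            has_parents, nxt, rng.uniform(params.init_low, params.init_high, n)
        )
        if not np.all(np.isfinite(nxt)) or np.abs(nxt).max() > 1e12:
            raise OverflowError(
                "expression diverged; reduce k_e, the noise, or edge weights"
            )
        x[:, t] = nxt
    return ExpressionDataset(organism, list(net.genes), x, "continuous")


def discretize(ds: ExpressionDataset, threshold: float | None = None) -> ExpressionDataset:
    """Binarize continuous expression: value > per-gene median -> 1.

    With ``threshold`` given, a single fixed cutoff is used for all genes
    instead of the per-gene median.  Constant genes become all-0 (warned).
    """
    if ds.kind != "continuous":
        raise ValueError("discretize expects a continuous dataset")
    if threshold is None:
        cut = np.median(ds.values, axis=1, keepdims=True)
    else:
        cut = np.full((ds.n_genes, 1), float(threshold))
    out = (ds.values > cut).astype(np.int8)
    constant = np.ptp(ds.values, axis=1) == 0
    if threshold is None and constant.any():
        names = [g for g, c in zip(ds.genes, constant) if c]
        warnings.warn(f"constant genes discretized to all-0: {names}")
    return ExpressionDataset(ds.organism, list(ds.genes), out, "binary")


def write_expression(ds: ExpressionDataset, path: str | Path) -> None:
    """TSV: rows = genes, columns t0..t(T-1)."""
    df = pd.DataFrame(
        ds.values, index=ds.genes, columns=[f"t{t}" for t in range(ds.T)]
    )
    df.to_csv(path, sep="\t")


def read_expression(path: str | Path, organism: str = "") -> ExpressionDataset:
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    kind = "binary" if np.isin(values, (0, 1)).all() else "continuous"
    if kind == "binary":
        values = values.astype(np.int8)
    return ExpressionDataset(organism, [str(g) for g in df.index], values, kind)
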