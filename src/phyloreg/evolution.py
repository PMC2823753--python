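"""Simulation of regulatory-network evolution along a species tree.

The model evolves a weighted adjacency matrix down the phylogeny.  On each
branch, gene content evolves first and regulatory connections second:

* each gene present at the branch start is duplicated with probability
  ``p_d`` (the new copy's connections are initialized by the chosen
  initialization model) and lost with probability ``p_l`` (removing its row
  and column);
* every remaining entry then mutates, 0 -> 1 with probability ``p_01``
  (a fresh signed weight is drawn) and 1 -> 0 with probability ``p_10``.

Copies created by duplication carry ids ``family.k`` and are globally
unique across the tree, so orthology in the union gene space is exact by
construction.  The true history of events is recorded and replayable.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .history import BranchEvents, DupLossHistory, GeneContent
from .networks import WeightedNet, gene_family
from .trees import Phylogeny

__all__ = [
    "EvoParams",
    "random_root",
    "init_duplicate",
    "evolve_branch",
    "simulate_tree",
    "expected_event_counts",
]


@dataclass(frozen=True)
class EvoParams:
    """Parameters of the network evolution model.

    ``pi1`` is the background proportion of edges (the prior on an entry
    being 1); ``p01``/``p10`` form the 2x2 edge substitution matrix P.
    Defaults put the edge dynamics close to stationarity at ``pi1``
    (p01/(p01+p10) ~ 0.15) and, on the standard 35-node/15-gene instance,
    yield on the order of 20 duplications and 20 losses along the tree.
    """

    p_d: float = 0.04
    p_l: float = 0.04
    pi1: float = 0.15
    p01: float = 0.009
    p10: float = 0.05
    init_mode: str = "neutral"  # neutral | inheritance | preferential
    r_lose: float = 0.1
    r_gain: float = 0.1
    weight_min: float = 0.25
    weight_max: float = 1.0
    self_loops: bool = True
    #: if True, p_d/p_l/p01/p10 are rates per unit branch length
    scale_by_branch_length: bool = False

    def __post_init__(self):
        for name in ("p_d", "p_l", "pi1", "p01", "p10", "r_lose", "r_gain"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.init_mode not in ("neutral", "inheritance", "preferential"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")

    @property
    def pi0(self) -> float:
        return 1.0 - self.pi1

    @property
    def P(self) -> np.ndarray:
        """2x2 edge substitution matrix over {0, 1}."""
        return np.array([[1 - self.p01, self.p01], [self.p10, 1 - self.p10]])

    def branch_probs(self, length: float) -> tuple[float, float, float, float]:
        """(p_d, p_l, p01, p10) effective on a branch of the given length."""
        if not self.scale_by_branch_length:
            return self.p_d, self.p_l, self.p01, self.p10
        clip = lambda p: float(min(1.0, p * length))
        return clip(self.p_d), clip(self.p_l), clip(self.p01), clip(self.p10)


def _draw_weights(params: EvoParams, size, rng: np.random.Generator) -> np.ndarray:
    """Signed weights, |w| uniform on [weight_min, weight_max], random sign."""
    mag = rng.uniform(params.weight_min, params.weight_max, size=size)
    sign = rng.choice((-1.0, 1.0), size=size)
    return mag * sign


def random_root(
    n_genes: int = 15,
    params: EvoParams = EvoParams(),
    rng: np.random.Generator | int | None = None,
) -> WeightedNet:
    """Random weighted root network with edge density ``pi1``.

    Each entry (off-diagonal, plus the diagonal when ``self_loops``) is an
    edge independently with probability ``pi1``; edge weights are signed
    with magnitude uniform on [weight_min, weight_max].
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    rng = np.random.default_rng(rng)
    genes = [f"g{i + 1:02d}" for i in range(n_genes)]
    present = rng.random((n_genes, n_genes)) < params.pi1
    if not params.self_loops:
        np.fill_diagonal(present, False)
    matrix = np.where(present, _draw_weights(params, (n_genes, n_genes), rng), 0.0)
    return WeightedNet(genes, matrix)


def init_duplicate(
    net: WeightedNet,
    source: str,
    new_id: str,
    params: EvoParams,
    rng: np.random.Generator,
    mode: str | None = None,
) -> WeightedNet:
    """Add a duplicated copy of ``source`` to the network.

    neutral
        Each connection of the new copy is an edge independently with
        probability ``pi1``, regardless of the source's connections.
    inheritance
        The copy inherits the source's row/column, then drops each
        inherited edge with ``r_lose`` and gains each non-edge with
        ``r_gain``.
    preferential
        The copy connects to ~Binomial(n, pi1) partners sampled without
        replacement with probability proportional to total (in+out)
        degree; each connection's direction is chosen at random.
    """
    mode = mode or params.init_mode
    idx = net.gene_index()
    if source not in idx:
        raise KeyError(f"unknown source gene {source!r}")
    n = net.n
    m = np.zeros((n + 1, n + 1))
    m[:n, :n] = net.matrix
    s = idx[source]

    if mode == "neutral":
        limit = n + 1 if params.self_loops else n
        row_edge = rng.random(limit) < params.pi1
        col_edge = rng.random(n) < params.pi1
        m[n, :limit] = np.where(row_edge, _draw_weights(params, limit, rng), 0.0)
        m[:n, n] = np.where(col_edge, _draw_weights(params, n, rng), 0.0)
    elif mode == "inheritance":
        m[n, :n] = net.matrix[s, :]
        m[:n, n] = net.matrix[:, s]
        if params.self_loops:
            m[n, n] = net.matrix[s, s]
            # regulation between the two copies mirrors the source's self-edge
            m[n, s] = net.matrix[s, s]
            m[s, n] = net.matrix[s, s]
        new_row_col = np.zeros((n + 1, n + 1), dtype=bool)
        new_row_col[n, :] = True
        new_row_col[:, n] = True
        if not params.self_loops:
            new_row_col[n, n] = False
        inherited = new_row_col & (m != 0)
        absent = new_row_col & (m == 0)
        drop = inherited & (rng.random(m.shape) < params.r_lose)
        gain = absent & (rng.random(m.shape) < params.r_gain)
        m[drop] = 0.0
        m[gain] = _draw_weights(params, int(gain.sum()), rng)
    elif mode == "preferential":
        degree = (net.matrix != 0).sum(axis=0) + (net.matrix != 0).sum(axis=1)
        k = int(rng.binomial(n, params.pi1))
        k = min(k, n)
        if k > 0:
            weights = degree.astype(float)
            if weights.sum() == 0:
                weights = np.ones(n)
            partners = _weighted_sample_without_replacement(weights, k, rng)
            w = _draw_weights(params, k, rng)
            outgoing = rng.random(k) < 0.5
            for p, wi, out in zip(partners, w, outgoing):
                if out:
                    m[n, p] = wi
                else:
                    m[p, n] = wi
        if params.self_loops and rng.random() < params.pi1:
            m[n, n] = _draw_weights(params, (), rng)
    else:  # pragma: no cover
        raise ValueError(f"unknown init mode {mode!r}")

    return WeightedNet(list(net.genes) + [new_id], m)


def _weighted_sample_without_replacement(
    weights: np.ndarray, k: int, rng: np.random.Generator
) -> list[int]:
    chosen: list[int] = []
    w = weights.astype(float).copy()
    for _ in range(k):
        total = w.sum()
        if total <= 0:
            remaining = [i for i in range(len(w)) if i not in chosen]
            chosen.append(int(rng.choice(remaining)))
            continue
        i = int(rng.choice(len(w), p=w / total))
        chosen.append(i)
        w[i] = 0.0
    return chosen


class _CopyNamer:
    """Allocates globally unique copy ids ``family.k`` across a simulation."""

    def __init__(self, genes):
        self.next_index: dict[str, int] = {}
        for g in genes:
            fam = gene_family(g)
            parts = g.split(".", 1)
            k = int(parts[1]) if len(parts) > 1 else 0
            self.next_index[fam] = max(self.next_index.get(fam, 0), k) + 1

    def new_copy(self, source: str) -> str:
        fam = gene_family(source)
        k = self.next_index.get(fam, 1)
        self.next_index[fam] = k + 1
        return f"{fam}.{k}"


def evolve_branch(
    parent: WeightedNet,
    params: EvoParams,
    rng: np.random.Generator,
    branch_length: float = 1.0,
    namer: _CopyNamer | None = None,
    max_resample: int = 100,
) -> tuple[WeightedNet, BranchEvents]:
    """Evolve a network along one branch; returns the child and the events.

    Duplications are applied first (each gene present at the branch start,
    once), then losses (again on the branch-start genes, so a fresh copy
    cannot be lost on the branch that created it), then edge mutations on
    every remaining entry.  If a loss draw would empty the network it is
    redrawn (up to ``max_resample`` times).
    """
    if parent.n == 0:
        raise ValueError("parent network is empty")
    p_d, p_l, p01, p10 = params.branch_probs(branch_length)
    namer = namer or _CopyNamer(parent.genes)
    start_genes = list(parent.genes)
    events = BranchEvents()

    net = parent
    for g in start_genes:
        if rng.random() < p_d:
            new_id = namer.new_copy(g)
            net = init_duplicate(net, g, new_id, params, rng)
            events.duplications.append((g, new_id))

    for attempt in range(max_resample):
        lost = [g for g in start_genes if rng.random() < p_l]
        if len(lost) < net.n:
            break
    else:
        raise RuntimeError("could not draw a non-extinguishing loss set")
    events.losses = lost
    if lost:
        keep = [i for i, g in enumerate(net.genes) if g not in set(lost)]
        net = WeightedNet(
            [net.genes[i] for i in keep], net.matrix[np.ix_(keep, keep)]
        )
    else:
        net = net.copy()

    m = net.matrix
    mutable = np.ones(m.shape, dtype=bool)
    if not params.self_loops:
        np.fill_diagonal(mutable, False)
    u = rng.random(m.shape)
    gains = mutable & (m == 0) & (u < p01)
    losses = mutable & (m != 0) & (u < p10)
    m[gains] = _draw_weights(params, int(gains.sum()), rng)
    m[losses] = 0.0
    return net, events


def simulate_tree(
    tree: Phylogeny,
    root: WeightedNet,
    params: EvoParams = EvoParams(),
    seed: int | np.random.Generator | None = None,
) -> tuple[dict[str, WeightedNet], DupLossHistory]:
    """Evolve the root network down the tree; record the true history.

    Returns the weighted "true" networks at the leaves (keyed by organism
    label) and the replayable :class:`DupLossHistory`, whose ``contents``
    give the gene set at every node.  Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    namer = _CopyNamer(root.genes)
    nets: dict[str, WeightedNet] = {tree.root.label: root}
    branches: dict[tuple[str, str], BranchEvents] = {}
    contents: GeneContent = {tree.root.label: frozenset(root.genes)}
    for parent, child in tree.branches():
        child_net, events = evolve_branch(
            nets[parent.label], params, rng, branch_length=child.length, namer=namer
        )
        nets[child.label] = child_net
        branches[(parent.label, child.label)] = events
        contents[child.label] = frozenset(child_net.genes)
    history = DupLossHistory(
        root_content=frozenset(root.genes), branches=branches, contents=contents
    )
    history.validate(tree)
    leaf_nets = {leaf.label: nets[leaf.label] for leaf in tree.leaves}
    return leaf_nets, history


def expected_event_counts(
    tree: Phylogeny, n_root: int, p_d: float, p_l: float
) -> tuple[float, float]:
    """Analytic expectation of (duplications, losses) along the tree.

    Expected gene count propagates as E[n_child] = E[n_parent](1 + p_d - p_l)
    (duplications and losses both act once per branch-start gene); expected
    events on a branch are p_d * E[n_start] and p_l * E[n_start].  Ignores
    the resampling applied when a branch would lose every gene, which is
    negligible at realistic rates.
    """
    expect = {tree.root.label: float(n_root)}
    dups = losses = 0.0
    for parent, child in tree.branches():
        n_start = expect[parent.label]
        dups += p_d * n_start
        losses += p_l * n_start
        expect[child.label] = n_start * (1.0 + p_d - p_l)
    return dups, losses
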