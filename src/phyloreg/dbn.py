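"""Penalized dynamic-Bayesian-network structure learning from binary series.

The learner scores each gene's parent set (parents act at t-1) by the
maximum-likelihood log-probability of the gene's column minus a structure
penalty ``k_p * 2^|Pa| * log N``, where ``N`` is the number of observed
transitions and ``2^|Pa|`` the number of free CPT parameters for that gene.
The score is decomposable, so the network optimum is found by exhaustive
per-gene search over parent sets up to ``max_parents`` (exact at the gene
counts this package targets); a greedy forward-selection mode is available
for larger problems.

CPT entries are empirical conditional frequencies with Laplace smoothing
``alpha`` (default 1) to avoid log 0.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .expression import ExpressionDataset
from .networks import WeightedNet

__all__ = [
    "DbnModel",
    "score_gene",
    "learn_structure",
    "learn_structure_sweep",
    "cpt_edge_confidence",
    "default_kp_grid",
]


def default_kp_grid() -> np.ndarray:
    """The standard 11-point penalty sweep: k_p = 0 to 0.5 in steps of 0.05."""
    return np.round(np.linspace(0.0, 0.5, 11), 10)


@dataclass
class DbnModel:
    """A fitted first-order DBN: structure, CPTs, and diagnostics.

    ``cpts[g]`` has ``2 ** len(parents[g])`` entries, the probability that
    gene ``g`` is on given the parent configuration; configuration index
    encodes parent k (in listed order) at bit k.  ``single_effects[j, i]``
    is the empirical single-parent effect P(x_i=1|x_j=1) - P(x_i=1|x_j=0)
    used for confidence in edge absence.
    """

    genes: list[str]
    parents: dict[str, tuple[str, ...]]
    cpts: dict[str, np.ndarray]
    N: int
    alpha: float
    single_effects: np.ndarray

    @property
    def n_params(self) -> int:
        return sum(2 ** len(p) for p in self.parents.values())

    def cpt_effect(self, gene: str, parent: str) -> float:
        """Signed effect of one fitted parent, other parents averaged.

        Mean over the other parents' configurations of
        P(on | parent=1, rest) - P(on | parent=0, rest).
        """
        pa = self.parents[gene]
        pos = pa.index(parent)
        cpt = self.cpts[gene]
        idx = np.arange(len(cpt))
        on = (idx >> pos) & 1 == 1
        return float(cpt[on].mean() - cpt[~on].mean())


def _transition_arrays(D: ExpressionDataset) -> tuple[np.ndarray, np.ndarray, int]:
    if D.kind != "binary":
        raise ValueError("the DBN learner requires binary expression data")
    x = D.values.astype(np.int64)
    return x[:, :-1], x[:, 1:], D.T - 1


def _loglik_and_cpt(
    target: np.ndarray, parent_rows: np.ndarray, alpha: float
) -> tuple[float, np.ndarray]:
    """Smoothed ML log-likelihood of one gene's transitions and its CPT."""
    p = parent_rows.shape[0]
    if p:
        config = np.zeros(parent_rows.shape[1], dtype=np.int64)
        for k in range(p):
            config |= parent_rows[k] << k
    else:
        config = np.zeros(target.shape[0], dtype=np.int64)
    counts = np.bincount(config * 2 + target, minlength=2 ** (p + 1)).reshape(-1, 2)
    n0, n1 = counts[:, 0].astype(float), counts[:, 1].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        # unsmoothed fit on an unobserved configuration is 0/0; those
        # configurations contribute nothing to the likelihood either way
        p1 = (n1 + alpha) / (n0 + n1 + 2 * alpha)
        terms = n1 * np.log(p1) + n0 * np.log(1.0 - p1)
    loglik = float(np.where((n0 + n1) > 0, np.nan_to_num(terms), 0.0).sum())
    return loglik, np.where(np.isnan(p1), 0.5, p1)


def score_gene(
    D: ExpressionDataset,
    gene: str,
    parents: tuple[str, ...] | list[str],
    k_p: float,
    alpha: float = 1.0,
) -> float:
    """Penalized score of one gene's parent set.

    ``log Pr(column | parents) - k_p * 2^|parents| * log N`` with N = T - 1
    transitions; the full-network score is the sum over genes.
    """
    if len(set(parents)) != len(parents):
        raise ValueError("parents must be distinct")
    prev, nxt, N = _transition_arrays(D)
    idx = {g: i for i, g in enumerate(D.genes)}
    gi = idx[gene]
    if parents:
        rows = np.array([prev[idx[p]] for p in parents], dtype=np.int64)
    else:
        rows = np.empty((0, N), dtype=np.int64)
    loglik, _ = _loglik_and_cpt(nxt[gi], rows, alpha)
    return loglik - k_p * (2 ** len(parents)) * math.log(N)


def _single_parent_effects(
    prev: np.ndarray, nxt: np.ndarray, N: int, alpha: float
) -> np.ndarray:
    """Empirical effect[j, i] = P(x_i=1 | x_j=1) - P(x_i=1 | x_j=0)."""
    c11 = prev.astype(float) @ nxt.T.astype(float)  # [j, i]
    nj1 = prev.sum(axis=1, keepdims=True).astype(float)
    i1 = nxt.sum(axis=1, keepdims=True).T.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_on_j1 = (c11 + alpha) / (nj1 + 2 * alpha)
        p_on_j0 = (i1 - c11 + alpha) / (N - nj1 + 2 * alpha)
    # a constant regulator column carries no signal: zero effect
    return np.nan_to_num(p_on_j1 - p_on_j0)


def _gene_candidates(
    D: ExpressionDataset, gene_i: int, allow_self: bool
) -> list[int]:
    return [j for j in range(D.n_genes) if allow_self or j != gene_i]


def _enumerate_gene(
    prev: np.ndarray,
    nxt: np.ndarray,
    gene_i: int,
    candidates: list[int],
    max_parents: int,
    alpha: float,
) -> list[tuple[tuple[int, ...], float]]:
    """(parent set, log-likelihood) in tie-break order (size, then lex)."""
    out = []
    target = nxt[gene_i]
    for size in range(max_parents + 1):
        for pa in combinations(candidates, size):
            rows = prev[list(pa)] if pa else np.empty((0, target.shape[0]), int)
            loglik, _ = _loglik_and_cpt(target, rows, alpha)
            out.append((pa, loglik))
    return out


def _n_sets(n_candidates: int, max_parents: int) -> int:
    return sum(math.comb(n_candidates, k) for k in range(max_parents + 1))


def learn_structure_sweep(
    D: ExpressionDataset,
    kp_grid=None,
    max_parents: int = 3,
    alpha: float = 1.0,
    allow_self: bool = True,
    max_sets_per_gene: int = 2_000_000,
) -> dict[float, tuple[WeightedNet, DbnModel]]:
    """Learn one network per penalty coefficient, sharing the likelihoods.

    The per-parent-set log-likelihoods do not depend on ``k_p``, so the
    exhaustive enumeration is done once and each grid point only re-applies
    its penalty; results are identical to independent runs.
    """
    kp_grid = default_kp_grid() if kp_grid is None else np.asarray(kp_grid, float)
    prev, nxt, N = _transition_arrays(D)
    logN = math.log(N)
    n = D.n_genes
    effects = _single_parent_effects(prev, nxt, N, alpha)

    per_gene: list[list[tuple[tuple[int, ...], float]]] = []
    for i in range(n):
        cands = _gene_candidates(D, i, allow_self)
        if _n_sets(len(cands), max_parents) > max_sets_per_gene:
            raise ValueError(
                "exhaustive parent-set search too large; use method='greedy' "
                "in learn_structure or lower max_parents"
            )
        per_gene.append(_enumerate_gene(prev, nxt, i, cands, max_parents, alpha))

    out: dict[float, tuple[WeightedNet, DbnModel]] = {}
    for kp in kp_grid:
        parents_idx: list[tuple[int, ...]] = []
        for i in range(n):
            best_pa, best_score = (), -np.inf
            for pa, loglik in per_gene[i]:
                score = loglik - kp * (2 ** len(pa)) * logN
                if score > best_score:  # strict: ties keep the earlier set
                    best_pa, best_score = pa, score
            parents_idx.append(best_pa)
        out[float(kp)] = _assemble(D, parents_idx, prev, nxt, N, alpha, effects)
    return out


def _assemble(
    D: ExpressionDataset,
    parents_idx: list[tuple[int, ...]],
    prev: np.ndarray,
    nxt: np.ndarray,
    N: int,
    alpha: float,
    effects: np.ndarray,
) -> tuple[WeightedNet, DbnModel]:
    genes = D.genes
    parents = {}
    cpts = {}
    W = np.zeros((len(genes), len(genes)))
    for i, pa in enumerate(parents_idx):
        parents[genes[i]] = tuple(genes[j] for j in pa)
        rows = prev[list(pa)] if pa else np.empty((0, nxt.shape[1]), int)
        _, cpt = _loglik_and_cpt(nxt[i], rows, alpha)
        cpts[genes[i]] = cpt
        model_stub = DbnModel(genes, parents, cpts, N, alpha, effects)
        for j in pa:
            W[j, i] = model_stub.cpt_effect(genes[i], genes[j])
    model = DbnModel(list(genes), parents, cpts, N, alpha, effects)
    return WeightedNet(list(genes), W), model


def learn_structure(
    D: ExpressionDataset,
    k_p: float,
    max_parents: int = 3,
    alpha: float = 1.0,
    allow_self: bool = True,
    method: str = "exhaustive",
    return_model: bool = False,
):
    """Learn the score-optimal structure at one penalty coefficient.

    Returns a :class:`WeightedNet` whose weight on edge j->i is the signed
    CPT effect of j on i (other parents averaged); with ``return_model``
    the fitted :class:`DbnModel` is returned alongside.  Ties are broken
    toward smaller parent sets, then lexicographically.
    """
    if method == "exhaustive":
        net, model = learn_structure_sweep(
            D, [k_p], max_parents=max_parents, alpha=alpha, allow_self=allow_self
        )[float(k_p)]
    elif method == "greedy":
        net, model = _learn_greedy(D, k_p, max_parents, alpha, allow_self)
    else:
        raise ValueError(f"unknown method {method!r}")
    return (net, model) if return_model else net


def _learn_greedy(D, k_p, max_parents, alpha, allow_self):
    prev, nxt, N = _transition_arrays(D)
    logN = math.log(N)
    effects = _single_parent_effects(prev, nxt, N, alpha)
    parents_idx = []
    for i in range(D.n_genes):
        cands = _gene_candidates(D, i, allow_self)
        current: tuple[int, ...] = ()
        cur_ll, _ = _loglik_and_cpt(nxt[i], np.empty((0, nxt.shape[1]), int), alpha)
        cur_score = cur_ll - k_p * logN
        while len(current) < max_parents:
            best_j, best_score = None, cur_score
            for j in cands:
                if j in current:
                    continue
                trial = tuple(sorted(current + (j,)))
                ll, _ = _loglik_and_cpt(nxt[i], prev[list(trial)], alpha)
                score = ll - k_p * (2 ** len(trial)) * logN
                if score > best_score:
                    best_j, best_score = j, score
            if best_j is None:
                break
            current = tuple(sorted(current + (best_j,)))
            cur_score = best_score
        parents_idx.append(current)
    return _assemble(D, parents_idx, prev, nxt, N, alpha, effects)


def cpt_edge_confidence(model: DbnModel) -> np.ndarray:
    """Per-entry confidence in the fitted model's adjacency, in [0, 1].

    For a fitted edge j->i the confidence is |CPT effect of j on i| (other
    parents averaged).  For an absent entry it is the confidence that the
    absence is right: 1 - |empirical single-parent effect of j on i|, which
    is ~1 when j carries no signal for i and drops when an excluded
    candidate carries strong signal.
    """
    n = len(model.genes)
    conf = np.clip(1.0 - np.abs(model.single_effects), 0.0, 1.0)
    idx = {g: i for i, g in enumerate(model.genes)}
    for gene, pas in model.parents.items():
        i = idx[gene]
        for p in pas:
            conf[idx[p], i] = min(1.0, abs(model.cpt_effect(gene, p)))
    return conf
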