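"""Leaf-network refinement: RefineFast, RefineML and the iterative driver.

Both algorithms compare each leaf network entry with the corresponding
entry of the leaf's reconstructed parent.  Only entries that are not ``x``
in both matrices are eligible — refinement never edits gene contents.

* RefineFast resamples each eligible entry from the edge substitution
  matrix P conditioned on the parent's value (a pure sampling step; the
  original leaf value is discarded from the second round on).
* RefineML keeps the leaf value ``b`` as a prior weighted by a per-entry
  belief coefficient ``k_b`` and deterministically picks
  ``argmax_c p_ac * Q(c)`` with ``Q(c) = k_b`` if ``c = b`` else
  ``1 - k_b``, where ``a`` is the parent's value.

The belief coefficient mixes two terms: the confidence the base learner
assigns to the entry (from its CPT effects) and a phylogeny term — the
inverse-distance-weighted fraction of the other leaves that possess both
endpoint genes, so that corroboration from close relatives counts more.
"""
from __future__ import annotations

import numpy as np

from .ancestral import TernaryModel, build_Pprime, reconstruct_networks
from .dbn import DbnModel, cpt_edge_confidence
from .evolution import EvoParams
from .history import GeneContent
from .networks import TernaryNet, X
from .trees import Phylogeny

__all__ = [
    "refine_fast",
    "belief_coefficients",
    "refine_ml",
    "refine_iterate",
]


def _eligible(leaf: TernaryNet, parent: TernaryNet) -> np.ndarray:
    if leaf.genes != parent.genes:
        raise ValueError("leaf and parent must share one union gene list")
    return (leaf.matrix != X) & (parent.matrix != X)


def refine_fast(
    leaf: TernaryNet,
    parent: TernaryNet,
    params: EvoParams,
    rng: np.random.Generator | int | None = None,
) -> TernaryNet:
    """Resample eligible entries from the parent's evolutionary distribution.

    An eligible entry becomes 1 with probability ``p_a1`` where ``a`` is
    the parent's value (``p_01`` under an absent parent edge, ``1 - p_10``
    under a present one); x-involved entries are copied from the leaf.
    """
    rng = np.random.default_rng(rng)
    mask = _eligible(leaf, parent)
    p_on = np.where(parent.matrix == 1, 1.0 - params.p10, params.p01)
    draws = (rng.random(leaf.matrix.shape) < p_on).astype(np.int8)
    out = leaf.matrix.copy()
    out[mask] = draws[mask]
    return TernaryNet(list(leaf.genes), out)


def belief_coefficients(
    models: dict[str, DbnModel],
    tree: Phylogeny,
    contents: GeneContent,
    union_genes: list[str],
    beta: float = 0.5,
) -> dict[str, np.ndarray]:
    """Per-leaf, per-entry belief coefficients k_b in [0, 1].

    ``k_b = beta * term1 + (1 - beta) * term2`` where term1 is the base
    learner's CPT-derived confidence for the entry (embedded into the
    union gene space) and, for leaf k, term2 is
    ``sum_{i != k} (1 - h_i)/d_ik / sum_{i != k} 1/d_ik`` with ``h_i = 0``
    iff leaf i possesses both endpoint genes and ``d_ik`` the tree
    distance between the leaves.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must be in [0, 1]")
    n = len(union_genes)
    pos = {g: i for i, g in enumerate(union_genes)}
    leaves = tree.leaf_labels
    for lab in models:
        if lab not in set(leaves):
            raise ValueError(f"model for {lab!r} but no such leaf")

    # presence of both endpoint genes, per leaf, per entry
    both: dict[str, np.ndarray] = {}
    for lab in leaves:
        present = np.array([g in contents[lab] for g in union_genes])
        both[lab] = present[:, None] & present[None, :]

    out: dict[str, np.ndarray] = {}
    for lab in models:
        others = [m for m in leaves if m != lab]
        w = np.array([1.0 / tree.leaf_distance(lab, m) for m in others])
        stack = np.stack([both[m] for m in others]).astype(float)
        term2 = np.tensordot(w, stack, axes=(0, 0)) / w.sum()

        model = models[lab]
        conf_own = cpt_edge_confidence(model)
        term1 = np.zeros((n, n))
        idx = [pos[g] for g in model.genes]
        term1[np.ix_(idx, idx)] = conf_own
        out[lab] = np.clip(beta * term1 + (1.0 - beta) * term2, 0.0, 1.0)
    return out


def refine_ml(
    leaf: TernaryNet,
    parent: TernaryNet,
    beliefs: np.ndarray,
    params: EvoParams,
) -> TernaryNet:
    """Deterministic ML refinement of one leaf against its parent.

    For each eligible entry with parent value ``a`` and leaf value ``b``,
    assigns ``argmax_{c in {0,1}} p_ac * Q(c)`` with ``Q(c) = k_b`` when
    ``c = b`` and ``1 - k_b`` otherwise; ties go to 0.
    """
    mask = _eligible(leaf, parent)
    beliefs = np.asarray(beliefs, float)
    if beliefs.shape != leaf.matrix.shape:
        raise ValueError("belief matrix shape mismatch")
    P = params.P
    a = np.clip(parent.matrix, 0, 1).astype(int)
    b = np.clip(leaf.matrix, 0, 1).astype(int)
    q1 = np.where(b == 1, beliefs, 1.0 - beliefs)  # Q(c=1)
    q0 = np.where(b == 0, beliefs, 1.0 - beliefs)  # Q(c=0)
    score0 = P[a, 0] * q0
    score1 = P[a, 1] * q1
    choice = (score1 > score0).astype(np.int8)  # tie -> 0
    out = leaf.matrix.copy()
    out[mask] = choice[mask]
    return TernaryNet(list(leaf.genes), out)


def refine_iterate(
    tree: Phylogeny,
    leaf_nets: dict[str, TernaryNet],
    contents: GeneContent,
    params: EvoParams,
    algorithm: str = "ml",
    rounds: int = 3,
    models: dict[str, DbnModel] | None = None,
    beliefs: dict[str, np.ndarray] | None = None,
    beta: float = 0.5,
    rng: np.random.Generator | int | None = None,
    model: TernaryModel | None = None,
    return_snapshots: bool = False,
):
    """Alternate ancestral reconstruction and leaf refinement.

    Each round reconstructs ancestral networks from the current leaves and
    refines every leaf against its parent.  For ``algorithm="ml"`` the
    belief coefficients are computed once from the original base-learner
    models and reused in later rounds; for ``"fast"`` the refined samples
    replace the leaves entirely after round one.  Stops after ``rounds``
    rounds or at a fixed point, whichever comes first.
    """
    if algorithm not in ("fast", "ml"):
        raise ValueError("algorithm must be 'fast' or 'ml'")
    rng = np.random.default_rng(rng)
    model = model or build_Pprime(params)
    current = {lab: net.copy() for lab, net in leaf_nets.items()}
    union_genes = next(iter(current.values())).genes

    if algorithm == "ml" and beliefs is None:
        if models is None:
            raise ValueError("RefineML needs fitted models or belief maps")
        beliefs = belief_coefficients(models, tree, contents, union_genes, beta=beta)

    parent_of = {
        leaf.label: leaf.parent.label for leaf in tree.leaves
    }
    snapshots = []
    for _ in range(rounds):
        ancestors = reconstruct_networks(tree, current, contents, model)
        new = {}
        for lab, net in current.items():
            parent = ancestors[parent_of[lab]]
            if algorithm == "fast":
                new[lab] = refine_fast(net, parent, params, rng)
            else:
                new[lab] = refine_ml(net, parent, beliefs[lab], params)
        changed = any(
            not np.array_equal(new[lab].matrix, current[lab].matrix)
            for lab in current
        )
        current = new
        if return_snapshots:
            snapshots.append({lab: n.copy() for lab, n in current.items()})
        if not changed:
            break
    if return_snapshots:
        return current, snapshots
    return current
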