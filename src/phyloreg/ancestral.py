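"""Joint maximum-likelihood ancestral reconstruction (revised FastML).

Ancestral network adjacency matrices are reconstructed one entry ("site")
at a time by max-product dynamic programming on the rooted binary tree,
over the ternary character set {0, 1, x}: ``x`` marks entries whose row or
column gene is absent from a node, and nodes where the gene content forces
``x`` are fixed before the recursion runs.

The ternary substitution matrix P' extends the 2x2 edge matrix P with the
duplication/loss parameters and introduces no new parameters:
``p'_ab = (1 - p_l) p_ab`` for a, b in {0, 1}; ``p'_ax = p_l``;
``p'_xb = p_d pi_b``; ``p'_xx = 1 - p_d``.  Each row sums to 1 exactly.

All likelihood bookkeeping is in log space; ties in the argmax are broken
toward 0 (no edge), biasing reconstruction to sparsity.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evolution import EvoParams
from .history import GeneContent
from .networks import TernaryNet, X
from .trees import Phylogeny

__all__ = [
    "TernaryModel",
    "build_Pprime",
    "joint_ml_reconstruct",
    "reconstruct_site",
    "reconstruct_networks",
]

_XS = 2  # internal state index of the character x


@dataclass(frozen=True)
class TernaryModel:
    """3x3 substitution matrix over (0, 1, x) plus the edge prior (pi0, pi1)."""

    Pprime: np.ndarray
    pi: np.ndarray

    def __post_init__(self):
        P = np.asarray(self.Pprime, float)
        if P.shape != (3, 3) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("Pprime must be 3x3 with rows summing to 1")
        if not np.isclose(np.asarray(self.pi).sum(), 1.0):
            raise ValueError("pi must sum to 1")


def build_Pprime(params: EvoParams) -> TernaryModel:
    """Derive the ternary substitution matrix from the evolution parameters."""
    p_d, p_l = params.p_d, params.p_l
    P = params.P
    Pp = np.array(
        [
            [(1 - p_l) * P[0, 0], (1 - p_l) * P[0, 1], p_l],
            [(1 - p_l) * P[1, 0], (1 - p_l) * P[1, 1], p_l],
            [p_d * params.pi0, p_d * params.pi1, 1 - p_d],
        ]
    )
    return TernaryModel(Pprime=Pp, pi=np.array([params.pi0, params.pi1]))


def _log(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(p)


def joint_ml_reconstruct(
    tree: Phylogeny,
    leaf_states: dict[str, np.ndarray],
    trans: np.ndarray,
    log_prior: np.ndarray,
    forced: dict[str, np.ndarray] | None = None,
    free_states: tuple[int, ...] = (0, 1),
    return_loglik: bool = False,
):
    """Generic vectorized joint-ML (max-product) reconstruction over sites.

    Parameters
    ----------
    leaf_states:
        Per leaf label, an integer state array of shape (S,).
    trans:
        k x k substitution matrix (rows: parent state, columns: child).
    log_prior:
        (k, S) log prior over root states (use -inf to bar states).
    forced:
        Optional per-node arrays with a fixed state index, or -1 where the
        node is free to take any of ``free_states``.
    free_states:
        The states an unforced internal node may take (argmax ties go to
        the earliest listed state).

    Returns the per-node state arrays (internal nodes and leaves); with
    ``return_loglik`` also the per-site log-likelihood of the joint optimum.
    """
    k = trans.shape[0]
    logP = _log(np.asarray(trans, float))
    S = next(iter(leaf_states.values())).shape[0]
    forced = forced or {}
    free = list(free_states)

    L: dict[str, np.ndarray] = {}
    C: dict[str, np.ndarray] = {}
    for node in tree.postorder():
        lab = node.label
        if node.is_leaf:
            b = np.asarray(leaf_states[lab])
            L[lab] = logP[:, b]  # (k, S): parent state a -> p'_{a, b_s}
            C[lab] = np.broadcast_to(b, (k, S)).copy()
            continue
        j, kk = (c.label for c in node.children)
        M = L[j] + L[kk]  # (k, S)
        f = forced.get(lab)
        if node.parent is None:
            scores = log_prior + M  # (k, S)
            sub = scores[free]
            char = np.array(free)[np.argmax(sub, axis=0)]
            if f is not None:
                char = np.where(f >= 0, f, char)
            root_char = char
            best = np.take_along_axis(scores, char[None, :], axis=0)[0]
        else:
            cand = logP[:, free, None] + M[free][None, :, :]  # (k, |free|, S)
            Lnode = cand.max(axis=1)
            Cnode = np.array(free)[np.argmax(cand, axis=1)]
            if f is not None:
                fixed = f >= 0
                if fixed.any():
                    ff = np.where(fixed, f, 0)
                    forced_L = logP[:, ff] + M[ff, np.arange(S)][None, :]
                    Lnode = np.where(fixed[None, :], forced_L, Lnode)
                    Cnode = np.where(fixed[None, :], ff[None, :], Cnode)
            L[lab], C[lab] = Lnode, Cnode

    # top-down readout
    states: dict[str, np.ndarray] = {tree.root.label: root_char}
    for parent, child in tree.branches():
        a = states[parent.label]
        states[child.label] = C[child.label][a, np.arange(S)]
    if return_loglik:
        return states, best
    return states


def _site_forced_from_contents(
    tree: Phylogeny, contents: GeneContent, pairs: list[tuple[str, str]]
) -> dict[str, np.ndarray]:
    forced = {}
    for node in tree.preorder():
        present = contents[node.label]
        absent = np.array(
            [(gi not in present) or (gj not in present) for gi, gj in pairs]
        )
        forced[node.label] = np.where(absent, _XS, -1)
    return forced


def reconstruct_site(
    tree: Phylogeny,
    leaf_chars: dict[str, int],
    node_present: dict[str, bool],
    model: TernaryModel,
) -> dict[str, int]:
    """Reconstruct one adjacency entry; scalar convenience wrapper.

    ``leaf_chars`` maps each leaf to 0, 1 or :data:`X`; ``node_present``
    says whether both endpoint genes are present at each node (leaves
    included; a leaf must carry ``x`` iff absent).  Returns the character
    (0, 1 or :data:`X`) at every node.
    """
    to_state = {0: 0, 1: 1, X: _XS, "x": _XS}
    leaf_states = {}
    for leaf in tree.leaves:
        c = to_state[leaf_chars[leaf.label]]
        if (c == _XS) != (not node_present[leaf.label]):
            raise ValueError(f"leaf {leaf.label}: character/content mismatch")
        leaf_states[leaf.label] = np.array([c])
    forced = {
        n.label: np.array([_XS if not node_present[n.label] else -1])
        for n in tree.preorder()
    }
    log_prior = np.concatenate([_log(model.pi), [-np.inf]])[:, None]
    states = joint_ml_reconstruct(
        tree, leaf_states, model.Pprime, log_prior, forced=forced
    )
    back = {0: 0, 1: 1, _XS: X}
    return {lab: back[int(arr[0])] for lab, arr in states.items()}


def reconstruct_networks(
    tree: Phylogeny,
    leaf_nets: dict[str, TernaryNet],
    contents: GeneContent,
    model: TernaryModel | EvoParams,
) -> dict[str, TernaryNet]:
    """Reconstruct ancestral ternary networks at every internal node.

    Leaf networks must be embedded in a common union gene space with ``x``
    exactly at the rows/columns of genes absent per ``contents``; entries
    are reconstructed independently (sitewise) by the revised FastML.
    """
    if isinstance(model, EvoParams):
        model = build_Pprime(model)
    genes = None
    for net in leaf_nets.values():
        if genes is None:
            genes = net.genes
        elif net.genes != genes:
            raise ValueError("leaf networks must share one union gene list")
    n = len(genes)
    pairs = [(gi, gj) for gi in genes for gj in genes]
    forced = _site_forced_from_contents(tree, contents, pairs)

    leaf_states = {}
    for leaf in tree.leaves:
        flat = leaf_nets[leaf.label].matrix.reshape(-1).astype(np.int64)
        state = np.where(flat == X, _XS, flat)
        expect_x = forced[leaf.label] == _XS
        if not np.array_equal(state == _XS, expect_x):
            raise ValueError(
                f"leaf {leaf.label}: x entries disagree with gene contents"
            )
        leaf_states[leaf.label] = state

    log_prior = np.concatenate([_log(model.pi), [-np.inf]])[:, None]
    states = joint_ml_reconstruct(
        tree, leaf_states, model.Pprime, log_prior, forced=forced
    )
    out = {}
    for node in tree.internal_nodes:
        m = states[node.label].astype(np.int8)
        m[m == _XS] = X
        out[node.label] = TernaryNet(list(genes), m.reshape(n, n))
    return out
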