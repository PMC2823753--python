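"""Inference of ancestral gene contents and duplication/loss histories.

Three reconstruction models are provided, mirroring the alternatives a
practitioner has when the true history is unknown:

* duplication-only — an internal node's gene set is the intersection of
  its subtree's leaf gene sets (minimizes the number of duplications);
* loss-only — the union of the subtree's leaf gene sets (minimizes the
  number of losses);
* presence FastML — per-gene joint-ML reconstruction of the binary
  presence/absence character on the tree under a 2-state gain/loss model.

Histories can also be imported from JSON files produced externally (e.g.
exported from a reconciliation tool) via :meth:`DupLossHistory.load`.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ancestral import joint_ml_reconstruct
from .history import BranchEvents, DupLossHistory, GeneContent
from .networks import gene_family, sort_genes
from .trees import Phylogeny

__all__ = [
    "ContentModel",
    "presence_matrix",
    "content_duplication_only",
    "content_loss_only",
    "content_fastml",
    "derive_history",
    "randomize_orthology",
]


@dataclass(frozen=True)
class ContentModel:
    """2-state presence substitution model: gain g01, loss g10.

    Defaults derive from the network evolution parameters without new
    parameters: presence gain is driven by duplication (g01 = p_d) and
    absence by gene loss (g10 = p_l).  The root prior defaults to the
    leaf presence frequency of each gene's column.
    """

    g01: float = 0.04
    g10: float = 0.04

    def __post_init__(self):
        if not (0 <= self.g01 <= 1 and 0 <= self.g10 <= 1):
            raise ValueError("g01 and g10 must be in [0, 1]")

    @property
    def trans(self) -> np.ndarray:
        return np.array([[1 - self.g01, self.g01], [self.g10, 1 - self.g10]])


def presence_matrix(
    leaf_contents: dict[str, frozenset[str] | set[str]]
) -> pd.DataFrame:
    """Leaves x genes 0/1 DataFrame from per-organism gene sets."""
    genes = sort_genes(g for content in leaf_contents.values() for g in content)
    rows = {
        org: [1 if g in content else 0 for g in genes]
        for org, content in leaf_contents.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=genes)
    if (df.sum(axis=0) == 0).any():
        raise ValueError("every gene must be present in at least one organism")
    return df


def _check_presence(tree: Phylogeny, presence: pd.DataFrame) -> None:
    if set(presence.index) != set(tree.leaf_labels):
        raise ValueError("presence matrix rows must match the tree's leaves")


def _fold_contents(tree: Phylogeny, presence: pd.DataFrame, op) -> GeneContent:
    contents: GeneContent = {}
    genes = list(presence.columns)
    for node in tree.postorder():
        if node.is_leaf:
            row = presence.loc[node.label]
            contents[node.label] = frozenset(g for g in genes if row[g])
        else:
            a, b = (contents[c.label] for c in node.children)
            contents[node.label] = frozenset(op(a, b))
    return contents


def content_duplication_only(
    tree: Phylogeny, presence: pd.DataFrame
) -> tuple[GeneContent, DupLossHistory]:
    """Ancestral contents when gene-content differences are all duplications.

    Each internal node receives the intersection of its subtree's leaf
    gene sets; every parent->child content gain becomes a duplication
    event.  The resulting history has the minimum possible number of
    duplications (and no losses).
    """
    _check_presence(tree, presence)
    contents = _fold_contents(tree, presence, frozenset.intersection)
    return contents, derive_history(tree, contents)


def content_loss_only(
    tree: Phylogeny, presence: pd.DataFrame
) -> tuple[GeneContent, DupLossHistory]:
    """Ancestral contents when gene-content differences are all losses.

    Union fold; the history has the minimum possible number of losses
    (and no duplications).
    """
    _check_presence(tree, presence)
    contents = _fold_contents(tree, presence, frozenset.union)
    return contents, derive_history(tree, contents)


def content_fastml(
    tree: Phylogeny,
    presence: pd.DataFrame,
    model: ContentModel = ContentModel(),
    prior: tuple[float, float] | None = None,
) -> tuple[GeneContent, DupLossHistory]:
    """Joint-ML ancestral presence states, one gene column at a time.

    The per-column root prior defaults to the column's leaf presence
    frequency (clipped away from 0 and 1); pass ``prior`` to override
    with one (gamma0, gamma1) for all columns.
    """
    _check_presence(tree, presence)
    genes = list(presence.columns)
    leaf_states = {
        leaf: presence.loc[leaf].to_numpy().astype(np.int64)
        for leaf in presence.index
    }
    if prior is None:
        freq = presence.to_numpy().mean(axis=0).astype(float)
        freq = np.clip(freq, 1e-6, 1 - 1e-6)
        log_prior = np.log(np.vstack([1 - freq, freq]))
    else:
        g0, g1 = prior
        log_prior = np.log(np.array([[g0], [g1]])) * np.ones((2, len(genes)))
    states = joint_ml_reconstruct(tree, leaf_states, model.trans, log_prior)
    contents = {
        lab: frozenset(g for g, s in zip(genes, arr) if s == 1)
        for lab, arr in states.items()
    }
    return contents, derive_history(tree, contents)


def derive_history(tree: Phylogeny, contents: GeneContent) -> DupLossHistory:
    """Turn node gene contents into a replayable event history.

    Every gene gained on a branch becomes one duplication event (its
    source is an arbitrary same-family gene of the parent if one exists,
    else null), every gene lost becomes a loss event; each event sits on
    the branch where the content changes.
    """
    branches: dict[tuple[str, str], BranchEvents] = {}
    for parent, child in tree.branches():
        pc, cc = contents[parent.label], contents[child.label]
        ev = BranchEvents()
        for g in sorted(cc - pc):
            fam = gene_family(g)
            same_family = sorted(h for h in pc if gene_family(h) == fam)
            ev.duplications.append((same_family[0] if same_family else None, g))
        ev.losses = sorted(pc - cc)
        branches[(parent.label, child.label)] = ev
    hist = DupLossHistory(
        root_content=frozenset(contents[tree.root.label]),
        branches=branches,
        contents=dict(contents),
    )
    hist.validate(tree)
    return hist


def randomize_orthology(
    presence: pd.DataFrame, rng: np.random.Generator | int | None = None
) -> pd.DataFrame:
    """Scramble copy<->column assignments within each multi-copy family.

    For every gene family with more than one column, each organism's
    presence pattern over that family's columns is permuted uniformly at
    random (independently per organism).  Per-organism copy counts are
    preserved; single-copy families are untouched.
    """
    rng = np.random.default_rng(rng)
    out = presence.copy()
    families: dict[str, list[str]] = {}
    for col in presence.columns:
        families.setdefault(gene_family(col), []).append(col)
    for fam, cols in families.items():
        if len(cols) < 2:
            continue
        block = out[cols].to_numpy()
        for r in range(block.shape[0]):
            block[r] = block[r][rng.permutation(len(cols))]
        out[cols] = block
    return out
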