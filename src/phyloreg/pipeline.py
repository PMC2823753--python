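"""End-to-end simulation study: evolve, express, infer, refine, score.

This module strings the pieces together the way the simulation benchmark
does: evolve "true" weighted networks down a tree, generate binary
expression with DBNSim, infer leaf networks with the penalized DBN learner
over the 11-point k_p grid, refine them with RefineFast and RefineML using
a chosen duplication/loss history, and score everything with pooled
sensitivity/specificity sweeps.

The standard instance is a 35-node tree (18 leaves) with a 15-gene root
and duplication/loss rates giving on the order of 20 duplications and 20
losses along the tree.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ancestral import build_Pprime
from .content import presence_matrix
from .dbn import default_kp_grid, learn_structure_sweep
from .evaluate import RocPoint, balanced_accuracy, roc_sweep
from .evolution import EvoParams, random_root, simulate_tree
from .expression import DbnSimParams, dbnsim
from .history import DupLossHistory, GeneContent
from .networks import TernaryNet, embed, sort_genes
from .refine import refine_iterate
from .trees import Phylogeny, random_binary_tree

__all__ = ["ExperimentResult", "run_experiment", "run_replicates"]


@dataclass
class ExperimentResult:
    """ROC sweeps before and after refinement, plus run bookkeeping."""

    tree: Phylogeny
    history: DupLossHistory
    truths: dict[str, TernaryNet]
    base: list[RocPoint]
    fast: list[RocPoint]
    ml: list[RocPoint]

    @property
    def summary(self) -> dict[str, float]:
        return {
            "base": balanced_accuracy(self.base),
            "refine_fast": balanced_accuracy(self.fast),
            "refine_ml": balanced_accuracy(self.ml),
        }


def run_experiment(
    seed: int,
    n_leaves: int = 18,
    n_root: int = 15,
    params: EvoParams = EvoParams(),
    kp_grid=None,
    rounds: int = 3,
    max_parents: int = 3,
    history_model: str = "true",
    tree: Phylogeny | None = None,
) -> ExperimentResult:
    """One full simulate/infer/refine/score run.

    ``history_model`` selects the gene contents handed to refinement:
    ``"true"`` (recorded during simulation), ``"dup-only"``, ``"loss-only"``
    or ``"fastml"`` (reconstructed from the leaf presence patterns).
    """
    from .content import (  # local import to avoid cycle at module load
        content_duplication_only,
        content_fastml,
        content_loss_only,
    )

    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(4)]
    kp_grid = default_kp_grid() if kp_grid is None else np.asarray(kp_grid, float)

    if tree is None:
        tree = random_binary_tree(n_leaves, rngs[0])
    root = random_root(n_root, params, rngs[1])
    true_nets, history = simulate_tree(tree, root, params, rngs[2])

    union = sort_genes(g for net in true_nets.values() for g in net.genes)
    truths = {lab: embed(net, union) for lab, net in true_nets.items()}

    if history_model == "true":
        contents: GeneContent = history.contents
    else:
        leaf_sets = {lab: frozenset(net.genes) for lab, net in true_nets.items()}
        presence = presence_matrix(leaf_sets)
        fn = {
            "dup-only": content_duplication_only,
            "loss-only": content_loss_only,
            "fastml": content_fastml,
        }[history_model]
        contents, _ = fn(tree, presence)
        # refinement never edits leaf contents: keep the true leaf gene sets
        contents = dict(contents)
        for lab, genes in leaf_sets.items():
            contents[lab] = genes

    # expression + inference, one penalty sweep per organism
    sweeps = {}
    expr_rng = rngs[3]
    for lab, net in true_nets.items():
        D = dbnsim(net, DbnSimParams(), expr_rng, organism=lab)
        sweeps[lab] = learn_structure_sweep(
            D, kp_grid, max_parents=max_parents
        )

    base_grid: dict[float, dict[str, TernaryNet]] = {}
    models_grid: dict[float, dict] = {}
    for kp in (float(k) for k in kp_grid):
        base_grid[kp] = {
            lab: embed(sweeps[lab][kp][0], union) for lab in true_nets
        }
        models_grid[kp] = {lab: sweeps[lab][kp][1] for lab in true_nets}

    tern_model = build_Pprime(params)
    fast_grid, ml_grid = {}, {}
    refine_rng = np.random.default_rng(ss.spawn(1)[0])
    for kp, leaf_nets in base_grid.items():
        fast_grid[kp] = refine_iterate(
            tree, leaf_nets, contents, params, algorithm="fast",
            rounds=rounds, rng=refine_rng, model=tern_model,
        )
        ml_grid[kp] = refine_iterate(
            tree, leaf_nets, contents, params, algorithm="ml",
            rounds=rounds, models=models_grid[kp], model=tern_model,
        )

    return ExperimentResult(
        tree=tree,
        history=history,
        truths=truths,
        base=roc_sweep(base_grid, truths),
        fast=roc_sweep(fast_grid, truths),
        ml=roc_sweep(ml_grid, truths),
    )


def run_replicates(
    n_runs: int,
    seed: int,
    **kwargs,
) -> list[ExperimentResult]:
    """Independent seeded runs of :func:`run_experiment`."""
    child_seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)
    return [run_experiment(int(s), **kwargs) for s in child_seeds]
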