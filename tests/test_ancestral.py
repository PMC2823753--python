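"""Revised FastML over {0, 1, x}: P' construction and reconstruction."""
import numpy as np
import pytest

from phyloreg import (
    EvoParams,
    TernaryNet,
    X,
    build_Pprime,
    random_binary_tree,
    random_root,
    read_newick,
    reconstruct_networks,
    reconstruct_site,
    simulate_tree,
)
from phyloreg.networks import embed, sort_genes


def test_pprime_no_duplication_loss_limit():
    p = EvoParams(p_d=0.0, p_l=0.0, p01=0.1, p10=0.2)
    m = build_Pprime(p)
    np.testing.assert_allclose(m.Pprime[:2, :2], p.P)
    assert m.Pprime[0, 2] == 0.0 and m.Pprime[1, 2] == 0.0
    assert m.Pprime[2, 2] == 1.0


def test_pprime_rows_sum_to_one():
    for seed in range(10):
        rng = np.random.default_rng(seed)
        p = EvoParams(
            p_d=rng.uniform(0, 0.5), p_l=rng.uniform(0, 0.5),
            p01=rng.uniform(0, 0.5), p10=rng.uniform(0, 0.5),
            pi1=rng.uniform(0.05, 0.95),
        )
        m = build_Pprime(p)
        np.testing.assert_allclose(m.Pprime.sum(axis=1), 1.0, atol=1e-12)


def test_pprime_entry_arithmetic():
    m = build_Pprime(EvoParams(p_l=0.3, p01=0.1))
    assert m.Pprime[0, 1] == pytest.approx(0.7 * 0.1)


def test_two_leaf_unanimity(cherry):
    model = build_Pprime(EvoParams(p01=0.05, p10=0.05, pi1=0.3))
    out = reconstruct_site(
        cherry,
        {"A": 1, "B": 1},
        {n.label: True for n in cherry.preorder()},
        model,
    )
    assert out[cherry.root.label] == 1


def test_all_absent_forces_x(quartet):
    model = build_Pprime(EvoParams())
    out = reconstruct_site(
        quartet,
        {l: X for l in quartet.leaf_labels},
        {n.label: False for n in quartet.preorder()},
        model,
    )
    assert all(v == X for v in out.values())


def test_leaf_content_mismatch_rejected(cherry):
    model = build_Pprime(EvoParams())
    with pytest.raises(ValueError):
        reconstruct_site(
            cherry, {"A": 1, "B": X},
            {n.label: True for n in cherry.preorder()}, model,
        )


# -- independent 2-state joint-ML pruning oracle ------------------------------

def _joint_ml_2state_oracle(tree, leaf_chars, P, pi):
    """Textbook max-product pruning over {0,1}, written independently."""
    L, C = {}, {}
    for node in tree.postorder():
        if node.is_leaf:
            b = leaf_chars[node.label]
            L[node.label] = {a: P[a][b] for a in (0, 1)}
            C[node.label] = {a: b for a in (0, 1)}
        elif node.parent is not None:
            j, k = (c.label for c in node.children)
            L[node.label], C[node.label] = {}, {}
            for a in (0, 1):
                scores = {c: P[a][c] * L[j][c] * L[k][c] for c in (0, 1)}
                best = max(scores, key=lambda c: (scores[c], -c))
                L[node.label][a] = scores[best]
                C[node.label][a] = best
    j, k = (c.label for c in tree.root.children)
    root_scores = {a: pi[a] * L[j][a] * L[k][a] for a in (0, 1)}
    root = max(root_scores, key=lambda a: (root_scores[a], -a))
    out = {tree.root.label: root}
    for parent, child in tree.branches():
        out[child.label] = C[child.label][out[parent.label]]
    return out


def test_matches_standard_two_state_pruning(tree10, rng):
    """With p_d = p_l = 0 and all genes present, the ternary recursion
    reduces to standard 2-state joint ML."""
    p = EvoParams(p_d=0.0, p_l=0.0, p01=0.15, p10=0.25, pi1=0.4)
    model = build_Pprime(p)
    present = {n.label: True for n in tree10.preorder()}
    P2 = {0: {0: 1 - p.p01, 1: p.p01}, 1: {0: p.p10, 1: 1 - p.p10}}
    pi = {0: p.pi0, 1: p.pi1}
    for _ in range(50):
        chars = {l: int(rng.integers(2)) for l in tree10.leaf_labels}
        got = reconstruct_site(tree10, chars, present, model)
        want = _joint_ml_2state_oracle(tree10, chars, P2, pi)
        # compare achieved joint probabilities (ties on labelings allowed)
        def score(lab2s):
            p_ = pi[lab2s[tree10.root.label]]
            for parent, child in tree10.branches():
                p_ *= P2[lab2s[parent.label]][lab2s[child.label]]
            return p_

        assert score(got) == pytest.approx(score(want))


def test_sitewise_independence(quartet):
    """Leaf nets differing in one entry differ only at that entry upstream."""
    genes = ["a", "b"]
    base = TernaryNet(genes, [[0, 1], [0, 0]])
    other = TernaryNet(genes, [[0, 1], [1, 0]])
    contents = {n.label: frozenset(genes) for n in quartet.preorder()}
    model = build_Pprime(EvoParams(p01=0.05, p10=0.05))
    nets_a = {l: base.copy() for l in quartet.leaf_labels}
    anc_a = reconstruct_networks(quartet, nets_a, contents, model)
    nets_b = {l: (other.copy() if l == "A" else base.copy())
              for l in quartet.leaf_labels}
    anc_b = reconstruct_networks(quartet, nets_b, contents, model)
    for lab in anc_a:
        diff = anc_a[lab].matrix != anc_b[lab].matrix
        assert not diff[[0, 0], [0, 1]].any()
        assert not diff[1, 1]


def test_identical_leaves_reconstruct_identically(quartet):
    genes = ["a", "b", "c"]
    rng = np.random.default_rng(0)
    m = rng.integers(0, 2, (3, 3)).astype(np.int8)
    net = TernaryNet(genes, m)
    contents = {n.label: frozenset(genes) for n in quartet.preorder()}
    model = build_Pprime(EvoParams(p01=0.05, p10=0.05))
    anc = reconstruct_networks(
        quartet, {l: net.copy() for l in quartet.leaf_labels}, contents, model
    )
    for a in anc.values():
        assert a == net


def test_vectorized_networks_equal_per_site_runs(params):
    """Sitewise recomputation oracle on a simulated 10-leaf instance."""
    tree = random_binary_tree(10, seed=5)
    root = random_root(8, params, 5)
    leaf_nets, history = simulate_tree(tree, root, params, seed=5)
    union = sort_genes(g for n in leaf_nets.values() for g in n.genes)
    embedded = {lab: embed(n, union) for lab, n in leaf_nets.items()}
    model = build_Pprime(params)
    anc = reconstruct_networks(tree, embedded, history.contents, model)
    gi = {g: i for i, g in enumerate(union)}
    rng = np.random.default_rng(6)
    sites = [(int(rng.integers(len(union))), int(rng.integers(len(union))))
             for _ in range(25)]
    for i, j in sites:
        chars = {l: int(embedded[l].matrix[i, j]) for l in tree.leaf_labels}
        present = {
            n.label: union[i] in history.contents[n.label]
            and union[j] in history.contents[n.label]
            for n in tree.preorder()
        }
        out = reconstruct_site(tree, chars, present, model)
        for node in tree.internal_nodes:
            assert anc[node.label].matrix[i, j] == out[node.label]


def test_ancestors_satisfy_content_invariant(params):
    tree = random_binary_tree(8, seed=9)
    root = random_root(8, params, 9)
    leaf_nets, history = simulate_tree(tree, root, params, seed=9)
    union = sort_genes(g for n in leaf_nets.values() for g in n.genes)
    embedded = {lab: embed(n, union) for lab, n in leaf_nets.items()}
    anc = reconstruct_networks(tree, embedded, history.contents, params)
    for node in tree.internal_nodes:
        content = history.contents[node.label]
        m = anc[node.label].matrix
        for i, gi_ in enumerate(union):
            for j, gj_ in enumerate(union):
                both = gi_ in content and gj_ in content
                assert (m[i, j] != X) == both


def test_reconstruction_beats_random_perturbations(params):
    """The joint labeling's likelihood is maximal among random relabelings."""
    tree = random_binary_tree(12, seed=11)
    model = build_Pprime(EvoParams(p01=0.1, p10=0.1, p_d=0.1, p_l=0.1))
    rng = np.random.default_rng(11)
    present = {n.label: True for n in tree.preorder()}
    chars = {l: int(rng.integers(2)) for l in tree.leaf_labels}
    out = reconstruct_site(tree, chars, present, model)

    def loglik(lab2s):
        p = np.log(model.pi[lab2s[tree.root.label]])
        for parent, child in tree.branches():
            p += np.log(model.Pprime[lab2s[parent.label], lab2s[child.label]])
        return p

    best = loglik(out)
    internals = [n.label for n in tree.internal_nodes]
    for _ in range(1000):
        trial = dict(out)
        for lab in internals:
            if rng.random() < 0.4:
                trial[lab] = int(rng.integers(2))
        assert loglik(trial) <= best + 1e-9
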