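"""Evolve a regulatory network down a species tree with duplication/loss.

Builds a random 10-leaf tree and a 12-gene root network, evolves the
network along every branch, and summarizes the resulting history and the
diversity of the leaf networks.
"""
import phyloreg as pr

params = pr.EvoParams()  # p_d = p_l = 0.04, edge dynamics near density 0.15
tree = pr.random_binary_tree(10, seed=42)
root = pr.random_root(12, params, 42)
leaf_nets, history = pr.simulate_tree(tree, root, params, seed=42)

print(f"tree: {tree.n_leaves} leaves, {tree.n_nodes} nodes")
print(f"root network: {root.n} genes, {root.n_edges} edges")
print(f"history: {history.n_duplications} duplications, "
      f"{history.n_losses} losses")
sizes = sorted(net.n for net in leaf_nets.values())
print(f"leaf gene counts: min {sizes[0]}, max {sizes[-1]}")

# how widely are edges shared across the leaf networks?
table = pr.edge_sharing_table([n.binarize() for n in leaf_nets.values()])
shared_by_all = table["proportion"].iloc[-1]
print(f"fraction of union edges present in every leaf: {shared_by_all:.2f}")
print("(the rest of the union edges were gained, lost, or carried by "
      "duplicated copies on only part of the tree)")
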