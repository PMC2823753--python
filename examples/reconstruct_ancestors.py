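"""Reconstruct ancestral networks by joint maximum likelihood over {0,1,x}.

Simulates evolution with duplications and losses, embeds the leaf networks
in the union gene space, and reconstructs every internal node's ternary
adjacency matrix given the true gene contents.
"""
import phyloreg as pr
from phyloreg.networks import embed, sort_genes

params = pr.EvoParams()
tree = pr.random_binary_tree(8, seed=11)
root = pr.random_root(10, params, 11)
leaf_nets, history = pr.simulate_tree(tree, root, params, seed=11)

union = sort_genes(g for net in leaf_nets.values() for g in net.genes)
embedded = {lab: embed(net, union) for lab, net in leaf_nets.items()}
print(f"union gene space: {len(union)} genes across {len(embedded)} leaves")

ancestors = pr.reconstruct_networks(
    tree, embedded, history.contents, pr.build_Pprime(params)
)
for node in tree.internal_nodes:
    net = ancestors[node.label]
    present = len(net.present_genes)
    print(f"node {node.label}: {present} genes present, "
          f"{len(net.edges())} reconstructed edges")
print("entries of genes absent from a node are x and were fixed by the "
      "gene content before the recursion ran")
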