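"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the code paths they check: patristic
distances are recomputed by walking both tips' ancestor chains to the root,
and group-by tallies are recomputed with plain dict arithmetic.
"""

import numpy as np
import pytest

from cwrphylo import PhyloTree, read_newick
from cwrphylo.simulate import SimConfig, simulate_tree


def random_yule_tree(seed: int, n_tips: int) -> PhyloTree:
    """Seeded ultrametric height-1 tree from the package's Yule generator."""
    return simulate_tree(SimConfig(seed=seed, n_tips=n_tips, n_crops=2))


def random_rough_tree(seed: int, n_tips: int) -> PhyloTree:
    """Yule topology with branch lengths resampled i.i.d. uniform(0.01, 1):
    a generic non-ultrametric rooted tree."""
    tree = random_yule_tree(seed, n_tips)
    rng = np.random.default_rng(seed + 10_000)
    for edge in tree.dtree.preorder_edge_iter():
        if edge.tail_node is not None:
            edge.length = float(rng.uniform(0.01, 1.0))
    return tree


def brute_force_patristic(tree: PhyloTree) -> tuple[list[str], np.ndarray]:
    """All-pairs path sums by upward traversal from both tips to the root."""
    leaves = list(tree.dtree.leaf_node_iter())

    def chain(leaf):
        # node -> cumulative distance from the leaf
        out, node, dist = {}, leaf, 0.0
        while node is not None:
            out[id(node)] = dist
            dist += node.edge.length or 0.0
            node = node.parent_node
        return out

    chains = [chain(leaf) for leaf in leaves]
    n = len(leaves)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            # lowest common ancestor = nearest node present in both chains
            best = None
            for node_id, di in chains[i].items():
                if node_id in chains[j]:
                    total = di + chains[j][node_id]
                    if best is None or total < best:
                        best = total
            values[i, j] = values[j, i] = best
    return [l.taxon.label for l in leaves], values


@pytest.fixture
def three_tip_tree() -> PhyloTree:
    return read_newick("((A:1,B:1):0.5,C:1.5);")
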