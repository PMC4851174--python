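"""Gene tree simulation under the multispecies coalescent (MSC).

Within each species-tree branch of duration T and population size Ne, every
pair of extant gene lineages coalesces independently at rate 1/(2*Ne), so j
lineages merge at total rate j*(j-1)/2 / (2*Ne).  Lineages that fail to
coalesce within a branch are handed rootward and pooled at species-tree
nodes; above the species root the process continues in the origin branch's
Ne until a single lineage (the gene root) remains.  Loci are independent
("free recombination between loci") and each locus draws from its own
substream so that the first j loci of a large set equal a j-locus draw at the
same seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .treeio import GeneTree, Node, SpeciesTree

__all__ = [
    "SamplingDesign",
    "simulate_gene_tree",
    "simulate_locus_set",
    "count_deep_coalescences",
    "locus_rng",
]


@dataclass
class SamplingDesign:
    """Uniform sampling design: individuals per species and locus count."""

    n_individuals: int = 1
    n_loci: int = 1

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_loci < 1:
            raise ValueError("need at least one individual and one locus")


def locus_rng(seed: int, *path: int) -> np.random.Generator:
    """Deterministic hierarchical substream: (seed, replicate, locus, ...).

    Built directly from a SeedSequence over the full path, so any replicate
    or locus can be regenerated in isolation and subsets are stable.
    """
    return np.random.default_rng(np.random.SeedSequence((seed, *path)))


def simulate_gene_tree(
    species_tree: SpeciesTree, n_individuals: int, rng: np.random.Generator
) -> GeneTree:
    """Simulate one gene tree inside a species tree under the MSC.

    Gene copies are labelled ``<species>_<index>`` with indices 1..ni.
    """
    if n_individuals < 1:
        raise ValueError("need at least one individual per species")
    if not species_tree.pop_sizes:
        raise ValueError("species tree branches need population sizes")

    # gene lineages waiting at the bottom of each species-tree branch
    pending: dict[Node, list[Node]] = {}
    for leaf in species_tree.leaves():
        pending[leaf] = [
            Node(f"{leaf.label}_{i + 1}", 0.0) for i in range(n_individuals)
        ]

    for sp_node in species_tree.postorder():
        if sp_node.is_leaf:
            lineages = pending[sp_node]
        else:
            lineages = []
            for child in sp_node.children:
                lineages.extend(pending.pop(child))
        top = sp_node.parent.height if sp_node.parent is not None else np.inf
        ne = species_tree.pop_sizes[sp_node]
        pending[sp_node] = _coalesce_in_branch(
            lineages, sp_node.height, top, ne, rng
        )

    (root_lineage,) = pending[species_tree.root]
    return GeneTree(root_lineage)


def _coalesce_in_branch(
    lineages: list[Node],
    bottom: float,
    top: float,
    ne: float,
    rng: np.random.Generator,
) -> list[Node]:
    """Run the coalescent among ``lineages`` from height ``bottom`` to ``top``."""
    t = bottom
    lineages = list(lineages)
    while len(lineages) > 1:
        j = len(lineages)
        rate = j * (j - 1) / 2.0 / (2.0 * ne)
        t_next = t + rng.exponential(1.0 / rate)
        if t_next >= top:
            break
        t = t_next
        i1, i2 = rng.choice(j, size=2, replace=False)
        a, b = lineages[int(i1)], lineages[int(i2)]
        parent = Node(None, t)
        parent.add_child(a)
        parent.add_child(b)
        lineages = [x for x in lineages if x is not a and x is not b]
        lineages.append(parent)
    return lineages


def simulate_locus_set(
    species_tree: SpeciesTree,
    design: SamplingDesign,
    seed: int,
    replicate: int = 0,
) -> list[GeneTree]:
    """Simulate ``design.n_loci`` independent gene trees.

    Each locus uses the substream (seed, replicate, locus), so the first j
    trees of a large draw are identical to a j-locus draw at the same seed.
    """
    return [
        simulate_gene_tree(
            species_tree, design.n_individuals, locus_rng(seed, replicate, locus)
        )
        for locus in range(design.n_loci)
    ]


def count_deep_coalescences(gene_tree: GeneTree, species_tree: SpeciesTree) -> int:
    """Maddison's deep coalescence cost of a gene tree in a species tree.

    For every species-tree branch, count the gene lineages that exit the
    branch rootward (the distinct gene-tree ancestors, at the branch's top
    height, of the copies sampled from that branch's species) and add the
    excess over one.  A gene tree perfectly congruent with the species tree
    scores 0; each lineage persisting past a divergence adds 1.
    """
    sp_labels = set(species_tree.leaf_labels)
    for sp in gene_tree.species_map.values():
        if sp not in sp_labels:
            raise ValueError(f"gene copy mapped to unknown species {sp!r}")

    leaves_by_species: dict[str, list[Node]] = {}
    for leaf in gene_tree.leaves():
        leaves_by_species.setdefault(
            gene_tree.species_map[leaf.label or ""], []
        ).append(leaf)

    cost = 0
    for sp_node in species_tree.nodes():
        if sp_node.parent is None:
            continue  # the root has no rootward branch
        species_below = [
            lf.label or "" for lf in _subtree_leaves(sp_node)
        ]
        copies = [lf for sp in species_below for lf in leaves_by_species.get(sp, [])]
        if not copies:
            continue
        top = sp_node.parent.height
        ancestors = {_ancestor_at(leaf, top) for leaf in copies}
        cost += len(ancestors) - 1
    return cost


def _subtree_leaves(node: Node) -> list[Node]:
    stack, out = [node], []
    while stack:
        nd = stack.pop()
        if nd.is_leaf:
            out.append(nd)
        else:
            stack.extend(nd.children)
    return out


def _ancestor_at(leaf: Node, height: float, atol: float = 1e-12) -> Node:
    """The gene-tree lineage containing ``leaf`` at the given height.

    Returns the node at the bottom of the branch that crosses the query
    height.  A coalescence lying exactly at the query height (within atol)
    counts as already merged, so congruent gene trees score zero deep
    coalescences.
    """
    node = leaf
    while node.parent is not None and node.parent.height <= height + atol:
        node = node.parent
    return node
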