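"""Multispecies coalescent gene trees and deep coalescence counts."""

import dendropy
import numpy as np
import pytest
from dendropy.model import reconcile

from mscbench import gene_sim as gs
from mscbench import species_sim as ss
from mscbench.treeio import GeneTree, Node, SpeciesTree, parse_newick, write_newick
from tests.conftest import random_species_tree


def _single_species_tree(ne):
    root = Node("A", 0.0)
    # a lone species: the "tree" is one tip whose origin branch extends upward
    tree = SpeciesTree(root)
    tree.pop_sizes = {root: ne}
    return tree


class TestSimulateGeneTree:
    def test_pairwise_tmrca_expectation(self, rng):
        """Two copies in one population coalesce after mean 2*Ne."""
        ne = 0.5
        sp = _single_species_tree(ne)
        tm = np.array(
            [gs.simulate_gene_tree(sp, 2, rng).height for _ in range(10_000)]
        )
        se = tm.std(ddof=1) / np.sqrt(len(tm))
        assert abs(tm.mean() - 2 * ne) < 3 * se

    def test_containment_invariant(self, rng):
        for _ in range(30):
            sp = random_species_tree(6, rng, ne=0.3)
            gt = gs.simulate_gene_tree(sp, 2, rng)
            gt.check_against(sp)

    def test_copy_labels_follow_species_index_convention(self, rng, three_species_tree):
        gt = gs.simulate_gene_tree(three_species_tree, 2, rng)
        assert sorted(gt.leaf_labels) == [
            "A_1", "A_2", "B_1", "B_2", "C_1", "C_2",
        ]
        assert gt.species_of("A_2") == "A"

    def test_three_taxon_concordance_probability(self, rng, three_species_tree):
        """P(gene topology == species topology) = 1 - (2/3) e^{-T/(2Ne)} for
        the asymmetric three-species tree with one copy per species."""
        t_internal = 1.0  # internal branch duration of the fixture
        ne = 1.0
        reps = 10_000
        match = 0
        for _ in range(reps):
            gt = gs.simulate_gene_tree(three_species_tree, 1, rng)
            # concordant iff A_1 and B_1 are sisters
            mrca_ab = gt.mrca(["A_1", "B_1"])
            match += {leaf.label for leaf in _leaves_below(mrca_ab)} == {"A_1", "B_1"}
        p_expected = 1.0 - (2.0 / 3.0) * np.exp(-t_internal / (2.0 * ne))
        se = np.sqrt(p_expected * (1 - p_expected) / reps)
        assert abs(match / reps - p_expected) < 4 * se

    def test_long_branch_guarantees_coalescence(self, rng):
        """Two copies nearly always coalesce within a 20*(2Ne)-long branch."""
        ne = 0.1
        a, b = Node("A", 0.0), Node("B", 0.0)
        root = Node(None, 20 * 2 * ne)
        root.add_child(a)
        root.add_child(b)
        sp = SpeciesTree(root)
        sp.pop_sizes = {n: ne for n in sp.nodes()}
        below = sum(
            gs.simulate_gene_tree(sp, 2, rng).mrca(["A_1", "A_2"]).height < root.height
            for _ in range(2000)
        )
        assert below / 2000 > 0.999

    def test_msprime_cross_validation_two_species(self, rng):
        """Mean cross-species TMRCA agrees with an independent coalescent
        simulator (msprime) on a two-species toy."""
        msprime = pytest.importorskip("msprime")
        t_split, ne = 1.0, 0.5
        a, b = Node("A", 0.0), Node("B", 0.0)
        root = Node(None, t_split)
        root.add_child(a)
        root.add_child(b)
        sp = SpeciesTree(root)
        sp.pop_sizes = {n: ne for n in sp.nodes()}
        ours = np.array(
            [gs.simulate_gene_tree(sp, 1, rng).height for _ in range(4000)]
        )

        dem = msprime.Demography()
        dem.add_population(name="A", initial_size=ne)
        dem.add_population(name="B", initial_size=ne)
        dem.add_population(name="AB", initial_size=ne)
        dem.add_population_split(time=t_split, derived=["A", "B"], ancestral="AB")
        reps = msprime.sim_ancestry(
            samples=[
                msprime.SampleSet(1, population="A", ploidy=1),
                msprime.SampleSet(1, population="B", ploidy=1),
            ],
            demography=dem,
            ploidy=2,
            num_replicates=4000,
            random_seed=11,
        )
        theirs = np.array([ts.first().tmrca(0, 1) for ts in reps])
        se = np.sqrt(ours.var() / len(ours) + theirs.var() / len(theirs))
        assert abs(ours.mean() - theirs.mean()) < 4 * se


def _leaves_below(node):
    stack, out = [node], []
    while stack:
        nd = stack.pop()
        if nd.is_leaf:
            out.append(nd)
        else:
            stack.extend(nd.children)
    return out


class TestLocusSet:
    def test_single_locus(self, rng, three_species_tree):
        trees = gs.simulate_locus_set(
            three_species_tree, gs.SamplingDesign(1, 1), seed=3
        )
        assert len(trees) == 1

    def test_prefix_stability_under_locus_count(self, three_species_tree):
        """The first 8 trees of a 256-locus draw equal an 8-locus draw."""
        big = gs.simulate_locus_set(
            three_species_tree, gs.SamplingDesign(2, 256), seed=5
        )
        small = gs.simulate_locus_set(
            three_species_tree, gs.SamplingDesign(2, 8), seed=5
        )
        for a, b in zip(small, big[:8]):
            assert write_newick(a) == write_newick(b)

    def test_gene_trees_at_least_species_height(self, rng):
        sp = random_species_tree(5, rng, ne=0.5)
        trees = gs.simulate_locus_set(sp, gs.SamplingDesign(2, 50), seed=9)
        heights = np.array([t.height for t in trees])
        assert (heights >= sp.height - 1e-12).all()
        assert heights.mean() > sp.height  # strictly above on average

    def test_height_difference_shrinks_with_ne(self, rng):
        sp_big = random_species_tree(5, rng, ne=1.0)
        sp_small = sp_big.copy()
        for node in sp_small.nodes():
            sp_small.pop_sizes[node] = 1e-4
        diff_big = np.mean(
            [t.height - sp_big.height
             for t in gs.simulate_locus_set(sp_big, gs.SamplingDesign(2, 100), seed=2)]
        )
        diff_small = np.mean(
            [t.height - sp_small.height
             for t in gs.simulate_locus_set(sp_small, gs.SamplingDesign(2, 100), seed=2)]
        )
        assert diff_big > diff_small > 0


class TestDeepCoalescences:
    def test_congruent_tree_scores_zero(self, three_species_tree):
        gt = GeneTree(parse_newick("((A_1:1,B_1:1):1,C_1:2);").root)
        assert gs.count_deep_coalescences(gt, three_species_tree) == 0

    def test_discordant_three_taxon_tree_scores_one(self, three_species_tree):
        gt = GeneTree(parse_newick("((B_1:2.5,C_1:2.5):0.5,A_1:3);").root)
        assert gs.count_deep_coalescences(gt, three_species_tree) == 1

    def test_nonnegative_on_simulated_trees(self, rng):
        for _ in range(20):
            sp = random_species_tree(5, rng, ne=1.0)
            gt = gs.simulate_gene_tree(sp, 2, rng)
            assert gs.count_deep_coalescences(gt, sp) >= 0

    def test_unknown_species_errors(self, three_species_tree):
        gt = GeneTree(parse_newick("((X_1:1,B_1:1):1,C_1:2);").root)
        with pytest.raises(ValueError):
            gs.count_deep_coalescences(gt, three_species_tree)

    def test_matches_dendropy_on_simulated_trees(self, rng):
        """Cross-check Maddison's cost against dendropy's reconciliation."""
        for _ in range(15):
            sp = random_species_tree(4, rng, ne=1.0)
            gt = gs.simulate_gene_tree(sp, 2, rng)
            ours = gs.count_deep_coalescences(gt, sp)
            assert ours == _dendropy_deep_coalescences(sp, gt, 2)


def _dendropy_deep_coalescences(species_tree, gene_tree, num_contained):
    sp_tns = dendropy.TaxonNamespace()
    sp = dendropy.Tree.get(
        data=write_newick(species_tree),
        schema="newick",
        taxon_namespace=sp_tns,
        rooting="force-rooted",
    )
    mapping = dendropy.TaxonNamespaceMapping.create_contained_taxon_mapping(
        containing_taxon_namespace=sp_tns,
        num_contained=num_contained,
        contained_taxon_label_fn=lambda taxon, i: f"{taxon.label}_{i + 1}",
    )
    gt = dendropy.Tree.get(
        data=write_newick(gene_tree),
        schema="newick",
        taxon_namespace=mapping.domain_taxon_namespace,
        rooting="force-rooted",
        preserve_underscores=True,
    )
    containing = reconcile.ContainingTree(
        sp,
        mapping.domain_taxon_namespace,
        mapping,
        contained_trees=[gt],
        fit_containing_edge_lengths=False,
    )
    return containing.num_deep_coalescences()
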