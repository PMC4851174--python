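"""Rooted branch score, relative error, rooted RF and aggregation rules."""

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from mscbench import metrics as mt
from mscbench import species_sim as ss
from mscbench.treeio import PosteriorSample, parse_newick, write_newick


def _oracle_clade_lengths(newick):
    """Independent clade->branch-length map computed via dendropy."""
    tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
    out = {}
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        leaves = frozenset(
            lf.taxon.label for lf in edge.head_node.leaf_iter()
        )
        out[leaves] = out.get(leaves, 0.0) + (edge.length or 0.0)
    return out


def _oracle_rbs(nwk1, nwk2):
    b1, b2 = _oracle_clade_lengths(nwk1), _oracle_clade_lengths(nwk2)
    return sum(abs(b1.get(c, 0.0) - b2.get(c, 0.0)) for c in set(b1) | set(b2))


class TestRBS:
    def test_identical_trees_zero(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        assert mt.rbs(t, t.copy()) == 0.0

    def test_single_branch_difference(self):
        t1 = parse_newick("((A:1,B:1):1,C:2);")
        t2 = parse_newick("((A:1,B:2):1,C:2);")
        # t2 is non-ultrametric; only B's pendant branch differs
        assert mt.rbs(t1, t2) == pytest.approx(1.0)

    def test_topology_difference_weighted_by_lengths(self):
        t1 = parse_newick("((A:1,B:1):1,C:2);")
        t2 = parse_newick("((A:1,C:1):1,B:2);")
        # union clades {A},{B},{C},{AB},{AC}: diffs 0+1+1+1+1
        assert mt.rbs(t1, t2) == pytest.approx(4.0)

    def test_leaf_set_mismatch_errors(self):
        t1 = parse_newick("((A:1,B:1):1,C:2);")
        t2 = parse_newick("((A:1,B:1):1,D:2);")
        with pytest.raises(ValueError):
            mt.rbs(t1, t2)

    def test_matches_oracle_on_random_pairs(self, rng):
        """RBS equals brute-force clade enumeration on 100 random 8-tip pairs."""
        for _ in range(100):
            n1 = write_newick(ss.simulate_yule(8, 1.0, rng))
            n2 = write_newick(ss.simulate_yule(8, 1.0, rng))
            ours = mt.rbs(parse_newick(n1), parse_newick(n2))
            assert ours == pytest.approx(_oracle_rbs(n1, n2), rel=1e-9)

    def test_metric_properties_on_random_triples(self, rng):
        for _ in range(25):
            a, b, c = (ss.simulate_yule(6, 1.0, rng) for _ in range(3))
            dab, dba = mt.rbs(a, b), mt.rbs(b, a)
            assert dab == pytest.approx(dba)  # symmetry
            assert dab >= 0
            assert mt.rbs(a, a) == 0.0
            assert mt.rbs(a, c) <= dab + mt.rbs(b, c) + 1e-9  # triangle


class TestRelativeError:
    def test_true_posterior_is_zero(self, rng):
        t = ss.simulate_yule(5, 1.0, rng)
        post = PosteriorSample(trees=[t.copy() for _ in range(5)])
        assert mt.relative_error(t, post) == 0.0

    def test_k_one_reduces_to_normalized_rbs(self, rng):
        t1, t2 = (ss.simulate_yule(5, 1.0, rng) for _ in range(2))
        post = PosteriorSample(trees=[t2])
        assert mt.relative_error(t1, post) == pytest.approx(
            mt.rbs(t1, t2) / t1.total_length
        )

    def test_scale_invariance(self, rng):
        t1, t2 = (ss.simulate_yule(5, 1.0, rng) for _ in range(2))
        e1 = mt.relative_error(t1, PosteriorSample(trees=[t2]))
        s1, s2 = t1.copy(), t2.copy()
        for tree in (s1, s2):
            for node in tree.nodes():
                node.height *= 7.3
        assert mt.relative_error(s1, PosteriorSample(trees=[s2])) == pytest.approx(e1)

    def test_monotone_as_truth_replaces_samples(self, rng):
        truth = ss.simulate_yule(5, 1.0, rng)
        other = ss.simulate_yule(5, 1.0, rng)
        errors = []
        for n_true in range(4):
            trees = [truth.copy()] * n_true + [other.copy()] * (3 - n_true) + [other.copy()]
            errors.append(mt.relative_error(truth, PosteriorSample(trees=trees)))
        assert all(e1 >= e2 - 1e-12 for e1, e2 in zip(errors, errors[1:]))


class TestErrorRatio:
    def test_basic_arithmetic(self):
        assert mt.error_ratio(0.02, 0.04) == pytest.approx(0.5)
        assert mt.error_ratio(0.04, 0.04) == 1.0
        assert mt.error_ratio(0.0, 0.04) == 0.0

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            mt.error_ratio(0.1, 0.0)


class TestRootedRF:
    def test_identical_topologies(self):
        t1 = parse_newick("((A:1,B:1):1,C:2);")
        t2 = parse_newick("((A:5,B:5):5,C:10);")
        assert mt.rooted_rf(t1, t2) == 0

    def test_three_taxon_swap(self):
        t1 = parse_newick("((A:1,B:1):1,C:2);")
        t2 = parse_newick("((A:1,C:1):1,B:2);")
        assert mt.rooted_rf(t1, t2) == 2

    def test_upper_bound_binary_trees(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 10))
            t1, t2 = (ss.simulate_yule(n, 1.0, rng) for _ in range(2))
            assert mt.rooted_rf(t1, t2) <= 2 * (n - 2)

    def test_matches_dendropy_on_random_pairs(self, rng):
        """rRF equals dendropy's rooted symmetric difference, 100 8-tip pairs."""
        for _ in range(100):
            n1 = write_newick(ss.simulate_yule(8, 1.0, rng))
            n2 = write_newick(ss.simulate_yule(8, 1.0, rng))
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(
                data=n1, schema="newick", taxon_namespace=tns, rooting="force-rooted"
            )
            d2 = dendropy.Tree.get(
                data=n2, schema="newick", taxon_namespace=tns, rooting="force-rooted"
            )
            expected = treecompare.symmetric_difference(d1, d2)
            assert mt.rooted_rf(parse_newick(n1), parse_newick(n2)) == expected


class TestPendantBias:
    def test_exact_estimate_zero_bias(self, rng):
        t = ss.simulate_yule(6, 1.0, rng)
        assert mt.pendant_edge_bias(t.copy(), t) == pytest.approx(0.0)

    def test_four_and_a_half_fold_is_350_percent(self):
        t1 = parse_newick("((A:4.5,B:4.5):1,C:9);")
        t0 = parse_newick("((A:1,B:1):1,C:2);")
        assert mt.pendant_edge_bias(t1, t0) == pytest.approx(350.0)

    def test_mixed_ratios_average(self):
        t0 = parse_newick("((A:1,B:1):1,C:2);")
        # A,B estimated 2x; C estimated 1x
        t1 = parse_newick("((A:2,B:2):1,C:2);")
        assert mt.pendant_edge_bias(t1, t0) == pytest.approx(100.0 * (1 + 1 + 0) / 3)


class TestSummarize:
    def test_constant_values(self, rng):
        s = mt.summarize([2.0] * 10, trim=0.25, rng=rng)
        assert s.point == 2.0
        assert s.ci_lower == s.ci_upper == 2.0

    def test_trimmed_mean_1_to_100(self, rng):
        s = mt.summarize(np.arange(1.0, 101.0), trim=0.25, rng=rng)
        assert s.point == pytest.approx(50.5)

    def test_zero_trim_is_plain_mean(self, rng):
        vals = [1.0, 2.0, 4.0, 9.0]
        s = mt.summarize(vals, trim=0.0, rng=rng)
        assert s.point == pytest.approx(np.mean(vals))

    def test_ci_brackets_point(self, rng):
        vals = rng.lognormal(0, 1, size=40)
        s = mt.summarize(vals, trim=0.25, rng=rng)
        assert s.ci_lower <= s.point <= s.ci_upper

    def test_overtrimming_errors(self, rng):
        with pytest.raises(ValueError):
            mt.summarize([1.0, 2.0], trim=0.5, rng=rng)
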