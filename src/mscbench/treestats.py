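"""Per-replicate tree and alignment statistics and residual correlations.

These are the descriptive statistics used to probe what drives residual
variation in MCMC mixing and species-tree error once the experimental
design variables (loci, species, individuals) are accounted for: species
tree height and shape, population sizes, incomplete lineage sorting (deep
coalescences and gene-vs-species tree height differences), and alignment
information content (variable sites, parsimony mutation counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gene_sim import count_deep_coalescences
from .seq_sim import count_variable_sites
from .treeio import Alignment, GeneTree, SpeciesTree, TimeTree

__all__ = [
    "ReplicateStats",
    "asymmetry",
    "fitch_mutations",
    "replicate_stats",
    "residual_correlations",
]

#: Family size for multiple-testing correction in the residual screen.
DEFAULT_N_TESTS = 48


@dataclass
class ReplicateStats:
    """The eight per-replicate statistics of the residual screen.

    ``mutations_per_variable_site`` is reported as NaN when the replicate has
    no variable sites at all (the ratio is undefined).
    """

    species_tree_height: float
    mean_population_size: float
    species_tree_asymmetry: float
    mean_deep_coalescences: float
    mean_parsimonious_mutations: float
    mean_variable_site_count: float
    mean_tree_height_difference: float
    mutations_per_variable_site: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def asymmetry(tree: TimeTree) -> float:
    """Species tree asymmetry: variance of per-tip root-path node counts.

    The depth of a tip is the number of edges on its path to the root, and
    the statistic is the *population* variance of those depths — 0 for a
    perfectly balanced tree, growing with caterpillar-like imbalance.
    Depends only on topology, not branch lengths.
    """
    depths = []
    stack = [(tree.root, 0)]
    while stack:
        node, d = stack.pop()
        if node.is_leaf:
            depths.append(d)
        else:
            stack.extend((c, d + 1) for c in node.children)
    if len(depths) < 2:
        return 0.0
    return float(np.var(depths))


def fitch_mutations(aln: Alignment, gene_tree: GeneTree) -> int:
    """Minimum (Fitch parsimony) mutation count of an alignment on its tree.

    Sums over sites the number of state changes required by the Fitch
    small-parsimony algorithm, generalised to multifurcating nodes via the
    standard intersection/union rule over all children.
    """
    tree_labels = set(gene_tree.leaf_labels)
    if set(aln.labels) != tree_labels:
        raise ValueError("alignment labels do not match gene tree leaves")
    mat = aln.to_array()
    row = {lab: i for i, lab in enumerate(aln.labels)}
    n_sites = aln.n_sites
    changes = np.zeros(n_sites, dtype=np.int64)
    # per-node state sets encoded as 4-bit masks, vectorised over sites
    masks: dict = {}
    for node in gene_tree.postorder():
        if node.is_leaf:
            masks[node] = np.left_shift(1, mat[row[node.label or ""]]).astype(np.int8)
        else:
            child_masks = [masks.pop(c) for c in node.children]
            inter = child_masks[0].copy()
            for cm in child_masks[1:]:
                nxt = inter & cm
                empty = nxt == 0
                changes += empty
                nxt[empty] = (inter | cm)[empty]
                inter = nxt
            masks[node] = inter
    return int(changes.sum())


def replicate_stats(
    species_tree: SpeciesTree,
    gene_trees: Sequence[GeneTree],
    alignments: Sequence[Alignment],
) -> ReplicateStats:
    """Compute the full per-replicate statistic bundle.

    Deep coalescences and tree height differences are averaged over loci;
    mutations per variable site is total mutations over total variable
    sites (NaN when no site varies).
    """
    if not gene_trees or len(gene_trees) != len(alignments):
        raise ValueError("need a nonempty, matched list of gene trees and alignments")
    deep = [count_deep_coalescences(gt, species_tree) for gt in gene_trees]
    height_diff = [gt.height - species_tree.height for gt in gene_trees]
    variable = [count_variable_sites(a) for a in alignments]
    mutations = [fitch_mutations(a, gt) for a, gt in zip(alignments, gene_trees)]
    total_var = sum(variable)
    mpvs = (sum(mutations) / total_var) if total_var > 0 else math.nan
    return ReplicateStats(
        species_tree_height=species_tree.height,
        mean_population_size=float(np.mean(list(species_tree.pop_sizes.values()))),
        species_tree_asymmetry=asymmetry(species_tree),
        mean_deep_coalescences=float(np.mean(deep)),
        mean_parsimonious_mutations=float(np.mean(mutations)),
        mean_variable_site_count=float(np.mean(variable)),
        mean_tree_height_difference=float(np.mean(height_diff)),
        mutations_per_variable_site=mpvs,
    )


def residual_correlations(
    residuals: Sequence[float],
    stats_table: pd.DataFrame,
    n_tests: int = DEFAULT_N_TESTS,
) -> pd.DataFrame:
    """Spearman correlations of residuals against each statistic column.

    rho uses average ranks for ties; p-values come from the asymptotic
    t approximation t = rho*sqrt((m-2)/(1-rho^2)) on m-2 df; the
    Benjamini-Hochberg adjustment is scaled to an external family size
    ``n_tests`` (the screen is one slice of a larger family of tests).
    Returns a frame indexed by statistic with columns rho, p, p_adj.
    """
    res = np.asarray(residuals, dtype=float)
    if len(res) < 4:
        raise ValueError("need at least 4 observations")
    if len(res) != len(stats_table):
        raise ValueError("residuals and statistics must have equal length")
    rows = {}
    for col in stats_table.columns:
        x = stats_table[col].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(res == res[0]):
            raise ValueError(f"constant series ({col!r}); Spearman rho undefined")
        rho, p = sps.spearmanr(res, x)
        rows[col] = (float(rho), float(p))
    table = pd.DataFrame(rows, index=["rho", "p"]).T
    table["p_adj"] = _benjamini_hochberg(table["p"].to_numpy(), n_tests)
    return table


def _benjamini_hochberg(pvalues: np.ndarray, n_tests: int) -> np.ndarray:
    """BH step-up adjustment with an externally fixed family size.

    p_adj(i) = min_{j >= i} ( p_(j) * n_tests / j ), capped at 1, where the
    ranks j run over the *sorted* supplied p-values but the multiplier uses
    the full family size n_tests even if fewer p-values are supplied.
    """
    m = len(pvalues)
    if n_tests < m:
        raise ValueError("family size cannot be smaller than the number of tests")
    order = np.argsort(pvalues)
    sorted_p = pvalues[order]
    adj = sorted_p * n_tests / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
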