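"""Species-tree accuracy metrics.

The central measure is the rooted branch score (RBS): the sum over the union
of the two trees' clades of the absolute difference in the length of the
branch extending rootward from each clade's MRCA, with a missing clade
contributing a branch length of zero.  Relative species tree error divides
the posterior-mean RBS to the true tree by the true tree's total branch
length, making error comparable across tree sizes and time scales.  Rooted
Robinson-Foulds distance, pendant-edge length bias and the trimmed-mean /
bootstrap-CI aggregation used for method comparison live here too.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import trim_mean

from .treeio import PosteriorSample, TimeTree, clade_lengths, clades

__all__ = [
    "ErrorSummary",
    "rbs",
    "relative_error",
    "error_ratio",
    "rooted_rf",
    "pendant_edge_bias",
    "summarize",
]


@dataclass
class ErrorSummary:
    """A point summary of per-replicate values with a bootstrap 95% CI."""

    point: float
    ci_lower: float
    ci_upper: float
    trim: float
    n: int


def _check_leaf_sets(t1: TimeTree, t2: TimeTree) -> None:
    s1, s2 = frozenset(t1.leaf_labels), frozenset(t2.leaf_labels)
    if s1 != s2:
        raise ValueError(
            f"leaf sets differ: only-in-first={sorted(s1 - s2)}, "
            f"only-in-second={sorted(s2 - s1)}"
        )


def rbs(t1: TimeTree, t2: TimeTree) -> float:
    """Rooted branch score between two trees on the same leaf set.

    Sums |b1(c) - b2(c)| over the union of clades, where b(c) is the length
    of the branch rootward of clade c's MRCA and a clade absent from a tree
    has branch length zero.  Symmetric, and zero iff the trees agree in both
    topology and branch lengths.
    """
    _check_leaf_sets(t1, t2)
    b1 = clade_lengths(t1)
    b2 = clade_lengths(t2)
    return float(
        sum(abs(b1.get(c, 0.0) - b2.get(c, 0.0)) for c in set(b1) | set(b2))
    )


def relative_error(true_tree: TimeTree, posterior: PosteriorSample) -> float:
    """Relative species tree error: mean posterior RBS over true tree length.

    e_T = (1/k) * sum_i RBS(T_true, T_i) / L_true, averaging over the k
    posterior samples as drawn (duplicate topologies are not collapsed).
    """
    length = true_tree.total_length
    if length <= 0:
        raise ValueError("true tree has zero total branch length")
    total = sum(rbs(true_tree, t) for t in posterior.trees)
    return total / (posterior.k * length)


def error_ratio(error_a: float, error_b: float) -> float:
    """Ratio of two relative errors sharing the same true tree.

    Values below 1 mean method a (conventionally the multispecies
    coalescent) achieved lower error than method b (concatenation).
    """
    if error_b == 0:
        raise ZeroDivisionError("denominator error is zero; ratio undefined")
    return error_a / error_b


def rooted_rf(t1: TimeTree, t2: TimeTree) -> int:
    """Rooted Robinson-Foulds distance: |clades(t1) symmetric-diff clades(t2)|.

    Singleton tip clades are shared by construction, so this equals the
    symmetric difference over internal clades; branch lengths are ignored.
    """
    _check_leaf_sets(t1, t2)
    return len(clades(t1) ^ clades(t2))


def pendant_edge_bias(estimated: TimeTree, truth: TimeTree) -> float:
    """Mean percentage bias of estimated pendant (tip) branch lengths.

    100 * mean over tips of (estimated/true - 1); e.g. estimates averaging
    4.5x the true length give a bias of 350%.
    """
    _check_leaf_sets(estimated, truth)
    est = {leaf.label: leaf.branch_length for leaf in estimated.leaves()}
    ratios = []
    for leaf in truth.leaves():
        if leaf.branch_length <= 0:
            raise ValueError(f"true pendant length for {leaf.label!r} is not positive")
        ratios.append(est[leaf.label] / leaf.branch_length - 1.0)
    return 100.0 * float(np.mean(ratios))


def summarize(
    values: Sequence[float],
    trim: float = 0.25,
    n_bootstrap: int = 1000,
    rng: np.random.Generator | None = None,
) -> ErrorSummary:
    """Symmetric trimmed mean with a percentile bootstrap 95% CI.

    ``trim`` is the fraction cut from *each* tail (floor(n*trim) values);
    trim=0 reduces to the ordinary mean.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("no values to summarise")
    if not (0.0 <= trim < 0.5):
        raise ValueError("trim fraction must be in [0, 0.5)")
    if vals.size - 2 * int(np.floor(vals.size * trim)) < 1:
        raise ValueError("too few values left after trimming")
    if rng is None:
        rng = np.random.default_rng(0)
    point = float(trim_mean(vals, trim)) if trim > 0 else float(vals.mean())
    stats = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        sample = vals[rng.integers(vals.size, size=vals.size)]
        stats[b] = trim_mean(sample, trim) if trim > 0 else sample.mean()
    lo, hi = np.percentile(stats, [2.5, 97.5])
    # percentile bootstrap can nominally exclude the point; keep it bracketed
    lo, hi = min(float(lo), point), max(float(hi), point)
    return ErrorSummary(point, lo, hi, trim, int(vals.size))
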