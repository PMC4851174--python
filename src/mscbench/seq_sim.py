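"""Nucleotide sequence simulation along gene trees.

Supports JC, HKY and GTR substitution models with optional discrete-gamma
among-site rate variation, a strict clock per locus, and the two
between-locus rate models used in the experimental designs: log-uniform
rates on [mu0/F, mu0*F] (with the first locus pinned at mu0) and i.i.d.
gamma-distributed per-locus clock rates.

The rate matrix Q is normalised so the expected substitution rate at
stationarity is one, hence (clock rate x branch duration) is in expected
substitutions per site.  Site-specific gamma rates use the standard
equal-probability discretisation with category means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .treeio import Alignment, GeneTree, Node

__all__ = [
    "SubstitutionModel",
    "ClockModel",
    "draw_locus_rates",
    "simulate_alignment",
    "count_variable_sites",
    "discrete_gamma_rates",
]

BASES = "ACGT"


@dataclass
class SubstitutionModel:
    """A reversible nucleotide substitution model.

    ``exchangeabilities`` are the six upper-triangle rates in the order
    AC, AG, AT, CG, CT, GT (CT conventionally normalised to 1 for GTR);
    ``gamma_shape`` of 0 disables among-site rate variation.
    """

    kind: str = "JC"
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    kappa: float = 1.0
    exchangeabilities: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    gamma_shape: float = 0.0
    gamma_categories: int = 4

    def __post_init__(self) -> None:
        if self.kind not in ("JC", "HKY", "GTR"):
            raise ValueError(f"unknown substitution model {self.kind!r}")
        if abs(sum(self.freqs) - 1.0) > 1e-8:
            raise ValueError("base frequencies must sum to 1")
        if self.kind == "JC" and any(abs(f - 0.25) > 1e-12 for f in self.freqs):
            raise ValueError("JC requires equal base frequencies")
        if any(f <= 0 for f in self.freqs):
            raise ValueError("base frequencies must be positive")

    @classmethod
    def jc(cls, gamma_shape: float = 0.0) -> "SubstitutionModel":
        return cls(kind="JC", gamma_shape=gamma_shape)

    @classmethod
    def hky(
        cls,
        kappa: float,
        freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
        gamma_shape: float = 0.0,
    ) -> "SubstitutionModel":
        return cls(kind="HKY", kappa=kappa, freqs=freqs, gamma_shape=gamma_shape)

    @classmethod
    def gtr(
        cls,
        exchangeabilities: tuple[float, ...],
        freqs: tuple[float, float, float, float],
        gamma_shape: float = 0.0,
    ) -> "SubstitutionModel":
        return cls(
            kind="GTR",
            exchangeabilities=tuple(exchangeabilities),
            freqs=freqs,
            gamma_shape=gamma_shape,
        )

    def rate_matrix(self) -> np.ndarray:
        """Q, normalised to one expected substitution per unit branch length."""
        pi = np.asarray(self.freqs, dtype=float)
        if self.kind == "JC":
            s = np.ones(6)
        elif self.kind == "HKY":
            # transitions: A<->G (index 1) and C<->T (index 4)
            s = np.array([1.0, self.kappa, 1.0, 1.0, self.kappa, 1.0])
        else:
            s = np.asarray(self.exchangeabilities, dtype=float)
        q = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for rate, (i, j) in zip(s, pairs):
            q[i, j] = rate * pi[j]
            q[j, i] = rate * pi[i]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mean_rate = -float(np.dot(pi, np.diag(q)))
        return q / mean_rate

    def site_rates(self) -> np.ndarray:
        """Relative rates of the discrete-gamma categories (mean 1)."""
        if self.gamma_shape <= 0:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_shape, self.gamma_categories)


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Equal-probability discrete-gamma category rates (category means).

    The mean-one Gamma(shape, 1/shape) distribution is cut into
    ``n_categories`` equal-probability bins and each bin is represented by
    its conditional mean, computed from the incomplete gamma function.
    """
    if shape <= 0 or n_categories < 1:
        raise ValueError("need positive shape and at least one category")
    cuts = gamma_dist.ppf(
        np.arange(1, n_categories) / n_categories, shape, scale=1.0 / shape
    )
    bounds = np.concatenate([[0.0], cuts, [np.inf]])
    # E[X; a<X<b] for X~Gamma(k, 1/k) is gammainc(k+1, k*b) - gammainc(k+1, k*a)
    upper = gammainc(shape + 1.0, shape * bounds[1:])
    upper[-1] = 1.0
    lower = gammainc(shape + 1.0, shape * bounds[:-1])
    rates = (upper - lower) * n_categories
    return rates / rates.mean()


@dataclass
class ClockModel:
    """Between-locus clock rate model.

    kind="fixed": every locus at ``base_rate``.
    kind="log-uniform-locus": locus 1 pinned at ``base_rate``; the rest drawn
    with log(rate) uniform on [log(mu0/F), log(mu0*F)] so slower and faster
    loci are equally dense around mu0.
    kind="gamma-locus": i.i.d. Gamma(shape, scale) rates for every locus.
    """

    kind: str = "fixed"
    base_rate: float = 1.0
    spread_factor: float = 1.0
    shape: float = 1.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "log-uniform-locus", "gamma-locus"):
            raise ValueError(f"unknown clock model {self.kind!r}")
        if self.base_rate <= 0:
            raise ValueError("base rate must be positive")
        if self.spread_factor < 1.0:
            raise ValueError("spread factor F must be >= 1")


def draw_locus_rates(
    n_loci: int, clock: ClockModel, rng: np.random.Generator
) -> np.ndarray:
    """Per-locus strict-clock rates under the given between-locus model."""
    if n_loci < 1:
        raise ValueError("need at least one locus")
    if clock.kind == "gamma-locus":
        return rng.gamma(clock.shape, clock.scale, size=n_loci)
    rates = np.full(n_loci, clock.base_rate, dtype=float)
    if clock.kind == "log-uniform-locus" and clock.spread_factor > 1.0 and n_loci > 1:
        lo = np.log(clock.base_rate / clock.spread_factor)
        hi = np.log(clock.base_rate * clock.spread_factor)
        rates[1:] = np.exp(rng.uniform(lo, hi, size=n_loci - 1))
    return rates


def simulate_alignment(
    gene_tree: GeneTree,
    model: SubstitutionModel,
    clock_rate: float,
    n_sites: int,
    rng: np.random.Generator,
) -> Alignment:
    """Evolve an alignment down a gene tree under a strict clock.

    The root sequence is drawn from the stationary frequencies; each branch
    applies P = expm(Q * clock_rate * tau * r_cat) independently per site,
    with each site keeping one gamma rate category across the whole tree.
    """
    if n_sites < 1:
        raise ValueError("need at least one site")
    if clock_rate < 0:
        raise ValueError("clock rate must be nonnegative")
    q = model.rate_matrix()
    cat_rates = model.site_rates()
    n_cat = len(cat_rates)
    site_cat = rng.integers(n_cat, size=n_sites)
    pi = np.asarray(model.freqs)

    root_states = rng.choice(4, size=n_sites, p=pi)
    states: dict[Node, np.ndarray] = {gene_tree.root: root_states}
    seqs: dict[str, str] = {}
    for node in gene_tree.nodes():
        if node.parent is not None:
            dist = clock_rate * node.branch_length
            child_states = np.empty(n_sites, dtype=np.int64)
            for c in range(n_cat):
                mask = site_cat == c
                if not mask.any():
                    continue
                p = expm(q * dist * cat_rates[c]) if dist > 0 else np.eye(4)
                p = np.clip(p, 0.0, None)
                p /= p.sum(axis=1, keepdims=True)
                child_states[mask] = _evolve_sites(states[node.parent][mask], p, rng)
            states[node] = child_states
        if node.is_leaf:
            seq = states[node]
            seqs[node.label or ""] = "".join(BASES[s] for s in seq)
    return Alignment(seqs, clock_rate=clock_rate)


def _evolve_sites(
    parent_states: np.ndarray, p: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample child states site-wise from transition matrix rows."""
    out = np.empty_like(parent_states)
    u = rng.random(parent_states.shape[0])
    cdf = np.cumsum(p, axis=1)
    out = (u[:, None] > cdf[parent_states]).sum(axis=1)
    return np.minimum(out, 3)


def count_variable_sites(aln: Alignment) -> int:
    """Number of alignment columns with more than one distinct base."""
    if not aln.sequences:
        raise ValueError("empty alignment")
    mat = aln.to_array()
    return int(np.sum((mat != mat[0]).any(axis=0)))
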