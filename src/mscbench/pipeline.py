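"""Desk-scale orchestration of the three simulation experiments.

* Experiment 1 — rapidly speciating birth-death trees (lambda=1, mu=0.2),
  HKY kappa=4 / equal frequencies, strict clock at 0.01 substitutions per
  site per time unit, 200-site loci, locus counts doubling 2..256, with
  larger locus sets being supersets of smaller ones at the same seed.
* Experiment 2 — Yule trees calibrated to an expected root height R, constant
  per-branch Ne, JC, 1000-site loci, log-uniform between-locus rate variation
  with spread F=3; one set of species trees is shared across locus counts
  while gene trees and sequences are redrawn per locus count.
* Experiment 3 — empirically calibrated "shallow" and "deep" designs
  (GTR+Gamma, gamma per-branch Ne with shape 2, gamma per-locus clock rates;
  64 nt loci for the shallow design, 110-3511 nt for the deep design).

External Bayesian inference is an interface, not a dependency: bundles are
exported as NEXUS/FASTA and posteriors imported from NEXUS tree logs and
tab-separated traces.  For end-to-end testing a *synthetic* pseudo-posterior
generator perturbs the true tree with noise that shrinks as loci are added,
reproducing the qualitative power-law testbed without running any MCMC.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import gene_sim, metrics, scaling, seq_sim, species_sim
from .treeio import (
    Alignment,
    GeneTree,
    Node,
    PosteriorSample,
    SpeciesTree,
    write_newick,
    write_nexus_trees,
)

__all__ = [
    "ExperimentConfig",
    "ReplicateBundle",
    "generate",
    "filter_replicates",
    "surrogate_estimate",
    "paired_surrogate_estimates",
    "aggregate",
    "export_bundle",
]

#: Empirically calibrated parameter sets for the two experiment-3 designs.
EXP3_PARAMS = {
    "shallow": dict(
        n_species=8,
        birth_rate=125.3,
        ne_mean=6.35e-3,
        freqs=(0.290, 0.212, 0.204, 0.294),
        exchangeabilities=(0.367, 0.940, 0.246, 0.305, 1.000, 0.353),
        gamma_shape=0.0383,
        clock_shape=6.22,
        clock_scale=0.173,
        locus_length=(64, 64),
    ),
    "deep": dict(
        n_species=12,
        birth_rate=20.7,
        ne_mean=1.53e-4,
        freqs=(0.266, 0.240, 0.263, 0.231),
        exchangeabilities=(0.152, 0.694, 0.100, 0.155, 1.000, 0.127),
        gamma_shape=0.233,
        clock_shape=5.15,
        clock_scale=0.195,
        locus_length=(110, 3511),
    ),
}


@dataclass
class ExperimentConfig:
    """Full specification of a simulation experiment condition.

    Use the classmethod constructors for the canonical designs; parameters
    are exposed so scaled-down variants can be configured explicitly.
    """

    experiment: str  # {exp1, exp2, exp3-shallow, exp3-deep}
    n_species: int
    n_individuals: int
    n_loci: tuple[int, ...]
    n_replicates: int
    seed: int
    n_sites: int = 200
    birth_rate: float = 1.0
    death_rate: float = 0.0
    expected_root_height: float | None = None
    population: species_sim.PopulationModel = field(
        default_factory=species_sim.PopulationModel
    )
    substitution: seq_sim.SubstitutionModel = field(
        default_factory=seq_sim.SubstitutionModel
    )
    clock: seq_sim.ClockModel = field(default_factory=seq_sim.ClockModel)
    locus_length_range: tuple[int, int] | None = None
    share_species_trees: bool = False  # experiment-2 reuse rule
    simulate_sequences: bool = True

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if any(nl < 1 for nl in self.n_loci):
            raise ValueError("locus counts must be >= 1")
        if self.experiment not in ("exp1", "exp2", "exp3-shallow", "exp3-deep"):
            raise ValueError(f"unknown experiment {self.experiment!r}")

    # -- canonical designs -------------------------------------------------

    @classmethod
    def exp1(
        cls,
        n_species: int = 5,
        n_individuals: int = 2,
        n_loci: Sequence[int] = (2, 4, 8, 16, 32, 64, 128, 256),
        n_replicates: int = 100,
        seed: int = 0,
    ) -> "ExperimentConfig":
        """Rapid-speciation birth-death design (lambda=1, mu=0.2, HKY k=4)."""
        return cls(
            experiment="exp1",
            n_species=n_species,
            n_individuals=n_individuals,
            n_loci=tuple(n_loci),
            n_replicates=n_replicates,
            seed=seed,
            n_sites=200,
            birth_rate=1.0,
            death_rate=0.2,
            population=species_sim.PopulationModel(kind="constant", value=1.0),
            substitution=seq_sim.SubstitutionModel.hky(kappa=4.0),
            clock=seq_sim.ClockModel(kind="fixed", base_rate=0.01),
        )

    @classmethod
    def exp2(
        cls,
        n_species: int = 5,
        n_loci: Sequence[int] = (1, 2, 4),
        expected_root_height: float = 1.0,
        pop_size: float = 0.5,
        n_replicates: int = 100,
        seed: int = 0,
    ) -> "ExperimentConfig":
        """Calibrated-Yule design for the coalescent-vs-concatenation sweep."""
        return cls(
            experiment="exp2",
            n_species=n_species,
            n_individuals=1,
            n_loci=tuple(n_loci),
            n_replicates=n_replicates,
            seed=seed,
            n_sites=1000,
            birth_rate=species_sim.calibrated_birth_rate(
                n_species, expected_root_height
            ),
            expected_root_height=expected_root_height,
            population=species_sim.PopulationModel(kind="constant", value=pop_size),
            substitution=seq_sim.SubstitutionModel.jc(),
            clock=seq_sim.ClockModel(
                kind="log-uniform-locus", base_rate=0.01, spread_factor=3.0
            ),
            share_species_trees=True,
        )

    @classmethod
    def exp3(
        cls,
        depth: str,
        n_individuals: int = 2,
        n_loci: Sequence[int] = (1, 2, 4, 8),
        n_replicates: int = 100,
        seed: int = 0,
    ) -> "ExperimentConfig":
        """Empirically calibrated design; depth is 'shallow' or 'deep'."""
        p = EXP3_PARAMS[depth]
        lo, hi = p["locus_length"]
        return cls(
            experiment=f"exp3-{depth}",
            n_species=p["n_species"],
            n_individuals=n_individuals,
            n_loci=tuple(n_loci),
            n_replicates=n_replicates,
            seed=seed,
            n_sites=lo,
            birth_rate=p["birth_rate"],
            population=species_sim.PopulationModel(
                kind="gamma", shape=2.0, mean=p["ne_mean"]
            ),
            substitution=seq_sim.SubstitutionModel.gtr(
                p["exchangeabilities"], p["freqs"], gamma_shape=p["gamma_shape"]
            ),
            clock=seq_sim.ClockModel(
                kind="gamma-locus", shape=p["clock_shape"], scale=p["clock_scale"]
            ),
            locus_length_range=None if lo == hi else (lo, hi),
        )

    def config_hash(self) -> str:
        payload = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(self).items()
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class ReplicateBundle:
    """One replicate: the true species tree plus per-locus gene trees and
    alignments, tagged with the provenance needed to regenerate it."""

    replicate: int
    species_tree: SpeciesTree
    gene_trees: list[GeneTree]
    alignments: list[Alignment]
    seed: int
    config_hash: str

    @property
    def n_loci(self) -> int:
        return len(self.gene_trees)

    def subset(self, n_loci: int) -> "ReplicateBundle":
        """First-n-loci view (the locus-subsetting rule of experiment 1)."""
        if n_loci > self.n_loci:
            raise ValueError("cannot subset beyond the simulated locus pool")
        return ReplicateBundle(
            self.replicate,
            self.species_tree,
            self.gene_trees[:n_loci],
            self.alignments[:n_loci],
            self.seed,
            self.config_hash,
        )


def _simulate_species_tree(
    config: ExperimentConfig, rng: np.random.Generator
) -> SpeciesTree:
    if config.death_rate > 0:
        tree = species_sim.simulate_birth_death(
            config.n_species, config.birth_rate, config.death_rate, rng
        )
    else:
        tree = species_sim.simulate_yule(config.n_species, config.birth_rate, rng)
    return species_sim.assign_population_sizes(tree, config.population, rng)


def generate(config: ExperimentConfig, n_loci: int | None = None) -> list[ReplicateBundle]:
    """Generate all replicate bundles for one condition.

    ``n_loci`` defaults to the largest configured locus count; smaller
    analyses take prefixes with :meth:`ReplicateBundle.subset`.  Determinism:
    identical (config, seed) give identical bundles; the species-tree stream
    depends only on (seed, replicate), so experiment 2's rule that one set of
    species trees is reused across locus counts holds automatically, while
    its gene trees and sequences are redrawn per locus count via an
    nl-dependent substream.
    """
    if n_loci is None:
        n_loci = max(config.n_loci)
    chash = config.config_hash()
    bundles = []
    for rep in range(config.n_replicates):
        sp_rng = gene_sim.locus_rng(config.seed, rep)
        species_tree = _simulate_species_tree(config, sp_rng)
        # experiment 2 redraws loci per nl; experiment 1 shares one pool
        locus_key = (rep, n_loci) if config.share_species_trees else (rep,)
        rate_rng = gene_sim.locus_rng(config.seed, *locus_key, 10**6)
        rates = seq_sim.draw_locus_rates(n_loci, config.clock, rate_rng)
        gene_trees, alignments = [], []
        for locus in range(n_loci):
            g_rng = gene_sim.locus_rng(config.seed, *locus_key, locus)
            gt = gene_sim.simulate_gene_tree(species_tree, config.n_individuals, g_rng)
            gene_trees.append(gt)
            if config.simulate_sequences:
                ns = config.n_sites
                if config.locus_length_range is not None:
                    lo, hi = config.locus_length_range
                    ns = int(g_rng.integers(lo, hi + 1))
                alignments.append(
                    seq_sim.simulate_alignment(
                        gt, config.substitution, float(rates[locus]), ns, g_rng
                    )
                )
        bundles.append(
            ReplicateBundle(rep, species_tree, gene_trees, alignments, config.seed, chash)
        )
    return bundles


def export_bundle(bundle: ReplicateBundle, out_dir) -> None:
    """Write a bundle as Newick + NEXUS + FASTA for external inference."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rep = bundle.replicate
    (out / f"{rep}_species.nwk").write_text(write_newick(bundle.species_tree) + "\n")
    write_nexus_trees(bundle.gene_trees, out / f"{rep}_genetrees.nex")
    for locus, aln in enumerate(bundle.alignments):
        aln.write_fasta(out / f"{rep}_{locus}.fasta")
    manifest = {
        "replicate": rep,
        "seed": bundle.seed,
        "config_hash": bundle.config_hash,
        "n_loci": bundle.n_loci,
    }
    (out / f"{rep}_manifest.json").write_text(json.dumps(manifest, indent=1))


def filter_replicates(
    posteriors: Sequence[PosteriorSample],
    threshold: float = 200.0,
    posterior_col: str = "posterior",
    age_col: str = "species_tree_height",
) -> tuple[list[int], list[tuple[int, str]]]:
    """Partition replicates by the minimum-ESS convergence rule.

    A replicate is kept iff both the log-posterior trace and the species
    tree age trace have ESS >= threshold.  Returns (kept indices, list of
    (discarded index, reason)); the two partitions always cover the input.
    """
    kept: list[int] = []
    discarded: list[tuple[int, str]] = []
    for i, post in enumerate(posteriors):
        for col in (posterior_col, age_col):
            if col not in post.trace.columns:
                raise ValueError(f"trace missing required column {col!r}")
        ess_post = scaling.ess(post.trace[posterior_col])
        ess_age = scaling.ess(post.trace[age_col])
        if min(ess_post, ess_age) >= threshold:
            kept.append(i)
        else:
            discarded.append(
                (i, f"ESS posterior={ess_post:.1f}, age={ess_age:.1f} < {threshold:g}")
            )
    return kept, discarded


# -- synthetic pseudo-posteriors ------------------------------------------


def _jitter_tree(
    tree: SpeciesTree, sigma: float, rng: np.random.Generator
) -> SpeciesTree:
    """Multiplicatively jitter internal-branch gaps by lognormal factors.

    Each internal node's height above its tallest child is rescaled, which
    preserves parent-above-child ordering and ultrametricity.
    """
    new = tree.copy()
    for node in new.postorder():
        if node.is_leaf:
            continue
        base = max(c.height for c in node.children)
        gap = node.height - base
        node.height = base + gap * float(rng.lognormal(0.0, sigma))
    return new


def _random_nni(tree: SpeciesTree, rng: np.random.Generator) -> None:
    """One random height-respecting NNI move, in place (no-op if none valid)."""
    candidates = []
    for node in tree.nodes():
        if node.parent is None or node.is_leaf:
            continue
        siblings = [s for s in node.parent.children if s is not node]
        for sib in siblings:
            for child in node.children:
                if sib.height < node.height:  # sib can move under node
                    candidates.append((node, sib, child))
    if not candidates:
        return
    node, sib, child = candidates[int(rng.integers(len(candidates)))]
    parent = node.parent
    parent.children[parent.children.index(sib)] = child
    child.parent = parent
    node.children[node.children.index(child)] = sib
    sib.parent = node


def surrogate_estimate(
    bundle: ReplicateBundle,
    noise: float,
    k: int,
    rng: np.random.Generator,
    n_loci: int | None = None,
) -> PosteriorSample:
    """Synthetic pseudo-posterior standing in for external Bayesian inference.

    Each of the k samples perturbs the true species tree: node heights are
    jittered multiplicatively (lognormal with sigma = noise/sqrt(n_loci)) and
    the topology is rearranged by a random NNI with probability min(1,
    noise/n_loci).  By construction the relative error shrinks as loci are
    added, emulating the power-law testbed; noise=0 returns exact copies.
    The trace carries a synthetic log-posterior and the tree ages.
    """
    if k < 1:
        raise ValueError("need k >= 1 samples")
    nl = n_loci if n_loci is not None else max(bundle.n_loci, 1)
    sigma = noise / np.sqrt(nl)
    p_nni = min(1.0, noise / nl)
    trees: list[SpeciesTree] = []
    for _ in range(k):
        t = _jitter_tree(bundle.species_tree, sigma, rng)
        if noise > 0 and rng.random() < p_nni:
            _random_nni(t, rng)
        trees.append(t)
    ages = [t.height for t in trees]
    trace = pd.DataFrame(
        {
            "state": np.arange(k),
            "posterior": -np.asarray(
                [metrics.rbs(bundle.species_tree, t) for t in trees]
            ),
            "species_tree_height": ages,
        }
    )
    return PosteriorSample(trees=list(trees), trace=trace)


def paired_surrogate_estimates(
    bundle: ReplicateBundle,
    noise: float,
    k: int,
    rng: np.random.Generator,
    crossover: float = 1.0,
    n_loci: int | None = None,
) -> tuple[PosteriorSample, PosteriorSample]:
    """Synthetic coalescent-like vs concatenation-like estimator pair.

    Both are pseudo-posteriors built by perturbing the true tree; the
    "coalescent" estimator's jitter scale grows with the tree's mean branch
    length b in coalescent units as sqrt(b / crossover) while the
    "concatenation" estimator keeps the base scale, so their error ratio
    crosses 1 near b = crossover — the qualitative behaviour the comparison
    pipeline must detect.  Entirely synthetic; no inference is run.
    """
    b = species_sim.mean_branch_length_coalescent(bundle.species_tree)
    coalescent_noise = noise * float(np.sqrt(b / crossover))
    post_coal = surrogate_estimate(bundle, coalescent_noise, k, rng, n_loci=n_loci)
    post_concat = surrogate_estimate(bundle, noise, k, rng, n_loci=n_loci)
    return post_coal, post_concat


def aggregate(
    table: pd.DataFrame,
    value_col: str = "error",
    trim: float = 0.25,
    n_bootstrap: int = 200,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-condition summaries of a replicate-level metric table.

    Groups by (n, ni, nl) and reports the replicate count, median, trimmed
    mean and bootstrap CI for each condition; conditions with no usable
    replicates appear as flagged (NaN) rows rather than being dropped.
    Callers apply the ESS filter *before* aggregation for error summaries
    but not for ESS-rate summaries.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    required = {"n", "ni", "nl", value_col}
    if not required <= set(table.columns):
        raise ValueError(f"table needs columns {sorted(required)}")
    rows = []
    for (n, ni, nl), grp in table.groupby(["n", "ni", "nl"]):
        vals = grp[value_col].dropna().to_numpy()
        if len(vals) == 0:
            rows.append(
                dict(n=n, ni=ni, nl=nl, count=0, median=np.nan,
                     trimmed_mean=np.nan, ci_lower=np.nan, ci_upper=np.nan)
            )
            continue
        eff_trim = trim if len(vals) - 2 * int(np.floor(len(vals) * trim)) >= 1 else 0.0
        summ = metrics.summarize(vals, trim=eff_trim, n_bootstrap=n_bootstrap, rng=rng)
        rows.append(
            dict(
                n=n, ni=ni, nl=nl, count=len(vals),
                median=float(np.median(vals)),
                trimmed_mean=summ.point,
                ci_lower=summ.ci_lower,
                ci_upper=summ.ci_upper,
            )
        )
    return pd.DataFrame(rows)
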