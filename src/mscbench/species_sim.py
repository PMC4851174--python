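"""Species tree simulation under Yule and birth-death models.

Trees are conditioned on the number of extant tips *n*.  The pure-birth Yule
tree is built backward in time: while j lineages remain, the next (going
rootward) speciation is Exponential(j*lambda) away and a uniformly chosen
pair of lineages is joined, giving E[root height] = (H_n - 1)/lambda and an
expected mean branch length of 1/(2*lambda).  The birth-death simulator runs
forward with per-lineage birth rate lambda and death rate mu, rejecting
histories that do not reach exactly n extant survivors, then prunes extinct
lineages to the reconstructed tree.

Per-branch effective population sizes (constant, or i.i.d. gamma with shape 2
in the empirically calibrated designs) are attached to every branch including
the origin branch above the root.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .treeio import Node, SpeciesTree

__all__ = [
    "SpeciationModel",
    "PopulationModel",
    "SimulationError",
    "harmonic",
    "calibrated_birth_rate",
    "simulate_yule",
    "simulate_birth_death",
    "assign_population_sizes",
    "expected_mean_branch_length",
    "mean_branch_length_coalescent",
]

MAX_REJECTIONS = 10**6


class SimulationError(RuntimeError):
    pass


@dataclass
class SpeciationModel:
    """Speciation process parameters.

    birth_rate and death_rate are events per lineage per time unit
    (death_rate = 0 gives the Yule model); n_tips is the conditioned number of
    extant species; expected_root_height, when set, is used to calibrate the
    birth rate instead of taking it literally.
    """

    birth_rate: float
    death_rate: float = 0.0
    n_tips: int = 2
    expected_root_height: float | None = None

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("need n >= 2 tips")
        if not (0.0 <= self.death_rate < self.birth_rate):
            raise ValueError("need 0 <= death rate < birth rate")


@dataclass
class PopulationModel:
    """Per-branch effective population size model.

    kind="constant" puts ``value`` on every branch; kind="gamma" draws
    i.i.d. Gamma(shape, mean/shape) sizes per branch.
    """

    kind: str = "constant"
    value: float = 1.0
    shape: float = 2.0
    mean: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "gamma"):
            raise ValueError(f"unknown population model kind {self.kind!r}")
        if self.kind == "constant" and self.value <= 0:
            raise ValueError("constant Ne must be positive")
        if self.kind == "gamma" and (self.shape <= 0 or self.mean <= 0):
            raise ValueError("gamma Ne parameters must be positive")


def harmonic(n: int) -> float:
    """The n-th harmonic number H_n = sum_{k=1..n} 1/k."""
    return float(np.sum(1.0 / np.arange(1, n + 1)))


def calibrated_birth_rate(n: int, expected_root_height: float) -> float:
    """Yule birth rate giving an expected root height of R for n tips.

    lambda = (1/R) * sum_{k=2..n} 1/k = (H_n - 1)/R, since the expected root
    height of an n-tip Yule tree is sum_{k=2..n} 1/(k*lambda).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if expected_root_height <= 0:
        raise ValueError("expected root height must be positive")
    return (harmonic(n) - 1.0) / expected_root_height


def simulate_yule(n: int, birth_rate: float, rng: np.random.Generator) -> SpeciesTree:
    """Simulate a pure-birth species tree conditioned on n extant tips."""
    if n < 2:
        raise ValueError("need n >= 2")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    lineages: list[Node] = [Node(f"T{i + 1}", 0.0) for i in range(n)]
    height = 0.0
    for j in range(n, 1, -1):
        height += rng.exponential(1.0 / (j * birth_rate))
        i1, i2 = rng.choice(j, size=2, replace=False)
        a = lineages[int(i1)]
        b = lineages[int(i2)]
        parent = Node(None, height)
        parent.add_child(a)
        parent.add_child(b)
        lineages = [x for x in lineages if x is not a and x is not b]
        lineages.append(parent)
    return SpeciesTree(lineages[0])


def simulate_birth_death(
    n: int, birth_rate: float, death_rate: float, rng: np.random.Generator
) -> SpeciesTree:
    """Simulate a reconstructed birth-death tree with exactly n extant tips.

    Forward simulation from a single origin lineage; histories that go
    extinct before reaching n extant lineages are rejected.  The simulation
    stops at the first event that would follow the moment the extant count
    reaches n, so extant count never exceeds n; extinct lineages are then
    pruned and unifurcations suppressed.  With death_rate = 0 the root-height
    and topology distributions coincide with :func:`simulate_yule`.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not (0.0 <= death_rate < birth_rate):
        raise ValueError("need 0 <= death rate < birth rate")
    total = birth_rate + death_rate
    p_birth = birth_rate / total
    for _ in range(MAX_REJECTIONS):
        # each lineage: (birth_time, parent_index); children discovered later
        birth_times = [0.0]
        parents = [-1]
        death_times: dict[int, float] = {}
        alive = [0]
        t = 0.0
        failed = False
        while len(alive) < n:
            t += rng.exponential(1.0 / (total * len(alive)))
            idx = alive[int(rng.integers(len(alive)))]
            if rng.random() < p_birth:
                for _child in range(2):
                    parents.append(idx)
                    birth_times.append(t)
                    alive.append(len(parents) - 1)
                death_times[idx] = t
                alive.remove(idx)
            else:
                death_times[idx] = t
                alive.remove(idx)
                if not alive:
                    failed = True
                    break
        if failed:
            continue
        # dwell at n lineages until the next event, then stop just before it
        t += rng.exponential(1.0 / (total * n))
        return _reconstruct(birth_times, parents, death_times, alive, t)
    raise SimulationError("birth-death rejection sampling did not converge")


def _reconstruct(
    birth_times: list[float],
    parents: list[int],
    death_times: dict[int, float],
    alive: list[int],
    stop_time: float,
) -> SpeciesTree:
    """Prune extinct lineages and build the height-based extant tree."""
    children: dict[int, list[int]] = {}
    for i, p in enumerate(parents):
        if p >= 0:
            children.setdefault(p, []).append(i)
    extant = set(alive)
    has_extant: dict[int, bool] = {}

    def mark(i: int) -> bool:
        res = i in extant
        for k in children.get(i, []):
            if mark(k):
                res = True
        has_extant[i] = res
        return res

    mark(0)
    counter = [0]

    def build(i: int) -> Node:
        kids = [k for k in children.get(i, []) if has_extant.get(k)]
        if i in extant:
            counter[0] += 1
            return Node(f"T{counter[0]}", 0.0)
        if len(kids) == 1:
            return build(kids[0])  # suppress unifurcation
        node = Node(None, stop_time - death_times[i])
        for k in kids:
            node.add_child(build(k))
        return node

    return SpeciesTree(build(0))


def assign_population_sizes(
    tree: SpeciesTree, model: PopulationModel, rng: np.random.Generator
) -> SpeciesTree:
    """Attach an effective population size to every branch, root included.

    The tree is modified in place and returned for convenience.
    """
    for node in tree.nodes():
        if model.kind == "constant":
            tree.pop_sizes[node] = model.value
        else:
            tree.pop_sizes[node] = float(
                rng.gamma(model.shape, model.mean / model.shape)
            )
    return tree


def expected_mean_branch_length(
    expected_root_height: float, n: int, mean_inv_pop_size: float
) -> float:
    """Expected Yule mean branch length in coalescent units tau/(2*Ne).

    The Yule expected mean branch length is 1/(2*lambda) = R/(2*(H_n - 1)),
    so dividing by 2*Ne gives b = (1/4) * R/(H_n - 1) * (1/Ne).  The third
    argument is the mean *reciprocal* population size E[1/Ne], which is the
    quantity that enters linearly.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if expected_root_height <= 0 or mean_inv_pop_size < 0:
        raise ValueError("inputs must be positive")
    return 0.25 * expected_root_height / (harmonic(n) - 1.0) * mean_inv_pop_size


def mean_branch_length_coalescent(tree: SpeciesTree) -> float:
    """Mean branch length of a species tree in coalescent units.

    Each non-root branch contributes tau_b / (2 * Ne_b); the root branch has
    no defined length and is excluded.
    """
    values = []
    for node in tree.nodes():
        if node.parent is None:
            continue
        if node not in tree.pop_sizes:
            raise ValueError("every branch needs an Ne to convert to coalescent units")
        values.append(node.branch_length / (2.0 * tree.pop_sizes[node]))
    return float(np.mean(values))
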