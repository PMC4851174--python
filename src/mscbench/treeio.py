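"""Rooted time-tree containers and I/O.

Every tree in this package is rooted and measured in *node heights*: leaves
sit at height 0 and heights increase toward the root, so the branch length of
a node is ``parent.height - node.height``.  This is the natural convention for
ultrametric species and gene trees and for the coalescent arithmetic used in
the simulators.

Parsing of Newick and NEXUS (including BEAST-style translate tables) is
delegated to :mod:`dendropy`; the containers and writers here are purposely
small so the rest of the package can reason about heights directly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TreeParseError",
    "TraceFormatError",
    "Node",
    "TimeTree",
    "SpeciesTree",
    "GeneTree",
    "Alignment",
    "PosteriorSample",
    "parse_newick",
    "write_newick",
    "clades",
    "read_trace",
    "combine_traces",
    "read_nexus_trees",
]

#: Relative tolerance (to total tree height) for ultrametricity checks.
ULTRAMETRIC_RTOL = 1e-6


class TreeParseError(ValueError):
    """Raised for malformed Newick/NEXUS input."""


class TraceFormatError(ValueError):
    """Raised for malformed tab-separated trace logs."""


class Node:
    """A node of a rooted time tree.

    Attributes
    ----------
    label:
        Leaf label (``None`` for internal nodes unless named).
    height:
        Distance above the leaves, in the tree's time units.
    parent, children:
        Topology links; the root has ``parent is None``.
    """

    __slots__ = ("label", "height", "parent", "children")

    def __init__(self, label: str | None = None, height: float = 0.0):
        self.label = label
        self.height = float(height)
        self.parent: Node | None = None
        self.children: list[Node] = []

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def branch_length(self) -> float:
        """Length of the branch extending rootward from this node.

        Undefined (``nan``) for the root, which has no rootward branch.
        """
        if self.parent is None:
            return float("nan")
        return self.parent.height - self.height

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        tag = self.label if self.label is not None else "<internal>"
        return f"Node({tag}, h={self.height:.6g})"


class TimeTree:
    """A rooted tree with node heights (leaves at height 0)."""

    def __init__(self, root: Node):
        self.root = root

    # -- traversal ---------------------------------------------------------

    def nodes(self) -> Iterator[Node]:
        """Preorder traversal."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.nodes() if n.is_leaf]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.nodes() if not n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label or "" for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    @property
    def height(self) -> float:
        return self.root.height

    @property
    def total_length(self) -> float:
        """Sum of all branch lengths (root branch excluded)."""
        return sum(n.branch_length for n in self.nodes() if n.parent is not None)

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        h = max(self.root.height, 1e-300)
        return all(abs(leaf.height) <= rtol * h for leaf in self.leaves())

    def copy(self) -> "TimeTree":
        new = TimeTree(_copy_subtree(self.root))
        _copy_extras(self, new)
        return new

    def leaf_by_label(self, label: str) -> Node:
        for leaf in self.leaves():
            if leaf.label == label:
                return leaf
        raise KeyError(label)

    def mrca(self, labels: Iterable[str]) -> Node:
        """Most recent common ancestor of the given leaf labels."""
        want = set(labels)
        below: dict[Node, set[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = {node.label or ""}
            else:
                below[node] = set().union(*(below[c] for c in node.children))
            if want <= below[node]:
                return node
        raise KeyError(f"labels not all present: {sorted(want)}")

    def __repr__(self) -> str:  # pragma: no cover
        return f"{type(self).__name__}(n={self.n_leaves}, height={self.height:.6g})"


def _copy_subtree(node: Node) -> Node:
    new = Node(node.label, node.height)
    for child in node.children:
        new.add_child(_copy_subtree(child))
    return new


def _copy_extras(src: "TimeTree", dst: "TimeTree") -> None:
    if isinstance(src, SpeciesTree) and isinstance(dst, SpeciesTree):
        order = list(src.nodes())
        new_order = list(dst.nodes())
        dst.pop_sizes = {nn: src.pop_sizes[on] for on, nn in zip(order, new_order)}


class SpeciesTree(TimeTree):
    """An ultrametric species tree carrying an effective population size on
    every branch, including the root (origin) branch.

    ``pop_sizes`` maps each node to the Ne of the branch extending rootward
    from it; the root's entry is the ancestral population above the root.
    """

    def __init__(self, root: Node, pop_sizes: Mapping[Node, float] | None = None):
        super().__init__(root)
        self.pop_sizes: dict[Node, float] = dict(pop_sizes or {})

    def validate(self) -> None:
        labels = self.leaf_labels
        if len(set(labels)) != len(labels):
            raise ValueError("species tree leaf labels must be unique")
        if self.pop_sizes:
            for node in self.nodes():
                if self.pop_sizes.get(node, 0.0) <= 0.0:
                    raise ValueError("every branch needs Ne > 0")

    def copy(self) -> "SpeciesTree":
        new_root = _copy_subtree(self.root)
        new = SpeciesTree(new_root)
        for on, nn in zip(self.nodes(), new.nodes()):
            if on in self.pop_sizes:
                new.pop_sizes[nn] = self.pop_sizes[on]
        return new


class GeneTree(TimeTree):
    """A gene tree whose leaves are gene copies mapped onto species.

    Copy labels follow the ``<species>_<index>`` convention and the map is
    derivable from labels, but an explicit map may be supplied for external
    input.
    """

    def __init__(self, root: Node, species_map: Mapping[str, str] | None = None):
        super().__init__(root)
        if species_map is None:
            species_map = {
                lab: lab.rsplit("_", 1)[0] for lab in (n.label or "" for n in self.leaves())
            }
        self.species_map: dict[str, str] = dict(species_map)

    def species_of(self, leaf_label: str) -> str:
        return self.species_map[leaf_label]

    def check_against(self, species_tree: SpeciesTree, atol: float = 1e-9) -> None:
        """Assert the multispecies-coalescent containment invariant.

        For gene copies from two different species, their coalescence cannot
        predate (be lower than) the divergence of those species.
        """
        sp_labels = set(species_tree.leaf_labels)
        for sp in self.species_map.values():
            if sp not in sp_labels:
                raise ValueError(f"species {sp!r} not in the species tree")
        # species divergence heights
        leaves = self.leaves()
        below: dict[Node, set[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = {self.species_map[node.label or ""]}
            else:
                below[node] = set().union(*(below[c] for c in node.children))
                if len(below[node]) > 1:
                    div = species_tree.mrca(below[node]).height
                    if node.height < div - atol:
                        raise AssertionError(
                            f"gene coalescence at {node.height:.6g} below species "
                            f"divergence {div:.6g} for {sorted(below[node])}"
                        )


@dataclass
class Alignment:
    """A single-locus nucleotide alignment plus its strict-clock rate.

    ``sequences`` maps gene-copy labels to equal-length strings over ACGT;
    ``clock_rate`` is in expected substitutions per site per time unit.
    """

    sequences: dict[str, str]
    clock_rate: float = 1.0

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("sequences must be of equal length")

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def labels(self) -> list[str]:
        return list(self.sequences)

    def to_array(self) -> np.ndarray:
        """Integer-coded (A,C,G,T)=(0..3) matrix, rows in label order."""
        coding = {"A": 0, "C": 1, "G": 2, "T": 3}
        return np.array(
            [[coding[b] for b in self.sequences[lab]] for lab in self.labels],
            dtype=np.int8,
        )

    def write_fasta(self, path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(seq), id=lab, description="") for lab, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def read_fasta(cls, path, clock_rate: float = 1.0) -> "Alignment":
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls(seqs, clock_rate)

    def write_nexus(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#NEXUS\nbegin data;\n")
            fh.write(f"  dimensions ntax={len(self.sequences)} nchar={self.n_sites};\n")
            fh.write("  format datatype=dna missing=? gap=-;\n  matrix\n")
            for lab, seq in self.sequences.items():
                fh.write(f"    {lab}  {seq}\n")
            fh.write("  ;\nend;\n")


@dataclass
class PosteriorSample:
    """Posterior species-tree samples plus scalar trace columns.

    ``trees`` is the ordered list of sampled trees (length k); ``trace`` holds
    named numeric series of equal length (at minimum the log posterior and the
    species-tree age for ESS-based filtering).
    """

    trees: list[TimeTree] = field(default_factory=list)
    trace: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("a posterior needs k >= 1 tree samples")
        labels = frozenset(self.trees[0].leaf_labels)
        for t in self.trees[1:]:
            if frozenset(t.leaf_labels) != labels:
                raise ValueError("all posterior trees must share one leaf set")

    @property
    def k(self) -> int:
        return len(self.trees)


# -- Newick ----------------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree) -> TimeTree:
    """Convert a dendropy tree into a height-based TimeTree.

    Heights are reconstructed from branch lengths: depth below the root is
    accumulated, then flipped so the deepest leaf sits at height 0.
    """
    droot = dtree.seed_node
    depth: dict = {droot: 0.0}
    for edge in dtree.preorder_edge_iter():
        if edge.tail_node is not None:
            length = edge.length if edge.length is not None else 0.0
            depth[edge.head_node] = depth[edge.tail_node] + float(length)
    max_depth = max(depth[lf] for lf in dtree.leaf_node_iter())

    def build(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = Node(label, max_depth - depth[dnode])
        for child in dnode.child_nodes():
            node.add_child(build(child))
        return node

    return TimeTree(build(droot))


def parse_newick(text: str) -> TimeTree:
    """Parse one rooted Newick string into a :class:`TimeTree`.

    Node heights are reconstructed from branch lengths with the deepest leaf
    at height 0.  Non-ultrametric input is accepted; callers that require
    ultrametricity check :meth:`TimeTree.is_ultrametric`.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", rooting="force-rooted",
            suppress_internal_node_taxa=True, preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeParseError(f"malformed newick: {exc}") from exc
    if dtree.seed_node is None or not any(dtree.leaf_node_iter()):
        raise TreeParseError("empty tree")
    return _from_dendropy(dtree)


def write_newick(tree: TimeTree, precision: int = 12) -> str:
    """Serialize to rooted Newick with branch lengths from node heights."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            core = node.label or ""
        else:
            core = "(" + ",".join(fmt(c) for c in node.children) + ")"
        if node.parent is None:
            return core
        return f"{core}:{node.branch_length:.{precision}g}"

    return fmt(tree.root) + ";"


def read_nexus_trees(path, burnin_frac: float = 0.0) -> list[TimeTree]:
    """Read a NEXUS trees block (translate tables supported) into TimeTrees.

    ``burnin_frac`` drops the leading fraction of trees, as done when
    summarising an MCMC tree log.
    """
    try:
        dtrees = dendropy.TreeList.get(
            path=str(path), schema="nexus", preserve_underscores=True
        )
    except Exception as exc:
        raise TreeParseError(f"malformed NEXUS: {exc}") from exc
    trees = [_from_dendropy(t) for t in dtrees]
    start = int(len(trees) * burnin_frac)
    return trees[start:]


def write_nexus_trees(trees: Sequence[TimeTree], path) -> None:
    """Write a batch of trees (e.g. one per locus) as a NEXUS trees block."""
    labels = trees[0].leaf_labels if trees else []
    with open(path, "w") as fh:
        fh.write("#NEXUS\nbegin taxa;\n")
        fh.write(f"  dimensions ntax={len(labels)};\n  taxlabels\n")
        for lab in labels:
            fh.write(f"    {lab}\n")
        fh.write("  ;\nend;\nbegin trees;\n")
        for i, tree in enumerate(trees):
            fh.write(f"  tree TREE_{i} = {write_newick(tree)}\n")
        fh.write("end;\n")


# -- clades ----------------------------------------------------------------


def clades(tree: TimeTree) -> set[frozenset[str]]:
    """The set of monophyletic clades of a rooted tree.

    One clade per node *except the root* (which has no rootward branch);
    singleton tip clades are included.  This is the clade set over which the
    rooted branch score sums.
    """
    below: dict[Node, frozenset[str]] = {}
    out: set[frozenset[str]] = set()
    for node in tree.postorder():
        if node.is_leaf:
            below[node] = frozenset([node.label or ""])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.children))
        if node.parent is not None:
            out.add(below[node])
    return out


def clade_lengths(tree: TimeTree) -> dict[frozenset[str], float]:
    """Map each clade to the length of its rootward branch.

    If several nodes span the same leaf set (zero-length internal branches),
    their rootward branch lengths are summed so the map stays well defined.
    """
    below: dict[Node, frozenset[str]] = {}
    out: dict[frozenset[str], float] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[node] = frozenset([node.label or ""])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.children))
        if node.parent is not None:
            key = below[node]
            out[key] = out.get(key, 0.0) + node.branch_length
    return out


# -- trace logs ------------------------------------------------------------


def read_trace(path_or_buffer) -> pd.DataFrame:
    """Read a BEAST-style tab-separated trace log.

    The first column is the MCMC state index; comment lines starting with
    ``#`` are skipped; all columns are returned as numeric series keyed by
    the header.  Ragged rows raise :class:`TraceFormatError`.
    """
    if hasattr(path_or_buffer, "read"):
        lines = path_or_buffer.read().splitlines()
    else:
        with open(path_or_buffer) as fh:
            lines = fh.read().splitlines()
    rows = [ln for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    if not rows:
        raise TraceFormatError("empty trace log")
    header = rows[0].split("\t")
    data = []
    for i, ln in enumerate(rows[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise TraceFormatError(
                f"ragged row at data line {i}: expected {len(header)} fields, got {len(fields)}"
            )
        data.append(fields)
    df = pd.DataFrame(data, columns=header)
    return df.apply(pd.to_numeric)


def combine_traces(first: pd.DataFrame, second: pd.DataFrame) -> pd.DataFrame:
    """Concatenate a resumed chain onto its parent chain.

    BEAST's resume facility re-logs the final state of the parent run as the
    first row of the continuation, so when the boundary states coincide the
    duplicate leading row of the second log is dropped.
    """
    if list(first.columns) != list(second.columns):
        raise TraceFormatError("trace logs have different columns")
    state_col = first.columns[0]
    if len(second) and len(first) and second[state_col].iloc[0] == first[state_col].iloc[-1]:
        second = second.iloc[1:]
    return pd.concat([first, second], ignore_index=True)
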