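"""Rooted phylogenetic trees, Newick I/O, and node-age calibrations.

The tree container used throughout the package is a small mutable rooted
tree.  Branch lengths may be in substitutions/site (gene trees, species
trees before dating) or in Myr (chronograms); the ``units`` tag records
which.  Node ages are measured in Ma before present and increase root-ward,
so the duration of a branch is ``age(parent) - age(child)``.

Newick parsing and serialisation are delegated to dendropy, which copes
with the label-quoting dialects produced by the usual inference tools
(ASTRAL, RAxML); internal-node labels are read but play no role in clade
matching, which is always by tip sets.
"""

from __future__ import annotations

import io
import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import dendropy

__all__ = [
    "Node",
    "PhyloTree",
    "Calibration",
    "CalibrationSet",
    "read_newick",
    "read_newick_list",
    "write_newick",
    "read_calibrations",
]


class NewickError(ValueError):
    """Malformed Newick input."""


class Node:
    """A node in a rooted tree.

    ``length`` is the length of the branch subtending this node (None for
    the root or for topology-only trees); ``age`` is the node age in Ma
    when the tree is dated.
    """

    __slots__ = ("label", "length", "age", "parent", "children", "id")

    def __init__(self, label: Optional[str] = None,
                 length: Optional[float] = None) -> None:
        self.label = label
        self.length = length
        self.age: Optional[float] = None
        self.parent: Optional["Node"] = None
        self.children: list["Node"] = []
        self.id: int = -1

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.id} {self.label or ''} {kind}>"


class PhyloTree:
    """Rooted tree with unique, non-empty tip labels.

    ``units`` is one of ``"subs"`` (substitutions/site), ``"myr"``, or
    ``"none"`` (topology only).
    """

    def __init__(self, root: Node, units: str = "subs") -> None:
        self.root = root
        self.units = units
        self._reindex()
        self._validate()

    # -- construction and bookkeeping ------------------------------------

    def _reindex(self) -> None:
        self.nodes: list[Node] = list(self._postorder(self.root))
        for i, nd in enumerate(self.nodes):
            nd.id = i

    def _validate(self) -> None:
        labels = [nd.label for nd in self.leaves()]
        if any(not lb for lb in labels):
            raise NewickError("empty tip label")
        if len(labels) != len(set(labels)):
            dup = sorted({lb for lb in labels if labels.count(lb) > 1})
            raise NewickError(f"duplicate tip labels: {dup}")
        for nd in self.nodes:
            if nd is not self.root and nd.parent is None:
                raise NewickError("non-root node without parent")
            if nd.length is not None and nd.length < 0:
                raise NewickError(f"negative branch length on node {nd.id}")

    @staticmethod
    def _postorder(node: Node) -> Iterator[Node]:
        stack = [(node, False)]
        while stack:
            nd, expanded = stack.pop()
            if expanded:
                yield nd
            else:
                stack.append((nd, True))
                for ch in reversed(nd.children):
                    stack.append((ch, False))

    # -- traversal -------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        return iter(self.nodes)

    def preorder(self) -> Iterator[Node]:
        return reversed(self.nodes)

    def leaves(self) -> list[Node]:
        return [nd for nd in self.nodes if nd.is_leaf]

    def internal_nodes(self, include_root: bool = True) -> list[Node]:
        out = [nd for nd in self.nodes if not nd.is_leaf]
        if not include_root:
            out = [nd for nd in out if nd is not self.root]
        return out

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(nd.label for nd in self.leaves())

    def n_tips(self) -> int:
        return len(self.leaves())

    def is_binary(self) -> bool:
        return all(len(nd.children) == 2 for nd in self.internal_nodes())

    def has_lengths(self) -> bool:
        return all(nd.length is not None for nd in self.nodes
                   if nd is not self.root)

    # -- clades and MRCA -------------------------------------------------

    def clades(self) -> dict[int, frozenset[str]]:
        """Tip-set of the clade descending each node, keyed by node id."""
        out: dict[int, frozenset[str]] = {}
        for nd in self.postorder():
            if nd.is_leaf:
                out[nd.id] = frozenset([nd.label])
            else:
                out[nd.id] = frozenset().union(
                    *(out[ch.id] for ch in nd.children))
        return out

    def find_tip(self, label: str) -> Node:
        for nd in self.leaves():
            if nd.label == label:
                return nd
        raise KeyError(f"unknown tip name: {label!r}")

    def mrca(self, tips: Iterable[str]) -> Node:
        """Most recent common ancestor of a nonempty set of tip labels."""
        tipset = set(tips)
        if not tipset:
            raise ValueError("mrca of an empty tip set")
        here = self.taxa
        missing = tipset - here
        if missing:
            raise KeyError(f"unknown tip name(s): {sorted(missing)}")
        clades = self.clades()
        best = self.root
        for nd in self.postorder():
            if tipset <= clades[nd.id]:
                return nd
        return best  # pragma: no cover - root always contains all tips

    # -- ages ------------------------------------------------------------

    def set_ages_from_lengths(self) -> None:
        """Compute node ages assuming an ultrametric tree in time units."""
        depth: dict[int, float] = {self.root.id: 0.0}
        for nd in self.preorder():
            if nd is self.root:
                continue
            depth[nd.id] = depth[nd.parent.id] + (nd.length or 0.0)
        height = max(depth[lf.id] for lf in self.leaves())
        for nd in self.nodes:
            nd.age = height - depth[nd.id]
        for lf in self.leaves():
            if abs(lf.age) < 1e-9 * max(height, 1.0):
                lf.age = 0.0

    def set_lengths_from_ages(self) -> None:
        for nd in self.nodes:
            if nd is self.root:
                continue
            nd.length = nd.parent.age - nd.age

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        if not self.has_lengths():
            return False
        depth: dict[int, float] = {self.root.id: 0.0}
        for nd in self.preorder():
            if nd is self.root:
                continue
            depth[nd.id] = depth[nd.parent.id] + nd.length
        d = [depth[lf.id] for lf in self.leaves()]
        span = max(d)
        return span == 0 or (max(d) - min(d)) <= rel_tol * span

    def root_age(self) -> float:
        if self.root.age is None:
            raise ValueError("tree is not dated")
        return self.root.age

    def check_dated(self) -> None:
        """Assert parent age strictly exceeds child age everywhere."""
        for nd in self.nodes:
            if nd.age is None:
                raise ValueError("undated node in dated tree")
            if nd is not self.root and not nd.parent.age > nd.age:
                raise ValueError(
                    f"parent age {nd.parent.age} not > child age {nd.age}")

    # -- copy / prune ----------------------------------------------------

    def copy(self) -> "PhyloTree":
        def clone(nd: Node) -> Node:
            new = Node(nd.label, nd.length)
            new.age = nd.age
            for ch in nd.children:
                new.add_child(clone(ch))
            return new

        return PhyloTree(clone(self.root), units=self.units)

    def pruned_to(self, taxa: Iterable[str],
                  suppress_unifurcations: bool = True) -> "PhyloTree":
        """Restrict to a taxon subset.

        Degree-2 nodes created by pruning are suppressed with branch lengths
        summed, so path lengths between retained tips are preserved.  Node
        ages of retained nodes are untouched.
        """
        keep = set(taxa)
        if not keep & set(self.taxa):
            raise ValueError("pruning would remove every tip")
        tree = self.copy()

        def prune(nd: Node) -> Optional[Node]:
            if nd.is_leaf:
                return nd if nd.label in keep else None
            kept = [c for c in (prune(ch) for ch in nd.children)
                    if c is not None]
            if not kept:
                return None
            if len(kept) == 1 and suppress_unifurcations:
                child = kept[0]
                if nd.length is not None and child.length is not None:
                    child.length = child.length + nd.length
                elif nd.length is not None:
                    child.length = nd.length
                child.parent = nd.parent
                return child
            nd.children = kept
            for c in kept:
                c.parent = nd
            return nd

        new_root = prune(tree.root)
        if new_root is None:  # pragma: no cover - guarded above
            raise ValueError("pruning removed every tip")
        new_root.parent = None
        if suppress_unifurcations and len(new_root.children) == 1:
            new_root = new_root.children[0]
            new_root.parent = None
            new_root.length = None
        return PhyloTree(new_root, units=self.units)


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed)
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree, units: str) -> PhyloTree:
    def conv(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label is not None:
            label = dnode.label
        nd = Node(label=label, length=dnode.edge.length)
        for ch in dnode.child_nodes():
            nd.add_child(conv(ch))
        return nd

    return PhyloTree(conv(dtree.seed_node), units=units)


def read_newick(text: str, units: str = "subs") -> PhyloTree:
    """Parse a single Newick tree from a string.

    Quoted labels and underscore conventions are handled; inner-node labels
    are retained but never used for matching.  A tree without any branch
    lengths is tagged ``units="none"`` (topology only).
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickError(f"Newick parse error: {exc}") from exc
    tree = _from_dendropy(dtree, units)
    if all(nd.length is None for nd in tree.nodes if nd is not tree.root):
        tree.units = "none"
    return tree


def read_newick_list(text: str, units: str = "subs") -> list[PhyloTree]:
    """Parse a collection of Newick trees (one per line / semicolon)."""
    out = []
    for chunk in text.split(";"):
        if chunk.strip():
            out.append(read_newick(chunk + ";", units=units))
    return out


def write_newick(tree: PhyloTree, precision: int = 17) -> str:
    """Serialise with branch lengths at ``precision`` significant digits."""

    def fmt(nd: Node) -> str:
        if nd.is_leaf:
            body = _quote(nd.label)
        else:
            body = "(" + ",".join(fmt(c) for c in nd.children) + ")"
            if nd.label:
                body += _quote(nd.label)
        if nd.length is not None:
            body += f":{nd.length:.{precision}g}"
        return body

    return fmt(tree.root) + ";"


_UNSAFE = set(" ()[]:;,'\"")


def _quote(label: Optional[str]) -> str:
    if label is None:
        return ""
    if any(ch in _UNSAFE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Calibrations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Calibration:
    """A node-age bound anchored by the MRCA of ``clade_tips``."""

    clade_tips: frozenset[str]
    bound: str          # "min" or "max"
    age: float          # Ma

    def __post_init__(self) -> None:
        if self.bound not in ("min", "max"):
            raise ValueError(f"bound must be 'min' or 'max', got {self.bound}")
        if self.age <= 0:
            raise ValueError("calibration ages must be positive")
        if not self.clade_tips:
            raise ValueError("calibration needs at least one anchor tip")


@dataclass
class CalibrationSet:
    """Minimum/maximum node-age constraints.

    All anchor tips must be present in the tree the set is applied to; the
    package errors rather than silently re-anchoring when constraint taxa
    are missing.
    """

    calibrations: list[Calibration] = field(default_factory=list)

    def __iter__(self) -> Iterator[Calibration]:
        return iter(self.calibrations)

    def __len__(self) -> int:
        return len(self.calibrations)

    def add(self, clade_tips: Iterable[str], bound: str, age: float) -> None:
        self.calibrations.append(
            Calibration(frozenset(clade_tips), bound, age))

    def resolve(self, tree: PhyloTree) -> dict[int, tuple[float, float]]:
        """Map node id -> (min_age, max_age), checking min <= max."""
        bounds: dict[int, list[float]] = {}
        for cal in self.calibrations:
            node = tree.mrca(cal.clade_tips)
            lo, hi = bounds.setdefault(node.id, [0.0, math.inf])
            if cal.bound == "min":
                bounds[node.id][0] = max(lo, cal.age)
            else:
                bounds[node.id][1] = min(hi, cal.age)
        for nid, (lo, hi) in bounds.items():
            if lo > hi:
                raise ValueError(
                    f"infeasible calibration at node {nid}: min {lo} > max {hi}")
        return {nid: (lo, hi) for nid, (lo, hi) in bounds.items()}


def read_calibrations(text: str) -> CalibrationSet:
    """Parse a delimited calibration table: clade_tips, bound, age.

    ``clade_tips`` is a semicolon-separated tip list; lines starting with
    '#' are comments.  Tab- or comma-delimited.
    """
    cs = CalibrationSet()
    for ln, line in enumerate(io.StringIO(text), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(",")
        if len(parts) != 3:
            raise ValueError(f"calibration line {ln}: expected 3 fields")
        tips = [t.strip() for t in parts[0].split(";") if t.strip()]
        cs.add(tips, parts[1].strip().lower(), float(parts[2]))
    return cs
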