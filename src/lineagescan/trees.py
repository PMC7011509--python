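"""Rooted-tree containers for the reconciliation pipeline.

Two tree flavours share one node structure:

* :class:`SpeciesTree` — an ultrametric, uniquely-labelled taxonomy tree
  whose branch lengths are in millions of years (MY); node ages in MYA are
  derived from leaf depths (leaves sit at age 0).
* :class:`GeneTree` — a rooted binary gene-family tree with branch lengths
  in substitutions per site.  Leaf labels follow the convention
  ``<species>|<copy id>`` so every leaf carries the species it was sampled
  from; a bare label (no ``|``) is taken as the species itself.

Newick text is parsed with dendropy; the classes below add the invariants
the downstream analyses rely on (unique labels, non-negative lengths,
ultrametricity, binarity) and fast ancestor/LCA queries.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy

__all__ = [
    "Node",
    "SpeciesTree",
    "GeneTree",
    "NewickError",
    "parse_newick",
]

# Relative slack allowed when checking that all root-to-leaf depths of a
# calibrated species tree agree (ultrametricity).
_ULTRAMETRIC_RTOL = 1e-6


class NewickError(ValueError):
    """Raised for malformed Newick input or violated tree invariants."""


@dataclass
class Node:
    """A node of a rooted tree; the edge to ``parent`` has length ``length``."""

    label: str
    length: float = 0.0
    parent: Optional["Node"] = None
    children: list["Node"] = field(default_factory=list)
    # Filled in by the owning tree: preorder index and depth from the root
    # (sum of edge lengths), used for O(depth) LCA walks.
    index: int = -1
    depth: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out: list[Node] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list["Node"]:
        return [n for n in self.preorder() if n.is_leaf]


def _quote_label(label: str) -> str:
    if label and not any(c in label for c in " ()[]{}:;,'\t\n"):
        return label
    return "'" + label.replace("'", "''") + "'"


def _format_length(x: float) -> str:
    # repr gives the shortest decimal that round-trips the float
    return repr(float(x))


class _BaseTree:
    """Shared plumbing: parsing, serialisation, indexing, LCA queries."""

    def __init__(self, root: Node):
        self.root = root
        self._index()

    # -- construction -----------------------------------------------------

    @classmethod
    def _root_from_newick(cls, text: str, next_auto: int = 1) -> Node:
        if not text.strip():
            raise NewickError("empty Newick string")
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickError(f"malformed Newick: {exc}") from exc

        def convert(dnode: dendropy.Node) -> Node:
            nonlocal next_auto
            if dnode.taxon is not None:
                label = str(dnode.taxon.label)
            elif dnode.label is not None:
                label = str(dnode.label)
            else:
                label = f"__auto_{next_auto}"
                next_auto += 1
            length = dnode.edge.length
            if length is None:
                length = 0.0
            if length < 0:
                raise NewickError(
                    f"negative branch length {length} on node {label!r}"
                )
            node = Node(label=label, length=float(length))
            for child in dnode.child_nodes():
                cnode = convert(child)
                cnode.parent = node
                node.children.append(cnode)
            return node

        return convert(dtree.seed_node)

    def _index(self) -> None:
        labels: set[str] = set()
        self.nodes: list[Node] = []
        for i, node in enumerate(self.root.preorder()):
            if node.label in labels:
                raise NewickError(f"duplicate node label {node.label!r}")
            labels.add(node.label)
            node.index = i
            node.depth = node.length + (node.parent.depth if node.parent else 0.0)
            self.nodes.append(node)
        self._by_label = {n.label: n for n in self.nodes}

    # -- queries ----------------------------------------------------------

    def __getitem__(self, label: str) -> Node:
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(f"no node labelled {label!r} in tree") from None

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    @property
    def leaves(self) -> list[Node]:
        return [n for n in self.nodes if n.is_leaf]

    def is_ancestor_or_equal(self, anc: Node, node: Node) -> bool:
        while node is not None:
            if node is anc:
                return True
            node = node.parent
        return False

    def lca(self, a: Node, b: Node) -> Node:
        """Last common ancestor by walking the deeper node up first."""
        seen = set()
        while a is not None:
            seen.add(id(a))
            a = a.parent
        while b is not None:
            if id(b) in seen:
                return b
            b = b.parent
        raise ValueError("nodes share no ancestor (not in the same tree)")

    def path_down(self, anc: Node, desc: Node) -> list[Node]:
        """Nodes strictly below ``anc`` on the path to ``desc`` (inclusive).

        Each returned node identifies the species-tree edge entering it.
        Returns an empty list when ``anc is desc``.
        """
        path: list[Node] = []
        node = desc
        while node is not anc:
            if node is None:
                raise ValueError(
                    f"{anc.label!r} is not an ancestor of {desc.label!r}"
                )
            path.append(node)
            node = node.parent
        path.reverse()
        return path

    # -- serialisation ----------------------------------------------------

    def to_newick(self) -> str:
        """Canonical Newick text: all labels written, lengths in repr form."""
        out = io.StringIO()

        def write(node: Node) -> None:
            if node.children:
                out.write("(")
                for i, child in enumerate(node.children):
                    if i:
                        out.write(",")
                    write(child)
                out.write(")")
            out.write(_quote_label(node.label))
            if node.parent is not None:
                out.write(":" + _format_length(node.length))

        write(self.root)
        out.write(";")
        return out.getvalue()

    def __len__(self) -> int:
        return len(self.nodes)


class SpeciesTree(_BaseTree):
    """Calibrated taxonomy tree; branch lengths in MY, node ages in MYA.

    Invariants enforced at construction: unique labels, a single root,
    non-negative lengths, ultrametric leaf depths (all leaves at age 0),
    and strictly positive parent-over-child age ordering.
    """

    def __init__(self, root: Node):
        super().__init__(root)
        self._assign_ages()

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        return cls(cls._root_from_newick(text))

    def _assign_ages(self) -> None:
        depths = [leaf.depth for leaf in self.leaves]
        root_age = max(depths)
        tol = _ULTRAMETRIC_RTOL * max(root_age, 1.0)
        for leaf, d in zip(self.leaves, depths):
            if abs(d - root_age) > tol:
                raise NewickError(
                    f"species tree is not ultrametric: leaf {leaf.label!r} at "
                    f"depth {d}, expected {root_age}"
                )
        self.ages: dict[str, float] = {}
        for node in self.nodes:
            age = 0.0 if node.is_leaf else root_age - node.depth
            if age < 0:
                age = 0.0
            self.ages[node.label] = age
        for node in self.nodes:
            for child in node.children:
                if not child.is_leaf and self.ages[node.label] <= self.ages[child.label]:
                    raise NewickError(
                        f"age of {node.label!r} not greater than child "
                        f"{child.label!r}"
                    )

    def age(self, label: str) -> float:
        return self.ages[self[label].label]

    @property
    def root_age(self) -> float:
        return self.ages[self.root.label]


def _species_of(label: str) -> str:
    return label.split("|", 1)[0]


class GeneTree(_BaseTree):
    """Rooted binary gene tree; lengths in substitutions per site.

    Per-branch annotations (dN/dS, dS, substituted-site indices) are keyed
    by the label of the child node of each branch; absent entries mean the
    quantity was not estimated for that branch.
    """

    def __init__(
        self,
        root: Node,
        dnds: dict[str, float] | None = None,
        ds: dict[str, float] | None = None,
        substituted_sites: dict[str, list[int]] | None = None,
    ):
        super().__init__(root)
        for node in self.nodes:
            if node.children and len(node.children) != 2:
                raise NewickError(
                    f"gene tree must be binary; node {node.label!r} has "
                    f"{len(node.children)} children"
                )
        self.dnds = dict(dnds or {})
        self.ds = dict(ds or {})
        self.substituted_sites = {
            k: list(v) for k, v in (substituted_sites or {}).items()
        }

    @classmethod
    def from_newick(cls, text: str, **annotations) -> "GeneTree":
        return cls(cls._root_from_newick(text), **annotations)

    def species_of(self, leaf: Node) -> str:
        return _species_of(leaf.label)

    def leaf_species(self) -> set[str]:
        return {self.species_of(leaf) for leaf in self.leaves}

    def branches(self) -> list[Node]:
        """All non-root nodes; each identifies the branch above it."""
        return [n for n in self.nodes if n.parent is not None]

    def root_to_leaf_lengths(self) -> list[float]:
        return [leaf.depth for leaf in self.leaves]


def parse_newick(text: str, expect_ages: bool = False) -> SpeciesTree | GeneTree:
    """Parse Newick text into a :class:`SpeciesTree` or :class:`GeneTree`.

    ``expect_ages=True`` builds a species tree (branch lengths read as MY of
    an ultrametric tree, node ages derived); otherwise a binary gene tree
    with lengths in substitutions per site.
    """
    if expect_ages:
        return SpeciesTree.from_newick(text)
    return GeneTree.from_newick(text)
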