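"""Rooted binary phylogeny: Newick parsing, validation, traversal.

The tree is strictly bifurcating.  The root-state disambiguation rule used
downstream speaks of left and right subtrees, which presumes bifurcation,
so multifurcations are rejected rather than silently resolved.  "Left" and
"right" are the first and second child in Newick order, making results
reproducible for a given input string.

Branch lengths are parsed and retained (the synthetic-data simulator uses
them) but ignored by the parsimony inference, which is purely topological.
Internal-node labels in the input are accepted; unlabeled internal nodes
receive generated ``node_<k>`` names (pre-order) so branch events can be
reported against stable identifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Optional

log = logging.getLogger(__name__)

__all__ = [
    "NewickError",
    "TreeValidationError",
    "PhyloNode",
    "PhyloTree",
    "parse_newick",
    "subtree_leaf_count",
    "SpeciesReport",
    "validate_species",
]


class NewickError(ValueError):
    """Malformed Newick input."""


class TreeValidationError(ValueError):
    """Structurally valid Newick that violates the tree contract."""


class PhyloNode:
    """A tree node carrying an (initially empty) presence/absence state set.

    ``state_set`` holds a subset of {0, 1} (1 = sequence present) filled in
    by the parsimony pass; ``final_state`` is the single resolved state
    after root disambiguation.
    """

    __slots__ = ("label", "children", "branch_length", "parent",
                 "state_set", "final_state")

    def __init__(
        self,
        label: Optional[str] = None,
        children: Optional[list["PhyloNode"]] = None,
        branch_length: Optional[float] = None,
    ):
        self.label = label
        self.children: list[PhyloNode] = list(children or [])
        self.branch_length = branch_length
        self.parent: Optional[PhyloNode] = None
        self.state_set: Optional[frozenset[int]] = None
        self.final_state: Optional[int] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["PhyloNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["PhyloNode"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self) -> Iterator["PhyloNode"]:
        return (n for n in self.postorder() if n.is_leaf)

    @property
    def leaf_count(self) -> int:
        return sum(1 for _ in self.leaves())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal[{len(self.children)}]"
        return f"<PhyloNode {self.label!r} {kind}>"


def subtree_leaf_count(node: PhyloNode) -> int:
    """Number of leaves under ``node`` (a leaf counts as one)."""
    return node.leaf_count


class PhyloTree:
    """A validated rooted binary tree with at least three leaves."""

    def __init__(self, root: PhyloNode):
        self.root = root
        self._validate()
        self._name_internals()
        for node in root.preorder():
            for child in node.children:
                child.parent = node
        self.leaf_order: list[str] = [n.label for n in root.preorder() if n.is_leaf]

    def _validate(self) -> None:
        labels = []
        for node in self.root.postorder():
            if node.is_leaf:
                if not node.label:
                    raise TreeValidationError("leaf without a label")
                labels.append(node.label)
            elif len(node.children) != 2:
                raise TreeValidationError(
                    f"internal node {node.label or '(unnamed)'} has "
                    f"{len(node.children)} children; the tree must be strictly binary"
                )
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeValidationError(f"duplicate leaf labels: {', '.join(dupes)}")
        if len(labels) < 3:
            raise TreeValidationError(
                f"tree has {len(labels)} leaves; need query, target and at "
                "least one outgroup (>= 3)"
            )

    def _name_internals(self) -> None:
        taken = {n.label for n in self.root.preorder() if n.label}
        k = 0
        for node in self.root.preorder():
            if not node.is_leaf and not node.label:
                while f"node_{k}" in taken:
                    k += 1
                node.label = f"node_{k}"
                taken.add(node.label)
                k += 1

    def find(self, label: str) -> Optional[PhyloNode]:
        for node in self.root.preorder():
            if node.label == label:
                return node
        return None

    def render(self, lengths: bool = True) -> str:
        """Newick string; generated internal names are not written back."""

        def fmt(node: PhyloNode) -> str:
            if node.is_leaf:
                s = node.label
            else:
                inner = ",".join(fmt(c) for c in node.children)
                lab = node.label if node.label and not node.label.startswith("node_") else ""
                s = f"({inner}){lab}"
            if lengths and node.branch_length is not None:
                s += f":{node.branch_length:g}"
            return s

        return fmt(self.root) + ";"


_DELIMS = set(",():;")


def parse_newick(text: str) -> PhyloTree:
    """Parse a rooted binary Newick tree.

    Labels and optional ``:length`` annotations are captured; a missing
    terminal ``;`` is tolerated with a warning.  Unbalanced parentheses,
    multifurcations, duplicate leaf labels and trees with fewer than three
    leaves are errors.
    """
    s = text.strip()
    if not s:
        raise NewickError("empty Newick string")
    if s.endswith(";"):
        s = s[:-1].strip()
    else:
        log.warning("Newick string does not end with ';'")
    pos = 0

    def peek() -> str:
        return s[pos] if pos < len(s) else ""

    def read_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in _DELIMS:
            pos += 1
        return s[start:pos].strip()

    def read_length() -> Optional[float]:
        nonlocal pos
        if peek() != ":":
            return None
        pos += 1
        tok = read_label()
        try:
            return float(tok)
        except ValueError:
            raise NewickError(f"bad branch length {tok!r} at position {pos}") from None

    def parse_node() -> PhyloNode:
        nonlocal pos
        if peek() == "(":
            pos += 1
            children = [parse_node()]
            while peek() == ",":
                pos += 1
                children.append(parse_node())
            if peek() != ")":
                raise NewickError(f"unbalanced parentheses at position {pos}")
            pos += 1
            label = read_label() or None
            node = PhyloNode(label=label, children=children)
        else:
            label = read_label()
            if not label:
                raise NewickError(f"expected a leaf label at position {pos}")
            node = PhyloNode(label=label)
        node.branch_length = read_length()
        return node

    root = parse_node()
    if pos != len(s):
        raise NewickError(f"unexpected trailing characters at position {pos}: {s[pos:]!r}")
    return PhyloTree(root)


@dataclass
class SpeciesReport:
    """Result of checking tree leaves against the supplied chain files."""

    ok: bool
    problems: list[str]
    missing_chains: list[str]
    extra_chains: list[str]


def validate_species(
    tree: PhyloTree, query: str, target: str, chain_species: set[str]
) -> SpeciesReport:
    """Check that query/target are leaves and every non-query leaf has a chain.

    Returns a structured report; callers abort when ``ok`` is False.
    """
    leaves = set(tree.leaf_order)
    problems: list[str] = []
    if query not in leaves:
        problems.append(f"query species {query!r} is not a leaf of the tree")
    if target not in leaves:
        problems.append(f"target species {target!r} is not a leaf of the tree")
    if query == target:
        problems.append("query and target species must differ")
    if query in chain_species:
        problems.append(
            f"a chain file was supplied for the query species {query!r}; chains "
            "must map the query genome onto every other species"
        )
    missing = sorted(leaves - {query} - chain_species)
    extra = sorted(chain_species - (leaves - {query}))
    if missing:
        problems.append("no chain file for tree species: " + ", ".join(missing))
    if extra:
        problems.append("chain species not in the tree: " + ", ".join(extra))
    return SpeciesReport(not problems, problems, missing, extra)
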