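"""Maximum-parsimony inference of ancestral presence/absence states.

A post-order Fitch pass assigns each internal node the most frequent state
among its two children's state sets (one vote per symbol per child), or the
union of observed symbols on a tie.  On a binary presence/absence alphabet
this reproduces classical Fitch set operations: the intersection of the
children's sets when it is non-empty, their union otherwise.

The root of the tree stands for the most-recent common ancestor of the
query and target species.  When its Fitch state set is ambiguous ({0, 1})
the state is resolved by a fixed decision tree:

1. take the root child subtending more leaves (ties: the first child); if
   its state set is a singleton, adopt that state;
2. otherwise, if the opposite child is not a leaf and its state set is a
   singleton, adopt that state;
3. otherwise fall back to the ``priority`` parameter: ``gain`` resolves to
   absent (treating insertions as evolutionarily cheaper), ``loss`` to
   present — unless pruning is disabled, in which case the call is
   ``ambiguous``.

Step 1, for a tree whose outermost outgroup is a single terminal leaf, is
equivalent to pruning that outgroup at the branch above the root and
rerooting.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Union

from .phylogeny import PhyloTree

__all__ = [
    "ABSENT",
    "PRESENT",
    "AMBIGUOUS",
    "RootCall",
    "BranchEvent",
    "fitch_postorder",
    "resolve_root",
    "assign_final_states",
    "branch_events",
    "count_changes",
]

ABSENT = 0
PRESENT = 1
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class RootCall:
    """Resolved root state and which rule produced it.

    ``state`` is 0, 1 or ``"ambiguous"``; ``resolved_by`` is one of
    ``fitch``, ``larger_subtree``, ``opposite_subtree``, ``priority`` or
    ``none`` (the last only together with an ambiguous state).
    """

    state: Union[int, str]
    resolved_by: str


@dataclass(frozen=True)
class BranchEvent:
    """A state change on the edge ``parent_label -> child_label``."""

    parent_label: str
    child_label: str
    event: str  # "gain" (0 -> 1) or "loss" (1 -> 0)


def fitch_postorder(tree: PhyloTree, leaf_states: Mapping[str, int]) -> PhyloTree:
    """Run the post-order Fitch pass, filling ``state_set`` on every node.

    ``leaf_states`` maps every leaf label to 0 (absent) or 1 (present);
    the query leaf is always 1 by construction (its feature exists).
    """
    for node in tree.root.postorder():
        if node.is_leaf:
            if node.label not in leaf_states:
                raise ValueError(f"no observed state for leaf {node.label!r}")
            state = leaf_states[node.label]
            if state not in (ABSENT, PRESENT):
                raise ValueError(
                    f"leaf {node.label!r}: state must be 0 or 1, got {state!r}"
                )
            node.state_set = frozenset((state,))
        else:
            votes: Counter[int] = Counter()
            for child in node.children:
                for sym in child.state_set:
                    votes[sym] += 1
            top = max(votes.values())
            winners = [sym for sym, c in votes.items() if c == top]
            node.state_set = frozenset(winners if len(winners) == 1 else votes)
        node.final_state = None
    return tree


def resolve_root(
    tree: PhyloTree, priority: str = "gain", no_prune: bool = False
) -> RootCall:
    """Resolve the root state after :func:`fitch_postorder`."""
    if priority not in ("gain", "loss"):
        raise ValueError(f"priority must be 'gain' or 'loss', got {priority!r}")
    root = tree.root
    if root.state_set is None:
        raise ValueError("resolve_root called before fitch_postorder")
    if len(root.state_set) == 1:
        return RootCall(next(iter(root.state_set)), "fitch")
    a, b = root.children
    if b.leaf_count > a.leaf_count:
        a, b = b, a
    if len(a.state_set) == 1:
        return RootCall(next(iter(a.state_set)), "larger_subtree")
    if not b.is_leaf and len(b.state_set) == 1:
        return RootCall(next(iter(b.state_set)), "opposite_subtree")
    if no_prune:
        return RootCall(AMBIGUOUS, "none")
    return RootCall(ABSENT if priority == "gain" else PRESENT, "priority")


def assign_final_states(tree: PhyloTree, root_call: RootCall) -> PhyloTree:
    """Pre-order final pass: collapse every state set to a single state.

    The root takes the resolved state; every other node keeps its own state
    when its set is a singleton and inherits its parent's final state
    otherwise (the standard Fitch final-pass convention, which preserves
    the minimum change count).
    """
    if root_call.state == AMBIGUOUS:
        raise ValueError("cannot assign final states from an ambiguous root")
    for node in tree.root.preorder():
        if node.parent is None:
            node.final_state = root_call.state
        elif len(node.state_set) == 1:
            node.final_state = next(iter(node.state_set))
        else:
            node.final_state = node.parent.final_state
    return tree


def branch_events(tree: PhyloTree) -> list[BranchEvent]:
    """All edges whose finalized endpoint states differ, in pre-order."""
    events: list[BranchEvent] = []
    for node in tree.root.preorder():
        if node.final_state is None:
            raise ValueError("branch_events called before assign_final_states")
        for child in node.children:
            if child.final_state != node.final_state:
                kind = "gain" if node.final_state == ABSENT else "loss"
                events.append(BranchEvent(node.label, child.label, kind))
    return events


def count_changes(tree: PhyloTree) -> int:
    """Number of edges whose finalized endpoint states differ."""
    return sum(
        1
        for node in tree.root.preorder()
        for child in node.children
        if child.final_state != node.final_state
    )
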