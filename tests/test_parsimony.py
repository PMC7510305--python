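"""Fitch post-order pass, root disambiguation, final states and events."""

import itertools

import numpy as np
import pytest

from phylomap.parsimony import (
    AMBIGUOUS,
    BranchEvent,
    RootCall,
    assign_final_states,
    branch_events,
    count_changes,
    fitch_postorder,
    resolve_root,
)
from phylomap.phylogeny import PhyloNode, PhyloTree, parse_newick

from _oracles import brute_min_changes, brute_root_costs, enumerate_topologies
from conftest import LADDER5

GAIN_PATTERN = {"Q": 1, "T": 0, "O1": 0, "O2": 1, "O3": 0}


def test_constant_leaves_give_constant_internal_states(ladder5):
    fitch_postorder(ladder5, {l: 1 for l in ladder5.leaf_order})
    for node in ladder5.root.postorder():
        assert node.state_set == frozenset({1})
    call = resolve_root(ladder5)
    assert call == RootCall(1, "fitch")
    assign_final_states(ladder5, call)
    assert branch_events(ladder5) == []


def test_independent_gains_pattern_roots_absent(ladder5):
    """Two independent gains (cost 2) beat three independent losses (cost 3)."""
    fitch_postorder(ladder5, GAIN_PATTERN)
    assert ladder5.root.state_set == frozenset({0})
    costs = brute_root_costs(ladder5, GAIN_PATTERN)
    assert costs == {0: 2, 1: 3}
    call = resolve_root(ladder5)
    assert call.state == 0 and call.resolved_by == "fitch"
    assign_final_states(ladder5, call)
    events = branch_events(ladder5)
    assert sorted(ev.event for ev in events) == ["gain", "gain"]
    assert {ev.child_label for ev in events} == {"Q", "O2"}


def test_three_leaf_tie_stores_union_then_majority_wins():
    tree = parse_newick("((Q,T),O1);")
    fitch_postorder(tree, {"Q": 1, "T": 0, "O1": 1})
    qt = tree.find("Q").parent
    assert qt.state_set == frozenset({0, 1})
    assert tree.root.state_set == frozenset({1})  # votes 1:2 vs 0:1


def test_vote_rule_reproduces_classical_fitch_set_operations():
    """On binary trees, the majority-vote rule equals intersection-if-
    nonempty-else-union at every internal node."""
    labels = ("a", "b", "c", "d", "e")
    for tree in itertools.islice(enumerate_topologies(labels), 20):
        for bits in range(2 ** len(labels)):
            states = {l: bits >> i & 1 for i, l in enumerate(labels)}
            fitch_postorder(tree, states)
            for node in tree.root.postorder():
                if node.is_leaf:
                    continue
                x, y = (c.state_set for c in node.children)
                expected = (x & y) or (x | y)
                assert node.state_set == frozenset(expected)


def test_unlabeled_leaf_raises_naming_the_leaf(ladder5):
    with pytest.raises(ValueError, match="O3"):
        fitch_postorder(ladder5, {"Q": 1, "T": 0, "O1": 0, "O2": 1})


def test_larger_subtree_resolution_equals_pruning_outermost_outgroup():
    """Ambiguous root on a ladder resolves from the big subtree's base —
    the same state Fitch gives after pruning the terminal outgroup."""
    tree = parse_newick("(((Q,T),O1),O2);")
    states = {"Q": 1, "T": 1, "O1": 1, "O2": 0}
    fitch_postorder(tree, states)
    assert tree.root.state_set == frozenset({0, 1})
    call = resolve_root(tree)
    assert call == RootCall(1, "larger_subtree")

    pruned = parse_newick("((Q,T),O1);")
    fitch_postorder(pruned, states)
    assert pruned.root.state_set == frozenset({1})
    assert resolve_root(pruned).state == call.state


def test_opposite_subtree_rule_applies_when_larger_base_ambiguous():
    # Constructed state sets (not reachable from a plain Fitch pass on a
    # binary tree): larger child ambiguous, opposite child internal and
    # unambiguous -> its state is adopted.
    tree = parse_newick("(((a,b),c),(d,e));")
    big, small = tree.root.children
    for node in tree.root.postorder():
        node.state_set = frozenset({0, 1})
    big.state_set = frozenset({0, 1})
    small.state_set = frozenset({1})
    tree.root.state_set = frozenset({0, 1})
    call = resolve_root(tree)
    assert call == RootCall(1, "opposite_subtree")


def test_opposite_leaf_does_not_resolve_falls_to_priority():
    # Constructed state sets: the larger subtree's base is ambiguous and the
    # only unambiguous descendant of the root is a leaf, which must NOT be
    # used for disambiguation — the priority parameter decides instead.
    tree = parse_newick("(((Q,T),O1),O2);")
    for node in tree.root.postorder():
        node.state_set = frozenset({0, 1})
    leaf = tree.root.children[1]
    assert leaf.is_leaf
    leaf.state_set = frozenset({1})
    assert resolve_root(tree, priority="gain") == RootCall(0, "priority")
    assert resolve_root(tree, priority="loss") == RootCall(1, "priority")
    assert resolve_root(tree, no_prune=True) == RootCall(AMBIGUOUS, "none")


def test_priority_default_and_no_prune_on_balanced_tree():
    tree = parse_newick("((Q,T),(O1,O2));")
    fitch_postorder(tree, {"Q": 1, "T": 0, "O1": 1, "O2": 0})
    assert tree.root.state_set == frozenset({0, 1})
    assert resolve_root(tree) == RootCall(0, "priority")
    assert resolve_root(tree, priority="loss") == RootCall(1, "priority")
    assert resolve_root(tree, no_prune=True).state == AMBIGUOUS


def test_assign_final_states_rejects_ambiguous_root(ladder5):
    fitch_postorder(ladder5, GAIN_PATTERN)
    with pytest.raises(ValueError, match="ambiguous"):
        assign_final_states(ladder5, RootCall(AMBIGUOUS, "none"))


def test_ambiguous_node_inherits_parent_final_state():
    tree = parse_newick("((Q,T),O1);")
    fitch_postorder(tree, {"Q": 1, "T": 0, "O1": 1})
    call = resolve_root(tree)
    assign_final_states(tree, call)
    qt = tree.find("Q").parent
    assert qt.final_state == tree.root.final_state == 1
    events = branch_events(tree)
    assert events == [BranchEvent(qt.label, "T", "loss")]


def test_single_query_gain_on_terminal_branch(ladder5):
    states = {l: 0 for l in ladder5.leaf_order}
    states["Q"] = 1
    fitch_postorder(ladder5, states)
    call = resolve_root(ladder5)
    assert call.state == 0
    assign_final_states(ladder5, call)
    events = branch_events(ladder5)
    assert len(events) == 1
    assert events[0].child_label == "Q" and events[0].event == "gain"


def test_final_labeling_achieves_bruteforce_minimum_small_trees():
    """For every 3-5 leaf topology and leaf pattern with an unambiguous
    Fitch root, the implied change count equals the enumerated minimum."""
    for n in (3, 4, 5):
        labels = tuple(f"s{i}" for i in range(n))
        for tree in enumerate_topologies(labels):
            for bits in range(2 ** n):
                states = {l: bits >> i & 1 for i, l in enumerate(labels)}
                fitch_postorder(tree, states)
                call = resolve_root(tree)
                if call.resolved_by != "fitch":
                    continue
                assign_final_states(tree, call)
                assert count_changes(tree) == brute_min_changes(tree, states)


def test_symmetry_relabeling_states_swaps_gain_and_loss():
    rng = np.random.default_rng(7)
    labels = tuple(f"s{i}" for i in range(5))
    trees = list(enumerate_topologies(labels))
    for _ in range(30):
        tree = trees[int(rng.integers(len(trees)))]
        states = {l: int(rng.integers(2)) for l in labels}
        flipped = {l: 1 - s for l, s in states.items()}

        fitch_postorder(tree, states)
        call = resolve_root(tree, priority="gain")
        if call.state == AMBIGUOUS:
            continue
        assign_final_states(tree, call)
        ev = [(e.parent_label, e.child_label, e.event) for e in branch_events(tree)]

        fitch_postorder(tree, flipped)
        call2 = resolve_root(tree, priority="loss")
        assert call2.state == 1 - call.state
        assign_final_states(tree, call2)
        swapped = [
            (p, c, "gain" if e == "loss" else "loss")
            for p, c, e in [(e.parent_label, e.child_label, e.event)
                            for e in branch_events(tree)]
        ]
        assert swapped == ev


def test_determinism_identical_inputs_identical_outputs(ladder5):
    runs = []
    for _ in range(2):
        fitch_postorder(ladder5, GAIN_PATTERN)
        call = resolve_root(ladder5)
        assign_final_states(ladder5, call)
        runs.append((call, tuple(branch_events(ladder5))))
    assert runs[0] == runs[1]
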