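"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: parsimony scores come
from exhaustive enumeration of internal labelings, mapping statistics from
per-base enumeration of aligned positions, and tree shapes from direct
recursive construction.
"""

from __future__ import annotations

from itertools import product
from typing import Iterator

import numpy as np

from phylomap.chain_io import ChainAlignment, ChainBlock, ChainHeader
from phylomap.phylogeny import PhyloNode, PhyloTree


def enumerate_topologies(labels: tuple[str, ...]) -> Iterator[PhyloTree]:
    """Every rooted binary tree over the given (labeled) leaves.

    The first label is pinned to the left part of each split so each
    unordered bipartition is generated once; the count is (2n-3)!!.
    """

    def build(leaves: tuple[str, ...]) -> Iterator[PhyloNode]:
        if len(leaves) == 1:
            yield PhyloNode(label=leaves[0])
            return
        head, rest = leaves[0], leaves[1:]
        for mask in range(2 ** len(rest)):
            left = (head,) + tuple(r for i, r in enumerate(rest) if mask >> i & 1)
            right = tuple(r for i, r in enumerate(rest) if not mask >> i & 1)
            if not right:
                continue
            for ln in build(left):
                for rn in build(right):
                    yield PhyloNode(children=[ln, rn])

    for root in build(labels):
        yield PhyloTree(root)


def brute_min_changes(tree: PhyloTree, leaf_states: dict[str, int]) -> int:
    """Minimum number of state changes over all internal labelings."""
    nodes = list(tree.root.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    edges = [(parent, child) for parent in nodes for child in parent.children]
    best = None
    for assignment in product((0, 1), repeat=len(internals)):
        state = {id(n): s for n, s in zip(internals, assignment)}
        for n in nodes:
            if n.is_leaf:
                state[id(n)] = leaf_states[n.label]
        cost = sum(1 for p, c in edges if state[id(p)] != state[id(c)])
        if best is None or cost < best:
            best = cost
    return best


def brute_root_costs(tree: PhyloTree, leaf_states: dict[str, int]) -> dict[int, int]:
    """Minimum change count conditional on each root state."""
    nodes = list(tree.root.postorder())
    internals = [n for n in nodes if not n.is_leaf and n.parent is not None]
    edges = [(parent, child) for parent in nodes for child in parent.children]
    out = {}
    for root_state in (0, 1):
        best = None
        for assignment in product((0, 1), repeat=len(internals)):
            state = {id(n): s for n, s in zip(internals, assignment)}
            state[id(tree.root)] = root_state
            for n in nodes:
                if n.is_leaf:
                    state[id(n)] = leaf_states[n.label]
            cost = sum(1 for p, c in edges if state[id(p)] != state[id(c)])
            if best is None or cost < best:
                best = cost
        out[root_state] = best
    return out


def perbase_overlap_and_gap(
    aln: ChainAlignment, start: int, end: int
) -> tuple[int, int]:
    """Aligned-base count and longest internal unaligned run, by enumeration."""
    aligned = set()
    for rs, re, _, _ in aln.block_spans():
        for p in range(max(rs, start), min(re, end)):
            aligned.add(p)
    if not aligned:
        return 0, 0
    lo, hi = min(aligned), max(aligned)
    max_run = run = 0
    for p in range(lo, hi + 1):
        if p in aligned:
            run = 0
        else:
            run += 1
            max_run = max(max_run, run)
    return len(aligned), max_run


def random_chain(
    rng: np.random.Generator,
    chain_id: int = 1,
    ref_name: str = "chr1",
    max_blocks: int = 5,
) -> ChainAlignment:
    """A structurally valid random chain with <= max_blocks blocks."""
    n_blocks = int(rng.integers(1, max_blocks + 1))
    blocks = []
    for i in range(n_blocks):
        size = int(rng.integers(1, 30))
        if i == n_blocks - 1:
            blocks.append(ChainBlock(size))
        else:
            blocks.append(ChainBlock(size, int(rng.integers(0, 25)),
                                     int(rng.integers(0, 25))))
    ref_span = sum(b.size + b.gap_ref for b in blocks)
    dest_span = sum(b.size + b.gap_dest for b in blocks)
    ref_start = int(rng.integers(0, 50))
    dest_start = int(rng.integers(0, 50))
    strand = "+" if rng.random() < 0.5 else "-"
    header = ChainHeader(
        score=int(rng.integers(0, 10_000)),
        ref_name=ref_name,
        ref_size=ref_start + ref_span + int(rng.integers(0, 50)),
        ref_strand="+",
        ref_start=ref_start,
        ref_end=ref_start + ref_span,
        dest_name="chrD",
        dest_size=dest_start + dest_span + int(rng.integers(0, 50)),
        dest_strand=strand,
        dest_start=dest_start,
        dest_end=dest_start + dest_span,
        chain_id=chain_id,
    )
    return ChainAlignment(header, tuple(blocks))
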