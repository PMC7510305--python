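import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

from phylomap.chain_io import ChainAlignment, ChainBlock, ChainHeader, build_index
from phylomap.phylogeny import parse_newick

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

LADDER5 = "((((Q:1,T:1):1,O1:1):1,O2:1):1,O3:1);"


@pytest.fixture
def ladder5():
    """Five-leaf ladder: query + target + three progressively deeper outgroups."""
    return parse_newick(LADDER5)


def make_chain(
    blocks,
    chain_id=1,
    score=1000,
    ref_name="chr1",
    ref_start=0,
    dest_name="chrD",
    dest_start=0,
    dest_strand="+",
    ref_size=None,
    dest_size=None,
):
    """Build a valid ChainAlignment from (size, gap_ref, gap_dest) triples.

    The final block's gaps are dropped automatically; header spans are
    derived from the block arithmetic.
    """
    blist = []
    for i, spec in enumerate(blocks):
        size, gr, gd = (spec if isinstance(spec, tuple) else (spec, 0, 0))
        if i == len(blocks) - 1:
            blist.append(ChainBlock(size))
        else:
            blist.append(ChainBlock(size, gr, gd))
    ref_span = sum(b.size + b.gap_ref for b in blist)
    dest_span = sum(b.size + b.gap_dest for b in blist)
    header = ChainHeader(
        score=score,
        ref_name=ref_name,
        ref_size=ref_size if ref_size is not None else ref_start + ref_span,
        ref_strand="+",
        ref_start=ref_start,
        ref_end=ref_start + ref_span,
        dest_name=dest_name,
        dest_size=dest_size if dest_size is not None else dest_start + dest_span,
        dest_strand=dest_strand,
        dest_start=dest_start,
        dest_end=dest_start + dest_span,
        chain_id=chain_id,
    )
    return ChainAlignment(header, tuple(blist))


def index_of(*chains, species="sp"):
    return build_index(chains, species)


@pytest.fixture
def identity_index():
    """Whole-chromosome identity chain: 100 bp, one block, chr1 -> chrD."""
    return index_of(make_chain([100]))


@pytest.fixture
def gapped_index():
    """One chain with a 10 bp reference gap at [50, 60)."""
    return index_of(make_chain([(50, 10, 0), 40]))
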