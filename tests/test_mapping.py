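"""Feature-to-species mapping: overlap fraction, gap tolerance, chain choice."""

import logging

import numpy as np
import pytest
from hypothesis import given, strategies as st

from phylomap.mapping import (
    BedError,
    BedReader,
    GenomicFeature,
    MappingParams,
    choose_chain,
    evaluate_candidates,
    map_feature,
)
from phylomap.chain_io import build_index

from _oracles import perbase_overlap_and_gap, random_chain
from conftest import index_of, make_chain


def feat(start, end, chrom="chr1", name="f"):
    return GenomicFeature(chrom, start, end, name)


def test_identity_chain_full_overlap(identity_index):
    res = map_feature(feat(10, 20), identity_index)
    assert res.present
    assert res.overlap_fraction == 1.0
    assert res.max_gap == 0
    assert res.dest_intervals == (("chrD", 10, 20),)


def test_gap_spanning_feature_under_default_and_strict_params(gapped_index):
    f = feat(45, 65)  # 5 bp in block 1, 10 bp in the gap, 5 bp in block 2
    res = map_feature(f, gapped_index)
    assert res.present  # single-base rule
    assert res.overlap_fraction == pytest.approx(0.5)
    assert res.max_gap == 10

    assert not map_feature(f, gapped_index, MappingParams(threshold=0.6)).present
    assert map_feature(f, gapped_index, MappingParams(threshold=0.5)).present
    assert not map_feature(f, gapped_index, MappingParams(gap=5)).present
    assert map_feature(f, gapped_index, MappingParams(gap=10)).present


def test_feature_inside_interblock_gap_never_maps(gapped_index):
    f = feat(51, 59)
    for params in (MappingParams(), MappingParams(threshold=1.0),
                   MappingParams(gap=0), MappingParams(drop_split=True)):
        assert not map_feature(f, gapped_index, params).present


def test_absent_chromosome_is_absence_not_error(identity_index):
    res = map_feature(feat(0, 10, chrom="chr9"), identity_index)
    assert not res.present
    assert res.max_gap is None and res.chain_id is None


def test_leading_and_trailing_gap_bases_do_not_count_as_internal_gap():
    # Feature starts inside the gap: only bases after the first overlapped
    # block boundary count toward max_gap.
    idx = index_of(make_chain([(50, 10, 0), 40]))
    res = map_feature(feat(55, 75), idx)
    assert res.max_gap == 0
    assert res.overlap_fraction == pytest.approx(15 / 20)


def test_minus_strand_destination_emitted_as_forward_coordinates():
    # Block dest-local [0,30) on a '-' chain of dest_size 100 -> forward [70,100).
    idx = index_of(make_chain([30], dest_strand="-", dest_size=100))
    res = map_feature(feat(0, 30), idx)
    assert res.present
    assert res.dest_intervals == (("chrD", 70, 100),)


def test_choose_chain_keeps_longest_alignment():
    idx = index_of(
        make_chain([15], ref_start=0, chain_id=1, ref_size=200),
        make_chain([5], ref_start=20, chain_id=2, ref_size=200),
    )
    f = feat(0, 30)
    cands = evaluate_candidates(f, idx)
    assert {c.chain_id: c.overlap for c in cands} == {1: 15, 2: 5}
    chosen = choose_chain(cands)
    assert chosen.chain_id == 1
    res = map_feature(f, idx)
    assert res.present and res.chain_id == 1


def test_drop_split_discards_multichain_features():
    idx = index_of(
        make_chain([15], ref_start=0, chain_id=1, ref_size=200),
        make_chain([5], ref_start=20, chain_id=2, ref_size=200),
    )
    res = map_feature(feat(0, 30), idx, MappingParams(drop_split=True))
    assert not res.present
    assert res.chain_id is None


def test_equal_overlap_ties_break_by_score_then_id():
    a = make_chain([10], chain_id=5, score=100, ref_size=50)
    b = make_chain([10], chain_id=2, score=900, ref_size=50)
    chosen = choose_chain(evaluate_candidates(feat(0, 10), index_of(a, b)))
    assert chosen.chain_id == 2
    c = make_chain([10], chain_id=7, score=900, ref_size=50)
    chosen = choose_chain(evaluate_candidates(feat(0, 10), index_of(b, c)))
    assert chosen.chain_id == 2


@given(st.integers(0, 2**32 - 1))
def test_overlap_and_gap_match_perbase_enumeration(seed):
    rng = np.random.default_rng(seed)
    aln = random_chain(rng)
    idx = build_index([aln], "sp")
    h = aln.header
    start = int(rng.integers(max(0, h.ref_start - 10), h.ref_end + 5))
    end = start + int(rng.integers(1, 60))
    f = feat(start, end)
    res = map_feature(f, idx)
    overlap, max_gap = perbase_overlap_and_gap(aln, start, end)
    assert res.overlap_fraction == pytest.approx(overlap / f.length)
    if overlap:
        assert res.max_gap == max_gap
    else:
        assert not res.present


@given(st.integers(0, 2**32 - 1))
def test_threshold_and_gap_monotonicity(seed):
    rng = np.random.default_rng(seed)
    aln = random_chain(rng)
    idx = build_index([aln], "sp")
    h = aln.header
    start = int(rng.integers(max(0, h.ref_start - 10), h.ref_end))
    f = feat(start, start + int(rng.integers(1, 60)))
    thresholds = [0.0, 0.25, 0.5, 0.75, 1.0]
    present_t = [map_feature(f, idx, MappingParams(threshold=t)).present
                 for t in thresholds]
    for lo, hi in zip(present_t, present_t[1:]):
        assert lo or not hi  # present(t2) implies present(t1<=t2)
    gaps = [0, 1, 5, 20, -1]  # increasingly permissive; -1 = unlimited
    present_g = [map_feature(f, idx, MappingParams(gap=g)).present for g in gaps]
    for lo, hi in zip(present_g, present_g[1:]):
        assert hi or not lo  # present(g1) implies present(g2>=g1)


def test_identity_chain_oracle_any_feature_maps_to_itself(identity_index):
    rng = np.random.default_rng(0)
    for _ in range(50):
        s = int(rng.integers(0, 99))
        e = s + int(rng.integers(1, 100 - s + 1))
        res = map_feature(feat(s, e), identity_index)
        assert res.present and res.overlap_fraction == 1.0
        assert res.dest_intervals == (("chrD", s, e),)


def test_zero_length_feature_is_an_input_error():
    with pytest.raises(BedError):
        GenomicFeature("chr1", 10, 10, "f")


def test_bed_reader_autonames_and_skips_bad_lines(caplog):
    lines = [
        "# comment",
        "chr1\t0\t10\tsiteA\t.\t+",
        "chr1\t20\t30",
        "chr1\tnotanumber\t40\tbad",
        "chr1\t50\t40\tinverted",
        "chr2\t5\t9\tsiteB",
    ]
    with caplog.at_level(logging.WARNING):
        reader = BedReader(lines)
        feats = list(reader)
    assert [f.name for f in feats] == ["siteA", "feat_2", "siteB"]
    assert feats[0].extra == (".", "+")
    assert reader.skipped == 2


def test_bed_reader_strict_raises():
    with pytest.raises(BedError):
        list(BedReader(["chr1\tx\t10\tbad"], strict=True))
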