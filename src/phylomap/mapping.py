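"""Projection of single BED features through one species' chains.

For a feature and a species this module decides whether an orthologous
sequence exists in that species, applying the overlap-fraction threshold
(``-t``), the gap tolerance (``-g``) and the split-chain retention rule
(``-d``).

Semantics, fixed as this package's contract:

* Overlap and gap statistics are computed per single chain, never pooled
  across chains — pooling would silently merge paralogous placements.
* ``threshold = 0.0`` means "at least one aligned base", not "zero".
* ``max_gap`` counts reference-side (query-genome) unaligned bases falling
  inside the feature's span, between the first and last overlapped block of
  the evaluated chain.  Destination-side insertions do not count.
* Among chains overlapping the feature, the one with the largest aligned
  overlap is evaluated; ties go to the higher chain score, then the lower
  chain id.  With ``drop_split`` any feature overlapped by more than one
  chain is treated as unmapped (the historical bnMapper behaviour).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Optional, Sequence, Union

from .chain_io import BlockHit, ChainIndex

log = logging.getLogger(__name__)

__all__ = [
    "GenomicFeature",
    "MappingParams",
    "ChainCandidate",
    "MappingResult",
    "BedError",
    "BedReader",
    "read_bed",
    "evaluate_candidates",
    "choose_chain",
    "map_feature",
]


class BedError(ValueError):
    """A malformed BED line under strict parsing."""


@dataclass(frozen=True)
class GenomicFeature:
    """One query BED record (0-based half-open); the unit of classification."""

    chrom: str
    start: int
    end: int
    name: str
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise BedError(
                f"feature {self.name!r}: invalid span [{self.start},{self.end})"
            )
        if not self.name:
            raise BedError("feature name must be non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MappingParams:
    """Tunables of the mapping step.

    threshold
        Required fraction of feature bases aligned under the chosen chain,
        in [0, 1].  0.0 requires a single aligned base.
    gap
        Maximum tolerated reference-side gap inside the feature, in bp;
        -1 allows gaps of any length.
    drop_split
        Treat features overlapped by more than one chain as unmapped
        instead of keeping the chain with the longest alignment.
    """

    threshold: float = 0.0
    gap: int = -1
    drop_split: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError(f"threshold must be in [0,1], got {self.threshold}")
        if self.gap < -1:
            raise ValueError(f"gap must be >= -1, got {self.gap}")


@dataclass(frozen=True)
class ChainCandidate:
    """Per-chain evaluation of one feature."""

    chain_id: int
    score: int
    overlap: int
    max_gap: int
    dest_intervals: tuple[tuple[str, int, int], ...]


@dataclass(frozen=True)
class MappingResult:
    """Outcome of projecting one feature into one species.

    ``overlap_fraction`` and ``dest_intervals`` refer to the chosen chain;
    ``max_gap`` is None when no chain overlapped the feature at all.
    Destination intervals are forward-strand coordinates.
    """

    present: bool
    overlap_fraction: float
    max_gap: Optional[int]
    chain_id: Optional[int]
    dest_intervals: tuple[tuple[str, int, int], ...] = ()


def _merge_touching(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    intervals.sort()
    out: list[list[int]] = []
    for s, e in intervals:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def evaluate_candidates(
    feature: GenomicFeature, index: ChainIndex
) -> list[ChainCandidate]:
    """Evaluate every chain with at least one block overlapping the feature."""
    hits = index.query(feature.chrom, feature.start, feature.end)
    by_chain: dict[int, list[BlockHit]] = {}
    for h in hits:
        by_chain.setdefault(h.chain_id, []).append(h)

    out: list[ChainCandidate] = []
    for cid in sorted(by_chain):
        chain_hits = sorted(by_chain[cid], key=lambda h: h.block_index)
        header = index.chains[cid].header
        overlap = 0
        pieces: list[tuple[int, int]] = []
        for h in chain_hits:
            a = max(h.ref_start, feature.start)
            b = min(h.ref_end, feature.end)
            overlap += b - a
            ls = h.dest_start + (a - h.ref_start)
            le = h.dest_start + (b - h.ref_start)
            if header.dest_strand == "-":
                pieces.append((header.dest_size - le, header.dest_size - ls))
            else:
                pieces.append((ls, le))
        max_gap = 0
        for prev, nxt in zip(chain_hits, chain_hits[1:]):
            ga = max(prev.ref_end, feature.start)
            gb = min(nxt.ref_start, feature.end)
            if gb - ga > max_gap:
                max_gap = gb - ga
        dest = tuple(
            (header.dest_name, s, e) for s, e in _merge_touching(pieces)
        )
        out.append(ChainCandidate(cid, header.score, overlap, max_gap, dest))
    return out


def choose_chain(
    candidates: Sequence[ChainCandidate], drop_split: bool = False
) -> Optional[ChainCandidate]:
    """Pick the chain to evaluate the feature under.

    Default: the candidate with the largest aligned overlap (ties: higher
    score, then lower chain id).  With ``drop_split``, a feature split
    across more than one chain is treated as unmapped.
    """
    if not candidates:
        return None
    if drop_split and len(candidates) > 1:
        return None
    return max(candidates, key=lambda c: (c.overlap, c.score, -c.chain_id))


def map_feature(
    feature: GenomicFeature, index: ChainIndex, params: MappingParams = MappingParams()
) -> MappingResult:
    """Decide whether an orthologous sequence for ``feature`` exists in the
    species covered by ``index``.

    A chromosome absent from the index simply means absence (not an error):
    lack of alignment is the observation the downstream inference consumes.
    """
    chosen = choose_chain(evaluate_candidates(feature, index), params.drop_split)
    if chosen is None:
        return MappingResult(False, 0.0, None, None, ())
    frac = chosen.overlap / feature.length
    present = (
        chosen.overlap >= 1
        and (params.threshold == 0.0 or frac >= params.threshold)
        and (params.gap == -1 or chosen.max_gap <= params.gap)
    )
    return MappingResult(present, frac, chosen.max_gap, chosen.chain_id,
                         chosen.dest_intervals)


def _open_bed(source) -> IO[str]:
    with open(source, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(source, "rt")
    return open(source, "rt")


class BedReader:
    """Streaming BED 4+ reader.

    Yields :class:`GenomicFeature` per valid line.  Lines with fewer than
    three columns or non-integer/invalid coordinates are skipped with a
    warning (counted in ``skipped``), or raise :class:`BedError` under
    ``strict``.  Records without a name column get ``feat_<N>`` names.
    """

    def __init__(self, lines: Iterable[str], strict: bool = False):
        self._lines = lines
        self.strict = strict
        self.skipped = 0
        self._autonamed = False

    def __iter__(self) -> Iterator[GenomicFeature]:
        n = 0
        for lineno, raw in enumerate(self._lines, start=1):
            line = raw.rstrip("\n")
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                cols = s.split()
            try:
                if len(cols) < 3:
                    raise BedError(f"line {lineno}: fewer than 3 columns")
                chrom = cols[0]
                start, end = int(cols[1]), int(cols[2])
                n += 1
                if len(cols) >= 4 and cols[3]:
                    name = cols[3]
                else:
                    name = f"feat_{n}"
                    if not self._autonamed:
                        log.warning(
                            "BED line %d lacks a name column; auto-generating "
                            "feat_N identifiers", lineno,
                        )
                        self._autonamed = True
                yield GenomicFeature(chrom, start, end, name, tuple(cols[4:]))
            except (ValueError, BedError) as exc:
                if isinstance(exc, BedError) and self.strict:
                    raise
                if self.strict:
                    raise BedError(f"line {lineno}: {exc}") from None
                self.skipped += 1
                log.warning("skipping malformed BED line %d: %s", lineno, exc)


def read_bed(source, strict: bool = False) -> BedReader:
    """Open a BED file (plain or gzip) as a :class:`BedReader`."""
    return BedReader(_open_bed(source), strict=strict)
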