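"""UCSC liftover chain parsing, validation and interval indexing.

A chain is the pairwise-alignment currency of the liftover ecosystem: a
scored run of gapless aligned blocks separated by unaligned gaps on either
genome.  Every chain consumed here must carry the query genome (the genome
the BED features live on) on its *reference* side; the destination side is
the species the features are projected onto.

Coordinates are 0-based half-open throughout.  Destination coordinates of
'-'-strand chains are kept strand-local exactly as written in the file;
conversion to forward-strand coordinates happens only when mapped intervals
are emitted (see :mod:`phylomap.mapping`).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, NamedTuple, Sequence, Union

from intervaltree import IntervalTree

log = logging.getLogger(__name__)

__all__ = [
    "ChainParseError",
    "ChainIntegrityError",
    "ChainHeader",
    "ChainBlock",
    "ChainAlignment",
    "BlockHit",
    "ChainIndex",
    "parse_chain_file",
    "parse_chain_text",
    "format_chain",
    "write_chain_file",
    "build_index",
]


class ChainParseError(ValueError):
    """The file does not follow UCSC chain syntax."""


class ChainIntegrityError(ValueError):
    """Block arithmetic contradicts the chain header."""


@dataclass(frozen=True)
class ChainHeader:
    """The 12 fields of a ``chain`` header line (plus the id).

    ``ref_*`` is the reference (query-genome) side, ``dest_*`` the
    destination side.  Reference strand must be forward per UCSC
    convention; destination coordinates are strand-local when
    ``dest_strand`` is ``'-'``.
    """

    score: int
    ref_name: str
    ref_size: int
    ref_strand: str
    ref_start: int
    ref_end: int
    dest_name: str
    dest_size: int
    dest_strand: str
    dest_start: int
    dest_end: int
    chain_id: int

    def __post_init__(self) -> None:
        if self.ref_strand != "+":
            raise ChainIntegrityError(
                f"chain {self.chain_id}: reference strand must be '+', got "
                f"{self.ref_strand!r}"
            )
        if self.dest_strand not in ("+", "-"):
            raise ChainIntegrityError(
                f"chain {self.chain_id}: bad destination strand {self.dest_strand!r}"
            )
        if not (0 <= self.ref_start < self.ref_end <= self.ref_size):
            raise ChainIntegrityError(
                f"chain {self.chain_id}: reference span "
                f"[{self.ref_start},{self.ref_end}) out of range for size {self.ref_size}"
            )
        if not (0 <= self.dest_start < self.dest_end <= self.dest_size):
            raise ChainIntegrityError(
                f"chain {self.chain_id}: destination span "
                f"[{self.dest_start},{self.dest_end}) out of range for size {self.dest_size}"
            )


@dataclass(frozen=True)
class ChainBlock:
    """One gapless aligned block and the gaps separating it from the next.

    ``gap_ref``/``gap_dest`` are the unaligned base counts on the
    reference/destination side before the next block; both are zero for the
    final block of a chain.
    """

    size: int
    gap_ref: int = 0
    gap_dest: int = 0

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ChainIntegrityError(f"block size must be positive, got {self.size}")
        if self.gap_ref < 0 or self.gap_dest < 0:
            raise ChainIntegrityError(
                f"block gaps must be non-negative, got ({self.gap_ref}, {self.gap_dest})"
            )


@dataclass(frozen=True)
class ChainAlignment:
    """A chain header plus its ordered block list; arithmetic is verified."""

    header: ChainHeader
    blocks: tuple[ChainBlock, ...]

    def __post_init__(self) -> None:
        h = self.header
        if not self.blocks:
            raise ChainIntegrityError(f"chain {h.chain_id}: no blocks")
        last = self.blocks[-1]
        if last.gap_ref or last.gap_dest:
            raise ChainIntegrityError(
                f"chain {h.chain_id}: final block must have no trailing gaps"
            )
        ref_sum = sum(b.size + b.gap_ref for b in self.blocks)
        dest_sum = sum(b.size + b.gap_dest for b in self.blocks)
        if ref_sum != h.ref_end - h.ref_start:
            raise ChainIntegrityError(
                f"chain {h.chain_id}: blocks cover {ref_sum} reference bp but header "
                f"declares {h.ref_end - h.ref_start}"
            )
        if dest_sum != h.dest_end - h.dest_start:
            raise ChainIntegrityError(
                f"chain {h.chain_id}: blocks cover {dest_sum} destination bp but header "
                f"declares {h.dest_end - h.dest_start}"
            )

    def block_spans(self) -> list[tuple[int, int, int, int]]:
        """Absolute spans ``(ref_start, ref_end, dest_start, dest_end)`` per block.

        Destination coordinates are strand-local (as stored in the file).
        """
        spans = []
        r, d = self.header.ref_start, self.header.dest_start
        for b in self.blocks:
            spans.append((r, r + b.size, d, d + b.size))
            r += b.size + b.gap_ref
            d += b.size + b.gap_dest
        return spans


def _open_text(path) -> IO[str]:
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _ints(tokens: Sequence[str], lineno: int) -> list[int]:
    try:
        return [int(t) for t in tokens]
    except ValueError as exc:
        raise ChainParseError(f"line {lineno}: expected integer fields: {exc}") from None


def _parse_header(tokens: Sequence[str], lineno: int) -> ChainHeader:
    if len(tokens) != 13:
        raise ChainParseError(
            f"line {lineno}: chain header has {len(tokens)} fields, expected 13"
        )
    score = _ints(tokens[1:2], lineno)[0]
    ref_size, ref_start, ref_end = _ints([tokens[3], tokens[5], tokens[6]], lineno)
    dest_size, dest_start, dest_end = _ints([tokens[8], tokens[10], tokens[11]], lineno)
    chain_id = _ints(tokens[12:13], lineno)[0]
    return ChainHeader(
        score=score,
        ref_name=tokens[2],
        ref_size=ref_size,
        ref_strand=tokens[4],
        ref_start=ref_start,
        ref_end=ref_end,
        dest_name=tokens[7],
        dest_size=dest_size,
        dest_strand=tokens[9],
        dest_start=dest_start,
        dest_end=dest_end,
        chain_id=chain_id,
    )


def _parse_lines(lines: Iterable[str]) -> Iterator[ChainAlignment]:
    header: ChainHeader | None = None
    blocks: list[ChainBlock] = []
    lineno = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if line.startswith("#"):
            continue
        if header is None:
            if not line:
                continue
            if not line.startswith("chain"):
                raise ChainParseError(
                    f"line {lineno}: expected 'chain' header, got {line.split()[0]!r}"
                )
            header = _parse_header(line.split(), lineno)
            blocks = []
        else:
            if not line:
                raise ChainParseError(
                    f"line {lineno}: chain {header.chain_id} truncated "
                    "(missing terminal block line)"
                )
            tokens = line.split()
            if len(tokens) == 3:
                size, gap_ref, gap_dest = _ints(tokens, lineno)
                blocks.append(ChainBlock(size, gap_ref, gap_dest))
            elif len(tokens) == 1:
                blocks.append(ChainBlock(_ints(tokens, lineno)[0]))
                yield ChainAlignment(header, tuple(blocks))
                header = None
            else:
                raise ChainParseError(
                    f"line {lineno}: block line has {len(tokens)} fields, expected 1 or 3"
                )
    if header is not None:
        raise ChainParseError(
            f"line {lineno}: chain {header.chain_id} truncated at end of file"
        )


def parse_chain_text(text: str) -> list[ChainAlignment]:
    """Parse chains from an in-memory string (testing convenience)."""
    return list(_parse_lines(text.splitlines()))


def parse_chain_file(path) -> list[ChainAlignment]:
    """Parse a UCSC chain file (plain or gzip-compressed).

    Returns every chain in file order.  An empty file yields an empty list.
    Raises :class:`ChainParseError` on syntax errors (naming the line) and
    :class:`ChainIntegrityError` when block arithmetic contradicts a header
    (naming the chain id).
    """
    with _open_text(path) as fh:
        return list(_parse_lines(fh))


def format_chain(aln: ChainAlignment) -> str:
    """Render one chain back to UCSC chain text (with trailing blank line)."""
    h = aln.header
    out = [
        f"chain {h.score} {h.ref_name} {h.ref_size} {h.ref_strand} {h.ref_start} "
        f"{h.ref_end} {h.dest_name} {h.dest_size} {h.dest_strand} {h.dest_start} "
        f"{h.dest_end} {h.chain_id}"
    ]
    for b in aln.blocks[:-1]:
        out.append(f"{b.size}\t{b.gap_ref}\t{b.gap_dest}")
    out.append(f"{aln.blocks[-1].size}")
    out.append("")
    return "\n".join(out) + "\n"


def write_chain_file(chains: Iterable[ChainAlignment], path) -> None:
    with open(path, "wt") as fh:
        for aln in chains:
            fh.write(format_chain(aln))


class BlockHit(NamedTuple):
    """One indexed block intersecting a queried reference interval."""

    chain_id: int
    block_index: int
    ref_start: int
    ref_end: int
    dest_start: int  # strand-local
    dest_end: int


class ChainIndex:
    """Per-chromosome interval index over the reference-side aligned blocks
    of one species' chains."""

    def __init__(self, species_id: str, chains: Iterable[ChainAlignment]):
        self.species_id = species_id
        self.chains: dict[int, ChainAlignment] = {}
        self._spans: dict[int, list[tuple[int, int, int, int]]] = {}
        self.by_chrom: dict[str, IntervalTree] = {}
        for aln in chains:
            cid = aln.header.chain_id
            if cid in self.chains:
                raise ChainIntegrityError(
                    f"duplicate chain id {cid} in chains for {species_id!r}"
                )
            self.chains[cid] = aln
            spans = aln.block_spans()
            self._spans[cid] = spans
            tree = self.by_chrom.setdefault(aln.header.ref_name, IntervalTree())
            for i, (rs, re, _, _) in enumerate(spans):
                tree.addi(rs, re, (cid, i))

    @property
    def n_blocks(self) -> int:
        return sum(len(s) for s in self._spans.values())

    def chromosomes(self) -> set[str]:
        return set(self.by_chrom)

    def query(self, chrom: str, start: int, end: int) -> list[BlockHit]:
        """All blocks whose reference span intersects ``[start, end)``."""
        tree = self.by_chrom.get(chrom)
        if tree is None:
            return []
        hits = []
        for iv in tree.overlap(start, end):
            cid, i = iv.data
            rs, re, ds, de = self._spans[cid][i]
            hits.append(BlockHit(cid, i, rs, re, ds, de))
        hits.sort(key=lambda h: (h.chain_id, h.block_index))
        return hits


def build_index(
    chains: Iterable[ChainAlignment], species_id: str
) -> ChainIndex:
    """Build a :class:`ChainIndex` over parsed chains for one species."""
    return ChainIndex(species_id, chains)


def load_index(path, species_id: str) -> ChainIndex:
    """Parse a chain file and index it in one step."""
    return build_index(parse_chain_file(path), species_id)
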