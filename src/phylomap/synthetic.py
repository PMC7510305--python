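"""Forward simulation of indel evolution along a fixed phylogeny.

The simulator creates a toy ancestral coordinate space at the root of a
binary tree and evolves it down every branch with Poisson-sampled
insertions and deletions (uniform positions, geometric lengths).  Each
insertion opens a novel coordinate space with no homolog outside its own
descendants; there is no convergent insertion, so homoplasy can arise only
through independent deletions and the planted ground truth stays
well-defined.  Events on internal branches propagate to all descendant
leaves, which is exactly what makes outgroup evidence informative.

From the evolved leaf genomes the simulator derives, per non-query
species, a pairwise liftover chain set (query genome on the reference
side) by intersecting the two species' conserved segments in their shared
coordinate spaces, plants query BED features of three known truth classes

* ``ortholog`` — inside segments conserved in every leaf,
* ``gain``     — inside insertions that occurred on the query terminal branch,
* ``loss``     — inside ancestral segments deleted on the target terminal
  branch but conserved in the query and every outgroup,

and writes mutually consistent chain files, a BED file, the Newick tree
and a truth table.  A single seed governs every draw, so output files are
byte-identical across runs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .chain_io import ChainAlignment, ChainBlock, ChainHeader, format_chain
from .mapping import GenomicFeature
from .phylogeny import PhyloTree, parse_newick

log = logging.getLogger(__name__)

__all__ = [
    "SimulationError",
    "SimConfig",
    "Segment",
    "LineageMap",
    "build_lineage_map",
    "compose_maps",
    "SimResult",
    "simulate",
]

#: Query + target + three outgroups, the canonical small study phylogeny.
DEFAULT_NEWICK = (
    "((((query:1.0,target:1.0):0.3,out1:1.0):0.3,out2:1.3):0.3,out3:1.6);"
)


class SimulationError(ValueError):
    """The requested configuration cannot host the requested features."""


@dataclass(frozen=True)
class SimConfig:
    """Simulation conditions.

    Rates are expected events per base pair per unit branch length; indel
    lengths are geometric with the given means (bp).  Defaults describe a
    desk-scale study: a 100 kb ancestral genome on a five-leaf ladder with
    ~6 % of the genome inserted and ~9 % deleted per unit branch length,
    and 300 planted 20 bp features (transcription-factor motif scale),
    one third per truth class.
    """

    newick: str = DEFAULT_NEWICK
    genome_length: int = 100_000
    ins_rate: float = 6e-4
    del_rate: float = 6e-4
    ins_len_mean: float = 150.0
    del_len_mean: float = 150.0
    n_features: int = 300
    feature_len: int = 20
    seed: int = 2020
    query: str = "query"
    target: str = "target"
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.ins_rate < 0 or self.del_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.ins_len_mean < 1 or self.del_len_mean < 1:
            raise ValueError("indel length means must be >= 1")
        if self.feature_len < 1 or self.n_features < 0:
            raise ValueError("feature_len >= 1 and n_features >= 0 required")
        if self.genome_length < 4 * self.n_features * self.feature_len:
            raise ValueError(
                "genome_length must dwarf the total feature footprint "
                f"({self.genome_length} < 4 * {self.n_features} * {self.feature_len})"
            )

    def tree(self) -> PhyloTree:
        return parse_newick(self.newick)


@dataclass(frozen=True)
class Segment:
    """A run of bases with a shared origin.

    ``space`` is ``"root"`` for ancestral sequence or a unique insertion
    identifier; ``start``/``end`` are half-open coordinates inside that
    space.
    """

    space: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _total(genome: list[Segment]) -> int:
    return sum(seg.length for seg in genome)


def _delete_span(genome: list[Segment], pos: int, length: int) -> list[Segment]:
    """Remove ``[pos, pos+length)`` of the genome's own coordinates."""
    a, b = pos, pos + length
    out: list[Segment] = []
    cur = 0
    for seg in genome:
        s0, s1 = cur, cur + seg.length
        cur = s1
        if s1 <= a or s0 >= b:
            out.append(seg)
            continue
        keep_left = max(0, a - s0)
        keep_right = max(0, s1 - b)
        if keep_left:
            out.append(Segment(seg.space, seg.start, seg.start + keep_left))
        if keep_right:
            out.append(Segment(seg.space, seg.end - keep_right, seg.end))
    return out


def _insert_segment(genome: list[Segment], pos: int, new: Segment) -> list[Segment]:
    """Insert ``new`` at genome coordinate ``pos``."""
    out: list[Segment] = []
    cur = 0
    placed = False
    for seg in genome:
        s0, s1 = cur, cur + seg.length
        cur = s1
        if not placed and pos <= s0:
            out.append(new)
            placed = True
        if s0 < pos < s1:
            k = pos - s0
            out.append(Segment(seg.space, seg.start, seg.start + k))
            out.append(new)
            placed = True
            out.append(Segment(seg.space, seg.start + k, seg.end))
        else:
            out.append(seg)
    if not placed:
        out.append(new)
    return out


def _evolve(
    tree: PhyloTree, cfg: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, list[Segment]], dict[str, str]]:
    """Evolve the root genome down every branch.

    Returns the leaf genomes and a map from insertion-space id to the label
    of the child node whose branch created it.
    """
    genomes: dict[str, list[Segment]] = {}
    space_branch: dict[str, str] = {}
    counter = itertools.count()

    def descend(node, genome: list[Segment]) -> None:
        if node.is_leaf:
            genomes[node.label] = genome
            return
        for child in node.children:
            g = list(genome)
            t = child.branch_length if child.branch_length is not None else 1.0
            glen = _total(g)
            n_ins = int(rng.poisson(cfg.ins_rate * t * glen))
            n_del = int(rng.poisson(cfg.del_rate * t * glen))
            events = ["I"] * n_ins + ["D"] * n_del
            order = rng.permutation(len(events))
            for idx in order:
                glen = _total(g)
                if events[idx] == "I":
                    length = int(rng.geometric(1.0 / cfg.ins_len_mean))
                    pos = int(rng.integers(0, glen + 1))
                    sid = f"ins_{child.label}_{next(counter)}"
                    space_branch[sid] = child.label
                    g = _insert_segment(g, pos, Segment(sid, 0, length))
                else:
                    if glen == 0:
                        continue
                    length = int(rng.geometric(1.0 / cfg.del_len_mean))
                    pos = int(rng.integers(0, glen))
                    g = _delete_span(g, pos, min(length, glen - pos))
            descend(child, g)

    descend(tree.root, [Segment("root", 0, cfg.genome_length)])
    return genomes, space_branch


@dataclass
class LineageMap:
    """Piecewise-monotone map between one species' genome and the shared
    coordinate spaces it inherits.

    ``by_space[space]`` lists ``(src_start, src_end, own_start)`` triples
    sorted by source coordinate; segments of a given space never reorder
    under the indel model, so source order equals genome order.
    """

    species: str
    length: int
    by_space: dict[str, list[tuple[int, int, int]]]

    def space_intervals(self, space: str) -> list[tuple[int, int]]:
        """Merged source-coordinate intervals this genome retains of ``space``."""
        ivs = sorted((s, e) for s, e, _ in self.by_space.get(space, []))
        out: list[list[int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        return [(s, e) for s, e in out]


def build_lineage_map(species: str, genome: list[Segment]) -> LineageMap:
    by_space: dict[str, list[tuple[int, int, int]]] = {}
    cur = 0
    for seg in genome:
        by_space.setdefault(seg.space, []).append((seg.start, seg.end, cur))
        cur += seg.length
    for lst in by_space.values():
        lst.sort()
    return LineageMap(species, cur, by_space)


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _subtract(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            if b[k][0] > cur:
                out.append((cur, b[k][0]))
            cur = max(cur, b[k][1])
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def compose_maps(
    qmap: LineageMap,
    dmap: LineageMap,
    ref_name: str = "chr1",
    dest_name: str = "chr1",
) -> list[ChainAlignment]:
    """Compose two lineage maps through their shared coordinate spaces into
    a pairwise chain set with ``qmap`` on the reference side.

    Aligned pieces are the intersections of both genomes' conserved
    segments per space; runs that stay colinear on both genomes merge into
    single chains (block/gap arithmetic holds by construction), and a new
    chain starts wherever destination coordinates become non-monotone.
    """
    pieces: list[tuple[int, int, int, int]] = []
    for space in sorted(set(qmap.by_space) & set(dmap.by_space)):
        qa = qmap.by_space[space]
        da = dmap.by_space[space]
        i = j = 0
        while i < len(qa) and j < len(da):
            qs, qe, qo = qa[i]
            ds, de, do = da[j]
            a, b = max(qs, ds), min(qe, de)
            if b > a:
                pieces.append((qo + (a - qs), qo + (b - qs),
                               do + (a - ds), do + (b - ds)))
            if qe <= de:
                i += 1
            if de <= qe:
                j += 1
    pieces.sort()

    groups: list[list[tuple[int, int, int, int]]] = []
    cur: list[tuple[int, int, int, int]] = []
    for p in pieces:
        if cur and p[2] >= cur[-1][3]:
            cur.append(p)
        else:
            if cur:
                groups.append(cur)
            cur = [p]
    if cur:
        groups.append(cur)

    chains: list[ChainAlignment] = []
    for cid, group in enumerate(groups, start=1):
        merged: list[list[int]] = [list(group[0])]
        for q0, q1, d0, d1 in group[1:]:
            last = merged[-1]
            if q0 == last[1] and d0 == last[3]:
                last[1], last[3] = q1, d1
            else:
                merged.append([q0, q1, d0, d1])
        blocks: list[ChainBlock] = []
        for k, (q0, q1, d0, d1) in enumerate(merged):
            if k + 1 < len(merged):
                nq0, _, nd0, _ = merged[k + 1]
                blocks.append(ChainBlock(q1 - q0, nq0 - q1, nd0 - d1))
            else:
                blocks.append(ChainBlock(q1 - q0))
        header = ChainHeader(
            score=sum(b.size for b in blocks),
            ref_name=ref_name,
            ref_size=qmap.length,
            ref_strand="+",
            ref_start=merged[0][0],
            ref_end=merged[-1][1],
            dest_name=dest_name,
            dest_size=dmap.length,
            dest_strand="+",
            dest_start=merged[0][2],
            dest_end=merged[-1][3],
            chain_id=cid,
        )
        chains.append(ChainAlignment(header, tuple(blocks)))
    return chains


def _query_pieces(
    qmap: LineageMap, root_intervals: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Query-coordinate pieces of root-space intervals, never crossing a
    segment boundary (so each piece is contiguous in the query genome)."""
    out: list[tuple[int, int]] = []
    for s, e, off in qmap.by_space.get("root", []):
        for a, b in _intersect([(s, e)], root_intervals):
            out.append((off + (a - s), off + (b - s)))
    out.sort()
    return out


def _plant(
    pieces: list[tuple[int, int]],
    count: int,
    feature_len: int,
    rng: np.random.Generator,
    what: str,
    pad: int = 2,
) -> list[int]:
    """Pick ``count`` non-overlapping feature start positions inside pieces."""
    if count == 0:
        return []
    slots: list[int] = []
    for a, b in pieces:
        p = a
        while p + feature_len <= b:
            slots.append(p)
            p += feature_len + pad
    if len(slots) < count:
        raise SimulationError(
            f"only {len(slots)} candidate positions for {count} {what} features; "
            "increase genome_length or the event rates"
        )
    idx = rng.choice(len(slots), size=count, replace=False)
    return sorted(slots[i] for i in idx)


@dataclass
class SimResult:
    """Everything the simulator produced, plus writers for the on-disk form."""

    config: SimConfig
    tree: PhyloTree
    features: list[GenomicFeature]
    truth: dict[str, tuple[str, str]]  # name -> (label, event branch)
    chains: dict[str, list[ChainAlignment]]  # non-query species -> chains
    maps: dict[str, LineageMap]

    def truth_label(self, name: str) -> str:
        return self.truth[name][0]

    def write(self, out_dir) -> dict[str, Path]:
        """Write query.bed, tree.nwk, truth.tsv and chains/<species>.chain."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        bed = out / "query.bed"
        with open(bed, "wt") as fh:
            for f in self.features:
                fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.name}\n")
        paths["bed"] = bed

        nwk = out / "tree.nwk"
        nwk.write_text(self.config.newick.strip() + "\n")
        paths["newick"] = nwk

        truth = out / "truth.tsv"
        with open(truth, "wt") as fh:
            fh.write("#name\tlabel\tevent_branch\n")
            for f in self.features:
                label, branch = self.truth[f.name]
                fh.write(f"{f.name}\t{label}\t{branch}\n")
        paths["truth"] = truth

        chain_dir = out / "chains"
        chain_dir.mkdir(exist_ok=True)
        for species in sorted(self.chains):
            path = chain_dir / f"{species}.chain"
            with open(path, "wt") as fh:
                for aln in self.chains[species]:
                    fh.write(format_chain(aln))
            paths[f"chain_{species}"] = path
        return paths


def simulate(config: SimConfig = SimConfig()) -> SimResult:
    """Run the full simulation for one configuration.

    With all rates zero every chain is a whole-genome identity chain and
    every planted feature is an ortholog; gain (loss) features are only
    requested when the insertion (deletion) rate is positive.
    """
    tree = config.tree()
    leaves = tree.leaf_order
    if config.query not in leaves or config.target not in leaves:
        raise SimulationError(
            f"tree leaves {leaves} must include query {config.query!r} and "
            f"target {config.target!r}"
        )
    rng = np.random.default_rng(config.seed)
    genomes, space_branch = _evolve(tree, config, rng)
    maps = {lf: build_lineage_map(lf, genomes[lf]) for lf in leaves}
    qmap = maps[config.query]

    chains = {
        lf: compose_maps(qmap, maps[lf], ref_name=config.chrom,
                         dest_name=config.chrom)
        for lf in leaves
        if lf != config.query
    }

    # Truth classes by set algebra on the root coordinate space.
    root_in = {lf: maps[lf].space_intervals("root") for lf in leaves}
    conserved_all = root_in[leaves[0]]
    for lf in leaves[1:]:
        conserved_all = _intersect(conserved_all, root_in[lf])
    non_target = [root_in[lf] for lf in leaves if lf != config.target]
    kept_elsewhere = non_target[0]
    for ivs in non_target[1:]:
        kept_elsewhere = _intersect(kept_elsewhere, ivs)
    lost_in_target = _subtract(
        [(0, config.genome_length)], root_in[config.target]
    )
    loss_root = _intersect(kept_elsewhere, lost_in_target)

    ortholog_pieces = _query_pieces(qmap, conserved_all)
    loss_pieces = _query_pieces(qmap, loss_root)
    gain_pieces = sorted(
        (off, off + (e - s))
        for space, ivs in qmap.by_space.items()
        if space_branch.get(space) == config.query
        for s, e, off in ivs
    )

    n = config.n_features
    n_gain = 0 if config.ins_rate == 0 else n // 3
    n_loss = 0 if config.del_rate == 0 else n // 3
    n_orth = n - n_gain - n_loss

    flen = config.feature_len
    starts = {
        "ortholog": _plant(ortholog_pieces, n_orth, flen, rng, "ortholog"),
        "gain": _plant(gain_pieces, n_gain, flen, rng, "gain"),
        "loss": _plant(loss_pieces, n_loss, flen, rng, "loss"),
    }
    branch_of = {"ortholog": ".", "gain": config.query, "loss": config.target}

    records: list[tuple[int, str, str]] = []
    for label, pos_list in starts.items():
        for k, pos in enumerate(pos_list, start=1):
            records.append((pos, f"{label}_{k:03d}", label))
    records.sort()

    features: list[GenomicFeature] = []
    truth: dict[str, tuple[str, str]] = {}
    for pos, name, label in records:
        features.append(GenomicFeature(config.chrom, pos, pos + flen, name))
        truth[name] = (label, branch_of[label])

    return SimResult(config, tree, features, truth, chains, maps)
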