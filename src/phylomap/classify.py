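"""Per-feature orchestration: map, infer, label.

For each query feature: map it to the target species first.  If an
orthologous sequence exists there the feature is labeled ``ortholog`` and
no tree inference runs (so the result is invariant to outgroup chains).
Otherwise the feature is mapped to every outgroup, the leaves of the
phylogeny are labeled with the observed presence bits (query = 1, target =
0), and the root state — the most-recent common ancestor of query and
target — is inferred by parsimony.  An absent root means the sequence
arose on the query branch (``gain``); a present root means it was deleted
on the target branch (``loss``).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping, Optional

from .chain_io import ChainIndex
from .mapping import GenomicFeature, MappingParams, map_feature
from .parsimony import (
    AMBIGUOUS,
    BranchEvent,
    RootCall,
    assign_final_states,
    branch_events,
    fitch_postorder,
    resolve_root,
)
from .phylogeny import PhyloTree

log = logging.getLogger(__name__)

__all__ = [
    "ClassifiedFeature",
    "classify_feature",
    "run_dataset",
    "qualified_label",
    "format_header",
    "format_record",
    "write_records",
]

LABELS = ("ortholog", "gain", "loss", "ambiguous")


@dataclass
class ClassifiedFeature:
    """A feature plus its inferred evolutionary label.

    ``presence`` maps each non-query species to its observed presence bit;
    a value of None means the species was never mapped (orthologs
    short-circuit before outgroup mapping).  ``target_intervals`` carries
    the destination coordinates of the aligned pieces for orthologs.
    """

    feature: GenomicFeature
    label: str  # one of LABELS
    label_species: str  # query name for gain, target name for loss, "" otherwise
    presence: dict[str, Optional[int]]
    target_intervals: tuple[tuple[str, int, int], ...] = ()
    events: Optional[tuple[BranchEvent, ...]] = None
    root_call: Optional[RootCall] = None


def classify_feature(
    feature: GenomicFeature,
    indices: Mapping[str, ChainIndex],
    tree: PhyloTree,
    query: str,
    target: str,
    params: MappingParams = MappingParams(),
    priority: str = "gain",
    no_prune: bool = False,
    report_events: bool = False,
) -> ClassifiedFeature:
    """Classify one feature as ortholog / gain / loss / ambiguous."""
    try:
        target_res = map_feature(feature, indices[target], params)
        if target_res.present:
            return ClassifiedFeature(
                feature=feature,
                label="ortholog",
                label_species="",
                presence={target: 1},
                target_intervals=target_res.dest_intervals,
            )
        presence: dict[str, Optional[int]] = {target: 0}
        leaf_states = {query: 1, target: 0}
        for species in tree.leaf_order:
            if species in (query, target):
                continue
            res = map_feature(feature, indices[species], params)
            presence[species] = int(res.present)
            leaf_states[species] = int(res.present)
        fitch_postorder(tree, leaf_states)
        call = resolve_root(tree, priority=priority, no_prune=no_prune)
        if call.state == AMBIGUOUS:
            label, label_species = "ambiguous", ""
        elif call.state == 0:
            label, label_species = "gain", query
        else:
            label, label_species = "loss", target
        events: Optional[tuple[BranchEvent, ...]] = None
        if report_events and call.state != AMBIGUOUS:
            assign_final_states(tree, call)
            events = tuple(branch_events(tree))
        return ClassifiedFeature(
            feature=feature,
            label=label,
            label_species=label_species,
            presence=presence,
            events=events,
            root_call=call,
        )
    except KeyError as exc:
        raise ValueError(
            f"feature {feature.name!r}: no chain index for species {exc}"
        ) from None


def run_dataset(
    features: Iterable[GenomicFeature],
    indices: Mapping[str, ChainIndex],
    tree: PhyloTree,
    query: str,
    target: str,
    params: MappingParams = MappingParams(),
    priority: str = "gain",
    no_prune: bool = False,
    report_events: bool = False,
) -> Iterator[ClassifiedFeature]:
    """Classify a stream of features, preserving input order."""
    for feature in features:
        yield classify_feature(
            feature, indices, tree, query, target,
            params=params, priority=priority, no_prune=no_prune,
            report_events=report_events,
        )


def qualified_label(record: ClassifiedFeature) -> str:
    """Species-qualified label string, e.g. ``gain_hg19`` or ``loss_mm10``."""
    if record.label in ("ortholog", "ambiguous"):
        return record.label
    return f"{record.label}_{record.label_species}"


def format_header(species_order: list[str], report_events: bool = False) -> str:
    """Output header naming the species order of the presence pattern."""
    cols = ["#chrom", "start", "end", "name", "label",
            f"presence({','.join(species_order)})", "target_locus"]
    if report_events:
        cols.append("events")
    return "\t".join(cols)


def format_record(
    record: ClassifiedFeature,
    species_order: list[str],
    report_events: bool = False,
) -> str:
    """One tab-separated output row for a classified feature."""
    bits = []
    for sp in species_order:
        v = record.presence.get(sp)
        bits.append(f"{sp}={'.' if v is None else v}")
    if record.target_intervals:
        locus = ",".join(f"{c}:{s}-{e}" for c, s, e in record.target_intervals)
    else:
        locus = "."
    f = record.feature
    cols = [f.chrom, str(f.start), str(f.end), f.name,
            qualified_label(record), ",".join(bits), locus]
    if report_events:
        if record.events:
            cols.append(";".join(
                f"{ev.parent_label}->{ev.child_label}:{ev.event}"
                for ev in record.events
            ))
        else:
            cols.append(".")
    return "\t".join(cols)


def write_records(
    records: Iterable[ClassifiedFeature],
    handle: IO[str],
    species_order: list[str],
    report_events: bool = False,
) -> Counter:
    """Write the full labeled output; returns per-label tallies."""
    tallies: Counter = Counter()
    handle.write(format_header(species_order, report_events) + "\n")
    for record in records:
        handle.write(format_record(record, species_order, report_events) + "\n")
        tallies[qualified_label(record)] += 1
    return tallies
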