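# phylomap

Infer the evolutionary history of short genomic sequence features —
transcription-factor binding sites, enhancers, or any other BED-sized
interval — relative to a second species. Each query feature is labeled as
an **ortholog** (an aligned sequence exists in the target genome), a
lineage-specific **gain** (the sequence arose on the query branch), a
lineage-specific **loss** (the sequence existed in the common ancestor and
was deleted on the target branch), or **ambiguous**.

Distinguishing gain from loss matters because a gap in a pairwise
alignment says nothing about how it arose: a query-specific insertion and
a target-specific deletion look identical in two-species comparisons.
`phylomap` resolves the ambiguity with outgroup species and ancestral
state reconstruction, combining the mapping and inference steps that
otherwise require multi-stage liftover workflows into a single tool.

## Method

Inputs are (a) query features in BED format, (b) one UCSC liftover chain
file per non-query species, all with the query genome on the reference
side, and (c) a rooted binary Newick tree over all species.

For each feature:

1. **Map to the target.** The feature is intersected with the aligned
   blocks of every overlapping chain. Under the chain with the largest
   aligned overlap, presence requires: at least one aligned base, an
   aligned fraction ≥ `-t` (default 0.0, i.e. the single-base rule), and
   no internal reference-side gap longer than `-g` bp (default −1,
   unlimited). Features that pass are written out as orthologs with their
   destination coordinates.
2. **Map to every outgroup.** Failures enter ancestral reconstruction:
   each leaf of the phylogeny is labeled 1 (orthologous sequence found)
   or 0 (not found); the query leaf is 1 by construction.
3. **Fitch parsimony.** A post-order pass assigns each internal node the
   most frequent state among its children's state sets, or the union on a
   tie — the classical minimum-change reconstruction for presence/absence
   characters. The root is the most-recent common ancestor (MRCA) of
   query and target: root 0 ⇒ the sequence was gained on the query
   branch; root 1 ⇒ it was lost on the target branch.
4. **Root disambiguation.** If the root state set is {0, 1}, the state is
   taken from the base of the root's larger subtree if unambiguous
   (equivalent to pruning a single terminal outgroup and rerooting), then
   from the opposite subtree's base if it is internal and unambiguous,
   and otherwise from the `-p/--priority` parameter (`gain` ⇒ absent,
   `loss` ⇒ present). With `-n/--no_prune` such features are labeled
   `ambiguous` instead.
5. Optionally (`-e`), a pre-order pass localizes every gain (0→1) and
   loss (1→0) event to a branch.

Splitting a feature across several chains does not discard it: the chain
with the longest alignment is kept (disable with `-d/--drop_split`).

## Worked example

The package ships a simulator that evolves a toy ancestral genome along a
five-leaf phylogeny (query, target, three outgroups) with insertions and
deletions, and writes mutually consistent chain files, BED features and
ground-truth labels:

```
$ phylomap-example example --seed 42
$ cd example
$ phylomap query.bed tree.nwk query target \
    target=chains/target.chain out1=chains/out1.chain \
    out2=chains/out2.chain out3=chains/out3.chain -o labeled.tsv -e
INFO phylomap: classified 300 feature(s): gain_query=100, loss_target=100, ortholog=100
```

`labeled.tsv` holds one row per feature:

```
#chrom  start  end   name          label        presence(target,out1,out2,out3)  target_locus        events
chr1    559    579   ortholog_001  ortholog     target=1,out1=.,out2=.,out3=.    chr1:646-666        .
chr1    4076   4096  gain_001      gain_query   target=0,out1=0,out2=0,out3=0    .                   node_3->query:gain
chr1    7081   7101  loss_001      loss_target  target=0,out1=1,out2=1,out3=1    .                   node_3->target:loss
```

Reading the rows: `ortholog_001` aligned to the target at
`chr1:646-666`, so no tree inference ran (outgroup bits show `.`).
`gain_001` was found in no other species — parsimony places the MRCA at
0 and the gain on the query terminal branch. `loss_001` is present in
all three outgroups but not the target, so the MRCA state is 1 and a
loss is inferred on the target branch. The tallies match the simulator's
planted truth table (`truth.tsv`) exactly.

## Scope notes

The tool resolves histories between one query and one target species;
outgroups only polarize the MRCA state, and adding intermediate species
does not sharpen the placement of events in time. Guidance for real
analyses: use at least two (better, three or more) outgroups spanning
evolutionary distance comparable to the query/target clade, and prefer
high-quality assemblies — alignment errors in chains propagate directly
into spurious gain/loss calls. See `docs/methods.md` for the full model
description and limitations.
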