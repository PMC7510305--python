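# Methods

## Model

`phylomap` treats each query feature as a binary presence/absence
character on a fixed, rooted, strictly binary phylogeny whose leaves are
the query species, the target species and one or more outgroups. Presence
at a leaf is an observable: an orthologous sequence is found (or not) by
projecting the feature through the pairwise liftover chains between the
query genome and that species. Ancestral states are unobservable and are
reconstructed by unweighted (Wagner) parsimony: the reconstruction
minimizes the number of gain (0→1) and loss (1→0) events needed to
explain the leaf pattern. The root of the supplied tree is interpreted as
the most-recent common ancestor of the query/target pair for labeling
purposes: root absent ⇒ the feature's sequence arose on the query
lineage (`gain`); root present ⇒ it was deleted on the target lineage
(`loss`).

Branch lengths are parsed and kept but play no role in inference, which
is purely topological. Multifurcating trees are rejected rather than
arbitrarily resolved, because the root-disambiguation rule is defined in
terms of a left and a right subtree.

## Mapping semantics

For one feature and one species, every chain with at least one aligned
block overlapping the feature is a candidate. Per candidate we compute

* `overlap` — aligned feature bases under that chain's blocks;
* `max_gap` — the longest run of feature bases falling in the chain's
  inter-block *reference* gaps, measured between the first and last
  overlapped block. Destination-side insertions do not fragment the
  feature in query coordinates and therefore do not count toward `-g`.

The evaluated chain is the candidate with the largest `overlap` (ties:
higher chain score, then lower chain id — a deterministic contract the
chain format itself does not impose). Presence requires `overlap ≥ 1`,
`overlap / feature_length ≥ threshold` (the threshold 0.0 is implemented
as the explicit single-base rule, not a float comparison), and
`max_gap ≤ gap` unless `gap = −1`. With `drop_split` enabled, any feature
overlapped by more than one chain is unmapped — the stricter historical
behaviour; the default keeps the longest alignment, because discarding
split features systematically undercounts orthologs near chain breaks.

Statistics are never pooled across chains: pooling would silently merge
paralogous placements into one fictitious alignment.

Destination coordinates of `-`-strand chains stay strand-local until
mapped intervals are emitted, at which point they are converted to
forward-strand coordinates as `(size − end, size − start)`.

## Parsimony details

The post-order pass assigns each internal node the strict-majority symbol
across its two children's state sets (one vote per symbol per child), or
the union of observed symbols on a tie. On a binary alphabet and a binary
tree this is provably the classical Fitch rule — intersection when the
children's sets intersect, union otherwise — and the test suite asserts
that equivalence explicitly.

When the root set is ambiguous the decision tree is: (1) adopt the state
at the base of the root child subtending more leaves, if unambiguous —
for a ladder tree with a single terminal outgroup this equals pruning
that outgroup at the branch above the root and rerooting; (2) otherwise
adopt the state at the base of the opposite subtree if that node is
internal and unambiguous; (3) otherwise fall back to the `priority`
parameter (`gain` ⇒ 0, treating insertions as evolutionarily cheaper
than deletions; `loss` ⇒ 1), or label the feature `ambiguous` when
pruning is disabled. Two notes on this rule as implemented:

* With majority-vote state sets on a binary tree, step (2) is in fact
  unreachable (if the larger child is {0,1} and the other child is a
  singleton {x}, the root vote is 2:1 for x and the root is already
  unambiguous). The step is retained for contract completeness and is
  unit-tested with directly constructed state sets.
* A leaf-count tie between the root's children takes the first (left)
  child in Newick order as "larger"; documented so that results are
  reproducible for a given input string.

Branch events are reported from a pre-order final pass: the root takes
the resolved state, and every other node keeps its own state when its set
is a singleton, inheriting the parent's final state otherwise. This is
the standard Fitch final-pass convention; the spec for internal-node
resolution is deliberately minimal, and the choice is validated by an
exhaustive oracle: over every rooted binary topology with 3–6 leaves and
every leaf pattern, whenever the Fitch root is unambiguous, the number of
state changes implied by the final labeling equals the true minimum found
by enumerating all internal labelings. For ambiguous roots resolved via
the larger subtree, the finalized labeling is likewise checked to achieve
the enumerated minimum (either root choice of an ambiguous Fitch root is
optimal).

## Synthetic data

The simulator emulates exactly the processes the classifier must
distinguish: segmental insertion and deletion along a known tree.

* The root genome is a coordinate space of `genome_length` bases (default
  100 kb). Down each branch, insertion and deletion counts are Poisson
  with mean `rate × branch_length × genome_length` (default rates
  6×10⁻⁴ events/bp per unit branch length), positions uniform, lengths
  geometric (default mean 150 bp). Each insertion opens a novel
  coordinate space inherited only by its descendants; there is no
  convergent insertion, so ground truth stays well-defined and homoplasy
  can arise only from independent deletions.
* Pairwise chains are derived, not simulated: for each non-query species,
  the aligned pieces are the intersections of both genomes' conserved
  segments in every shared coordinate space, merged into chains wherever
  both genomes stay colinear. Because indels never reorder segments, the
  emitted chains satisfy the chain-format block arithmetic by
  construction, and the parser re-validates them.
* Features (default 300 of 20 bp — transcription-factor motif scale) are
  planted one third per truth class: in segments conserved in every leaf
  (`ortholog`), inside query-terminal-branch insertions (`gain`), and in
  ancestral segments deleted on the target terminal branch but conserved
  in the query and all outgroups (`loss`). Classes whose generating rate
  is zero get no features (all-ortholog datasets from zero-rate configs).
  Infeasible requests raise an error suggesting a larger genome or higher
  rates rather than silently under-planting.
* The default tree is the five-leaf ladder
  `((((query:1.0,target:1.0):0.3,out1:1.0):0.3,out2:1.3):0.3,out3:1.6)`,
  mirroring the canonical query + target + three-outgroups design.
  Terminal branch lengths near 1.0 with short internals keep roughly half
  of the ancestral genome conserved across all leaves while leaving ample
  target-specific deletion and query-specific insertion space for
  planting, comfortably above the demand at the default feature counts
  across seeds.

A single `numpy` seed governs every draw; outputs are byte-identical
across runs of the same configuration.

What the simulator does *not* model — and what passing its tests
therefore does not establish about real data: nucleotide substitutions,
alignment error (spurious or missing chain blocks), genomic
rearrangements and duplications (all simulated chains are colinear, so
paralogous multi-chain placements never arise naturally), convergent
insertion, and assembly artifacts. The mapping layer's split-chain and
minus-strand logic is exercised by constructed fixtures instead.

## Validation problem sizes

The shipped checks run at the following scales, chosen to make the
oracles exhaustive where enumeration is feasible and dense elsewhere:
all 1 053 rooted binary topologies with 3–6 labeled leaves × all leaf
patterns (≈ 42 000 unambiguous-root cases, ≈ 22 000 ambiguous ones)
against the brute-force oracle; 1 000 random chain/feature pairs against
per-base enumeration; and one fresh 100 kb / 300-feature simulation per
run for end-to-end recovery, which is exact (100 %) because each planted
feature's lineage carries at most the single event that defines its
class.

## Known limitations

* Resolution in time is inherently two-state: events are attributed to
  the query or target lineage; intermediate species add evidence for the
  MRCA state but not temporal precision, and the optional branch events
  are reported without temporal claims.
* Equal-parsimony patterns are decided by the documented tie-break
  cascade, not probabilistically; there is no likelihood model, no
  asymmetric gain/loss costs (Sankoff parsimony), and no uncertainty
  quantification on the labels.
* Chains are trusted as given; no attempt is made to detect alignment
  error beyond the format's internal arithmetic.
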