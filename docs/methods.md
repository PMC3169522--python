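# Methods

This note documents the models and algorithms behind `clustevo`, the free
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## The inference problem

A multi-gene machinery that sits in chromosomal clusters leaves several
correlated traces: its genes co-occur as syntenic blocks, their homologues
share a phyletic distribution, their gene trees agree with one another (and
disagree with the species tree where the whole block was transferred), and
paralogous block copies mirror ancient duplications. The pipeline exploits
each trace in turn: feature-based candidate screening, adjacency
clustering, homologue-family expansion and phyletic profiling, distance
phylogenetics with bootstrap, synteny-resolved supermatrix construction,
and finally a per-family evolutionary scenario (origin, losses,
duplications, transfers) on the species tree.

## Screening and clustering

A gene is a machinery candidate iff it has a signal peptide, a lipoprotein
signal, at least one predicted transmembrane segment, or a
protein–protein-interaction motif (TPR and coiled-coil are deliberately
collapsed into one boolean: the screen never distinguishes them). The
screen is monotone: adding a positive feature can never remove a candidate.

Chromosomes are treated as linear sequences of 0-based ordinal gene
positions; all ranges are half-open. Two candidate hits are chromosomal
neighbours when at most `max_gap` other loci intervene
(|Δordinal| − 1 ≤ `max_gap`); clusters are connected components of that
relation. The default `max_gap = 3` is the smallest value under which all
four regions of the motivating system assemble from their printed locus
tags. Cluster extension fills the contiguous run between the extreme hits;
pseudogene handling is purely data-driven (explicit fuse/discard rules in
the configuration), because automated pseudogene calling is out of scope.
Circular chromosomes are not wrapped (a known limitation; the clusters of
interest are interior).

Polar-effect screening flags relative-expression values outside
(`low`, `high`) with strict inequalities, defaulting to (0.4, 2.0) —
consistent with treating values in [0.40, 1.89] as non-polar while calling
out a ~4.7-fold change. `ND` cells (the deleted gene itself) are skipped.

## Homologue families

Pairwise similarity is the Smith–Waterman optimal local alignment score
(BLOSUM62, affine gaps, open −11 / extend −1, via Biopython's
`PairwiseAligner`), normalized by the smaller self-score, so identical
sequences score 1.0 and the threshold is independent of database size. A
family grows from its seeds by symmetric single-linkage — any sequence
scoring ≥ `sim_score_threshold` (default 0.3) against a current member
joins, and newly joined members act as fresh seeds — iterated to a fixed
point (or `max_iters`). The expansion is monotone in the threshold and
independent of input order (candidates are processed in sorted id order).
The 0.3 default replaces expert visual inspection of search output, which
cannot be automated faithfully; unrelated random length-200 protein pairs
score below it in well over 95% of draws, while family members at the
simulator's study conditions score ≈ 0.45 or higher.

An optional exact k-mer word prefilter (default `word_size = 7` in the
pipeline, off in the raw operation) skips the quadratic alignment whenever
a pair shares no length-k word — the same seeding idea as word-based local
search heuristics. At the study conditions the filter changes no family
(members share dozens of conserved 7-mers) and cuts the search cost by
roughly an order of magnitude.

The phyletic profile counts family members per genome. A family is
**Group A** (clade-restricted) when every carrier genome lies inside the
configured focal clades, **Group B** (broadly distributed) when at least
one carrier lies outside, and *absent* otherwise. Clade membership is by
label containment in each genome's clade path; no taxonomy database is
consulted.

## Distances, trees, support

Sequence distances use a uniform 20-state substitution model: `p` (raw
mismatch fraction, pairwise deletion), `poisson`
(d = −(19/20)·ln(1 − (20/19)p), the exact inverse of the simulator's
substitution chain) or `gamma`
(d = (19/20)·α·((1 − (20/19)p)^(−1/α) − 1)). Saturated pairs (argument
≤ 0) are set to a declared cap (default 10.0) with a logged warning; pairs
sharing no aligned columns are an error, not a guess. The uniform model was
chosen over an empirical matrix deliberately: it matches the simulator
exactly, enabling closed-form calibration checks, and desk-scale recovery
does not need LG-style realism. Maximum-likelihood and Bayesian inference
are out of scope by design; the distance+NJ+bootstrap combination is the
desk-scale substitute, so published tree figures are qualitative references
only.

Neighbor-joining follows Saitou–Nei with Studier–Keppler updates. Ties in
the Q criterion are broken toward the lexicographically smallest pair of
representative labels (a merged node is represented by the smallest leaf
label beneath it), so results are deterministic; negative branch lengths
are clamped to zero with the deficit logged. On additive matrices NJ
recovers the generating topology exactly (tested over random 6–10-leaf
trees, and cross-checked once against scikit-bio's implementation).

Bootstrap support resamples alignment columns with replacement; the
support of an internal edge is the percentage of replicates whose NJ tree
contains the same bipartition. Robinson–Foulds distance is the symmetric
difference of non-trivial unrooted bipartitions.

## Transfer displacement: what is detectable

The HGT signal is *displacement*: a copy (or block of copies) nesting,
with bootstrap support ≥ `support_min` (default 70%), among leaves from a
foreign part of the species tree. The test runs on the midpoint-rooted
gene tree and scans every supported clade as a candidate *block*:

- the block's supported neighbourhood (smallest supported strict ancestor
  with ≥ 2 extra leaves) must be inexplicable by the unrooted species tree
  (its taxa set matches no species-tree split restricted to the gene
  tree's taxa);
- removing the block must restore that consistency — this separates the
  received block from its donor-side context;
- multi-leaf blocks must be copy-redundant (every taxon in the block
  carries another copy elsewhere in the gene tree: a received operon copy
  coexists with the vertical one), while single-copy blocks fall back to
  the classic rule (all neighbours from a foreign reference clade);
- blocks whose whole neighbourhood fits inside a small species-tree region
  (≤ 35% of taxa) are discarded: short-range displacement is
  indistinguishable from local incongruence noise and paralogy.

When the two halves of an anomalous neighbourhood are both explicable, the
next enclosing clade and copy redundancy decide which half was received
(transfers onto internal branches otherwise invert: the received copies
look at home among each other and the lone donor copy looks displaced).
Detected blocks are peeled off and the scan repeats (default 3 rounds,
later rounds restricted to blocks whose taxa exactly fill a species
clade), so transfers stacked in one region unmask each other. Reference
clades for naming sources come from partitioning the species tree into
subtrees of ≤ 3 leaves, with singleton clades merged into their sister
clade (an isolated deep lineage would otherwise always look displaced).

Each surviving report becomes one transfer event on the branch above the
species-tree MRCA of the block's taxa, with the foreign clade as source
(`"unresolved"` when the foreign neighbourhood is mixed — directionality
is not always decidable, and the ambiguity is preserved rather than
guessed). Inferred transfer copies are then excluded both from the Dollo
presence row (so vertical origins/losses are re-estimated without
horizontally acquired tips) and from the duplication scan.

**Identifiability.** Not every real transfer creates a topological
conflict. A transfer from a lineage adjacent to the recipient lands where
vertical descent would have put it; a near-root transfer has no outgroup
context; a within-clade transfer looks like a local duplication. No
tree-comparison method can see these (and reconciliation-based inference
is an explicit non-goal), so recovery metrics report transfer *recall*
against the topologically visible events — a truth-log + species-tree
computable class mirroring the rules above — and transfer *precision*
against all surviving true events (detecting a hard event is not an
error). The unrestricted comparison is always reported alongside
(`transfer_unrestricted`); at the default study conditions roughly half of
surviving simulated transfers are visible.

## Dollo, Fitch, duplications

Single-gain Dollo parsimony places the origin on the branch above the MRCA
of all carriers and the losses at the maximal carrier-free subtrees below
it; this loss set is provably minimal among single-gain explanations and
is verified against exhaustive enumeration in the tests. A Fitch
small-parsimony count (gains unconstrained) serves as a quality-control
comparator: profiles where free gains beat the single-gain explanation
markedly are suspect.

Duplications use the species-overlap rule on the rooted gene tree: an
internal node whose child subtrees share at least one species is a
duplication, mapped to the species branch above the MRCA of the node's
species set. Midpoint rooting is used for inferred gene trees (outgroup
rooting is available in real mode via configuration but cannot be
automated in general).

Event-recovery metrics match (type, family, branch) tuples exactly —
transfers on the recipient branch only — against the *observable* true
events: events with surviving tip descendants (both daughter lineages for
duplications). Events that left no extant evidence are unknowable to any
inference and are excluded from denominators; timing is never compared,
because inference cannot recover it.

## Supermatrices

Families are concatenated only when they co-occur in a detected cluster in
at least one genome *and* their gene trees, restricted to ≥
`min_shared_taxa` (default 4) shared single-copy taxa, differ by RF ≤
`rf_congruence_max` (default 2); groups are transitive closures. Rows are
resolved by physical linkage: a genome with one copy of every family
contributes one row; multi-copy genomes contribute one row per detected
cluster containing exactly one copy of each family; copies without a
complete linked set are reported unassigned and genomes without a complete
tuple are dropped rather than gap-padded (gap rows distort
pairwise-deletion distances). Partition bookkeeping is lossless:
de-concatenating recovers each family's alignment restricted to the tuple
members.

## The simulator and the study conditions

The generator emulates the structure of the motivating system, not its
unknown numerical history (no quantitative rates are published for it;
defaults are chosen for signal strength):

- **Species tree**: random coalescent-style ultrametric tree, depth
  normalized to 1.0; default 20 taxa. A focal clade (~30% of taxa) stands
  in for the gliding lineage.
- **Gene content**: per-copy Gillespie process with duplication, loss and
  additive transfer rates per unit branch length (defaults 0.05 / 0.02 /
  0.15 for the core module). Transfer recipients are uniform among
  contemporaneous branches — the simplest null, deliberately without
  distance bias. Families declaring a module share a single event skeleton
  (the operon duplicates, dies and transfers as a unit) while their
  sequences evolve independently; this is what makes module families
  genuinely co-evolve, the premise behind congruence grouping and
  supermatrix construction. Two default modules: "core" (root origin,
  HGT-punctuated, plus one whole-module duplication at the focal-stem
  midpoint, emulating the diverged paralogous cluster copies) and
  "recent" (focal-stem origin, no transfer). Content histories are
  rejection-sampled until every family survives somewhere in the focal
  clade: the emulated discovery presupposes the focal organism carries the
  machinery, exactly as conditioning on the studied strain having the
  system.
- **Sequences**: root sequence uniform over 20 amino acids; along a branch
  of length t each site substitutes with probability
  (19/20)(1 − e^(−(20/19)·r·t)), replacement uniform over the other 19
  residues — the exact uniform-rate 20-state chain, whose pairwise
  difference has the closed form (19/20)(1 − e^(−(20/19)d)) and whose
  Poisson correction is exact. No indels, so family members are aligned by
  construction (real-mode alignments are inputs; alignment computation is
  out of scope). Default length 2000, rate 0.3 per unit depth.
- **Genomes**: with probability `p_linkage` (default 0.9) per genome,
  copies of the same module lineage are placed as one contiguous block;
  otherwise all copies scatter among filler loci (default 20 per genome,
  length 150, random sequences).
- **Features**: boolean features copy per-family role templates and flip
  independently with probability 0.05; filler loci draw from stated
  background frequencies.

Every event lands in a `TrueEventLog`; replaying the log — a separate
accounting path using no times and no randomness — reproduces the per-tip
copy counts exactly, which is enforced by a test.

What the generator does **not** emulate: indels and alignment uncertainty,
site-rate heterogeneity, amino-acid exchangeability structure, base-pair
coordinates and operon transcription, gene conversion, and
database/annotation noise beyond the feature flips. Passing recovery tests
therefore demonstrate the pipeline's logic under clean, strongly
identifiable histories — not performance on real annotation pipelines'
output.

## Problem sizes and determinism

The shipped tests and the acceptance script use desk-scale problem sizes
chosen as the package's own study conditions: 20-taxon trees, two
3-family modules, 2000-residue sequences, 100 bootstrap replicates, 10–20
simulated replicates per property, 2000 replicates for the birth–death
calibration. All randomness flows from a single seed through named
substreams; identical configuration yields byte-identical reports, and
every number in a run report is recomputable from the stage artifacts it
accompanies.

## Known limitations

- Transfer direction is frequently unresolvable from topology alone; the
  pipeline reports `"unresolved"` sources rather than guessing, and
  short-range transfers are invisible by construction (see above).
- Compound histories (several transfers stacked in one subtree, transfers
  into freshly duplicated regions) can fragment or mislocalize events by a
  branch; matching is branch-exact, so such near-misses count as both a
  false positive and a false negative in the metrics.
- Dollo origins are MRCA-based; origins above the MRCA (gain followed by
  early loss) are not distinguishable and finer placement is not
  attempted.
- Locus-tag rank is the proxy for gene order when explicit coordinates are
  absent; base-pair distances are never used.
- Absence of a homologue means no hit in the supplied proteomes; no
  nucleotide-level verification of absences is performed.
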