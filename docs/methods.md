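# Methods

## Scope and design

`phylobench` evaluates multiple-sequence-alignment methods by the quality
of the phylogenies inferred from their alignments. Alignment programs and
tree builders are deliberately *pluggable*: the evaluation logic — the two
tests, the split metrics, the duplication counting, the gap parsimony and
the statistics — is the package; the aligners being judged are external.
So that every pipeline runs and can be verified without third-party
executables, the package ships aligner *emulators* driven by its own
simulator (which knows the true alignment) and a built-in
neighbour-joining tree builder. Real programs drop in through command
templates (`{input}`/`{output}`/`{guidetree}` placeholders).

## Topology metrics

All comparisons are topological; branch lengths are parsed and preserved
but ignored by every metric.

- A *split* is the leaf bipartition induced by an internal edge of the
  unrooted tree; trivial splits (singleton blocks) are excluded.
- Robinson–Foulds distance: size of the symmetric difference of the two
  non-trivial split sets.
- Tree accuracy: TA = 1 − RF / (|S₁| + |S₂|). The denominator is the sum
  of the two trees' non-trivial split counts, which equals 2(n−3) when
  both trees are binary. This choice degrades gracefully for partially
  resolved trees (how to normalise RF for non-binary trees is genuinely
  open; the trees produced here are binary, so the two conventions
  coincide).
- Proportion of wrong splits: |S(inferred) \ S(reference)| / |S(inferred)|.
  Normalising by the *inferred* tree's split count makes "wrong" a
  property of the splits the method actually asserted, and keeps the
  score defined for partially resolved inferred trees. A star inferred
  tree has no splits to judge; such samples raise an error and are
  excluded, they never contribute a score.
- Newick output is canonical (children ordered by smallest descendant
  label), so equal topologies serialise identically; this is what makes
  whole-pipeline runs byte-reproducible.

## Minimum duplication scoring

A rooted gene-tree node whose two child subtrees contain overlapping
species sets certifies a duplication (species-overlap rule, strict
non-empty intersection, the root counted like any other node). Because
the root is generally unknown, the count is minimised over all 2n−3
rootings, then reduced by the absolute minimum number of duplications
m−1, where m is the maximum number of same-species genes in the family.
The normalised score is provably ≥ 0 (every rooting must explain the m
co-paralogs) and is 0 whenever the tree implies no duplications beyond
those the data force. Multifurcating gene trees are rejected rather than
silently resolved, since resolution would change counts.

A worked consequence of the rule: for the quartet with two species and
two paralogs each, the unrooted topology {a1,b1}|{a2,b2} scores 0 (one
overlap node under the internal-edge rooting, matching m−1 = 1), while
{a1,a2}|{b1,b2} scores 1 — every rooting of it leaves two overlap nodes
(the two paralog cherries, or one cherry plus the root).

## Gap parsimony

Every alignment column containing at least one gap becomes a binary
character (1 = gap). To avoid over-counting multi-column indels, maximal
runs of *consecutive* gap-containing columns with identical presence/
absence patterns are collapsed into one character of weight 1; a gap-free
column breaks a run. The uncollapsed variant (one character per column)
is retained as a control. Wagner parsimony on ordered binary states is
identical to Fitch counting, which is how scores are computed (bitmask
set operations vectorised over characters; rooting-invariant).

Tree search is exact up to 8 taxa (exhaustive enumeration of all
(2n−5)!! unrooted binary topologies, 10 395 at n = 8); above that, a
deterministic heuristic runs stepwise addition in sorted-id order
followed by nearest-neighbour interchange to a local optimum. When
several topologies tie for the minimum score, accuracy is averaged over
all of them (tie exploration on flat plateaus is capped at 50 trees) —
averaging avoids an arbitrary tie-break biasing the benchmark. An
alignment with no informative gap character (no character showing both
states) has no gap signal; the sample is excluded via a dedicated error.

## Distance tree builder

The built-in builder computes pairwise mismatch fractions with pairwise
deletion of gap sites, corrects them with the Poisson formula
d = −ln(1−p) for amino acids or Jukes–Cantor d = −¾ ln(1−4p/3) for
nucleotides, caps undefined or saturated pairs at 3.0 substitutions/site,
and runs neighbour joining. Branch lengths are dropped from the result
(all downstream metrics are topological, and NJ's occasional negative
estimates are irrelevant to topology). The builder is deterministic for
a given alignment.

## Bootstrap support

Columns are resampled with replacement (seeded), the builder is re-run,
and support is the fraction of replicate trees topologically identical
(RF = 0) to the tree from the original alignment. Failed replicates are
dropped with the denominator adjusted.

## Simulator

The generator's job is known truth, not maximal realism.

- Topology: comb (the sampling shape that guarantees mutual orthology)
  or random; branch lengths uniform on a configurable interval, default
  0.05–0.3 expected substitutions/site — a range spanning shallow to
  moderately divergent orthologs where tree inference is neither trivial
  nor hopeless.
- Substitutions: a site hit by at least one Poisson event on a branch is
  replaced uniformly by one of the other residues (the simplest
  exchangeable model). Multiple-hit reversions are slightly
  under-counted; immaterial here because every method sees identical
  inputs.
- Indels: events arrive at indel_rate × branch length × sequence length
  (default rate 0.1 per substitution), insertion or deletion with equal
  probability, geometric lengths with mean 3, uniform positions — the
  minimal standard indel process, enough to create heritable gap signal
  along branches.
- Every site ever created carries a persistent identity, so the true
  alignment (the full homology relation) is exact by construction;
  ungapping it reproduces the tip sequences, always.
- Duplications: d events are grafted onto the gene tree, each picking a
  branch uniformly among branches whose subtree contains no earlier
  duplication node (duplicating above one would copy it and silently
  inflate the event count), splitting it at its midpoint and copying the
  subtree. On the true rooted tree the species-overlap nodes are then
  exactly the d events.
- Aligner emulators: degradation q relocates each gap within a window of
  ±round(40·q) columns with probability q and inserts round(0.05·q·width)
  jittered gap columns that shear residues across rows — both operations
  preserve the ungapped sequences exactly, and the expected distance to
  the true alignment grows with q. The displacement scale grows with q
  because poor aligners misplace whole regions, not single columns; at
  small windows neighbour-joining on 500-residue alignments is
  essentially immune to the perturbation and the emulator would fail to
  emulate a *bad* aligner.

What the simulator does not model: empirical substitution matrices, rate
heterogeneity across sites, codon structure, indel hotspots, gene loss
and lateral transfer. Passing tests therefore demonstrate that the
pipelines measure what they claim under a known-truth process, not that
any particular real aligner will rank a particular way on biological
data.

## Statistics

- Method comparisons: two-sided Wilcoxon signed-rank on per-sample score
  pairs, samples excluded by either method dropped pairwise, zero
  differences dropped before ranking, exact null up to 25 informative
  pairs and a continuity-corrected normal approximation above. Fewer
  than 6 informative pairs yields an "insufficient data" result, not a
  p-value.
- Aggregates: per-method mean ± one standard deviation over included
  samples.
- Spearman correlations use midranks on ties.
- Comparing the two predictors of tree accuracy: the statistic is
  (z(r₁) − z(−r₂)) / √(2/(n−3)) with z = atanh, treating the two
  transformed correlations as independent with variance 1/(n−3) each.
  Because both correlations share the variable TA they are in fact
  mildly positively dependent, which makes the default test slightly
  conservative (measured empirically: rejection ≈ 0.045–0.05 at nominal
  0.05 under a moderate-signal null). A dependent-correlation variant
  (Steiger-style covariance adjustment, requiring r(BS, AV)) is
  available behind a flag; the independent form is the default because
  it is the simplest statistic consistent with the bivariate-normal
  assumption and the standard-normal limit.

## Numerical and degenerate-input conventions

- Gap symbols `-` and `.` (normalised to `-`); residues uppercased;
  `X`/`N` treated as residues. Column indices are 0-based half-open
  internally; the CLI reports 1-based positions.
- Terminal stop codons on coding sequences are tolerated and trimmed in
  back-translation; codon/residue disagreements are logged, or fatal in
  strict mode.
- Alignment distance between alignments with no residue–residue pairs at
  all is defined as 0 (nothing asserted, nothing contradicted).
- Saturated/undefined distances cap at 3.0 substitutions/site (logged).
- All randomness flows from explicit integer seeds; per-sample,
  per-method seeds are derived with `numpy.random.SeedSequence`, so runs
  are bit-reproducible and adding a method does not shift the draws of
  another.

## Problem sizes

The test suite and `scripts/acceptance.py` use desk-scale problem sizes
chosen to give stable directions at comfortable margins: six-taxon
families of length 500 (200 families in the suite, 150 in the script)
for the discordance, gap-signal and filtering analyses; 100/60 families
with 1–3 duplications for the minimum-duplication test; 1000 random gene
trees (n ≤ 10) for the rooting oracle; 10 000/2000 replicates for the
calibration of the correlation test. The genome-scale experiments the
two tests were designed for (tens of thousands of families, maximum
likelihood tree inference, 13 production aligners) are exactly what the
pluggable interfaces are for and are out of scope here.

## Known limitations

- The heuristic parsimony search (taxa > 8) is a local optimum; it is
  exact on every ≤ 8-taxon problem it is tested against but carries no
  global guarantee beyond that.
- The species-overlap count is a lower bound on true duplication events;
  families with heavy loss can be under-counted. The benchmark only
  relies on this bias being method-independent.
- The shared-homology-pair alignment distance counts residue–residue
  pairs only; gap-residue pairs are not scored.
- NJ on corrected distances is a stand-in for likelihood tree inference;
  rankings of real aligners at high divergence may differ under ML.
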