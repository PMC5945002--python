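# Methods

`fhalmine` mines flavin-dependent halogenase (FHal) genes from assembled
metagenomic contigs.  The pipeline chains gene prediction, profile-HMM
homology scoring with E-value filtering, a completeness filter built on
conserved sequence features, and distance phylogenetics for variant A/B
classification.  Every stage is implemented in this package so that the
whole chain can be exercised and validated on synthetic benchmarks with
known ground truth.

## Gene prediction

ORFs are predicted in all six reading frames under the bacterial genetic
code (NCBI table 11).  Within one stop-bounded segment the longest ORF
(earliest start codon, default start set {ATG}; {GTG, TTG} switchable) is
reported.  Segments that run off a contig edge are emitted as *partial*
genes with the corresponding `has_start`/`has_stop` flag cleared, so the
complete/incomplete split is made by the downstream completeness filter
rather than the gene caller; spans anchored by neither a start nor a stop
are discarded.  Codons containing `N` translate to `X` and never act as
start or stop.  The default minimum length of 100 aa removes spurious
micro-ORFs while passing every known FHal (~460-540 aa).  Coordinates are
0-based half-open internally and 1-based inclusive in GFF3 output; a
complete gene of `n` residues spans `3(n+1)` bp including its stop codon
(530 aa = 1593 bp, the RebH exemplar).

## Profile HMM

The family model is a classic match/insert/delete profile HMM with a
single-hit local alignment architecture: background-emitting flanking
states with self-loop probability 0.98, uniform entry `1/L` into any
match column, a constant per-column exit probability of 0.01, and exit
from the final match or delete state with probability 1.  Match emissions
are estimated from alignment columns whose occupancy is at least 0.5
(rule of majority) as `(counts + w * background) / (n + w)` with
background-proportional pseudocounts of total weight `w = 1` by default;
transition bundles use the same rule with a uniform prior over each
bundle's targets.  `I<->D` adjacencies observed in training rows are
illegal in this architecture and are skipped during counting.  Insert
states emit the background distribution, so inserts and flanks are
score-neutral per residue.  The background is an embedded
Robinson-Robinson-style amino-acid frequency table, fixed so that scores
do not depend on training data.  Scores are reported in bits,
`log2 P(seq|model) / P(seq|background)`; `X` residues carry odds ratio 1
in every state.  Forward and Viterbi are exact dynamic programs
(numba-compiled); both are verified against explicit path enumeration on
small models in the test suite.

Generative sampling draws from the *core* model (M1 through ML, without
local entry/exit truncation or flanks), so a fully deterministic model
emits its consensus exactly.

## E-values

The Forward-score null is modelled as a Gumbel distribution fitted by
maximum likelihood to i.i.d. decoy scores.  E-values are
`E(s) = N * (1 - exp(-exp(-lam (s - mu))))` for a database of `N`
sequences.  Two nulls are supported:

* the model background (the textbook choice, and `calibrate`'s default);
* the *codon null* — decoys drawn from the amino-acid composition of
  uniformly sampled sense codons, at length 150.

The pipeline defaults to the codon null because its actual null
population is ORFs translated from random DNA, whose composition is
codon-multiplicity-weighted rather than proteome-like: measured on
gene-free benchmark contigs, background ORFs score ~-11 bits under a
530-column model while proteome-background decoys at 450 aa score ~-19
with a Gumbel scale of ~0.4 bits, which would let essentially every
background ORF through any practical cutoff.  Codon-null decoys at
length 150 reproduce the observed background-ORF score distribution.

E-values from this scorer are **not** numerically comparable to HMMER3's.
The literature cutoff of 1e-150 for halogenase mining was defined against
HMMER3 E-values; it is carried in the configuration as
`paper_evalue_cutoff` for provenance only, and the operational default
cutoff for this scorer is `evalue_max = 1e-6` against its own
calibration, with the database size set to the number of scored ORFs.

## Seed expansion and alignment

Model construction follows a two-step scheme: characterized reference
sequences are compared to a candidate database with exact Smith-Waterman
local alignment (BLOSUM62; affine gaps, a gap of length k costing
11 + k, the BLAST protein defaults), and database sequences are retained
when at least one reference reaches 50% identity and 90% reference
coverage.  Identity is identical columns over *all* alignment columns
(gaps included) — the threshold's denominator must be pinned down for the
filter to be reproducible — and coverage is computed with the
characterized reference in the query role.  Retained sequences are
multiply aligned by a single progressive pass: a UPGMA guide tree over
cosine distances between 3-mer count vectors, then profile-profile merges
with sum-of-pairs BLOSUM62 scoring and affine gaps.  Profile columns are
weighted by total row count so that mostly-gap columns carry little
weight; iterative refinement is deliberately not implemented, and the
aligner's output feeds model construction and phylogenetics rather than
being an end in itself.

## Motifs, catalytic residues, completeness

Conserved features are scanned as degenerate patterns (`x` = any
residue): the FAD-binding fingerprint GxGxxG and the WxWxIP motif that
distinguishes halogenases from related monooxygenases.  All overlapping
matches are reported; downstream logic uses the first.  Catalytic
residues (the conserved lysine and glutamate) are projected from a
reference row of the training alignment onto a query through the model's
match columns via the query's Viterbi residue-to-column map; columns
deleted in the query map to nothing.

A gene is **complete** when (i) it has a start and a stop codon, (ii)
every required motif (default: GxGxxG and WxWxIP) is present, (iii) its
protein length falls in a configurable window (default 460-600 aa, wide
enough for both the ~530 aa variant A and the ~70 aa shorter variant B),
and (iv) its E-value passes the cutoff.  The catalytic-residue check is
reported but not part of the verdict by default.  Every failed criterion
carries a human-readable reason in the report.

## Phylogenetics and variant classification

Distances are p-distances with pairwise deletion of gapped columns
(preserving signal on partial-length candidates), with an optional
Poisson correction.  Trees are built with Saitou-Nei neighbour joining
(lowest-index tie-break, negative branch lengths clamped to zero), which
is exact on additive matrices — the property the test suite quantifies.
Branch support uses the classic Felsenstein bootstrap with 1000 column
resamples by default; support attaches to the full-data tree.

Variant A FHals halogenate free substrates; variant B enzymes act on
carrier-protein-bound substrates and run ~70 aa shorter.  A candidate is
classified by clade membership: the smallest bipartition side containing
the candidate together with references of exactly one class gives the
call.  When pure sides of *both* classes contain the candidate — which
necessarily happens whenever it attaches between the two reference
clades, since every deep split puts it on one side — raw side size is
biased by cohort composition, and the class of the patristically nearest
reference sharing a pure side decides instead.  If every side is mixed,
a length prior decides: closer to the variant A mean length (default
530 aa) or to that minus the 70 aa offset.  The evidence field records
which rule fired ('clade', 'length_prior', or 'both' when they agree).

## Synthetic benchmarks

The generator emulates the statistical structure the mining analysis
assumes, with a truth manifest for scoring:

* **Reference families.** Two synthetic FHal families share an ancestral
  consensus.  Variant A has 530 match columns with GxGxxG at 16-21, K at
  83 and WxWxIP at 275-280.  Variant B is a diverged subfamily (25% of
  unconstrained consensus positions substituted) with a 70-column block
  removed between the catalytic lysine and WxWxIP, giving 460 columns
  and a shifted motif spacing (WxWxIP at 205-210) — so within-family
  divergence is smaller than between-family divergence, as in real
  variant A/B halogenases.  Eight seed sequences per family (15%
  per-position substitution from their consensus) form the seed
  alignments; the family HMMs are built from them with light
  pseudocounts (weight 0.05) so motif columns stay near-deterministic
  and indel rates stay realistically low.
* **Planted genes.** Complete genes are sampled from a family HMM with
  rejection until they genuinely satisfy the completeness definition
  (leading Met, both motifs intact, length inside the filter window) —
  the manifest's "complete" label must be true by that definition, or
  the ground truth would mislabel itself.  Genes are reverse-translated
  with uniform synonymous codons, framed by a start and stop codon, and
  planted on a random strand at non-overlapping positions (>= 50 nt
  spacing) in i.i.d. background DNA at configurable GC.  An in-frame
  stop codon is placed immediately upstream of each interior gene so the
  ORF finder's earliest-start rule recovers exactly the planted span.
* **Partials.** Partial genes sit flush against a contig edge on the
  forward strand with 40% of their codons removed from the edge-facing
  end (head-truncation destroys the start, tail-truncation the stop).
* **Decoys.** Half are shuffled family samples (motif content destroyed);
  half are "monooxygenase-like" — genuine family samples with every
  WxWxIP occurrence ablated but GxGxxG retained, which therefore pass
  the E-value stage and specifically exercise the motif filter.

The default cohort echoes a familiar shape — 42 complete genes (30 A,
12 B) among 254 planted elements on 60 contigs of 8-20 kb — purely as a
default; it is a synthetic benchmark, not a reproduction of any real
metagenome's counts.  Default seed 1699.

Recovery scoring counts a planted gene as recovered when a reported
candidate overlaps at least 80% of its span on the correct strand (for
the complete stratum the candidate must also carry a complete verdict),
and counts complete-verdict candidates matching a decoy or nothing as
decoy false positives.

What the generator does **not** emulate: codon usage bias (irrelevant to
every downstream computation), sequencing error and assembly artifacts,
overlapping genes, taxonomic composition, and real FHal sequence space.
Passing the benchmark therefore demonstrates that the machinery is
correct and internally consistent, not that the thresholds transfer
unchanged to real metagenomes.

## Problem sizes and numerical choices

The shipped configurations are sized for a single CPU: calibration uses
200 decoys; the default benchmark is ~0.8 Mb of contigs carrying 254
planted elements, mined end-to-end (including a 1000-replicate bootstrap
on ~58 taxa) in well under a minute after JIT warm-up.  Oracle tests
enumerate HMM paths for models with up to 3 match columns and sequences
up to length 4, exhaustive local alignments for sequences up to length 6
over a reduced alphabet, and 100 random 6-10 leaf additive matrices for
neighbour joining.  Ties are deterministic everywhere: smallest end cell
then diagonal > up > left in Smith-Waterman; M > D > I in Viterbi;
lowest index pair in neighbour joining.  All stochastic operations take
explicit seeds (package default 1699).

## Known limitations

* The profile HMM is single-hit and local only; no multihit or glocal
  modes, and no HMMER file-format compatibility.
* The progressive aligner makes one pass; hard cases that MUSCLE's
  refinement would rescue can misalign, which degrades (but, on the
  benchmarks, does not break) downstream distances.
* E-values are calibrated, not derived from theory; they are only as
  good as the decoy null, and cross-scorer thresholds must be re-derived.
* The variant length prior assumes the ~70 aa A/B offset; families that
  violate it will fall back poorly when clade evidence is absent.
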