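# Methods

This note documents the models and procedures implemented in
`bahdscape`, the parameter defaults and why they were chosen, what the
synthetic generators do and do not emulate, and the numerical
conventions adopted where the underlying methods leave choices open.

## Gene-structure profiling

Coordinates are GFF3: 1-based, inclusive, so an interval's length is
`end − start + 1` and the intron between an exon ending at `e` and the
next starting at `s` spans `s − e − 1` bases.  Features are computed on
one representative transcript per gene — the isoform with the longest
total CDS, ties broken by transcript id — because per-gene summaries
over all isoforms would double-count shared exons and annotation sets
differ in how many isoforms they report.  Genes whose transcripts carry
no CDS features are excluded from family summaries and logged.
Per-species summaries report mean/median/n per feature; intron lengths
are pooled over all introns of a species' members, the other features
contribute one value per gene.  The cross-species grand mean is the
unweighted mean of per-species means, so species with large families do
not dominate it.

## Clade assignment

Queries are assigned the clade of their best similarity hit against a
labeled reference panel of characterized enzymes.  Two engines share one
filter contract:

* **alignment** — internal Smith–Waterman local alignment (BLOSUM62,
  affine gaps costing 11 + L for a gap of length L, the blastp default).
  Percent identity is identical positions over alignment columns with
  gap columns counted, matching how BLAST reports identity over
  alignment length.  Bit scores use Karlin–Altschul scaling with the
  standard gapped BLOSUM62 constants (λ = 0.267, K = 0.041); e-values
  use a fixed effective search space of 1e7 recorded in
  `AlignmentScoring`.  These e-values are a documented approximation for
  ranking and filtering, not a reimplementation of BLAST statistics.
* **profile** — imported phmmer/HMMER tabular hits ranked by e-value.

Best hits maximize bit score (alignment) or minimize e-value (profile);
ties break by higher identity, then longer match, then lexicographic
target id, so results are deterministic.  The conservative filter keeps
a call iff identity ≥ 40 **and** match length ≥ 200 (alignment) or
e-value ≤ 1e−50 (profile); all three boundaries pass, since the filter
removes hits *below* 40%/200 aa or with e-value strictly *larger* than
1e−50.  Only the identity/length filter applies to alignment hits — no
additional e-value cut — and the identity denominator is alignment
length (the common BLAST convention; the alternative, query length,
would make the filter stricter for gapped alignments).

## Motif enrichment

The finder is a deliberately simple, exactly testable discriminative
method: every foreground substring of width 5–8 (configurable within
3–15) plus its wildcard generalizations with up to 2 interior 'X'
positions is a candidate; candidates are scored by per-sequence
presence/absence with a one-sided Fisher exact test against the
background (all family sequences not in the clade), BH-adjusted over the
full candidate set, and the top 5 are reported after greedy redundancy
removal (a candidate is skipped when its foreground matches overlap a
selected motif's matches, at overlapping offsets, in > 80% of its
matched sequences).  Ties in p break toward more matched sequences, then
wider motifs, so a fully specified motif outranks its own wildcard
generalizations.  There is no PWM refinement, probabilistic seeding or
train/holdout split, and no claim of reproducing any particular
published motif strings; the method recovers planted motifs and strongly
conserved clade blocks, which is what the tests assert.  Structural
localization of motifs (acceptor vs donor pocket) is out of scope; only
sequence offsets are reported.

## NG86 Ka/Ks

The Nei–Gojobori (1986) counting method with Jukes–Cantor correction:

* **Sites** — each codon position contributes the fraction of its three
  possible nucleotide changes that preserve the amino acid; S and N per
  codon are averaged over the two sequences.  Changes creating stop
  codons count as nonsynonymous in site counting (the original NG86
  convention).
* **Differences** — codons differing at k positions are compared over
  all k! minimal mutational pathways; pathways passing through a stop
  intermediate are excluded, and synonymous/nonsynonymous steps are
  averaged over the remaining pathways (over all pathways in the rare
  case every one is blocked).
* **Correction** — p = D/Sites per class, d = −(3/4)·ln(1 − (4/3)·p);
  p ≥ 3/4 is reported as NaN with a saturation flag.  Saturated pairs
  stay in PCC analyses but are excluded from Ks bins and the linear fit.

Codon pairs come from back-translating a protein alignment (supplied, or
computed internally by global Needleman–Wunsch, BLOSUM62, −10/−0.5);
columns with a gap in either row are dropped pairwise.  A trailing stop
codon is trimmed; internal stops are input errors.  The genetic code is
the standard table only.  The estimator canonicalizes the argument order
internally so `ng86(a, b)` and `ng86(b, a)` are bitwise identical.  NG86
is used rather than a mutation-fraction method (yn00-style) because Ks
is consumed ordinally here — binning and regression — for which the
simpler estimator is sufficient and every count is oracle-testable; a
reader for externally computed yn00-style pair tables is provided.

## Expression divergence

Pearson correlations are computed over all unordered gene pairs;
zero-variance rows yield NaN (logged, never silently zeroed).
Co-expression calls use the 95th/5th percentiles of the upper-triangle
PCC distribution (self-correlations excluded, each pair once), with
linear interpolation between order statistics and strict exceedance for
flagging.  Ks bins are half-open `[x, x + 0.2)`; across bins with ≥ 3
pairs the module runs Kruskal–Wallis on PCC, all pairwise two-sample KS
tests with BH-FDR over that family, and an unbinned linear fit of PCC on
Ks reporting slope and R².  With fewer than two usable bins the rank
tests are skipped with a warning and the fit is still reported (NaN when
all Ks coincide).

## Pathway prediction

Partners of a focal gene partition by pre-computed co-expression
z-score: z ≥ 3 co-expressed, z ≤ 1 not co-expressed, the band in between
excluded from both sets (only the two tails are defined; boundary values
are inclusive).  The universe of each 2×2 table is the *annotated* genes
among the focal gene's two partner sets; each pathway with ≥ 2 annotated
genes in that universe (configurable) is tested one-sided (greater),
since enrichment among co-expressed genes is a directional question.
Q-values are computed per focal gene across its tested pathways —
correction scope could also be global across all focal genes, but the
per-gene scope matches how each gene's candidate pathways are screened
in practice; both are available.  BH is the default; Storey's π₀-spline
q-value (λ grid 0.05–0.95) is optional and falls back to π₀ = 1 below
~40 tests, where the spline is unstable.  A pathway is *enriched* iff
q < 0.05 and the co-expressed pathway fraction exceeds the
not-co-expressed one.

Combined verdicts per gene: `both-consistent` when some enriched
pathway's compound class is compatible with the orthology substrate
class under a user-supplied pathway→class map; `conflicting` when both
signals exist but no enriched pathway is compatible; a substrate class
absent from the map downgrades to `orthology-only` with a warning rather
than ever conflicting silently; single signals give
`coexpression-only`/`orthology-only`, neither gives `none`.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of `SimConfig` (one `default_rng`
seeded per call; a fixed seed yields byte-identical output) and every
emitted file parses with the corresponding pipeline reader.

* **Genomes** — intron counts from a categorical distribution defaulting
  to {0: 0.45, 1: 0.40, 2: 0.10, 3: 0.05} (seed-plant-like: mostly 0–1
  introns), geometric intron lengths with mean 200 bp, CDS of 410 codons
  (near the land-plant family average protein length) split across
  exons.  No codon-usage bias, repeats or UTRs.
* **Families** — 5 clade ancestors as independent random proteins
  (inter-clade identity is background-level, so best hits are
  informative), 8 descendants each, at a configurable fraction of
  residues substituted.  Real clades share a common fold and much higher
  inter-clade identity; the generator tests the assignment machinery,
  not realistic phylogenetic structure.
* **Paralog pairs** — `round(Ks_target · S)` synonymous single-nucleotide
  events (classified post hoc against the code, stop-creating changes
  rejected, repeated hits allowed) applied to a 500-codon ancestor, plus
  nonsynonymous events at 0.3× that rate per nonsynonymous site.  "True
  Ks" is bookkept as applied events per synonymous site, the oracle the
  NG86 recovery tests compare against.
* **Expression** — pair vectors share a latent component giving
  population correlation exp(−λ·Ks) (λ = 2.5, 60 samples) plus
  independent noise (sd 0.1).  Real expression is non-Gaussian and
  condition-structured; the generator provides only the decay signal the
  bin tests are designed to detect, so passing tests show the statistics
  work, not that any particular organism shows the signal.
* **Co-expression** — a Normal(0,1) background would place essentially
  no gene beyond z ≥ 3, leaving the 2×2 odds ratio undefined, so a
  baseline fraction (15%) of the 600 annotated partner genes is drawn in
  the co-expressed tail (z = 3 + |N(0,1)|), the rest below 1, with a 5%
  excluded band.  The planted pathway's co-expressed membership is then
  set deterministically so the realized odds ratio is as close as
  possible to the configured value (default 8, pathway size 15) —
  detection power then reflects the test, not planting noise.  An odds
  ratio of 1 plants nothing beyond baseline and measures the empirical
  type-I rate.

## Problem sizes and known limitations

The test suite and `scripts/acceptance.py` use family sizes of 40
queries against 5-reference panels, 500-codon CDS pairs with 50
replicates per Ks target, 125 expression pairs per replicate across five
Ks bins (20 replicates per condition), and 100 co-expression replicates
per operating-characteristic estimate — sizes at which every recovery
quantity is stable across seeds while the whole suite completes in well
under a minute per stage.

Limitations: the internal aligner's e-values are an approximation, not
BLAST's; the motif finder is exhaustive-enumeration, so very long
foregrounds with wide width ranges and many wildcards grow the candidate
set quickly; NG86 underestimates Ks relative to mutation-fraction
methods when transition/transversion bias is strong (irrelevant to the
unbiased generator, relevant to real data); and the pathway verdicts
depend entirely on the quality of the supplied co-expression z-scores,
pathway annotations and class map — they are screening hypotheses, not
functional assignments.
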