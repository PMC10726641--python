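# Methods

## Scope and data model

The package starts where variant callers stop.  Its unit of analysis is
the SNV key (chrom, 1-based pos, ref, alt); indels and MNVs are rejected
on ingest and multi-allelic VCF records are split into per-alt calls with
alt-specific allele depths.  Two call sets per cell are consumed: the
primary caller ("G", HaplotypeCaller-style records carrying
QUAL/DP/AD/PL/FS/QD) drives all downstream computation; the secondary
caller ("S", Strelka-style) contributes only key presence, and only its
PASS records are ingested — the caller's own filtering is trusted there.
Coordinates are 1-based internally; BED input is 0-based half-open and
converted on read.  Editing-site lists are matched on (chrom, pos) only,
because editing databases are site-level; germline and truth lists are
matched on the full allele.

## Core labeling model

The model assumes clonal evolution: an expressed somatic SNV recurs
across cells, artefacts are scattered nearly independently per cell, and
germline variants appear in almost every cell.  For a cohort of n cells
the effective recurrence window is

    L = max(floor, ceil(lower_frac * n)),  U = floor(upper_frac * n)

with defaults floor = 3, lower_frac = 0.10, upper_frac = 0.80.  The
ceil/floor arithmetic carries a 1e-9 guard because binary floating point
makes 0.1 * 30 come out just above 3, which would otherwise shift L by a
whole cell.

Recurrence is counted on post-annotation, *pre-quality* primary calls
(distinct cells per key).  Counting after the quality filter would make
the negative-set criterion ("no cross-cell recurrence") circular, since a
quality-failing detection is still a detection.  "No recurrence" is read
strictly as recurrence = 1 and exposed as `negative_max_recurrence`.

Per cell, a key called by both pipelines is consensus set A, a
primary-only key set B; secondary-only keys are ignored.  The per-call
quality predicate is dp >= 3, QD >= 2.0, FS <= 30.0 and at least one
alt-supporting read; QD/FS thresholds default to the classic strict
RNA-seq variant filter.  Absent QD/FS pass their thresholds: absence of
evidence of bias is not evidence of bias.  A positive key needs a set-A
call that quality-passes *in the same cell*; the looser any-cell
conjunction is available via `require_same_cell_a_pass=False`.

Labels partition the candidate universe: keys removed at annotation keep
their removal reason; recurrence > U is removed as over-recurrent (a
germline polymorphism or systematic artefact even if absent from the
lists); the positive/negative rules above apply; everything else is
unsure.  The labeling is deterministic and independent of cell-file
ordering — all outputs are key-sorted.

## Joint logistic-regression refinement

Training rows are the positive (y=1) and negative (y=0) keys.  Quality
features of a key are the arithmetic mean of its supporting calls'
features (QUAL, DP, VAF, min-normalized PL triple, AD_ref, AD_alt); the
mean is symmetric in the cells, and a `max_qual` alternative (features of
the highest-QUAL call) is exposed.  Sequence features are a 6-way
mutation-type one-hot, a 96-way SBS96 one-hot (pyrimidine-strand
collapsed, canonical lexicographic order), and optionally one component
per user-supplied reference signature, defined as that signature's
probability mass at the variant's SBS96 class — the only per-variant
quantity derivable from a signature matrix without fitting exposures.
Keys whose trinucleotide context contains N are excluded from both
submodels (the combination rule needs both probabilities) and logged.

The split is stratified 3:1 by class — plain random splitting degenerates
to single-class test sets at small n — and the minority class is randomly
oversampled with replacement to balance the training set.  Both submodels
are liblinear logistic regressions, C = 1.0 by default (config-exposed):
L1 on z-scored quality features (scaler statistics from the oversampled
training rows, stored with the model), L2 on the unscaled one-hots.
Non-convergence triggers one retry at 10x iterations, then fails loudly.

The joint probability is the thresholded weighted mean
P = 1/2 * sum over (P_seq, P_pos) of w*P with w = 1 iff P >= 0.5; its
attainable range is {0} plus [0.25, 1].  The weight cutoff and the final
decision threshold (both 0.5 by default) are separately tunable; a tie at
the threshold counts as positive.  Held-out performance is the AUC of the
joint probability — the joint classifier, not either submodel, is "the
model".  Refinement adds unsure keys whose joint call is positive to the
core set; it never removes core positives.

## Evaluation and downstream statistics

Precision, sensitivity and F0.5 = 1.25 p s / (0.25 p + s) are computed
against a truth key set, with 0/0 ratios reported as undefined rather
than 0.  The overlap coefficient |X∩Y|/min(|X|,|Y|) measures replicate
consistency.  Spectra are 96-class counts; cosine similarity compares
them scale-free.  Stage enrichment of a mutated gene uses the upper tail
of the hypergeometric distribution *inclusive* of the observed count,
P[X >= k] with X ~ HG(N cells, K carriers, n cells in stage) — the
standard over-representation form.  The headline `enriched` flag applies
the raw 0.05 threshold; Benjamini–Hochberg-adjusted values are emitted
alongside for transparency, not for the flag.  A cell counts as a carrier
of a gene if it carries at least one mutant key in the gene's span; a key
overlapping several genes goes to the alphabetically first.

## The simulator

The simulator emulates the post-calling world at VCF level: planting
calls, not reads.  Read-level realism (alignment, base errors) adds no
coverage of the computations under test, which begin at normalized calls.

A random A/C/G/T contig (default 100 kb) is tiled by genes with one
central exon each (exon fraction 0.5).  Planted classes use disjoint
exonic positions; per-cell artefact positions are drawn from the
remaining exonic space, so artefact recurrence arises only by birthday
collision (rare by construction).  Presence is Bernoulli per cell:
prevalence_clone * (1 - dropout) for somatic variants, 0.95 for germline,
0.30 for editing sites; presence vectors are redrawn if empty, so every
planted variant is observed at least once (conditioning on
detectability).  Somatic contexts are sampled from a 96-class spectrum by
building a class -> (position, alt) candidate pool over the reference;
the default spectrum is UV-like (75% C>T, doubled at pyrimidine
5'-neighbours).

Per present variant and cell: depth is negative binomial (true variants
mean 12, artefacts mean 6, dispersion 3), VAF is Beta (somatic (8,8),
germline (10,10), artefact (1.5,6)), AD_alt is a zero-truncated binomial
(a caller only emits a record with alt support), and PL is computed from
binomial read likelihoods at alt fractions (0.02, 0.5, 0.98).  QUAL, QD
and FS are class-conditional (true: N(100,30), N(15,4), Exp(3); artefact:
N(25,12), N(3,2.5), Exp(20)), giving sharp but overlapping separation —
roughly a third of artefact calls pass the QD/FS/depth gates and land in
the unsure set, so the classifier has a real problem to solve.  The
secondary caller re-emits a true call with probability 0.85 and an
artefact with probability 0.05, which directly controls how often
artefacts acquire set-A support.

Study conditions (presets): `default` is 50 cells with 200 clonal somatic
SNVs at prevalence 0.4, 100 germline sites, 30 editing sites and ~20
artefacts per cell; `high_burden` raises the burden to 2,000 somatic SNVs
on a 400 kb reference; `tiny` (12 cells, 20 somatic at prevalence 0.5,
dropout 0.3) keeps smoke tests fast.  Per-variant-per-cell dropout
defaults to 0.6, the realistic regime for full-length scRNA-seq where
allelic dropout, transcriptional bursting and capture losses compound;
at these settings the expected somatic recurrence is 0.4 * 0.4 * 50 = 8
cells against a floor of L = 5, so a tail of true variants falls below
the core filter — exactly the population refinement exists to recover.

What the simulator does *not* emulate: expression-level structure (gene
expression is implicit in dropout, not modeled), UMI chemistries, doublet
cells, strand-specific damage, position-in-read artefact profiles, or
correlated artefacts (index hopping, template switching) that could
recur across cells.  Passing tests therefore demonstrate the filtering
and classification logic under the stated statistical model, not
performance on any real dataset.

## Numerical and design choices

* Variant keys sort lexicographically; every table, VCF and design-matrix
  row order derives from that sort, making outputs byte-reproducible and
  independent of input-file order.
* All randomness flows from numpy `SeedSequence([seed, salt])` streams;
  the CLI and pipeline seeds default to 17.
* PL triples are min-normalized on ingest (idempotent); aggregated PL
  means are deliberately not re-normalized — they are features, not
  likelihoods.
* An empty positive or negative class aborts refinement with an
  instruction to relax thresholds rather than silently degrading.
* Undefined ratios (0/0 precision, empty-set overlap, zero-vector
  cosine, single-class AUC) are reported as `None`, never as 0.
* Problem sizes in the test suite (cohorts up to 50 cells, oracle trials
  on up to 16 cells x 50 keys, classifier calibration at n = 2,000) keep
  the whole suite around half a minute while leaving every statistical
  assertion comfortably powered.

## Known limitations

Only SNVs are modeled; indels and UMI-based 3'-end technologies are out
of scope.  Matching to germline/truth lists is exact per allele with no
liftover — inputs must share a genome build.  The signature-component
interpretation (per-class lookup) is a stated design choice; fitting
per-cell signature exposures is deliberately not attempted.  Secondary-
caller-only variants never enter the candidate universe: the primary
pipeline is the reference, and recall is bounded by it.
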