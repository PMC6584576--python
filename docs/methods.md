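# Methods

This note documents the models, conventions and numerical choices behind
`uvlinker`, and what the synthetic-data generator does and does not
emulate.

## The biological setting

In haploid-dominant dioecious plants, sex is determined by a U (female) or
V (male) chromosome present at the same 1N copy number as the autosomes
but never recombining and never co-occurring in one individual. Whole
genome resequencing of one male and one female therefore separates the
genome into three coverage classes: autosomes and organelles (covered in
both), U (female only) and V (male only). The package's analysis chain —
decontamination, coverage scan, marker cascade, divergence estimation —
is built around that structure.

## GC screening

Read and scaffold GC is computed over unambiguous bases only (N excluded
from numerator and denominator), making it exactly invariant under reverse
complement. Filtering is pair-aware: if either mate exceeds the threshold
the pair is discarded, because downstream assemblers require intact mate
files; the comparison is strictly greater-than, so a read exactly at the
threshold is kept. The threshold default of 0.55 sits between the ~0.45
host and ~0.65 contaminant modes and is exposed as a parameter.

Scaffold GC bimodality is summarized by a Gaussian-kernel density on a
0.001 grid with a configurable absolute bandwidth (default 0.02 GC units,
comfortably below the ~0.20 mode separation while smoothing over
per-scaffold sampling noise). The two highest local maxima are reported as
modes and the density minimum between them as the antimode; with fewer
than two maxima (e.g. a single scaffold) the antimode is absent.

## K-mer coverage

K-mers are counted canonically (lexicographic minimum of a k-mer and its
reverse complement); k-mers containing ambiguity codes are skipped because
canonicalization is undefined for them. The coverage estimate scans the
multiplicity histogram from 1 upward for the first local minimum — the
boundary of the error/low-abundance region — and takes the global maximum
beyond it, ties resolved toward lower multiplicity. The k-mer peak
converts to base coverage via read_len / (read_len − k + 1); with 100 bp
reads and k = 31 a 24× genome peaks near multiplicity 17. With error-free
simulated reads there is no error peak at multiplicity 1, but the
low-coverage tail still produces the required local minimum; histograms
with no interior minimum (single reads, degenerate inputs) return an
absent estimate rather than a guess.

## Differential-coverage scan

Windows are fixed-width (default 500 bp), non-overlapping, tiled from
position 0 of each segment; the terminal partial window is emitted with
its true width but excluded from flagging (its mean is noisier and its
width breaks the regions-bp arithmetic). Window means use the true window
width.

Library-size normalization is the median of per-window cov_a/cov_b over
windows with positive depth in both samples, optionally restricted to a
baseline segment set (putative autosomes). The median is robust to the
sex-specific regions that inflate exactly one library — the situation this
scan exists to find.

The log2 ratio uses a pseudo-count p (default 0.1) so zero-coverage
windows stay finite. The scale s is split symmetrically before the
pseudo-count is applied:

    ratio = log2( (cov_a/√s + p) / (√s·cov_b + p) )

At s = 1 this is the plain log2((a+p)/(b+p)). The one-sided form
log2((a+p)/(s·b+p)) is *not* exactly antisymmetric under swapping samples
and inverting the scale; the symmetric split is, to machine precision,
which makes the male/female orientation a pure labelling choice. A window
is flagged when |ratio| exceeds the threshold (default 4, i.e. a 16-fold
difference); a flagged window whose depleted sample has raw mean depth at
or below the absence floor (default 2×) is called sample-specific,
otherwise enriched. Adjacent flagged windows with identical calls merge
into regions (gap tolerance configurable, default adjacency only).

## Sex-marker cascade

The cascade annotates each region with the furthest stage it reaches:
region_only → has_gene (a predicted gene on the same scaffold; scaffold
wide by default, since marker validation works at scaffold granularity,
with an optional distance limit) → has_homolog (the gene's best homology
hit, selected by maximal bitscore with deterministic tie-breaking by
e-value then subject id) → sex_concordant (male-specific coverage with a
V-class homolog, or female-specific with U-class). Stage counts are
cumulative and therefore monotone non-increasing. Discordant combinations
(e.g. male-specific coverage, U homolog) are retained at has_homolog with
a note; silently dropping them would hide assembly or annotation errors.
Chromosome classes of homology subjects are supplied as an explicit
two-column map rather than parsed out of sequence names.

## Pairwise dN/dS (NG86)

Codon alignments are built by expanding a pairwise protein alignment
codon-by-codon against the source CDS (frame and translation are
validated; a trailing stop codon on the CDS is tolerated). Columns gapped
in either row and columns where either codon is a stop are removed, and
the removal mask is kept.

The estimator is Nei–Gojobori (1986) counting:

- **Sites.** For each codon position, the fraction of possible point
  mutations that are synonymous, with mutations creating stop codons
  excluded from the denominator; each position contributes exactly one
  site, so S + N = 3L identically for L retained codons. Both sequences
  are counted and averaged.
- **Differences.** Codon pairs differing at d positions are resolved by
  enumerating all d! substitution orderings, skipping pathways through
  stop codons, and averaging synonymous/nonsynonymous step counts over the
  legal pathways, so sd + nd = d exactly. In the rare case that every
  pathway passes through a stop, the average is taken over all pathways
  instead (the alternative — dropping the codon — would break the
  difference-count conservation).
- **Correction.** pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected,
  d = −(3/4)·ln(1 − 4p/3). Proportions at or beyond 3/4 are flagged as
  saturated and the estimate is removed downstream.

A transition/transversion-weighted variant is available behind the
`kappa` argument: transitions carry weight κ in both the site denominators
and the pathway weighting, with κ estimable from fourfold-degenerate third
positions (default 2 when no transversion is observed). The unweighted
NG86 is the tested contract because it is verifiable against a brute-force
pathway enumeration; the weighted variant shifts S upward when transitions
are synonymous-biased, but threshold-based conclusions (ω > 1) at the
simulated divergences are insensitive to the choice.

Filtering follows the conventional removal rules — dS = 0, dN > 2,
ω > 10 — with saturated estimates also removed and every removal reason
itemized. Retained estimates receive a natural-log ω for statistics;
ω = 0 (dN = 0) entries are transformed as log(ω + 1e-4), since a log of
zero is undefined and the handling of such ratios is otherwise a free
choice. Contrast statistics are invariant to the log base.

## Group statistics

Class summaries report n, the untransformed mean ω ± SE (the conventional
presentation scale) and the mean log ω. The omnibus test and the targeted
contrasts of each class against the autosomal baseline are computed from a
linear model on log ω: a mixed model with a scaffold random intercept when
per-gene scaffold ids are supplied (genes on one scaffold share linkage
history), otherwise ordinary least squares with a logged warning; the
result object records which model ran. Contrast p-values are reported
unadjusted, with a Holm-adjusted column alongside. A degenerate fit (zero
residual variance, as with identical values in every class) reports null
contrasts as t = 0, p = 1 rather than 0/0.

The copy-number scan flags genes whose |log₂ male/female coverage ratio|
strictly exceeds the threshold (default 4); positive ratios mean higher
male coverage.

qPCR relative expression is ratio = E^(Cq_control − Cq_target) with
amplification efficiency E fixed at 2 (perfect doubling) by default and
validated to (1, 2]. Missing target amplification yields an absent ratio
with a `no_amplification` note — in a UV system that is the expected
outcome for a sex-specific gene assayed in the opposite sex, not an error.
The factorial model is OLS on the ratio with gene, hydration state, sex
and all interactions; single-level factors are dropped with a warning, and
per-gene dehydration contrasts compare least-squares means of dehydrated
vs hydrated cells averaged over the sexes in which the gene amplifies.

Completeness percentages are rounded half-away-from-zero to one decimal
(783/1,440 → 54.4%); the three shares sum to 100 within rounding slack.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* the pipeline relies
on, at desk scale:

- Segment base composition is i.i.d. per site at the target GC (host 0.45,
  contaminant 0.65 by default). Realized GC of a ≥10 kb segment is within
  ±0.02 of target with very high probability. There is no isochore
  structure, no repeats, no real gene sequences — sufficient for testing
  threshold classifiers and coverage arithmetic, not for testing mappers
  or assemblers.
- Reads are 100 bp paired-end with ~300 bp Gaussian inserts, Poisson
  fragment counts per segment at the requested fold coverage, error-free
  by default (base qualities are never used downstream; a uniform error
  rate is available). Males sample autosomes + V + organelles, females
  autosomes + U; contaminant segments are sampled so that a configured
  fraction of all pairs is contaminant-derived. Organelles default to 10×
  the nuclear depth — organellar copy number per cell is variable and
  elevated; the exact multiplier is a free simulation parameter, not a
  claim about any real data set. Every read records its true origin, so
  exact truth coverage tracks and truth labels come for free without a
  mapping step.
- Ortholog pairs descend from a uniform-random sense-codon ancestor and
  evolve along two branches of t/2 under a continuous-time Markov process
  on the 61 sense codons with per-change weight κ^[transition] ·
  ω^[nonsynonymous], normalized to one expected substitution per codon
  site per unit time at the uniform codon distribution. Stop codons are
  outside the state space, so they are never created. Events are drawn
  site-by-site with exponential waiting times (vectorized Gillespie),
  giving exact control of ω; there is no codon-usage bias and no
  among-site rate variation.
- Cq tables follow a sex × hydration-state factorial with configurable
  per-gene baselines, dehydration shifts (one cycle ≈ one doubling of
  template) and Gaussian cycle noise (default SD 0.15, typical technical
  replicate scatter); sex-specific genes are missing in the opposite sex.

Default study conditions are three 100 kb autosomes, 50 kb U and V, 20 kb
and 15 kb organelles, two 30 kb contaminant segments, and 20× per-sample
coverage — scaled down ~1000× from a real liverwort genome project while
preserving hundreds of windows per compartment, enough to measure ≥95%
sensitivity/precision meaningfully. Identical configuration and seed give
byte-identical output files.

Passing recovery tests on these data therefore demonstrates correctness of
the *computations* (window arithmetic, normalization, thresholding,
counting-method estimation) under the structural assumptions; they say
nothing about mapping artifacts, repeat-induced coverage noise, isochores,
or real contaminant taxonomic composition.

## Verification choices

The NG86 implementation is checked against an independent brute-force
oracle (recursive pathway enumeration, genetic code taken from Biopython)
to 1e-9 over every sense-codon pair and thousands of random short
alignments. Corrected distances are compared only when the difference
proportion is at least 1e-6 away from the 3/4 saturation boundary, where
the correction's derivative diverges and the finite/undefined decision is
not numerically stable. ω recovery uses 200 replicate pairs of 2,000
codons at t = 0.3: the Monte-Carlo SE of the mean is well under the ±0.05
acceptance band at each ω ∈ {0.1, 0.5, 1.0}.
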