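# Methods

## Overview

thymoatac reimplements the analysis layer of a stage-resolved ATAC-seq
study as a reusable pipeline: per-stage Tn5 insertion counts and peak calls
go in; normalized accessibility clusters, motif-anchored footprint calls
and per-cluster enrichment tables come out. Because the real datasets this
kind of analysis consumes are large alignments produced by external tools
(read mapping, duplicate removal, peak calling are all out of scope), the
package ships a synthetic-data generator whose outputs carry ground-truth
labels; every claim the pipeline makes is tested as a recovery problem
against that truth.

## Coordinates and formats

All in-memory coordinates are 0-based half-open (BED convention); 1-based
coordinates exist only at display boundaries. Inputs and outputs are plain
text: BED3/BED6, ENCODE narrowPeak, per-strand bedGraph pairs for insertion
counts, FASTA, JASPAR PFM text, TSV and JSON. Insertion counts are the
pipeline's entry point; whether the upstream aligner applied the +4/−5 Tn5
offset is deliberately out of scope — the cut-track format is agnostic and
the generator plants its profiles directly in track coordinates.

## Accessibility matrix and normalization

Master peaks are the union of all samples' peak calls with overlapping and
bookended intervals merged (merge distance 0). FPKM for region *r* and
sample *s* is C(r,s) / (len(r)/10³ · depth(s)/10⁶), where C counts
fragments overlapping the region by at least 1 bp (any-overlap rather than
midpoint counting: the simplest contract, and the one documented here).
Libraries are first down-sampled without replacement to the median depth,
at the fragment level so read pairs stay intact.

The normalization chain is applied strictly in this order, and the matrix
records its state so the order cannot be violated silently:

1. each sample's column is divided by that sample's TSS enrichment;
2. robust scaling per column, (x − median) / IQR, with type-7 (linear
   interpolation) quantiles — stated explicitly because IQR conventions
   differ between environments;
3. each row is divided by its maximum across samples, so every region's
   most accessible stage scores exactly 1.

Step 3 reads "row-wise normalized by the maximum" as the row maximum across
samples: it is the only reading that makes rows comparable for k-means and
produces a 0–1 per-region scale. Rows whose post-scaling maximum is ≤ 0 or
whose values are all equal carry no relative information; they are zeroed,
flagged, and excluded from clustering. A zero column IQR is an error naming
the degenerate sample.

The TSS enrichment statistic is the mean aggregate insertion signal within
±250 bp of TSSs (profile oriented by TSS strand, built over ±1,000 bp)
divided by the mean over the two outermost 100 bp flanks, with a zero flank
total floored at one pseudo-insertion. The window sizes are this package's
choice: any positive per-sample scale factor preserves the downstream rank
structure, so the exact convention matters less than having one and
documenting it.

Replicate reproducibility is reported as both Pearson and Spearman
correlations of per-region fragment counts, because the two conventions
coexist in the literature this pipeline descends from; constant columns
yield NaN rather than an arbitrary value.

## Clustering and cluster descriptives

k-means uses scikit-learn's Lloyd algorithm with k-means++ initialization,
best of `n_starts` (default 1,000) random starts, seeded. The best-of-many
protocol makes the particular initialization variant immaterial. The k scan
(default 1..15) additionally warm-starts each k from the previous solution
plus its worst-fitting point and keeps the better fit, which guarantees the
reported WCSS curve is non-increasing in k. Defaults: k = 6, matching the
six accessibility archetypes the generator plants.

Cluster labels are attached by nearest-archetype template (stage-specific
unit vectors, all-ones, and a DN-elevated shared pattern); the mapping is
reported, not asserted.

TSS distance is measured from the region midpoint to the nearest TSS, 0 if
a TSS falls inside the region; distributions are compared pairwise between
clusters with two-sample Kolmogorov–Smirnov tests on log₁₀(d + 1)
(asymptotic p), Bonferroni-corrected by the number of pairs. Peak
categories use precedence promoter > exonic > distal, with the promoter
window strictly upstream of the TSS: [TSS − 200, TSS) on '+', mirrored on
'−'; an unstranded TSS is an error because "upstream" is undefined.

## PWM scanning with exact p-values

Scores are log₂(p<sub>b,j</sub> / background<sub>b</sub>) under a zero-order
background parameterized by GC fraction (default 0.417). PFM counts get a
0.25-per-cell pseudocount so log-odds stay finite. The null distribution of
the total window score is computed exactly by convolving per-column score
distributions, after discretizing each column's scores to integer bins of
1/1000 bit. The scanner and the p-value DP share the same integer bins: a
window's binned score is the sum of its per-column bins, so the reported
p-value is exactly the DP tail and hit sets agree with a brute-force oracle
to the last position. Both strands are scanned (the reverse strand via the
reverse-complement score table on forward coordinates); N bases contribute
score 0 (background); hits with p ≤ 10⁻⁴ (inclusive) are kept; hits
overlapping a blacklist by ≥ 1 bp are removed; overlapping hits for the
same motif are all retained since the downstream mixture model consumes
every match.

## Footprint mixture model

For each motif and sample a strand-specific count matrix is built over
±L bp (default L = 100, S = 2(2L+1) = 402 columns) around the motif center,
anchored at start + floor(width/2) — the left-of-center base for even
widths. Rows for '−'-strand occurrences are coordinate-reversed and
strand-swapped so all rows share the motif-relative frame; windows that
would run off a chromosome edge are dropped with a warning.

The two-component model is:

- Z<sub>l</sub> ~ Bernoulli(π<sub>l</sub>), logit π<sub>l</sub> = β·(1, score<sub>l</sub>);
- bound: R<sub>l</sub> ~ NegBin(μ₁, φ₁) and X<sub>l</sub> | R<sub>l</sub> ~ Multinomial(R<sub>l</sub>, τ);
- unbound: R<sub>l</sub> ~ NegBin(μ₀, φ₀) with the uniform profile 1/S,

with NegBin in mean/dispersion form (variance μ + μ²/φ). The prior
covariate is the PWM score only; sequence conservation and similar extras
are deliberately not modeled.

EM details, chosen so the recorded objective is provably non-decreasing:

- E-step: exact posteriors γ<sub>l</sub> = σ(η<sub>l</sub> + log P₁ − log P₀);
  the multinomial coefficient cancels between components and is omitted
  consistently from the recorded objective.
- τ update: closed form (Σ γ X + ε) / (Σ γ R + εS) with ε = 1 per column.
  This is the exact maximizer of the expected complete-data objective plus
  a Dirichlet smoothing term; the recorded trace is that penalized
  objective, so the τ smoothing never breaks monotonicity.
- NegBin updates: the posterior-weighted mean is the exact MLE of μ for any
  φ; φ is then maximized by bounded 1-D search on log φ (bounds 10⁻²..10⁶)
  with a keep-better safeguard against the previous value. Blockwise exact
  maximization was preferred over method-of-moments updates precisely
  because the latter cannot guarantee a monotone trace.
- β update: Newton/IRLS on the fractional-response logistic objective,
  ridge-stabilized, clipped at |β| ≤ 30 against separation, keep-better
  safeguarded.
- Initialization is deterministic: γ = 0.9 for rows in the top quartile of
  totals, 0.1 otherwise. If μ₁ < μ₀ after an M-step the components are
  swapped (γ → 1 − γ, β → −β, τ recomputed) to keep the bound component
  the high-count one.
- Convergence: relative objective change < 10⁻⁶, max 200 iterations;
  non-convergence returns the fit with a warning rather than an error.
- Fewer than 20 occurrences or an all-zero matrix is an error: the EM has
  nothing stable to fit.

A call is bound iff posterior > 0.99 (strict) and the motif interval is
entirely contained in a peak. Occupancy profiles divide the column-wise
aggregate over bound calls (optionally restricted to one cluster's regions)
by the aggregate over an equal-size seeded random sample of occurrences
with posterior ≤ 0.5 (non-strict) lying entirely off peaks, with a
pseudocount of 1 in numerator and denominator; a smaller-than-needed
unbound pool is used whole and flagged.

## Permutation enrichment

Overlap is measured in nucleotides (GAT's default statistic). The workspace
is merged; segments are clipped to it (a segment longer than every
workspace interval is an error). Each randomization independently re-places
every segment: workspace interval w is chosen with probability proportional
to max(len(w) − ℓ + 1, 0) and the start is uniform within the feasible
range. All annotation labels are scored against the same placements.
Expected overlap is the null mean; fold = observed/expected, with the
denominator floored at 1 bp only when the expected overlap is zero — the
floor exists to keep folds finite, and applying it above zero would bias
the ordinary sub-1-bp-expectation case away from its exact enumerable
value. Empirical p uses the +1/(n + 1) estimator (never zero), two-sided
via separate enrichment and depletion tails; default n = 1,000
randomizations. BH q-values are computed across motifs within each
(sample, cluster) family; the choice of family is this package's, since no
correction convention is canonical for such per-motif tables.

For footprint-in-cluster enrichment the workspace is the motif's
occurrences contained in master peaks, the segments are that motif's bound
calls in one sample, and the annotations are the cluster regions —
restricting the null to motif-sized, motif-placeable positions so cluster
composition, not motif density, drives the signal.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
desk scale:

- genome: i.i.d. bases at GC 0.417 (the scan background), default 2
  chromosomes × 160 kb;
- peaks: 25 peaks per archetype × 6 archetypes, 300 bp each, disjoint with
  ≥ 700 bp gaps; archetype membership determines which samples' PeakSets
  contain each peak;
- accessibility multipliers: stage-specific peaks are fully open (1.0) in
  their own stage and nearly closed (0.05) elsewhere; ubiquitous peaks are
  open everywhere; DN+ubiquitous peaks are fully open in DN and half open
  (0.5) elsewhere;
- motifs: two built-in sharp PWMs (14 and 12 bp, dominant-base probability
  ≈ 0.98) planted once per peak plus an equal number of decoys outside
  peaks, sequences sampled column-wise from the PWM, strand uniform; an
  occurrence is bound exactly in the samples where its peak is open
  (bound_fraction 1.0 by default);
- insertion counts: Poisson background (0.001/bp/strand), negative-binomial
  per-base counts in peaks scaled by the multiplier, and at each
  occurrence a NegBin total (bound mean 200, unbound mean 20, dispersion
  10) split multinomially over the footprint shape — multiplicative dip of
  0.4 over motif-covered positions, 1.8× flanking boost over 12 bp bands,
  15% strand asymmetry — or over a flat profile when unbound;
- fragments: per-peak Poisson counts proportional to the multiplier
  (mean 200 per fully open peak), length ≈ N(150, 40) bp, plus uniform
  background; each sample also gets a Bernoulli(0.5) pseudo-replicate
  split so replicate-correlation code has inputs;
- annotation: a TSS is placed immediately adjacent to 90% of ubiquitous
  peaks (alternating strands, close enough that the 200 bp promoter window
  reaches into the peak), plus background TSSs and exons, some of the
  latter overlapping non-ubiquitous peaks.

Bound-site count parameters (mean 200 vs 20, depletion 0.4) are the
conditions the recovery analyses are defined at. Everything is driven by
one integer seed; regeneration is byte-identical.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: Tn5 sequence bias and fragment-length structure,
nucleosome positioning, copy-number and mappability artifacts, overlapping
and nested peaks, motif clustering and cooperative binding, and realistic
motif information content. Recovery scores here (ARI 1.0, AUROC ≈ 1.0) are
upper bounds attainable when the model family matches the data exactly;
on real data the same machinery is expected to perform strictly worse.

## Pipeline scale and determinism

The default end-to-end run (simulate → matrix → cluster → scan → footprint
→ enrich → report) uses the generator defaults above — 150 master peaks,
two motifs, ≈ 600 occurrences per motif, 8 EM fits, 48 permutation tests —
and completes in well under a minute on one CPU; the test suite and the
acceptance script use the same sizes. All stage seeds derive from the one
config seed and are recorded, with output checksums, in `manifest.json`;
two runs with the same config are byte-identical. The `report` stage emits
TSV tables; plots are opt-in (`--plots`) so default outputs stay text-only.

## Known limitations

- The CENTIPEDE-style model here uses a single prior covariate (PWM score)
  and a single data type; multi-assay or conservation-aware extensions are
  out of scope.
- The exact-p DP assumes a zero-order background; Markov backgrounds are
  not supported.
- GAT-style isochore/mappability-aware randomization modes are not
  implemented; the workspace is the only constraint on placement.
- The elbow in the WCSS curve is reported, not used to choose k
  automatically; k is a user parameter (default 6).
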