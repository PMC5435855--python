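# Methods

This note documents the statistical procedures implemented in `srna-dekit`,
the parameters that matter, the design choices made where several defensible
options existed, and what the synthetic-data tests do and do not demonstrate
about real data.

## Data model and alignment

Reads are collapsed to unique sequences with integer abundances
(`ReadLibrary`); the *redundant* total counts every copy, the *non-redundant*
total counts distinct sequences. Sequences outside 15–35 nt are dropped at
ingestion (with a tally) — the window brackets all sRNA size classes of
interest with margin. U is normalized to T. Internal genomic coordinates are
0-based half-open everywhere; SAM (1-based) and GFF3 (1-based inclusive) are
converted at the I/O boundary, BED is used as-is.

Alignment is exact, full-length, ungapped, on both strands, reporting all
occurrences. In the 20–25 nt regime a single mismatch changes the identity of
an sRNA, so mismatch tolerance is deliberately omitted. The matcher hashes
library sequences (and reverse complements) by length and slides over each
chromosome once per distinct length — linear in genome size, independent of
read depth, and verified in tests against a brute-force both-strand scan.
Pre-computed SAM/BED alignments are accepted; gapped or clipped records are
skipped with a tally, since a non-full-length hit is not an identity match.

Annotation assigns class C to a read when at least one hit is fully contained
in a feature of type C. Containment is strand-agnostic by default (siRNAs
arise from both strands of a locus); a strand-aware switch exists. Reads with
no containing feature are `unannotated`.

## Quality checks

Complexity of a size class is non-redundant/redundant reads, in (0, 1]: values
near 1 mean a diverse pool of low-abundance variants, low values a few
dominant sequences. MA values use A = (a+b)/2 and M = log2(b/a) on pairs where
both abundances are positive; zero-containing pairs are excluded and tallied
rather than pseudo-counted — a diagnostic should not fabricate fold changes.
The per-size fold-change summaries use the same nonzero-pair rule, and their
single-number summary is the *centering score*: max over size classes of
|median M| (0 = replicates indistinguishable on average). Top-N Jaccard
defaults to N = 500; ties at the N-th abundance are broken lexicographically
so the result is deterministic. Quartiles everywhere are linear-interpolation
("type 7"). Abundance windows bucket nonzero abundances into [k·w, (k+1)·w)
so replicate distributions can be compared away from the overwhelming
low-abundance mass.

## Normalization

All six methods preserve zeros exactly and never produce negative values.
For scaling methods the normalization total T defaults to the mean of the
column sums: scaling far below the library sizes compresses expression and
hides DE; scaling far above inflates it.

* **Total count (RPM/RPT)**: value · T / column sum.
* **Upper quartile**: per-column factor = 75th percentile of the *nonzero*
  values. sRNA matrices are zero-dominated, so the quartile of the full
  column is frequently 0; restricting to nonzero values is the only reading
  that yields usable factors.
* **TMM**: M and A are computed against a reference column on library-scaled
  proportions (the canonical convention), restricted to sequences nonzero in
  both; the extreme 30% tails of M and 5% tails of A are trimmed; the factor
  is 2^(precision-weighted mean M), with inverse delta-method variances as
  weights; factors are rescaled to product 1. The automatic reference is the
  column whose nonzero upper quartile is closest to the mean of those
  quartiles. Under this convention a pure depth difference gives factor 1
  (depth is handled by the column-sum division), and columns that are exact
  scalar multiples normalize to equality — the invariant the tests assert.
  If fewer than 10 sequences survive trimming the untrimmed mean is used with
  a warning.
* **Median-of-ratios**: size factor = median over all-nonzero sequences of
  count / geometric mean across columns; columns divided by their factor.
* **Adapted quantile**: classic rank-wise-mean quantile normalization with two
  sRNA-specific rules: within-column ties all receive the mean of the
  reference values at their ranks, and original zeros are forced back to 0.
  On tie-free, zero-free matrices the method is idempotent.
* **Subsampling**: every column is drawn without replacement (multivariate
  hypergeometric on the collapsed counts) down to the minimum column sum.
  Step (i) checks distribution stability on a descending proportion grid
  (step 0.1) with a two-sample KS test on nonzero abundances (α = 0.05) and
  reports the first significant departure; step (ii) draws `n_boot` (default
  100) subsamples at the target, computes pairwise KS distances, flags a
  column when the median pairwise distance exceeds the 95th percentile of the
  subsample-to-original distances, and returns the medoid subsample (minimum
  summed distance), i.e. a draw representative of the distribution rather
  than an outlier. KS was chosen as the distribution-shape test because the
  quantity being preserved is the abundance distribution; test, α and grid
  step are configurable.

The evaluation report computes, per method × treatment × size class, the
quartiles of between-replicate M values on the normalized matrix and ranks
methods by centering score (with the raw matrix included as baseline). A good
normalization brings all distributions onto the 0 line.

## Noise offset from strand-bias KL curves

Windows of fixed length (default 1000 nt) tile each chromosome from position
0. Each genomic hit contributes count/(number of hits) to the strand-specific
abundance of the window containing its 5′-most genomic coordinate, so
multi-mapping reads conserve library totals. Strand bias is
plus/(plus+minus) ∈ [0, 1]; a symmetric definition would only relabel bins.

Nonzero windows are sorted by total abundance and grouped into consecutive
*levels* of at least `min_windows_per_level` (default 100) windows — a stable
histogram needs a minimum sample size — with the last level absorbing the
remainder; the level coordinate is the median window total. Per level, biases
are binned into `n_bias_bins` (default 100) equal bins on [0, 1] and the KL
divergence from the uniform distribution is computed in bits (the base only
rescales the curve; it cannot move the argmin). The curve is high at very low
abundance (one or two incident reads force bias to 0, ½ or 1), dips where
unbiased noise of moderate read count spreads bias broadly, and rises again
where strand-biased signal concentrates mass near 0 and 1. The per-sample
offset is the abundance at the global minimum of the LOESS smoothing
(degree 1, tricube weights, span 0.3, no robustness iterations — via
statsmodels lowess); ties resolve to the smallest abundance, and with fewer
than five levels (or heavily tied level coordinates) the raw curve is used
unsmoothed. The dataset offset is the minimum over samples; per-treatment
minima are also reported. Whether one KL point is computed per distinct
abundance value or per group of windows is a genuine design opening; the
level-grouping used here trades abundance resolution for histogram stability.

## Differential expression

CIs per treatment: min–max with two replicates (the maximal expression
interval), Chebyshev mean ± k·sd with three or more (sample sd, floored at 0;
k defaults to 2, distribution-free coverage ≥ 75%, configurable). Overlap is
closed-interval — touching endpoints give S — which avoids knife-edge DE
calls. U/D additionally requires |LOFC| ≥ threshold on the proximate extremes
(observed.lo vs reference.hi for U, observed.hi vs reference.lo for D);
otherwise the call demotes to S. For S calls an informational LOFC on
interval midpoints is reported but never used for calling or ranking; the
midpoint convention is this package's choice. Comparisons are consecutive
pairs in hierarchy order by default (time series); a vs-reference scheme
covers wild-type-versus-treatments designs. Clustering groups sequences by
exact pattern; the headline report suppresses groups of ≤ 15 members and the
all-S pattern.

## Synthetic data: what it emulates and what it does not

The generator emulates a replicated multi-treatment sRNA-seq experiment:
18–30 nt reads with a 22–23 nt peak; noise reads scattered uniformly with
uniform strand and geometric abundances (mean 2.5); strongly stranded signal
loci (plus-strand probability Beta(20, 1), mirrored to near 0 with
probability ½) with heavy-tailed expression — shifted Pareto (α = 0.8) above
the designed noise ceiling a₀ = 50, capped at 200·a₀ — so a minority of
sequences reach counts two orders of magnitude above noise, as abundant
miRNAs do; step fold changes (default ×8) spiked into 30% of loci at a random
time point; replicates differing only by a library-size factor and
multiplicative log-normal noise (sd 0.1). The default genome is 4 × 500 kb,
giving 2000 windows of 1 kb so the estimator's defaults (100 windows per
abundance level) yield ~20 abundance levels. Reads are exact genome
substrings by construction, so genome matching is 100% and alignment is
exercised end to end. A window-level shortcut generates `GenomeWindow`
profiles directly with the same abundance/bias models, which is what the
20-repetition offset-recovery study uses.

Not simulated: sequencing errors, ligation/adapter biases, multi-mapping
between distinct loci beyond chance repeats, cross-contamination, and
whole-size-class perturbations (e.g. RNAi mutants losing an entire class) —
for which no scaling normalization is adequate. Passing tests therefore
demonstrate correctness of the algorithms under the stated generative
assumptions, not robustness to those artifacts in real libraries.

## Numerical and reproducibility notes

Problem sizes in the test-suite and acceptance runs — 2 Mb genomes, ~20k
unique sequences per library, 20-repetition recovery studies — were chosen as
the smallest sizes at which every estimator operates in its intended regime
(enough windows per abundance level, enough qualifying spiked sequences).
All randomness flows through integer seeds (numpy `default_rng`); subsampling
normalization and the simulator are bit-reproducible under a fixed seed.
Writers emit sequences in lexicographic order so TSV outputs are byte-stable.
Offset-estimation tolerance is inherently one abundance-level spacing: the
estimate is a level median, so it cannot resolve the boundary more finely
than the level grid.

## Known limitations

* The offset estimator needs a reference genome (or precomputed alignments)
  and enough expressed windows (≥ 2 levels); genome-free workflows must
  supply a fixed offset.
* With exactly two replicates the min–max CI has no coverage guarantee; the
  U/D/S calls inherit its conservatism.
* Exact matching discards reads with any variation against the reference
  (SNVs, editing); their loss is visible in the genome-match QC.
* The adapted-quantile tie rule makes the method non-idempotent in the
  presence of ties (ties are averaged anew on each application).
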