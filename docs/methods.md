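# Methods

## Model and assumptions

The package analyses germline copy number measured by a two-channel SNP
array.  The copy-number signal for subject *i* at marker *j* is carried
by the total fluorescence of the two allele channels.  Because the dyes
differ systematically per marker, the A/B imbalance is estimated from
heterozygous subjects — whose true allelic ratio is 1 — as
ψⱼ = (1/K) Σ Aᵢⱼ/Bᵢⱼ over the K heterozygotes, and total intensity is
Iᵢⱼ = log₂(Aᵢⱼ + ψⱼBᵢⱼ).  Quantile normalization forces identical
intensity distributions across subjects, per-plate median normalization
removes batch offsets marker by marker, and subject centering
Zᵢⱼ = Iᵢⱼ − Īᵢ removes residual per-subject brightness.  On this scale a
single-copy loss sits near log₂(1/2) = −1 and a single-copy gain near
log₂(3/2) ≈ +0.58; in practice quantile normalization shrinks these
slightly (a planted −1 loss lands near −0.75 in the synthetic data).

Survival follows a proportional-hazards model with **left truncation**:
cases are diagnosed at time 0 but enter the study only at enrollment, so
a subject contributes to the risk set at event time *t* only if
entry < *t* ≤ exit.  Early deaths can never be enrolled; the
delayed-entry partial likelihood corrects the selection that this
induces.  All association tests — per-marker, per-region trend (state
coded −1/0/+1 as a continuous covariate, Wald test), 2-df categorical
(gain and loss indicators, likelihood-ratio test), and burden — are Cox
fits adjusted for study site indicators, age at diagnosis, and the
leading ancestry principal component(s); the number of components is a
parameter (default 1, and 2 is equally defensible — both adjustments are
supported).

## Numerical cores

**Cox engine.**  Newton–Raphson with step-halving on the delayed-entry
partial likelihood; Efron tie handling by default (less biased than
Breslow under heavy ties; Breslow available for cross-checks).
Convergence at relative log-likelihood change < 1e-9, cap 50 iterations.
Risk sums at each event time come from two descending cumulative sums
(over exits ≥ t and entries ≥ t), giving O(n log n + n p²) per
iteration.  Constant covariates raise a non-identifiability error;
monotone likelihoods (separation, |β| > 15 or a singular information
matrix) are flagged non-converged with p set to missing rather than
returning a spuriously small value.  Tests verify agreement with direct
numeric maximization of the same likelihood (1e-4), with lifelines on
both truncated and untruncated data, and exact reduction to the ordinary
Cox model when all entries are zero.

**Fused lasso.**  The −log₁₀ *p* profile of each chromosome is smoothed
by the exact minimizer of ½Σ(yₜ−fₜ)² + λ₁Σ|fₜ| + λ₂Σ|fₜ₊₁−fₜ|: the pure
fusion problem is solved with a direct O(n) taut-string style algorithm,
and the sparsity term is applied by soft-thresholding, which yields the
exact joint solution in one dimension.  Correctness is checked against
an independent split-variable quadratic program (SLSQP) to 1e-6.
Smoothing is per chromosome — fusing across chromosome boundaries is
biologically meaningless.  The fusion penalty default is a parsimony
rule (smallest λ₂ on a log grid giving at most √m distinct levels per
chromosome); it is a documented package convention, overridable
per run, since piecewise-constant smoothing tools typically tune
internally.  λ₁ defaults to 0.  Markers skipped in the scan
(near-constant Z, separation) are excised before smoothing and regions
of interest are reported over the surviving markers.

**Circular binary segmentation.**  Per sample and chromosome the maximal
arc statistic T = max |mean(arc) − mean(rest)| / (s·√(1/k + 1/(n−k)))
is computed over all arcs leaving every resulting piece at least
`min_width` (3) markers wide, and assessed by a permutation test
(α = 0.01, 1000 shuffles); accepted splits recurse (binary when the arc
touches a boundary, ternary otherwise).  Permutations are drawn in
escalating batches with deterministic early stopping: once the
exceedance count already forces p > α at the nominal 1000 shuffles the
decision cannot change and drawing stops, so clearly-null splits cost
~50 shuffles while borderline ones run the full 1000.  The split
decision is identical to the full test; only the reported p for
clearly-null splits is the coarser estimate from the shuffles actually
drawn.  There is no post-hoc "undo splits" pruning.  Everything is
deterministic given the seed.

**State calling and common regions.**  Segment means are classified per
sample against that sample's own percentiles of segment means (defaults
3rd/97th, unweighted; a marker-count-weighted variant is available).
A segment is a loss only if its mean is ≤ the lower threshold *and*
strictly below the upper one (symmetrically for gains), so degenerate
ties resolve to normal.  Recurrent regions are maximal marker runs where
≥ `recurrence` samples share the same alteration sign; a sample's state
in a region is its majority state over the region's markers, ties
normal.  Regions are tested with the trend model and Bonferroni-adjusted
over the number of testable regions (regions with a single state level
are reported untestable and excluded from the correction count).
Whether "recurrence = r" means ≥ r or > r is ambiguous in common tool
conventions; ≥ r is implemented.

**Local (region-of-interest) segmentation.**  Inside scan ROIs each
sample's Z window is segmented by recursive binary splitting with a
two-sample t-test criterion: a split needs p < 0.001, a standardized
mean difference ≥ 0.3 (the signal-to-noise parameter), and ≥ 5 markers
per side; the sample is called loss/gain when its most extreme candidate
segment mean is ≤ −0.3 / ≥ +0.15.  This realizes the documented
parameter semantics of a proprietary segmentation tool as a transparent
stand-in; note that strict top-down binary splitting is insensitive to
*interior* segments of modest amplitude (each single split dilutes them),
a known limitation stated here rather than papered over.

## Synthetic data generator

The generator emulates a three-site array study: per-site enrollment
proportions (0.33/0.47/0.20), age at diagnosis ~ N(59.4, 11²) years,
plates assigned round-robin, per-marker minor-allele frequencies uniform
on (0.05, 0.5) with Hardy–Weinberg genotypes, ~3% intensity-only probes,
and 0.5% missing genotype calls.  Intensities follow expected total
s_j·c/2 for copy number c (per-marker brightness s_j, log-normal SD
0.1), split between channels by B-allele dosage, with multiplicative
log-normal noise (σ = 0.15), per-(marker, plate) batch effects
(σ_p = 0.05), per-marker dye imbalance (log-normal SD 0.2) on the A
channel, and background ε = 0.05 at zero copies.  Copy number is capped
at 3: the analysis works with three-level states, so higher
amplifications add nothing testable.  Survival is exponential with
baseline hazard 1.9e-4/day (≈50% deaths under the 10-year
administrative censor), entry uniform on (0, 160) days (mean 80 days
diagnosis-to-enrollment), and subjects are redrawn until T > entry —
rejection sampling of the enrolled-cases law (discard-and-top-up would
give the same law).  Covariate effects default to log-HR 0.02/year of
age, ±0.1 by site, 0.1 per PC-1 unit, making PC-1 a genuine confounder
to adjust away.

What the generator does **not** emulate: linkage disequilibrium between
markers, genomic waves/GC content effects, intensity saturation (real
arrays compress gains below log₂(3/2)), population stratification beyond
a single confounder score, mosaicism, or the X chromosome.  Passing
tests therefore demonstrate the statistical machinery under a clean
array model, not robustness to every real-data artifact.

## Desk-scale study conditions and calling calibration

Default desk scale is 300 samples, 4 chromosomes × 500 markers.  The
calibration studies in `tests/test_acceptance.py` and
`scripts/acceptance.py` use:

- trend-test null calibration: n = 500 per replicate, 2000 replicates;
- hazard-ratio recovery: HR 1.75 at 20% carrier frequency, n = 1000,
  ~50% events, 200 replicates (the regime in which a cohort of ~1000
  cases is powered for common CNVs);
- CBS: planted 3-SD step at marker 50 of 100, and pure-noise profiles,
  200 seeded runs each;
- end-to-end detection: one planted loss with HR 2.0 at 15% frequency,
  n = 800, genome of 16 chromosomes × 25 markers, plus two
  survival-neutral gains (30% frequency) so the Bonferroni correction
  has genuine work to do; 50 replicates, and 50 full-null replicates
  for family-wise error.

Per-sample *relative* percentile calling always labels roughly one
lowest and one highest segment per sample, whatever the truth, so the
expected spurious per-marker coverage per alteration sign is about
n / n_chrom (each spurious call covers a whole noise chromosome and
lands on a uniformly random one).  The recurrence threshold must
therefore sit **between the spurious background n/n_chrom and the
planted carrier count**.  At full array scale (≈600k markers, ~1000+
segments per sample) the background is thin and the conventional
recurrence of 5 works; at desk scale the end-to-end study uses
recurrence 75 for n = 800 over 16 chromosomes (background ≈ 50,
carriers ≈ 120+).  This is an analytic consequence of the calling rule,
derived from the configuration, not a tuned constant; the package
defaults remain 3/97 percentiles with recurrence 5.

## Numerical conventions and degenerate inputs

- Marker positions are 1-based; segments and regions are closed bp
  intervals over their member markers; internal marker ranges are
  0-based half-open.
- QC removals use strict inequality (a call rate exactly at the
  threshold is retained); marker QC runs before sample QC, and sample
  call rates are computed over surviving SNP probes — the order is a
  fixed package convention.
- ψ falls back to 1 (the no-correction identity) for markers with no
  usable heterozygotes; heterozygotes with B = 0 are dropped from the ψ
  average and counted.
- Non-positive intensity totals are flagged missing, marker-median
  imputed for quantile normalization, and re-flagged afterward.
- Quantile-normalization ties take the mean of the pooled quantile
  values they span.
- Constant profiles segment to a single piece; constant covariates and
  single-level state vectors raise explicit identifiability errors.

## Known limitations

- The local ROI segmenter is a stand-in for a proprietary tool; only its
  published parameter meanings, not its internals, are reproduced.
- Burden counts ignore segment sizes by design (breakpoint estimation
  from array data is unreliable); the marker-weighted option is an
  extension, off by default.
- The percentile-based caller is frequency-calibrated, not
  amplitude-calibrated: at small segment counts per sample it forces
  tail calls (see the calibration note above).
- Wald p-values are reported for trend tests; Wald and LRT agree
  asymptotically but can diverge in tiny strata or near separation,
  where fits are flagged instead.
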