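# Methods

## Data model

One AFE export per array parses into a `FeatureTable`: per physical feature
(spot) the probe name, the microRNA it interrogates, the raw mean signal,
the AFE background-subtracted signal, the control type and the per-feature
detection flag.  The probe→gene layout with replicate multiplicities
(`ArrayDesign`) is inferred from the experimental features and must agree
across arrays.  Controls — nonzero ControlType, or a gene id with a control
prefix — are kept in the table for QC but excluded from every estimation,
normalization and summarization step: positive controls on these arrays are
sample-dependent and unusable for normalization, and negative controls
carry no signal.

Missing numeric cells are an error, not imputed: AFE exports are dense, so
a hole indicates corruption.  Gene identity is the AFE SystematicName.

## The four processed signals

**Total gene signal (TGS).**  Per probe, the robust average of its
replicate features' background-subtracted signals times the replicate
count; per microRNA, the sum of its probes' totals.  The default robust
average is the plain median: the vendor's own "robust average" procedure is
proprietary and unpublished, and the median is deterministic, documented
and testable.  An outlier-trimmed mean (drop beyond 1.5×IQR from the
quartiles, then mean) is available as an option.  A scaling convention note:
"total probe signal × number of probes" double-counts when probes disagree;
we accumulate Σ_probes (robust average × replicate count), which coincides
with the literal product when all probes agree.  TGS can be negative
(background-subtracted inputs can be), so before any log transform the
whole matrix is offset by |global min| + 2 when the minimum is ≤ 0 — a
single global constant, because per-column shifts would distort exactly the
between-array relations the subsequent normalization relies on.  After a
shift the global minimum is exactly 2.

**nor75.**  Each array's offset TGS is divided by that array's 75th
percentile, leaving every array with a linear-scale 75th percentile of
exactly 1, then log2.  Quantiles interpolate linearly between order
statistics (position 1 + (n−1)q), the convention of the major statistical
environments; this has to be pinned for the "equals 1" contract to be
exact.  The 75th percentile rather than the median is the vendor's
recommendation: if about half the microRNAs are unexpressed, the 75th
percentile is the median of the expressed half.  Whether the offset
precedes the scaling is not externally fixed; we offset first, since the
scaling requires positive percentiles.

**norQ.**  Offset TGS, quantile-normalized between arrays, log2.  Quantile
normalization replaces each value by the mean of same-rank values across
arrays (reference distribution = row means of the column-sorted matrix);
ties within a column receive the mean of the reference values their ranks
span — deterministic, and identical to limma's implementation (verified in
the test suite to 1e-10).  Idempotence holds exactly for tie-free columns;
tie-averaged values leave the common multiset, so a second pass can shift
them slightly — inherent to the tie rule, not an implementation artifact.

**norRMA / norRMAbg.**  Feature-level raw mean signals (experimental
features only) are quantile-normalized between arrays, log2-transformed,
and collapsed to probe level by the median over each probe's replicate
features (mean-of-middle-pair for even counts).  Each microRNA's probe ×
array matrix is then fitted with the additive model signal = microRNA value
+ probe effect + error by Tukey's median polish; the per-array microRNA
estimate is the overall effect plus the column effect, the probe (row)
effects absorbing probe affinity.  Median polish sweeps row medians first,
then column medians, re-centering the effect vectors each sweep; iteration
stops when the sum of absolute residuals falls by less than 1% (relative)
in a sweep, or at 10 sweeps — classical defaults, pinned so an
independently coded reference implementation reproduces the fit
cell-for-cell.  Residuals are recomputed from the final effects, so
overall + row + column + residual reconstructs the input to machine
precision.  Single-probe microRNAs (2 on this layout) pass through
unchanged.  norRMAbg additionally background-corrects each array's mean
signals first (below).

## Background correction

The convolution model takes the observed intensity as S = X + Y with true
signal X ~ Exp(α) and optical background Y ~ N(μ, σ²).  The posterior of X
given S = s is N(a, σ²) with a = s − μ − σ²α, truncated to [0, s], and the
correction is its mean

    E[X|S=s] = a + σ (φ(u) − φ(v)) / (Φ(u) − Φ(−v)),   u = a/σ, v = (s−a)/σ.

Numerics: for dim features both Φ terms sit in the far left tail and nearly
cancel; the ratio is evaluated in log space with expm1 (the difference of
log-pdfs is computed analytically as −(v−u)(s/σ)/2), which is accurate all
the way to s → 0⁺ — verified against direct numerical integration of the
truncated normal.  Bright features use the direct form, which is benign
there.  Observed s ≤ 0 lies outside the truncation interval; there the
untruncated asymptote a + σφ(u)/Φ(u) (computed via erfcx, which never
under- or overflows) is used, and all outputs are floored at 2⁻²⁰.  On the
positive axis the correction is strictly increasing; across s = 0 the two
regimes do not join monotonically, which is irrelevant for array data
(mean signals are positive) but worth knowing for generic inputs.

Parameters are estimated per array — background level is an array property
— from experimental features only, by the method of moments:
E S = μ + 1/α, Var S = σ² + 1/α², E(S−ES)³ = 2/α³, so α = (2/m₃)^{1/3},
μ = mean − 1/α, σ² = var − 1/α².  We chose moments over the traditional
density-mode heuristic deliberately: the mode of the convolution sits at
μ + σz* with z* solving σαΦ(z) = φ(z) (≈ 1.7σ for typical parameters), so
a mode-read μ is biased upward by tens of intensity units, while the moment
estimator recovers μ to within a couple of units at n ≈ 10⁵ (α to ~2%).
When the sample skewness is non-positive or the implied σ² is negative —
data with no visible exponential component — the estimator falls back to
the mode heuristic (Silverman-bandwidth Gaussian KDE mode for μ, RMS of
below-mode deviations for σ, 1/mean excess above the mode for α).  σ from
the moment route is the noisiest of the three (its sampling error scales
with the signal variance); α and μ are the quantities the correction is
sensitive to.

## Replicate-precision QC

Per biological group, per microRNA: mean and sample SD (n−1) of the log2
signal across the group's replicate arrays.  SD is computed within groups
because biological replicates exist only within a group; profiles are
overlaid across groups.  The SD-vs-mean trend is a least-squares fit of a
natural cubic spline with 5 knots total, placed at the {1/6, …, 5/6}
quantiles of the mean intensities, linear beyond the outer knots.  The
basis is patsy's natural cubic regression spline with explicit boundary
knots; the test suite verifies it spans the same space as the
truncated-power natural basis (fitted values to 1e−8) and that affine data
are reproduced exactly.  RLE is each array's signal minus the per-gene
across-array median, summarized per array as a five-number summary; after
effective normalization every array's RLE distribution is centered on zero.

## Detection filter

AFE's per-feature IsGeneDetected flag is aggregated to a gene-per-array
call: detected when more than a threshold fraction of the gene's features
are flagged (default: strict majority; "any" and "all" semantics are one
parameter away, since AFE's own gene-level aggregation is unpublished).  A
microRNA is kept when it is detected in at least `min_fraction` of the
arrays of at least one group (default 1.0 — every replicate of some group,
the strictest reading of "expressed in at least one group").  Controls are
removed unconditionally, and the full audit trail of calls is returned.

## Synthetic data

The generator emulates the v2.0 layout — 799 microRNAs × 16 features, the
(362, 45, 390, 2) × (2, 3, 4, 1) probe composition, 16 features split as
evenly as possible across a gene's probes (6+5+5 for three; real arrays
may split differently, the grid file being unavailable) — plus 20 negative
control probes at pure background and 4 positive-control targets × 4
probes × 5 replicates whose brightness varies per array.

Signals follow the background model's own assumptions: per-gene baseline
linear expression s_g ~ Exp(scale 500 intensity units), so the marginal of
the true signal across genes is exponential; per-group effects
N(0, 0.5 log2 units); probe affinities N(0, 0.5 log2) fixed across arrays;
per-feature noise N(0, 0.25 log2); additive background N(50, 10) intensity
units, clipped at 0.  The background-subtracted channel is mean signal
minus the true background mean, so it can be negative, as in AFE exports.
Defaults emulate an 8-array study: 2 tissue groups × 4 biological
replicates.  The detection flag is threshold-based (AFE's logic is
proprietary): a gene is detected on an array when its median feature
signal exceeds 568 = bg_mu + scale·ln(1/0.355), placing the detected
fraction near 35%, the fraction observed on real arrays of this design.
Everything derives from one integer seed; identical config and seed
reproduce the tables bit for bit.

What the generator does *not* emulate: spatial intensity gradients (the
AFE detrending surface is taken as given upstream), saturation,
probe-sequence-specific cross-hybridization, and the heavier-than-lognormal
tails of real probe effects.  Two consequences for interpreting green
tests: (i) the exp+normal background model is exactly true here, so the
background-correction recovery results are a best case; (ii) because probe
affinities are drawn additively in log space, median polish can cancel them
essentially perfectly, which real sequence-dependent effects only
approximate.  One known deviation in the opposite direction: the lognormal
probe/noise modulation inflates the third moment of the intensity marginal,
biasing the moment estimator's μ upward by a fraction (~0.2) of the signal
scale on simulated full-pipeline data — the tests assert exactly this
documented behavior, and exact recovery is asserted only on unmodulated
draws from the pure model.

## Problem sizes

Unit tests run on a reduced layout (9–15 genes) where the full one adds
nothing; pipeline-contract, RLE and filtering tests use the full 799-gene
× 8-array layout.  The replicate-SD method comparison is established
across 10 independent simulations of the full layout, and the
background-correction closed form is validated against a 10⁷-draw
Monte-Carlo conditional expectation; both run in well under a minute.

## Known limitations

- The AFE "robust average" and gene-level detection logic are proprietary;
  the median default and majority aggregation are documented stand-ins, so
  TGS values and kept-gene counts can differ from AFE's own output in ways
  that are configurable but not exactly reproducible.
- σ̂ from the moment estimator is noisy on small arrays; the correction's
  output depends on it only mildly (through σ²α and the truncation), but
  per-array parameter logs should be inspected for outliers.
- Quantile normalization forces identical intensity distributions; true
  global shifts in microRNA content between groups are normalized away, a
  property of the method rather than of this implementation.
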