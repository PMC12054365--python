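# Methods

## Scope and assumptions

`sxcalib` operates strictly downstream of integration and scaling: the
input is a table of symmetry-reduced, scaled reflection observations
(intensity, counting sigma, lattice id) plus one quality score per
lattice.  No space-group machinery, partiality or absorption correction
is included; negative intensities are retained (weak reflections are
legitimately negative after background subtraction) and only
non-positive or non-finite counting sigmas are rejected at read time.
Observations within a Miller group are assumed independent; the acentric
Wilson distribution is assumed wherever intensity statistics are invoked
(centric reflections follow a different law and are out of scope).

## Error models

Both calibrations transform the counting sigma; observed intensities are
never rescaled (any gain correction belongs to the scaling stage).

* Ev11: `sigma'^2 = s_fac^2 (sigma^2 + s_B <I_h> + s_add^2 <I_h>^2)`,
  global parameters.  `<I_h>` is the all-in ("biased") group mean.
* MM24: `sigma'^2 = s_fac^2 (sigma^2 + s_add(cc_l)^2 <I_h>^2)` with
  `s_add(cc) = s_add_0 + s_add_1 exp(-s_add_2 cc)`.  The exponential form
  guarantees positivity and monotone decay in the lattice quality score;
  a polynomial could cross zero and produce division-by-zero in the
  normalization.  The `s_B` term is dropped: it is collinear with the
  other terms and has no physical meaning.  `s_fac` sits outside the
  whole bracket in both models, keeping the two transforms nested.

The leave-one-out residual variance in the Ev11 deviations is
`sigma'_hk^2 + (sum_{j != k} sigma'_hj^2)/(n-1)^2`, which is exact for
independent, possibly heteroskedastic members and reduces to
`sigma'^2 (1 + 1/(n-1))` in the identically distributed case.  The
numerator uses the leave-one-out mean; every other use of `<I_h>` is the
all-in mean.

## MM24 objective

The loss is the negative log-likelihood of the observed pairwise
differences.  With pair scale `s_p = (sigma'_j^2 + sigma'_k^2)^(1/2)` and
`omega_p = |dI_p| / s_p`, each pair contributes
`-log p_std(omega_p) + log s_p`, where `p_std` is the standard
half-normal or half-t kernel.  The `log s_p` change-of-variable term is
essential: dropping it would make the objective decrease monotonically as
the sigmas are inflated (omega → 0 sits at the kernel mode) and the fit
would diverge to the parameter bounds.  Gradients over
(s_fac, s_add_0, s_add_1, s_add_2, nu) are analytic (digamma terms for
nu) and verified against central finite differences at 1e-5 relative
tolerance in the test suite.

Degrees of freedom are optimized on a log scale inside bounds
[1.5, 200]; the lower bound keeps the kernel integrable with a finite
mean, the upper bound is numerically indistinguishable from the
half-normal limit.  Other bounds: s_fac in [1e-3, 1e3], s_add_0 and
s_add_1 in [0, 10], s_add_2 in [0, 50].  Optimization uses scipy's
L-BFGS-B.  On exactly Gaussian synthetic noise the fitted nu runs to its
upper bound, as it should.

### Pair subsampling and determinism

At most 100 pairs per Miller index (configurable `cap`) are used.  Pairs
are enumerated lexicographically over observations sorted canonically by
(h, k, l, lattice_id, intensity, sigma); when the candidate count exceeds
the cap, exactly `cap` pairs are drawn without replacement by a fresh
`numpy` PCG64 generator whose seed is Cantor's pairing function applied
iteratively to the Miller indices shifted by +1000 (plus an optional user
offset).  The RNG algorithm is pinned by name so the subsample — and
therefore the fit — is bit-reproducible across runs, platforms and any
partitioning of the table.  The intensity/sigma tie-breakers in the
canonical sort make the enumeration invariant to input row order even
when one lattice holds several observations of the same index.

### Initialization

`s_add_0` and `s_add_2` start at 0.001.  `s_fac` and `s_add_1` come from
a least-squares fit of the binned mean absolute raw pairwise differences
`<|dI|>_b` (100 even bins spanning [0, 0.1 max<I_h>]; groups outside the
range excluded; bin centers as `<I>_b`) against
`(2/sqrt(pi)) s_fac (<sigma^2>_b + s_add_1^2 <I>_b^2)^(1/2)` — the mean
of `|X - Y|` for two N(mu, sigma_err^2) variables is
`(2/sqrt(pi)) sigma_err`.  The first populated bin's mean, an estimate of
the nonzero error of low-intensity reflections, anchors the starting
value of `s_fac` in this inner fit.  An additive offset in the fitted
curve was considered and rejected: it makes the model unable to recover a
known `s_fac` even on data with purely counting noise, because the
offset and the sigma term then describe the same quantity twice.  With
fewer than three populated bins the initialization falls back to
(1.0, 0.05) with a warning.

## Ev11 objective

Deviations are pooled in 100 intensity bins evenly spanning
[min <I_h>, max <I_h>] (assignment half-open, max closed into the last
bin; `m_b` counts observations of groups with multiplicity >= 2; empty
bins are skipped).  The target is `sum_b sqrt(m_b) (RMS_b(delta) - 1)^2`
— the square-root weight is the middle ground between weighting bins
equally and weighting observations equally.  Initialization: s_fac from
the overall RMS deviation under the identity transform, s_B = 0,
s_add = 0.01.  Analytic gradients, L-BFGS-B, bounds s_fac in
[1e-3, 1e3], s_B in [-1e3, 1e3] intensity units, s_add in [0, 10].

## Merging and statistics

Inverse-variance merging uses w = 1/sigma'^2, merged sigma
(sum w)^(-1/2); unweighted merging uses the arithmetic mean with the
standard error of the mean (single observations keep their calibrated
sigma).  No sigma or intensity cutoff is applied; the only filter is the
per-lattice correlation filter (threshold -1 disables it, the normal
operating mode; 0.1 is the suggested setting when data quality is
suspect).  No post-merge rescaling of the merged sigmas is applied.

Resolution shells are equal-volume (even in 1/d^3), count configurable.
CC1/2 splits each Miller group into two halves with the same
deterministic per-index generator used for subsampling (odd group sizes
place the extra observation by the same generator — an odd/even split by
input position would be biased by ordering); each half is merged and
CC1/2 is the Pearson correlation across groups with members in both
halves, per shell and overall.  Shells with fewer than three usable
groups are reported as NaN.

## Second-moment diagnostics

For acentric Wilson intensities the second moment `<I^2>/<I>^2` in a
shell is 2.  Gaussian measurement error on the normalized intensity
Z = I/Sigma yields an exponentially modified Gaussian for the observed
Z with mean 1 and variance 1 + sigma_Z^2, so the expected second moment
is `2 + <sigma_Z^2>`, with sigma_Z = merged sigma / shell mean and the
shell aggregating individual sigma_Z as the mean of squares (the
variance-consistent pooling).  The algebra is validated in the test
suite by direct simulation (Exp(1) + N(0, sigma_Z^2) reproduces
2 + sigma_Z^2 to Monte-Carlo precision).  Note the "= 2" statement
presumes an approximately constant Sigma within a shell: very wide
low-resolution shells on steeply falling Wilson curves mix different
means and sit genuinely above 2.  The simple MAD-based Z-filter
available in the diagnostics module is off by default and is *not*
equivalent to the outlier rejection and anisotropic-B correction that
phasing pipelines apply before their own second-moment analysis.

Rankit profiles use Blom plotting positions (i - 0.375)/(n + 0.25)
against the half-normal or half-t inverse CDF; exact order-statistic
means are not needed at these sample sizes.  Correct calibration puts
the sorted omega on a unit-slope line through the origin.

## Synthetic data generator

The generator emulates exactly the statistical structure the calibrators
assume, with ground truth retained:

* Miller indices from a reciprocal grid inside a resolution window
  (default 1.6-30 Å in a 60×70×80 Å orthorhombic cell); shell mean
  Sigma(d) = scale exp(-B/(2 d^2)) (defaults scale 2000, B 30 Å^2 —
  a typical protein falloff); true intensities Exp(Sigma(d)).
* Default 5000 Miller indices at mean multiplicity 20 (2 + Poisson, so
  every group is calibratable) over 200 lattices — about 1e5
  observations, the scale at which parameter recovery is validated.
* Per-lattice latent quality q in (0,1], mapped monotonically to the
  quality score cc_l, evenly spread over [0.15, 0.97] (the range over
  which the s_add(cc) curve is exercised), and to a mild counting-noise
  inflation (up to 3x for the worst lattice).  Counting sigmas follow
  sqrt(max(I, floor) + background).
* Observation noise has SD exactly
  `s_fac (sigma_count^2 + s_add(cc_l)^2 I_true^2)^(1/2)` (defaults
  s_fac 1.2, s_add_0 0.01, s_add_1 0.15, s_add_2 2.0), drawn Gaussian or
  Student-t rescaled to the same SD; optionally a stated fraction of
  observations is replaced by 100x-inflated intensities.
* The lattice records carry the assigned score cc_l; the correlation
  each lattice realizes against the true intensities is kept in the
  ground truth.  The two are deliberately distinct: the realized
  correlation is *determined* by the noise level, and at fractional
  errors below ~20% every lattice would realize cc near 1 — the score
  must be an independent covariate (as it is in the real pipeline,
  where it comes from upstream scaling) for the per-lattice error law
  to be identifiable over its whole range.  The realized correlation
  remains monotone in q, which is the property the score is meant to
  proxy.
* An alternative, deliberately mis-specified quality map ("power") is
  available for model-mismatch studies.

What passing tests on this generator do and do not show: they establish
correctness of the estimators under their own assumptions (independent
noise, exact model form, known scores).  Real serial data additionally
carry partiality residuals, non-Gaussian integration errors, correlated
per-frame effects and scoring noise, none of which are emulated; the
robustness and diagnostic machinery exists precisely because real data
violate these assumptions in unknown ways.

## Validation design choices

* Recovery checks run at ~1e5 observations, where the s_add(cc) curve is
  recovered within a few percent pointwise on cc in [0.2, 0.95] and
  s_fac within ~1%.
* The outlier-robustness comparison (half-t shift vs half-normal shift
  of s_fac under 1% gross outliers) holds nu fixed at 7 so the scale
  parameter is compared at matched kernel shape; with nu free the kernel
  re-shapes under contamination and its scale is not commensurable with
  the half-normal one.
* The Kolmogorov-Smirnov self-consistency check keeps one pair per
  Miller group: pairs within a group share observations, and the KS
  null requires (approximate) independence.
* Distributional checks (unit RMS, unit rankit slope, folded-difference
  mean) use counting-only configurations where the reported sigma is the
  entire true error, making the expected values exact rather than
  approximations contaminated by the finite-multiplicity estimate of
  `<I_h>`.

## Known limitations

* Acentric-only statistics; no Bijvoet separation, no twinning tests
  beyond the second moment.
* The all-in mean `<I_h>` in the sigma transforms is a finite-sample
  estimate; at low multiplicity or with gross outliers it biases both
  calibrations (outliers inflate their group's mean and hence the
  modeled variance of every member).  This is a property of the method,
  not of the implementation.
* The initialization's binned least squares assumes the bulk of
  intensities lies an order of magnitude below the maximum; pathological
  intensity distributions fall back to fixed starting values.
* MTZ support is read-only and heuristic about column labels.
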