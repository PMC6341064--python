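# Methods

## Signal model and preprocessing

A DSC-MRI acquisition is a 4D array `(x, y, slice, time)` of T2*-weighted
signal with repetition time TR (frame spacing, seconds) and echo time TE.
During the first pass of a gadolinium bolus the signal drops transiently;
under the standard single-compartment T2* model

```
S(t) = S0 · exp(−k · C(t) · TE),
```

so concentration is recovered as `C(t) = −ln(S(t)/S0)/TE` with `S0` the mean
over the pre-bolus baseline frames (default 8; at least 3 are required).
Voxels with nonpositive `S0` are undefined; nonpositive samples are clipped
to `1e−3·S0` before the logarithm.

Every time course is smoothed with a centered plain moving average
(default window 3 frames — the minimal symmetric window that suppresses
frame-to-frame noise while preserving sub-peak structure at both protocol
TRs; edges use the truncated window so a constant curve is unchanged).
Absolute TTP is the argmin of the smoothed *signal* within the first-pass
window, ties broken toward the earliest frame; no curve model is fitted for
the distribution-based parameters, and TTP lives on the TR grid — temporal
precision is deliberately controlled by TR alone. Since the signal-to-
concentration map is monotone decreasing, the signal argmin and the
concentration argmax give identical maps (asserted by test).

The first-pass window is detected on the brain-mean curve: it opens at the
first frame more than `k_sd` (default 2.0) baseline standard deviations
below the baseline mean and closes after the contiguous sub-threshold run,
extended by one smoothing window. A flat series raises "no bolus detected".

## The TDC and its double-Gaussian model

The TTP histogram over the first-pass window (bin width TR) is the TTP
distribution curve. It is modelled by a two-component Gaussian mixture
fitted by expectation-maximization on the raw TTP sample:

* fixed two components; weights constrained to sum to 1; components reported
  in ascending-mean order;
* initialization: means at the 40th and 90th sample percentiles, both SDs at
  half the sample SD, weights (0.8, 0.2); 5 seeded restarts (later restarts
  perturb the means, scale SD/4), best log-likelihood wins;
* convergence when the log-likelihood increase falls below 1e−6, cap 500
  iterations; a component whose SD collapses below 1e−8 of the sample SD
  aborts that restart; all restarts degenerating is an error;
* the per-iteration log-likelihood trace is stored and its monotonicity is
  asserted in the tests.

The EM is implemented in-package because the surrounding machinery needs
the loglik trace, the specific initialization and the restart policy;
`sklearn.mixture.GaussianMixture` is used as an independent cross-check in
the test suite, never as the implementation. On a sample that is truly a
single Gaussian the two-component likelihood is flat along a ridge of
equivalent splits; the *mixture* (not the individual components) is then
the identified object, and the tests check it against the sample moments.

The voxel score is the probability-weighted sum of per-component z-scores

```
z_f = k₁(ttp − μ₁)/σ₁ + k₂(ttp − μ₂)/σ₂,
```

implemented exactly as written; with k = (1, 0) it reduces to the classical
z-score. Note z_f is affine and strictly increasing in ttp, so thresholding
in z_f is equivalent to thresholding in ttp; the model also exposes the
mixture pdf/cdf for reporting. (The alternative reading of the score as the
quantile transform of the mixture CDF is deliberately not implemented; the
printed weighted-sum formula is authoritative here.)

### Venous inflection point

IPv is the latest curvature change on the descending (wash-out) limb of the
fitted density: sign changes of the analytic second derivative are bracketed
on a grid of spacing TR/10 over `[μ₁, μ₂ + 4σ₂]`, restricted to brackets
where the density slope is negative, and the latest bracket is polished by
Brent root finding (so the single-Gaussian case returns μ+σ, i.e. z_f = 1,
to machine precision). If no root is bracketed the fallback is μ₂ + σ₂.

## Standardization

A VOI is one slice by default (whole-brain is also available). The arrival
offset is the lower-tail quantile of the VOI's values — 3% for TTP, 2.275%
for z_f — using linear interpolation between order statistics (the
convention is a package choice; quantiles are translation-equivariant under
it). Standardization is the clamped subtraction `max(0, value − offset)`.
VOIs with fewer than `ceil(1/p)` defined voxels inherit the whole-brain
offset and are flagged in the offset table.

For TTP maps the subtraction is computed in the integer frame domain,
`(frames − x_l) − g·(x_{l+1} − x_l)` with `x_l` the anchor order statistic
and `g` the interpolation fraction. Every floating-point operand in that
expression is invariant under a constant integer shift of the slice's
frames, so per-slice delays cancel *bit-exactly* — the seconds-domain
formulation `max(0, ttp − offset)` is equal in real arithmetic but not
bit-stable. Reported offsets agree with the naive formulation to 1 ulp.

For stdZ, voxels with z_f < −3 are first excluded entirely (sentinel; they
enter neither offset estimation nor evaluation denominators) and the offset
is the empirical 2.275% quantile of the VOI's remaining z_f values under the
single global mixture fit. A per-slice mixture re-fit was considered and
rejected: it is numerically fragile at per-slice sample sizes, and the
standardized-score construction parallels the stdTTP offset, which is
empirical. The two rules — a 2.275% offset (the z = −2 tail) and a −3
inclusion bound — are independent and both applied as stated.

### Thresholds

Fixed: Tmax ≥ 6 s, stdTTP ≥ 7 s. Model-derived: z_f ≥ z_f(IPv); for stdZ
the threshold is the standardized equivalent, `max(0, z_f(IPv) − offset)`
per VOI, consistent with thresholding after the same transformation the map
received.

## Reference Tmax pipeline

* **Gamma-variate pre-fit** (Tmax branch only, on by default there; never
  used for the distribution parameters): `C(t) = K(t−t0)^α exp(−(t−t0)/β)`,
  zero for t ≤ t0. For fixed t0 the model is linear in (ln K, α, 1/β) on the
  log scale, so the fit is a weighted linear least-squares solve (weights ∝
  concentration, countering the log-domain distortion) inside a bracketed
  scalar minimization of the linear-domain residual over t0. Only the first
  pass is fitted (points up to the first post-peak drop below 30% of peak).
  Failures pass the raw curve through with a flag, never abort a map.
* **AIF selection**: candidates are brain voxels in the lowest 1% of TTP and
  the top 5% of peak concentration; ranked by ascending FWHM; the best 5
  curves are averaged. Deterministic given the inputs.
* **sSVD**: lower-triangular Toeplitz convolution matrix scaled by TR;
  singular values below `lambda_rel = 0.20` of the largest are truncated.
* **oSVD**: block-circulant embedding after zero-padding to 2N; per voxel
  the relative truncation threshold is raised along a ladder (0 plus 40
  geometric steps from 1e−4 to 0.5) until the oscillation index of the
  residue — mean absolute second difference normalized by `2·L·max|R|` —
  falls below `oi_threshold = 0.095`; if it never does, the most regularized
  solution is kept. Residue indices in the upper half of the circulant grid
  are negative lags, which is what makes the estimate delay-insensitive.
* **Tmax** is `TR · argmax` of the scaled residue (earliest tie wins), with
  no sub-TR interpolation. Both modes are available at any TR; nothing
  couples the mode to the protocol.

The truncation constants are the conventional methodological values; they
are not tuned per dataset. Note sSVD's residue estimate oscillates for
delayed residues (its documented delay sensitivity); the forward–inverse
consistency property (relative L2 error ≤ 10% on noiseless pairs at default
truncation) therefore holds for sSVD on undelayed residues and for oSVD
regardless of delay, and a residue with a flat top has no well-defined Tmax
at all — the synthetic pairs in the tests use delayed decaying-exponential
residues, the physiological shape.

## Evaluation

Confusion counts are taken inside an evaluation region (brain mask minus
sentinel-excluded voxels). Quality factors: sensitivity, specificity,
accuracy; an empty denominator yields "undefined", never 0. The ROC AUC is
the rank (Mann–Whitney) estimator with half credit for ties; the 95% CI
uses the DeLong placement-value variance (implemented directly; the AUC is
cross-checked against exhaustive pairwise concordance and sklearn). The
best-parameter odds ratio uses a 2×2 table with 0.5 continuity correction
on zero cells, normal-approximation CI and two-sided p, reported on the log
scale; ties for best accuracy within a measurement count every tied
parameter as best. Sørensen–Dice is intentionally absent (dropping true
negatives over-weights unspecific parameters); a Jaccard helper exists for
phantom QA only.

## The synthetic phantom

Each brain voxel carries a unit-peak gamma-variate concentration curve
(shape 3, scale 1.5 s → tissue first pass of ~10 s width) starting at
`tissue_arrival + slice_delay(slice)`, converted to signal with
`k = 18 a.u.` (≈40% peak signal drop at TE = 29 ms); Gaussian noise with SD
`S0/SNR` is added (no Rician correction — magnitude bias is negligible at
the simulated baseline SNR ≥ 20). Defaults: 32×32×8 grid, baseline signal
100, per-slice delays ramping linearly 0–2.1 s, tissue arrival 12 s,
SNR 20, and a spherical lesion (radius 3 voxels) whose bolus is delayed
10 s, dispersed ×1.3 and attenuated to 0.7 — an unambiguous hypoperfused
core. Four "artery" voxels per slice lead tissue arrival by 1 s with 3×
amplitude and a narrower bolus; they are the intended AIF targets and also
the physiological early tail that feeds the 3% offset. Two protocol presets
mirror common clinical settings (TR 1.390 s / TE 29 ms / 80 frames at 3T;
TR 0.689 s / TE 17 ms / 81 frames at 1.5T; sampling rates 0.72 and
1.45 Hz). Ground truth is the analytic peak time `t0 + α·β` per voxel plus
the geometry masks. Identical specs (including seed) give bit-identical
phantoms.

What the phantom does *not* emulate: head motion, susceptibility artifacts,
partial-volume vessels, contrast extravasation, recirculation (a second
delayed bolus can be enabled through a custom spec), heterogeneous tissue
classes, or realistic infarct shapes. Passing tests therefore demonstrate
algorithmic correctness and the designed contrasts (delay cancellation,
lesion separability at stated SNR), not clinical performance; on this
sharply bimodal synthetic TDC the IPv threshold sits on the far wash-out
limb of the lesion mode, so z_f/stdZ sensitivity is low by construction
while their specificity is high — cohort-level behavior on patients is out
of scope.

## Problem sizes and runtime choices

The shipped tests and the acceptance script use a 32×32×8×80 phantom
(delay-invariance check: 32×32×10×80), a 50,000-point sample for mixture
recovery, 200 simulations for DeLong coverage, and 81-frame synthetic
convolution pairs — sizes chosen so the full suite runs in well under a
minute each while leaving all effects far above their noise floors. All
randomness is seeded; estimator classes follow the scikit-learn fit /
transform convention with trailing-underscore fitted attributes.

## Known limitations

* The first-pass window is global; severely delayed pathology outside the
  detected window would be boundary-flagged rather than measured.
* The TDC model has exactly two components; more complex arrival-time
  distributions (e.g. bilateral disease) are absorbed, not resolved.
* Tmax constants (`lambda_rel`, `oi_threshold`) follow the methodological
  literature and are not auto-calibrated to noise level.
* No motion correction or spatial filtering anywhere, by design.
* NIfTI inputs are assumed co-registered; there is no resampling, and axis
  conventions are enforced, not inferred.
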