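# tdcperf

AIF-free perfusion parameters for dynamic susceptibility contrast (DSC) MRI,
built around the brain-wide time-to-peak (TTP) histogram, plus a reference
Tmax pipeline and a voxelwise evaluation suite. The package targets
researchers comparing perfusion-map readouts for acute ischemic stroke
(penumbra/infarct delineation) who want methods that do not depend on
arterial-input-function (AIF) selection or deconvolution, exercised
end-to-end on synthetic digital phantoms with known ground truth.

## The parameters

For each voxel the absolute TTP is the time of the (smoothed) signal minimum
during the first pass of the contrast bolus. Three distribution-based
parameters are derived from the TTP histogram (whose first-pass envelope is
the *TTP distribution curve*, TDC):

* **stdTTP** — per-VOI standardized TTP. With the VOI (by default one
  slice) arrival offset `oTTP⁻ = Q_VOI(0.03)`, the lower 3% quantile of the
  VOI's TTP values,

  ```
  stdTTP = max(0, ttp − oTTP⁻)          [seconds]
  ```

  This simulates simultaneous bolus arrival in all slices: per-slice
  run-time delays cancel exactly. Critical perfusion: stdTTP ≥ 7 s.

* **z_f** — the TDC is modelled by a two-component Gaussian mixture
  (`TDC_f`, fitted by EM; components in ascending-mean order, k₁+k₂ = 1) and
  each voxel's TTP becomes the dimensionless weighted score

  ```
  z_f = k₁ (ttp − μ₁)/σ₁ + k₂ (ttp − μ₂)/σ₂
  ```

  Critical perfusion: z_f ≥ IPv, the venous inflection point of the fitted
  density — the latest curvature change on its descending (wash-out) limb.

* **stdZ** — z_f standardized like stdTTP, with the per-VOI lower
  2.275% quantile offset (the single-Gaussian equivalent of z_f = −2),
  after excluding voxels with z_f < −3. Critical perfusion: the
  standardized equivalent of IPv.

The reference **Tmax** is the peak time of the residue function recovered by
truncated-SVD deconvolution of the tissue concentration curve against an
automatically selected AIF, with gamma-variate pre-fitting. Both standard
(Toeplitz, sSVD) and delay-insensitive block-circulant oscillation-index
regularized (oSVD) variants are provided. Critical perfusion: Tmax ≥ 6 s.

The evaluation suite scores thresholded maps voxelwise against a ground-
truth lesion mask (sensitivity / specificity / accuracy), computes rank-
estimator ROC AUCs with DeLong 95% confidence intervals, and runs
continuity-corrected odds-ratio tests for the best-parameter question.

## Worked example

```python
import tdcperf as tp

spec = tp.PhantomSpec(seed=0)               # 3T long-TR protocol, SNR 20
series, truth = tp.generate_phantom(spec)
result = tp.compute_parameter_maps(series, truth.brain_mask, seed=0)

print(f"first-pass window: frames [{result.window.start_frame}, {result.window.end_frame})")
m = result.model
print(f"TDC_f: mu = ({m.mu[0]:.2f}, {m.mu[1]:.2f}) s, "
      f"sigma = ({m.sigma[0]:.2f}, {m.sigma[1]:.2f}) s, k = ({m.k[0]:.3f}, {m.k[1]:.3f})")
print(f"IPv: ttp = {result.ipv.ttp_at_ipv:.2f} s, z_f = {result.ipv.zf_at_ipv:.2f}")

report = tp.evaluate_maps(result, truth.lesion_mask, truth.brain_mask)
for name, res in sorted(report.results.items()):
    qf = res["quality"]
    print(f"{name:7s} sens={qf.sensitivity:.3f} spec={qf.specificity:.3f} "
          f"acc={qf.accuracy:.3f} AUC={res['roc'].auc:.3f}")
```

prints

```
first-pass window: frames [8, 34)
TDC_f: mu = (17.86, 29.44) s, sigma = (0.95, 0.87) s, k = (0.976, 0.024)
IPv: ttp = 30.31 s, z_f = 12.81
Tmax    sens=1.000 spec=1.000 acc=1.000 AUC=1.000
stdTTP  sens=1.000 spec=1.000 acc=1.000 AUC=1.000
stdZ    sens=0.236 spec=1.000 acc=0.982 AUC=1.000
z_f     sens=0.236 spec=1.000 acc=0.982 AUC=1.000
```

The default phantom embeds a spherical lesion whose bolus is delayed by
10 s, dispersed and attenuated, inside a brain with per-slice arrival delays
at baseline SNR 20. The mixture's early component (μ₁ ≈ 17.9 s, weight
0.98) is normal tissue, the late component the lesion; stdTTP at its 7 s
threshold and Tmax at 6 s recover the lesion perfectly at this noise level,
while the IPv threshold — sitting on the far wash-out limb of this sharply
bimodal synthetic TDC — marks only the latest-arriving lesion core, so z_f
and stdZ trade sensitivity for specificity here. The same pipeline is
available from the shell:

```sh
tdcperf simulate --out phantom --preset 3T_longTR --seed 0
tdcperf compute  --series phantom/series.nii.gz --brain phantom/brain_mask.nii.gz --out maps
tdcperf evaluate --series phantom/series.nii.gz --brain phantom/brain_mask.nii.gz \
                 --truth phantom/lesion_mask.nii.gz --out report
```

## Layout

```
src/tdcperf/
  phantom.py          synthetic 4D bolus-passage phantoms + ground truth
  io.py               NIfTI/JSON/CSV readers and writers, containers
  preprocessing.py    smoothing, concentration, first-pass window, TTP map
  tdc.py              TDC histogram, EM mixture (TdcMixtureModel), z_f, IPv
  standardization.py  per-VOI offsets (VoiStandardizer), stdTTP/stdZ, thresholds
  deconvolution.py    gamma-variate fit, AIF selection, sSVD/oSVD (SvdDeconvolver)
  evaluation.py       confusion/quality factors, DeLong ROC, odds ratios
  workflow.py         end-to-end map computation and evaluation
  cli.py              `tdcperf simulate | compute | evaluate`
```

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
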