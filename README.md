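# mpdwi

Marchenko–Pastur PCA (MPPCA) denoising and diffusion tensor / kurtosis
imaging toolkit for diffusion MRI, with a scan–rescan reproducibility
statistics battery and a synthetic multi-shell phantom generator.

## Who this is for

Quantitative diffusion MRI metrics — especially the kurtosis family — are
noisy at clinically feasible SNR, which limits their test–retest
reproducibility and inflates the sample sizes needed for group studies.
`mpdwi` implements random-matrix-theory denoising of magnitude and
complex-valued diffusion data, DTI/DKI fitting with outlier-robust kurtosis
metrics, and the statistics used to quantify scan–rescan agreement, so that
the whole chain — raw series → denoised series → parameter maps →
reproducibility report — can be run and validated end to end on phantoms
with known ground truth.

## The method

**MPPCA denoising.** A patch of the 4-D series around each voxel is arranged
as an M × N matrix X (M diffusion volumes × N voxels). When the noise-free
signal is low rank, the eigenvalues of XXᵀ split into a few signal
components and a pure-noise bulk following the Marchenko–Pastur law. With
M′ = min(M, N), N′ = max(M, N) and eigenvalues x₁ ≥ … ≥ x_{M′}, two bulk
estimators

    σ₁²(p) = Σ_{i>p} xᵢ / ((N′−p)(M′−p)),
    σ₂²(p) = (x_{p+1} − x_{M′}) / (4 √((N′−p)(M′−p)))

are compared; the smallest p with σ₂² ≤ σ₁² gives the retained rank and the
noise level σ. Reconstruction keeps the top p singular vectors, optionally
replacing each singular value s by the minimum-MSE shrinkage
√M′σ · η(s/(√M′σ)), η(y) = √((y²−γ−1)² − 4γ)/y for y above the bulk edge
1+√γ, γ = M′/N′.

Three augmentations mirror current practice: (i) *adaptive patching* — the
N = 100 patch voxels are chosen inside a 7×7×7 box by the joint distance
w = |r−r₀|^α ‖S(r)−S(r₀)‖^β (α = 1, β = 2), so patches follow anatomy and
stay closer to low rank; (ii) *symmetric thresholding* (the formulas above,
symmetric in M′ and N′); (iii) *singular-value shrinkage*.

**Complex two-pass denoising.** The smooth shot-to-shot phase φ is first
estimated by low-rank denoising of the complex images with 15×15 2-D
patches; the data are then unwound, S_real = Re(S e^{−iφ_dn}), which turns
Rician magnitude noise into zero-mean Gaussian noise and removes the
Rayleigh noise floor (mean σ√(π/2) where the true signal vanishes); the
real part is finally denoised with the 3-D adaptive machinery.

**DTI/DKI.** Signals follow the cumulant expansion
ln S(b,n̂)/S₀ = −b D(n̂) + (1/6) b² D̄² W(n̂), fitted by unconstrained
weighted linear least squares (b in ms/µm², so D is in µm²/ms and W is
dimensionless). Scalar maps come in two conventions: the W family
(MW = W_iikk/5 exactly via the trace identity, AW = W(v̂₁), RW analytic
transverse average — robust to outliers) and the classical K family
(angular averages of D̄²W(n̂)/D(n̂)², quadrature-based, outlier-prone where
D(n̂) is small).

**Reproducibility statistics.** Pairwise CV (μ̂ = (x₁+x₂)/2,
σ̂ = √(π/2)|x₁−x₂|), Lin's concordance correlation coefficient, ICC(A,1),
the Rayleigh noise-floor estimator (direction-averaged b = 2000 signal over
S₀ in a zero-signal region), and the two-group sample-size formula
n₁ = 2(Z_{α/2}+Z_β)² σ_p²/(μ₁−μ₂)².

## Worked example

```python
import numpy as np
from mpdwi import (PhantomSpec, simulate_scan_rescan, denoise_magnitude,
                   DWISeries, fit_wlls_dki, kurtosis_metrics_W)
from mpdwi.stats import cv_summary

spec = PhantomSpec(grid=(24, 24, 10), snr_b0=13.0)
phantom, scans = simulate_scan_rescan(spec, "P92", n_repeats=2, seed=1)
wm = phantom.masks["wm"]

mw = {}
for arm in ("none", "denoised"):
    maps = []
    for scan in scans:
        series = scan
        if arm == "denoised":
            res = denoise_magnitude(scan)
            series = DWISeries(signal=res.denoised, bvals=scan.bvals,
                               bvecs=scan.bvecs)
        maps.append(kurtosis_metrics_W(fit_wlls_dki(series))["mw"])
    mw[arm] = cv_summary(maps[0], maps[1], wm)["cv_voxel"]

print(f"voxel-wise MW test-retest CV, no denoising : {mw['none']:.1%}")
print(f"voxel-wise MW test-retest CV, MPPCA        : {mw['denoised']:.1%}")
```

Output:

```
voxel-wise MW test-retest CV, no denoising : 20.8%
voxel-wise MW test-retest CV, MPPCA        : 1.3%
```

The phantom is scanned twice with independent complex Gaussian noise at
b0-SNR 13 on a 65-volume b = 0/1000/2000 protocol. Without denoising the
mean kurtosis MW fluctuates by ~21% between scans in the homogeneous
white-matter slab; MPPCA removes most of that variance (on a perfectly
homogeneous phantom the residual CV is far below what heterogeneous in vivo
tissue would show).

The same pipeline is available from the shell:

```bash
mpdwi simulate --protocol P92 --snr 13 --repeats 2 --seed 42 --out-prefix ph
mpdwi denoise  --in ph_rep1_dwi.nii.gz --bval ph_rep1.bval --bvec ph_rep1.bvec \
               --phase ph_rep1_phase.nii.gz --method complex --out-prefix dn1
mpdwi fit      --in dn1_dwi.nii.gz --bval ph_rep1.bval --bvec ph_rep1.bvec \
               --model dki --out-prefix maps1
mpdwi stats    --maps1 maps1 --maps2 maps2 --roi ph_truth_labels.nii.gz \
               --out report.tsv
mpdwi power    --mu1 1.0 --mu2 0.95 --var-between 0.0025 --sigma-bar2 0
```

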