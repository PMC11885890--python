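# Methods

This note records the models implemented in `mpdwi`, the defaults and why,
the numerical choices, and what the synthetic phantoms do and do not
emulate.

## Random-matrix denoising (`mpdwi.rmt`, `mpdwi.patching`, `mpdwi.denoise`)

### Model and rank selection

A patch matrix X (M volumes × N voxels) is modelled as low-rank signal plus
i.i.d. noise. Eigenvalues x_i of XXᵀ are used unnormalized (x_i = s_i², no
division by N); the (N′−p)(M′−p) factors in the estimators absorb the
scale. Rank selection compares the bulk-mean estimator σ₁²(p) with the
bulk-spread estimator σ₂²(p) = (x_{p+1} − x_{M′}) / (4√((N′−p)(M′−p))) and
returns the smallest p with σ₂² ≤ σ₁²: while signal eigenvalues are still
counted in the bulk, the spread exceeds the mean; the crossing marks
consistency with a Marchenko–Pastur bulk. The square root in the σ₂²
denominator makes the expression reduce to the classical MP edge-width
identity σ² = (x₁−x_{M′})/(4√(M′N′)) at p = 0; without it the estimator is
dimensionally inconsistent and fails the pure-noise calibration test.

Properties established by the Monte-Carlo suite at M′ = 50, N′ = 100:
σ̂² is unbiased within 5%; the selector admits one spurious component in
roughly 9% of pure-noise draws (a finite-size property of the symmetric
threshold, not of the implementation — planted-rank tests therefore assert
p ≥ rank always and p = rank in ≥ 90% of draws). Signal is never lost: if
no crossing occurs (possible only for elongated aspect ratios N′ ≫ M′) the
patch degenerates to p = M′−1 with σ = 0, a fail-safe that returns the
input unchanged rather than destroying signal.

No mean-centering is applied before the SVD; the MP derivation operates on
raw signal matrices.

### Shrinkage

Retained singular values are shrunk with the minimum-Frobenius-MSE shrinker
η(y) = √((y²−γ−1)²−4γ)/y above the bulk edge, γ = M′/N′. The
reconstruction scales σ by √M′ (`scale="M"`), with a `scale="N"` switch.
The √N′ convention is the one under which the shrinker argument has its
bulk edge exactly at 1+√γ; the √M′ default is retained deliberately as the
primary convention and only shrinks retained (above-threshold) components,
where the practical difference is small — the planted-signal tests confirm
shrink-on MSE ≤ shrink-off MSE under the default.

### Adaptive patching

Patch voxels are selected inside a (2R+1)³ box (R = 3) by
w = |r−r₀|^α ‖S(r)−S(r₀)‖^β with α = 1, β = 2 and N = 100 voxels kept.
Distances are computed on the noisy signals themselves (no reference
image); noise inflates all ‖ΔS‖ equally in expectation, preserving the
ranking. Ties (e.g., constant regions where all w = 0) are broken by
spatial distance then lexicographic index, making the selection fully
deterministic. At volume edges the box is clipped, never padded — padding
fabricates signal. Each voxel takes its denoised value from the patch in
which it is the center (moving patch, no overlap averaging).

### Complex two-pass pipeline

The phase pass denoises the *complex* images (magnitude·e^{iφ}) with
15×15 2-D in-slice patches, symmetric thresholding, no shrinkage, and takes
the angle of the reconstruction — wrapped phase maps are never filtered
directly, which avoids 2π-wrap artifacts. All M volumes are processed
jointly. The phase patches (2-D boxes) and signal patches (3-D adaptive)
are deliberately different constructions so the two passes do not reuse the
same subspaces. A non-overlapping tiling (`phase_stride`) is available for
speed; edge tiles absorb remainders thinner than half a kernel.

After unwinding, the real-valued data may contain negative values where the
noise floor was removed; they are preserved (clipping would reintroduce a
floor) and the tensor fit handles them by row deletion (below).

Noise conventions: for complex patches σ² estimates the total complex
variance (sum of the real and imaginary channel variances); the sigma map
reported by the complex arm refers to the real channel of the second pass,
i.e., σ_complex/√2. In a zero-signal region the magnitude-arm sigma map
instead estimates the Rayleigh spread √(2−π/2)·σ_channel ≈ 0.655 σ_channel
of the floored data — the two maps measure different quantities there by
construction.

## Tensor estimation (`mpdwi.dki`)

b-values are converted from s/mm² to ms/µm², so D is in µm²/ms and W
dimensionless. Shells are clustered with a 50 s/mm² tolerance; b < 50
counts as b = 0. The 22-parameter model (ln S₀, 6 D, 15 quartic
coefficients) is fitted by OLS on log-signals followed by two reweighted
iterations with weights equal to squared predicted signals (configurable);
W = 6C/D̄² recovers the kurtosis tensor from the fitted b² coefficients.
Non-positive signals (possible after complex denoising) are excluded
voxel-wise from the log-domain fit (row deletion) rather than clamped:
clamping biases the fit, deletion only costs precision. DTI metrics come
from a separate 7-parameter fit restricted to b ≤ 1000.

Noise-bias expectations (Monte-Carlo, b0-SNR 13, 65-volume protocol):
the Rician floor at b = 2000 biases the DKI-fit median MD upward by ~6%;
with zero-mean Gaussian noise of the same level (the phase-unwound regime)
the bias drops to ~1–3%. This is the mechanism by which complex denoising
reduces parameter bias.

Scalar maps: eigenvalues are ordered descending with v̂₁'s z-component made
non-negative (a sign convention only). RD and RW use exact transverse-plane
averages — for a quadratic form the circle average is (λ₂+λ₃)/2, for the
quartic form it is (3/8)(W′₁₁₁₁+W′₂₂₂₂)+(3/4)W′₁₁₂₂ in the eigenframe —
verified against 3600-point circle quadrature to 1e-8. MW uses the trace
identity W̄ = W_iikk/5, verified against dense spherical quadrature to
1e-6. K-convention metrics integrate D̄²W(n̂)/D(n̂)² over a deterministic
Fibonacci sphere (10,000 nodes by default; doubling changes MK by < 1e-4)
and a 3600-node transverse circle; voxels with non-positive-definite D are
flagged NaN. The kurtosis outlier rule (value < −1 or > 10, strict bounds,
NaN counts as outlier) is applied both when counting outliers and before
ROI means.

## Reproducibility statistics (`mpdwi.stats`)

σ̂ = √(π/2)|x₁−x₂| is implemented exactly as defined; note its expectation
is √2 times the per-measurement SD (it estimates the SD of the
difference). CV summaries exclude voxels with |μ̂| below a configurable
epsilon (normalising by a near-zero mean is unstable) and report the
excluded count; both the voxel-wise (per-voxel CV averaged over the ROI)
and ROI-level (CV of ROI means) variants are returned. ICC(A,1) is the
two-way random-effects, absolute-agreement, single-measurement form from
ANOVA mean squares, computed on pooled voxels per metric (an
interpretation: per-voxel ICC then summarising would be the alternative);
it is cross-checked against pingouin in the tests. The sample-size formula
uses normal (not t) quantiles, as in the standard closed form — a slight
optimism relative to an exact t-test power analysis. The noise floor is the
direction-averaged b = 2000 signal over S₀ per voxel of a zero-signal
region; its median estimates σ√(π/2)/S₀ for magnitude data and drops
towards zero for phase-unwound data.

## Synthetic phantoms (`mpdwi.simulate`)

The generator emulates the study conditions the pipeline targets: two-shell
b = 0/1000/2000 s/mm² protocols with 65 volumes (P92: 5+20+40) or 50
volumes (P127/S127: 5+15+30), b0-SNR in the 9–13 range, spatially smooth
per-volume phase, a homogeneous single-fiber WM slab large enough that an
adaptive patch can find 100 same-signal voxels (≥ 1000 voxels at the
default 40×40×12 grid), and a CSF compartment (isotropic D = 3 µm²/ms)
whose b = 2000 signal is e⁻⁶ ≈ 0.25% of S₀ — the zero-signal pool for
noise-floor estimation. Gradient directions are fixed
electrostatic-repulsion point sets shipped as text files.

Ground-truth tensors are representative literature-range values, not fitted
to any dataset: single-fiber WM AD = 2.0 / RD = 0.5 µm²/ms (FA ≈ 0.71) with
MW = 0.9, AW = 0.6, RW = 1.3; a 60/40 two-fiber crossing (unequal weights
keep the principal direction well defined); GM D = 0.8 µm²/ms, W = 0.6,
both isotropic; CSF W = 0. S₀ = 1000 everywhere in tissue; a 2-voxel air
border (S₀ = 0) provides pure-noise voxels for SNR verification. Noise is
additive complex Gaussian per channel with σ = S₀/snr_b0; the stored
magnitude is Rician. The phase model is a per-slice, per-volume quadratic
polynomial with coefficients ~N(0, 1 rad) plus a uniform offset, emulating
smooth shot-to-shot phase. All randomness derives from a single seed via
`SeedSequence` spawning, so every experiment is exactly reproducible.

What the phantom does *not* emulate: partial-volume mixing, Gibbs ringing,
EPI distortion, motion, eddy currents, spatially varying (g-factor) noise,
physiological noise, or registration error. Passing tests therefore show
that the estimators and the denoising chain behave correctly under their
stated noise model — the in vivo CV levels will be higher, and artifact
correction must come from other tools.

### Problem sizes

The end-to-end checks run on a 24×24×10 grid (1080-voxel WM slab, 480-voxel
CSF region) with the 65-volume P92 protocol and b0-SNR 13; unit and
property suites use 12–16 voxel grids and 100-draw Monte-Carlo at
M′ = 50/N′ = 100. These sizes were chosen so a full run finishes in minutes
on a single CPU while every region still contains enough voxels for stable
medians.

## Known limitations

- The symmetric MP threshold over-counts the rank by one in ~9% of patches
  at typical patch sizes; the shrinker suppresses most of the resulting
  leakage but sigma maps in structured regions inherit small fluctuations.
- The phase pass assumes within-window phase excursions well below π;
  rapidly varying phase (strong motion, high-order shims) degrades the
  estimate toward the raw phase.
- K-convention metrics are quadrature-based and inherit a ~1e-4 absolute
  quadrature error at default node counts; the W family is exact.
- The CLI operates on single series; population template building,
  registration and harmonization are out of scope.
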