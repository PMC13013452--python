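# Methods

`mdrc` implements, at desk scale, the analysis chain of massively
multidimensional diffusion–relaxation correlation MRI: simulation of
b(ω)–τ_R–τ_E encoded signals, Monte Carlo inversion into nonparametric
**D**(ω)–R1–R2 distributions, frequency-resolved metrics, and classification
of the distribution components by manual binning and by data-driven Gaussian
mixture clustering.

## Signal model

Each voxel's signal is a weighted sum over distribution components,

    S = Σ_i w_i · exp(−⟨b : D_i(ω_cent)⟩) · [1 − exp(−τ_R R1_i)] · exp(−τ_E R2_i),

where each component is an axisymmetric diffusion tensor with eigenvalues
dispersing from their long-time values D_∥, D_⊥ toward the high-frequency
diffusivity D_0 via Lorentzian transitions

    D(ω) = D_0 − (D_0 − D_limit) / (1 + (ω/Γ)²),

with corner frequencies Γ_∥, Γ_⊥ in rad/s. The Γ convention follows the
inversion limits (0.1–10⁵), which only make dimensional sense as rates
spanning the probed window. A component is the parameter vector
[D_∥, D_⊥, θ, φ, D_0, Γ_∥, Γ_⊥, R1, R2] plus a weight w.

**Encoding kernel.** The spectral integral ∫ b(ω):D(ω) dω is approximated by
contracting the total b-tensor with the tensor evaluated at the row's
centroid frequency (exact for narrow encoding spectra). Measured waveform
spectra can be supplied per row as discretized (ω_j, b_j-tensor) lists; the
default kernel is the centroid approximation because waveform spectra are
acquisition-specific and rarely available. The contraction uses the closed
form b·D_iso·(1 + 2 b_Δ D_Δ P₂(cos β)) for two axisymmetric tensors, tested
against the explicit 3×3 double-dot product.

**Noise.** Rician by default (magnitude reconstruction):
√((S+n₁)² + n₂²) with n₁, n₂ ~ N(0, S0_ref/SNR) and S0_ref the maximum
noiseless signal; Gaussian noise is available for oracle tests.

## Monte Carlo inversion

The inverse problem is ill-posed; it is attacked by random search with
non-negative least squares (NNLS) weighting:

1. **Proliferation** (20 steps): sample 200 fresh candidates within the
   limits, merge with current survivors, fit weights by NNLS, keep
   components above the extinction floor (10⁻⁶ × max weight).
2. **Mutation/extinction** (20 steps): multiply each log-sampled parameter by
   exp(u·r), u ~ U(−1, 1), with the range r shrinking geometrically
   (0.5 × 0.8^step); perturb orientations by random axis jitter of matching
   magnitude; refit; extinguish.
3. **Truncation**: keep the 10 highest-weight members of the final positive
   support and refit. Because a plain subset refit parks some weights at the
   NNLS boundary, zeroed slots are refilled from the weight-ranked remainder
   and refitted (falling back to the pool-fit weights if the pool is
   exhausted), so a solution normally carries exactly 10 components with
   positive weights.
4. **Bootstrap** (100 repetitions): repeat the search on with-replacement
   resamples of the (row, datum) pairs. Pooled, a voxel's distribution
   comprises 1,000 components.

Sampling laws are log-uniform for diffusivities, corner frequencies and
relaxation rates (the bounds span decades) and area-uniform on the
hemisphere for orientations; D_0 is taken as the max of the three
diffusivity draws so dispersion rises toward D_0. Survivors are always
retained in the next candidate set, making the fitted residual
non-increasing across steps.

**S0 convention.** S0 is the mean over bootstrap solutions of the
per-solution total weight; fraction maps over the pooled ensemble divide by
n_solutions·S0 (the pooled total weight), so fractions sum to exactly 1.

**Determinism.** Per-voxel generators derive from (global seed, i, j, k), so
image inversions are independent of worker count and scheduling.

**Identifiability.** Only D(ω) *inside the probed frequency window* is
constrained by the data; the long-time and high-frequency plateaus of a
component with Γ outside the window are individually degenerate. All
recovery checks therefore compare ω-evaluated metrics, mirroring how the
method itself reports distributions.

## Frequency-resolved metrics

At an evaluation frequency ω (by convention a percentile — default 10/50/90,
linear interpolation — of the protocol's centroid frequencies):

    D_iso(ω) = (D_∥(ω) + 2 D_⊥(ω))/3
    D_Δ(ω)   = (D_∥(ω) − D_⊥(ω)) / (3 D_iso(ω)) ∈ [−0.5, 1]

and the restriction measures over the window [ω_min, ω_max] (the 10th–90th
percentile of the protocol),

    Δ_{ω/2π} D_iso = [D_iso(ω_max) − D_iso(ω_min)] / [(ω_max − ω_min)/2π],

analogously for D_Δ². Δ_{ω/2π} D_iso ≥ 0 for every Lorentzian component and
is large where the corner frequency falls inside the window — the signature
of restriction in dense cell layers.

## Binning

Rectangular bins in the (D_iso, D_Δ²) plane with half-open intervals
[min, max). Default partition: WM-like (D_iso < FW threshold, D_Δ² ≥ 0.25),
GM-like (D_iso < threshold, D_Δ² < 0.25), FW-like (D_iso ≥ threshold), with
thresholds 1.0/1.5/2.5 ×10⁻⁹ m²/s for the ex vivo rat / in vivo rat / human
presets. The numeric limits are a modeling choice (no canonical values are
published), all overridable; bin-level comparisons with reported maps are
therefore qualitative. Per voxel, f_bin = Σ_{i∈bin} w_i / S0 and
E_bin[X] = Σ w_i X_i / (S0 f_bin), undefined (NaN) where f_bin = 0.

## Clustering

Weights enter the design matrix by replication: each component contributes
round(100·w_i / Σ_voxel w) identical rows (per-voxel normalization, so every
voxel contributes ≈100 rows regardless of brightness; components rounding to
0 are omitted). Columns are then divided by their population standard
deviation, computed after replication; the scale is stored and reused to
project unreplicated components for assignment.

The rows are modeled as a full-covariance Gaussian mixture fitted by EM:
k-means++-style seeding of hard responsibilities, best of 5 seeded runs,
tolerance 10⁻⁶ relative log-likelihood, max 500 iterations, covariance
ridge 10⁻⁶ (on the standardized scale). BIC = −2·loglik + p·ln n with
p = k−1 + kd + kd(d+1)/2 guides k selection; the scan table is returned and
the argmin is advisory. Components are hard-assigned by maximum posterior
responsibility (lowest index on ties); soft responsibilities are retained.

Variable presets: `bins3` {D_iso, D_Δ²} for the 3-bin comparison;
`full_rat` {D_iso, D_Δ, R1, R2, Δ_{ω/2π}D_iso}; `full_human`
{D_iso, D_Δ, R1, R2}. Δ_{ω/2π}D_Δ² is computed but excluded from default
sets. Cluster reports are ordered by descending share of replicated rows
(percent_data). Per-subject models are compared by optimally matching
centroids (Hungarian assignment) and reporting the per-cluster spread.

## Phantoms

Protocol presets draw rows within the printed ranges of the three
experiments (ex vivo rat: b ≤ 7.13×10⁹ s/m², ω/2π 29–110 Hz,
b_Δ ∈ {−0.5, 0, 0.5, 1}, τ_R 0.2–7 s, τ_E 6–180 ms; in vivo rat and human
analogues), with eight anchor rows (minimum b, maximum τ_R, minimum τ_E)
pinning S0. Tissue presets are log-normal component generators:

| preset | D_∥, D_⊥ (10⁻⁹ m²/s) | Γ (rad/s) | R1, R2 (1/s) | character |
|---|---|---|---|---|
| wm_like | 0.60, 0.08 | 5×10⁴ | 1.2, 35 | anisotropic, coherent axis |
| gm_like | 0.35, 0.24 | 5×10⁴ | 0.7, 18 | near-isotropic |
| fw_like | 2.0, 2.0 | 5×10⁴ | 0.35, 4 | fast, isotropic |
| restricted_like | 0.12, 0.10 (D_0 = 0.9) | 300 | 0.8, 25 | disperses inside the window |

Centers echo reported tissue modes (tissue D_iso ≈ 0.27×10⁻⁹ m²/s; free
water above 1×10⁻⁹ m²/s ex vivo at 18 °C); the restricted preset's corner
frequency (≈48 Hz) sits inside the ex vivo window so its Δ_{ω/2π}D_iso is an
order of magnitude above the other classes. Spread is 0.15 in log-space
(0.08 for free water), 2–3 components per voxel with Dirichlet(5) weight
splits — enough intra-voxel heterogeneity to exercise the inversion without
making single-voxel recovery ambiguous. What the phantom does *not* emulate:
partial-volume mixing beyond class boundaries, exchange between
compartments, spatially correlated noise, susceptibility/EPI artifacts, and
realistic anatomy; a green phantom test establishes algorithmic correctness,
not in-tissue performance.

## Histology statistics

Patch-wise structure-tensor coherency C = (λ_max − λ_min)/(λ_max + λ_min)
of Gaussian-derivative gradients (σ = 2 px default), C = 0 for flat patches;
patches tile the image without overlap (default 70 µm to match an in-plane
voxel). Optical density OD = max(0, −ln(I/I_background)) per pixel,
patch-averaged, normalized by the image's maximum per-pixel OD. Smoothing
scale and normalization reference are not canonical; results are
qualitative.

## Numerical and design choices

- Strict SI internally (m²/s, s, rad/s); files and reports use ω/2π in Hz.
- NNLS via `scipy.optimize.nnls`; zero kernel columns get weight 0; NaN in
  data is rejected.
- Angles: physics convention (θ polar from +z, φ azimuthal from +x);
  degrees accepted in acquisition files via explicit header tags
  (`theta[deg]`, `tau_r[ms]`, ...).
- b_Δ is accepted anywhere in [−0.5, 1], not only the printed discrete set.
- Inversion limit presets allow degenerate point limits (min = max) for
  testing.
- Constant feature columns are left unscaled (scale 1) rather than
  rejected, matching `StandardScaler` behavior.
- The desk-scale defaults for CI-sized runs (8×8×1 voxels, 150 rows,
  bootstrap 20) keep full-pipeline checks within minutes on one CPU;
  production settings (100 bootstraps) run ~20 s per voxel.

## Known limitations

- The centroid-frequency kernel is exact only for narrow encoding spectra;
  broad-spectrum waveforms need the explicit spectral kernel.
- The proliferation/mutation schedule is a faithful reconstruction of a
  random-search inversion, not a port of any reference implementation;
  component-level agreement with other implementations is statistical, not
  bitwise.
- Non-axisymmetric encoding tensors are not supported.
- Exchange between water populations and microscopic kurtosis are outside
  the model.
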