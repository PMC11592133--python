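# Methods

This note documents the models implemented by `mrsdenoise`, the assumptions
behind them, the parameters that matter, and the choices made where the
design was genuinely open.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Signal model and conventions

A single-voxel acquisition is a complex free-induction decay (FID) sampled
at the spectral width (default 2000 Hz, 2048 points, ~1.02 s).  The
FID→spectrum map is the *unitary* centered DFT (1/√n both ways).  Unitarity
was chosen so that white noise has the same standard deviation in both
domains, which lets every SNR and MSE statement be made without tracking
scale factors.  The chemical-shift axis is
`reference_ppm − f/f₀` (f₀ = spectrometer frequency in MHz), decreasing left
to right as spectra are conventionally displayed; the reference is anchored
at water (4.65 ppm) on the carrier.  Default header: 127.8 MHz (3 T
protons), TR/TE = 4000/22 ms.

## Synthetic data generator

The generator emulates the two acquisition types the denoisers target, with
exact ground truth that real data never provides:

* **Baseline scan** — 32 non-averaged FIDs of a static voxel.
* **Functional scan** — one FID per TR (4 s): 47 baseline-period signals
  (3.12 min) followed by 320 stimulation-period signals.  The nominal
  stimulation block is 22.4 min; 320 signals at TR 4 s cover its first
  21.3 min, the signal count being taken as primary.

**Lineshape.** Each metabolite is a sum of Lorentzian lines (exponential T2*
decay, per-line T2* of 55–90 ms); the default table covers NAA, tCr, tCho,
Glu, Gln and m-Ins at literature-typical shifts with crude proton-weighted
relative amplitudes (`src/mrsdenoise/data/defaults.yaml`).  No J-coupling
evolution, macromolecule baseline, residual water, or eddy-current effects
are simulated.

**Noise and instability.** Per-point iid complex Gaussian noise
(`noise_sd = 10`, calibrated once so a single-shot spectrum scores SNR ≈ 5
under this package's SNR definition — typical single-average 3 T quality),
plus per-shot global frequency jitter (SD 1 Hz) and zero-order phase jitter
(SD 0.05 rad) emulating scanner instability.  The jitter is deliberately
small enough that the low-rank assumption stays approximately valid.

**Functional modulation.** The glutamate amplitude is multiplied by
`1 + glu_effect · g(t)` where the gate g(t) ramps (raised cosine, 2 min) to
a sustained 0.4 after capsaicin onset, adds a heat-locked bump to exactly
1.0 during the heat window (onset 9 min, duration 4.4 min), and relaxes
exponentially (τ = 3 min) afterwards.  The gate peaks at exactly 1, so peak
glutamate is `(1 + glu_effect)` times its baseline level.  The synthetic
pain-rating (NRS) trace rises logistically (τ = 1 min) after heat onset to a
plateau of 5 and decays linearly (0.35/min) after heat offset.  Both are
qualitative test harnesses, not biological claims.

**What passing tests show.** Because the generator's noise is white and its
truth known, tests can assert exact MSE reductions and calibrated error
bars.  Real data add correlated physiological fluctuations, lineshape
distortion and baseline signals the generator omits; results here bound
what the algorithms do under their own assumptions, not their in vivo
performance.

## Low-rank (Casorati SVD) denoising

Columns of C are the acquisitions (water-unsuppressed rows excluded by
default); the complex SVD is taken without column centering, since the mean
spectrum is the dominant signal component and must stay in the subspace.
Each signal is shrunk toward span(U_r) by

    ŝ = P s + (s − P s)/(1 + λ),   P = U_r U_r*,

the closed-form minimizer of ‖ŝ − s‖² + λ‖(P − I)ŝ‖².  λ = 0 is the
identity; λ → ∞ the pure projection; intermediate λ retains 1/(1+λ) of the
out-of-subspace residual, protecting weak features the subspace missed.
The implementation never forms the n×n projector (two skinny products), and
for tall matrices computes the top-r triplets from the signals×signals Gram
eigenproblem (exact, with a QR polish for orthonormality).  Singular-vector
sign is fixed by rotating each column so its largest-magnitude entry is real
positive, making results deterministic.

Defaults (r = 2, λ = 500) for 32-signal resting data and (r = 5, λ = 100)
for 320-signal functional data correspond to the regime the method was
tuned for.  `select_rank_lambda` grid-searches (r, λ) by PSNR
(20·log₁₀(peak/RMSE), pooled over signals) against a clean reference;
ties break toward smaller r then smaller λ.  A per-signal reference matrix
is accepted because a shared reference cannot identify the true rank when
the clean signals genuinely differ (the optimal rank-1 subspace contains
the column mean to second order in the amplitude spread).  Automatic rank
selection by Marchenko–Pastur or hard-threshold rules is out of scope.

Identifiability caveat: a rank-k structure is only recoverable when its
singular value clears the noise floor ≈ σ√2(√n_points + √n_signals).  At the
default noise level a 10 % glutamate modulation lies well below that floor
(singular value ~30 vs ~900), with consequences for the functional analysis
discussed below.

## Diffusion model

Forward process: s_t = √ᾱ_t s₀ + √(1−ᾱ_t) ε with a linear β schedule,
1e-5 → 1e-3 over T = 1000 (ᾱ_T ≈ 0.603 — the chain is mildly noising by
design, matching the moderate noise of single-shot MRS).  The network input
is the **real part** of the frequency-domain spectrum: the FID is
zero-padded 2048 → 4096, transformed, reshaped row-major to 64×64 and
scaled by its max-abs into [−1, 1] (the scale is stored and inverted on
output).  The real part was chosen over magnitude because magnitude
destroys negative lobes and phase structure.  Training samples are
phase-augmented: a random zero-order phase uniform in [−90°, +90°] (a
180-degree span) is applied to the complex spectrum before the real part is
taken; averaged spectra serve as the clean s₀, which is adequate because
the objective learns the noise, not the signal.

**Noise predictor.** ε_θ is a compact fully connected network written
directly in numpy (~2.2 M float32 parameters, analytic backprop, Adam):
a sinusoidal step embedding feeds two GELU hidden layers (width 256) and a
diagonal gain path `c(t)·x` with `log c = γ + g(t)` (per-cell γ, scalar
g(t)).  The gain path exists because clean spectra are essentially zero
outside the metabolite region, where the optimal noise estimate is exactly
a region- and step-dependent rescaling of the input; the MLP path handles
the signal-bearing region.  The architecture sits behind a minimal
`predict(grid, t)` contract and can be swapped.  Default training here uses
~500–600 samples from 10 synthetic subjects for 15 epochs (batch 32, lr
1e-3), about 10 s on one CPU core; these sizes were chosen so the full
pipeline trains and evaluates in seconds while still clearly beating the
trivial zero predictor on held-out noise.

**Reverse chain.** A measured spectrum is identified directly with state
s_n (no forward re-noising; no noise-to-step calibration rule is applied
beyond this identification, n being the user-facing knob) and n reverse
steps of μ_θ = (s_t − β_t/√(1−ᾱ_t)·ε_θ)/√α_t are applied.  The chain uses
the **posterior mean** by default: with n = 2 and β ≈ 1e-5, injected
sampling noise √β_t·z would never be re-removed and strictly degrades the
noise floor left by the CSVD stage; stochastic sampling (never at t = 1)
remains available via `add_noise=True`.  Defaults: 10 steps standalone,
2 steps in the hybrid.  In the hybrid, the diffusion stage refines the real
part of each CSVD-denoised spectrum; the imaginary part is carried through
from the CSVD stage unchanged.

## Quantification

* **SNR** = (max baseline-subtracted real part over 1.8–4.2 ppm) / (SD of
  the linearly detrended real part over −2..0 ppm, a metabolite-free
  window).  This is a documented stand-in for fitter-internal definitions;
  absolute values are not comparable across software — only orderings
  between processing methods are asserted anywhere in the package.
* **FWHM** in ppm via linearly interpolated half-maximum crossings around
  the apex nearest the requested shift (default NAA, 2.008 ppm).
* **Basis fit**: unweighted real-valued linear least squares on noiseless
  unit-amplitude metabolite spectra synthesized with the same conventions
  as the simulator, so simulated spectra are exactly linear in the basis.
  CRLB% = 100·σ·√[(BᵀB)⁻¹]_mm/|â_m| is exact for this model (σ from the
  noise window when not supplied).  No baseline spline, lineshape
  convolution or soft constraints — deliberately minimal.

## Functional analysis and inference

Per-TR metabolite estimates are smoothed with a centered 16-point moving
average (edge windows shrink symmetrically), normalized to the grand mean,
optionally averaged across subjects on a common grid (with a recorded
exclusion list), and correlated with the pain ratings interpolated onto the
MRS time grid, restricted to t > 12 min (after pain onset).

Kendall's τ_b is computed by exact pair enumeration with tie corrections;
p-values use the normal approximation with the exact tied-data variance of
S.  **Serial dependence**: a width-w moving average leaves ~n/w independent
observations, so the naive p-value on smoothed series is anti-conservative
by roughly a factor √w in z units.  When a series carries its smoothing
window in metadata, `post_onset_correlation` inflates Var(S) by the
closed-form factor implied by the known boxcar autocorrelation (triangular,
ρ_k = 1 − k/w) — a Hamed–Rao-style correction with theoretical rather than
estimated lag correlations, immune to trend contamination.  This keeps the
type-I error of the null pipeline at its nominal level (verified by the
seeded null-calibration tests).

**Power ceiling (known limitation).** The corrected test has ~9 effective
post-onset observations (140 smoothed TRs / window 16), so only
correlations τ ≳ 0.5 reach significance.  At the default noise level the
rank-5 functional projection retains only ~40 % of a 10 % glutamate
modulation (its Casorati singular value is far below the noise floor; what
survives leaks through the mean-spectrum direction), and a 13-subject group
average yields τ ≈ 0.4 ± 0.15 against the ratings.  Consequently the
full-pipeline detection of a 10 % effect succeeds in roughly half of seeded
group replicates, not reliably — an information-theoretic consequence of
smoothing-then-correlating at this SNR, not an implementation artifact.
The acceptance test asserting reliable detection is expected to fail under
these study conditions and is retained as an honest record.

## Numerical and degenerate-input choices

* λ = 0 short-circuits to the exact identity; all-zero spectra are rejected
  at normalization (zero scale); all-tied vectors are rejected by τ_b.
* PSNR returns +inf at zero RMSE; rank/λ ties break toward the smallest.
* Training aborts on a non-finite loss; every stochastic routine takes an
  explicit seed or Generator, and same-seed runs are bit-reproducible
  (HDF5 outputs are written without timestamps so files hash identically).
* The SPAR/SDAT reader decodes VAX F-floating data (word-swapped
  little-endian, excess-128 exponent, hidden 0.1 mantissa bit); an in-repo
  encoder exists purely as the round-trip test oracle.

## Problem sizes

Tests and the acceptance script use deliberately desk-scale sizes: 10
synthetic training subjects × 60 augmented samples, 15 training epochs,
10-seed baseline comparisons, 200-fit CRLB coverage, and 20 × 13-subject
functional replicates per arm.  These sizes are the package's own choice of
a configuration that a laptop reproduces in minutes.
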