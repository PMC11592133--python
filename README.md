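# mrsdenoise

Hybrid denoising for in vivo single-voxel ¹H magnetic resonance spectroscopy
(MRS): a regularized low-rank projection built on the Casorati matrix of
repeated acquisitions, combined with a short-chain denoising diffusion
probabilistic model (DDPM) applied to individual spectra.  The package is
aimed at MRS methods researchers who want to shorten scan times — recovering
near-averaged spectral quality from single, non-averaged acquisitions — and
at functional-MRS analyses that need per-repetition (4 s) metabolite time
courses during a stimulation paradigm.

## The methods in brief

**Low-rank (CSVD) stage.** Stack the n non-averaged complex FIDs from one
voxel as columns of a Casorati matrix C ∈ ℂ^(points × signals).  Because the
acquisitions are highly correlated, C ≈ U_r Σ_r V_r* for a small rank r while
white noise is full rank.  Each signal s is shrunk toward the estimated
subspace by the closed-form solution of

    min_ŝ ‖ŝ − s‖² + λ‖(U_r U_r* − I) ŝ‖²   ⇒   ŝ = P s + (s − P s)/(1 + λ),

with P = U_r U_r*.  Defaults: (r = 2, λ = 500) for 32-signal resting scans,
(r = 5, λ = 100) for 320-signal functional scans.

**Diffusion stage.** A DDPM with linear variance schedule β_t from 1e-5 to
1e-3 over T = 1000 steps is trained on clean (averaged) spectra mapped to
64×64 grids in [−1, 1], using the standard noise-prediction objective
E‖ε − ε_θ(s_t, t)‖² with s_t = √ᾱ_t s₀ + √(1−ᾱ_t) ε.  A measured noisy
spectrum is identified with an intermediate chain state and a small number
of reverse steps is applied: 10 when used alone, 2 after the CSVD stage
(the hybrid, "CSVD+DDPM2").

**Evaluation.** SNR (peak over noise-window SD), FWHM (ppm, interpolated
half-maximum crossings), a linear basis fit with exact Cramér–Rao bounds in
place of a commercial fitter, and a functional-MRS analysis: per-TR
glutamate estimates, window-16 moving average, normalization to the mean,
and a tie-corrected Kendall correlation (serial-dependence-corrected
p-values) against pain ratings after stimulus onset.

A synthetic-data generator with exact ground truth stands in for scanner
data: Lorentzian metabolite basis (NAA, tCr, tCho, Glu, Gln, m-Ins),
per-shot complex Gaussian noise and frequency/phase jitter, and a
capsaicin/heat functional paradigm with a stimulus-locked glutamate
modulation plus a synthetic pain-rating trace.

## Worked example

```sh
mrsdenoise simulate baseline --out scan.h5 --seed 7
mrsdenoise train-ddpm --inp scan.h5 --out model.npz --epochs 10 --seed 0
mrsdenoise denoise --inp scan.h5 --out den.h5 --method hybrid --model model.npz --seed 0
mrsdenoise quantify --inp den.h5 --out quant.csv
```

or from Python:

```python
import numpy as np
import mrsdenoise as m

series, truth = m.simulate_baseline_dataset(seed=7)     # 32 noisy FIDs
spec_raw = m.fid_to_spectrum(series.data[0], series.header)
den = m.csvd_denoise(series, m.BASELINE_CONFIG)          # r=2, lam=500
spec_den = m.fid_to_spectrum(den.data[0], series.header)
print(f"SNR raw  {m.estimate_snr(spec_raw):5.2f}")
print(f"SNR CSVD {m.estimate_snr(spec_den):5.2f}")
```

prints (seed 7):

```
SNR raw   6.01
SNR CSVD 18.14
```

i.e. the low-rank projection lifts a single 4-second acquisition from SNR ≈ 6
to SNR ≈ 18, approaching the ≈ 23 obtained by averaging all 32 acquisitions
(a 128-second scan), and the 2-step diffusion refinement adds a further small
gain on top.

## Layout

- `src/mrsdenoise/spectra.py` — FID/spectrum containers, unitary FFT, ppm axis
- `src/mrsdenoise/simulate.py` — synthetic acquisitions with ground truth
- `src/mrsdenoise/csvd.py` — Casorati SVD and the regularized projection
- `src/mrsdenoise/ddpm.py`, `network.py` — diffusion schedule, training, reverse chain
- `src/mrsdenoise/quantify.py` — SNR, FWHM, basis fit with analytic CRLB
- `src/mrsdenoise/fmrs.py` — time courses, smoothing, Kendall correlation
- `src/mrsdenoise/io.py`, `cli.py` — HDF5 container, SPAR/SDAT reader, CLI
- `docs/methods.md` — models, assumptions, parameter choices, limitations
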