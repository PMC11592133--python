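"""Denoising diffusion probabilistic model (DDPM) for 1D spectra.

Forward process: a Markov chain that mixes small Gaussian noise into a clean
spectrum s_0 over T steps with variance schedule beta_t, giving the closed
form marginal

    s_t = sqrt(abar_t) s_0 + sqrt(1 - abar_t) eps,   abar_t = prod(1 - beta_l).

Reverse process: a network eps_theta(s_t, t) predicts the mixed-in noise and
the posterior mean

    mu_theta = (s_t - beta_t / sqrt(1 - abar_t) * eps_theta) / sqrt(alpha_t)

walks the chain backwards.  For *measured* spectra the chain is entered
part-way: a noisy spectrum is identified directly with state s_n (no forward
re-noising) and n reverse steps are applied — n is the knob trading noise
removal against hallucination.  Defaults: 10 steps standalone, 2 steps after
low-rank (CSVD) denoising.

Spectra enter the network as 64x64 grids: the 2048-point FID is zero-padded
to 4096, transformed, the real part taken, reshaped row-major and scaled to
[-1, 1]; the scale is kept so the output can be mapped back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .csvd import CsvdConfig, BASELINE_CONFIG, csvd_denoise
from .network import DenoiseMLP
from .spectra import (
    AcquisitionHeader,
    FidSeries,
    Spectrum,
    fid_to_spectrum,
    spectrum_to_fid,
    zero_pad,
    apply_phase0,
)

__all__ = [
    "DiffusionSchedule",
    "NetworkSample",
    "make_schedule",
    "spectrum_to_sample",
    "sample_to_spectrum",
    "build_training_set",
    "forward_sample",
    "train",
    "TrainConfig",
    "reverse_step",
    "ddpm_denoise",
    "hybrid_denoise",
    "save_checkpoint",
    "load_checkpoint",
]

GRID_SIDE = 64
GRID_LEN = GRID_SIDE * GRID_SIDE  # 4096, the zero-padded spectrum length


@dataclass(frozen=True)
class DiffusionSchedule:
    """Variance schedule tables beta_t, alpha_t = 1 - beta_t, abar_t."""

    beta: np.ndarray
    alpha: np.ndarray
    alpha_bar: np.ndarray

    @property
    def T(self) -> int:
        return len(self.beta)

    def __post_init__(self) -> None:
        b = np.asarray(self.beta, dtype=float)
        if np.any(b <= 0) or np.any(b >= 1):
            raise ValueError("beta_t must lie in (0, 1)")
        if np.any(np.diff(b) < 0):
            raise ValueError("beta must be nondecreasing")
        if np.any(np.diff(self.alpha_bar) >= 0):
            raise ValueError("alpha_bar must be strictly decreasing")


def make_schedule(T: int = 1000, beta_start: float = 1e-5, beta_end: float = 1e-3) -> DiffusionSchedule:
    """Linear beta schedule from beta_start to beta_end inclusive over T steps."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if not (0 < beta_start <= beta_end < 1):
        raise ValueError("need 0 < beta_start <= beta_end < 1")
    beta = np.linspace(beta_start, beta_end, T)
    alpha = 1.0 - beta
    return DiffusionSchedule(beta=beta, alpha=alpha, alpha_bar=np.cumprod(alpha))


@dataclass
class NetworkSample:
    """A spectrum in network coordinates: 64x64 grid scaled to [-1, 1]."""

    grid: np.ndarray
    scale: float
    n_original: int
    phase_applied: float = 0.0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != (GRID_SIDE, GRID_SIDE):
            raise ValueError(f"grid must be {GRID_SIDE}x{GRID_SIDE}")
        if not self.scale > 0:
            raise ValueError("scale must be > 0 (degenerate all-zero spectrum?)")
        if np.max(np.abs(self.grid)) > 1.0 + 1e-12:
            raise ValueError("grid must lie in [-1, 1]")


def _padded_real_spectrum(fid: np.ndarray, header: AcquisitionHeader,
                          phase: float = 0.0) -> np.ndarray:
    padded = zero_pad(np.asarray(fid, dtype=np.complex128), GRID_LEN)
    if phase:
        padded = apply_phase0(padded, phase)
    spec = fid_to_spectrum(padded, header.with_n_points(GRID_LEN))
    return np.real(spec.values)


def spectrum_to_sample(spectrum: Spectrum, phase: float = 0.0,
                       source_id: str = "") -> NetworkSample:
    """Map a spectrum into network coordinates.

    The underlying FID is recovered, zero-padded 2048 -> 4096, optionally
    zero-order phased (training augmentation), re-transformed; the real part
    is reshaped row-major to 64x64 and divided by its max-abs.
    """
    n = spectrum.n_points
    if n not in (GRID_LEN // 2, GRID_LEN):
        raise ValueError(f"expected {GRID_LEN // 2} or {GRID_LEN} points, got {n}")
    fid = spectrum_to_fid(spectrum)
    real = _padded_real_spectrum(fid, spectrum.header, phase=phase)
    scale = float(np.max(np.abs(real)))
    if scale == 0.0:
        raise ValueError("all-zero spectrum cannot be normalized")
    return NetworkSample(
        grid=(real / scale).reshape(GRID_SIDE, GRID_SIDE),
        scale=scale,
        n_original=n,
        phase_applied=phase,
        source_id=source_id,
    )


def sample_to_spectrum(sample: NetworkSample, header: AcquisitionHeader) -> Spectrum:
    """Invert the normalization: real spectrum of length 4096 on the padded axis."""
    values = sample.grid.reshape(GRID_LEN) * sample.scale
    hdr = header.with_n_points(GRID_LEN)
    from .spectra import ppm_axis_for

    return Spectrum(values=values, ppm_axis=ppm_axis_for(hdr), header=hdr)


def build_training_set(
    clean_spectra: list[Spectrum],
    n_per_source: int = 2000,
    seed: int = 0,
    phase_range: tuple[float, float] = (-np.pi / 2, np.pi / 2),
) -> list[NetworkSample]:
    """Phase-augmented training samples from clean (averaged) spectra.

    Each source spawns ``n_per_source`` copies with a random zero-order
    phase drawn uniformly from ``phase_range`` (default a 180-degree span,
    [-90, +90] degrees) applied to the complex spectrum before the real
    part is taken.  Deterministic for a fixed seed.
    """
    if not clean_spectra:
        raise ValueError("clean_spectra must be nonempty")
    rng = np.random.default_rng(seed)
    out: list[NetworkSample] = []
    for k, spec in enumerate(clean_spectra):
        phases = rng.uniform(phase_range[0], phase_range[1], size=n_per_source)
        for phi in phases:
            out.append(spectrum_to_sample(spec, phase=float(phi), source_id=f"source{k}"))
    return out


def forward_sample(
    s0: np.ndarray,
    t: int,
    schedule: DiffusionSchedule,
    rng: np.random.Generator | int | None = None,
    eps: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Diffuse a clean grid to step t; returns (s_t, eps) with eps ~ N(0, I)."""
    if not (1 <= t <= schedule.T):
        raise ValueError(f"t={t} outside 1..{schedule.T}")
    s0 = np.asarray(s0, dtype=float)
    if eps is None:
        eps = np.random.default_rng(rng).standard_normal(s0.shape)
    ab = schedule.alpha_bar[t - 1]
    return np.sqrt(ab) * s0 + np.sqrt(1.0 - ab) * eps, eps


@dataclass
class TrainConfig:
    epochs: int = 20
    batch: int = 32
    lr: float = 1e-3
    seed: int = 0


def train(
    predictor: DenoiseMLP,
    samples: list[NetworkSample] | np.ndarray,
    schedule: DiffusionSchedule,
    config: TrainConfig | None = None,
) -> DenoiseMLP:
    """Fit eps_theta by minimizing E||eps - eps_theta(s_t, t)||^2, t uniform.

    Mutates and returns ``predictor``; the per-epoch loss curve accumulates
    in ``predictor.training_meta['loss_curve']``.
    """
    config = config or TrainConfig()
    if isinstance(samples, np.ndarray):
        grids = samples.reshape(len(samples), -1)
    else:
        if not samples:
            raise ValueError("samples must be nonempty")
        grids = np.stack([s.grid.reshape(-1) for s in samples])
    predictor.train_epochs(
        grids, schedule.alpha_bar,
        epochs=config.epochs, batch=config.batch, lr=config.lr, seed=config.seed,
    )
    return predictor


def reverse_step(
    s_t: np.ndarray,
    t: int,
    predictor: DenoiseMLP,
    schedule: DiffusionSchedule,
    rng: np.random.Generator | int | None = None,
    add_noise: bool = False,
) -> np.ndarray:
    """One reverse transition s_t -> s_{t-1}.

    The mean is mu_theta = (s_t - beta_t/sqrt(1-abar_t) * eps_theta)/sqrt(alpha_t).
    By default the chain is deterministic (posterior mean); with
    ``add_noise=True`` Gaussian noise of variance beta_t is injected for
    t > 1 (never at t = 1).  Short denoising chains never re-remove injected
    noise, so the mean chain is the default here.
    """
    if not (1 <= t <= schedule.T):
        raise ValueError(f"t={t} outside 1..{schedule.T}")
    s_t = np.asarray(s_t, dtype=float)
    beta = schedule.beta[t - 1]
    alpha = schedule.alpha[t - 1]
    ab = schedule.alpha_bar[t - 1]
    eps_hat = np.asarray(predictor.predict(s_t, t), dtype=float)
    mu = (s_t - beta / np.sqrt(1.0 - ab) * eps_hat) / np.sqrt(alpha)
    if add_noise and t > 1:
        z = np.random.default_rng(rng).standard_normal(s_t.shape)
        return mu + np.sqrt(beta) * z
    return mu


def _reverse_chain(grids: np.ndarray, n_steps: int, predictor: DenoiseMLP,
                   schedule: DiffusionSchedule, rng, add_noise: bool) -> np.ndarray:
    rng = np.random.default_rng(rng)
    out = grids
    for t in range(n_steps, 0, -1):
        out = reverse_step(out, t, predictor, schedule, rng=rng, add_noise=add_noise)
    return out


def ddpm_denoise(
    spectrum: Spectrum,
    n_steps: int,
    predictor: DenoiseMLP,
    schedule: DiffusionSchedule,
    rng: np.random.Generator | int | None = None,
    add_noise: bool = False,
) -> Spectrum:
    """Partial reverse denoising of a measured spectrum.

    The spectrum is mapped to network coordinates and identified *directly*
    with chain state s_{n_steps} (no forward re-noising); n_steps reverse
    transitions are applied and the normalization inverted.  ``n_steps=0``
    returns the input unchanged.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if n_steps == 0:
        return spectrum
    sample = spectrum_to_sample(spectrum)
    grid = _reverse_chain(sample.grid.reshape(1, -1), n_steps, predictor,
                          schedule, rng, add_noise)
    out = NetworkSample(
        grid=np.clip(grid.reshape(GRID_SIDE, GRID_SIDE), -1.0, 1.0),
        scale=sample.scale,
        n_original=sample.n_original,
        source_id=sample.source_id,
    )
    return sample_to_spectrum(out, spectrum.header)


def hybrid_denoise(
    series: FidSeries,
    cfg: CsvdConfig = BASELINE_CONFIG,
    predictor: DenoiseMLP | None = None,
    schedule: DiffusionSchedule | None = None,
    n_steps: int = 2,
    rng: np.random.Generator | int | None = None,
    add_noise: bool = False,
) -> FidSeries:
    """Low-rank projection first, then a short diffusion chain per signal.

    The diffusion stage refines the *real* part of each CSVD-denoised
    spectrum; the imaginary part is retained from the CSVD stage.
    ``n_steps=0`` degenerates to plain CSVD denoising.
    """
    low_rank = csvd_denoise(series, cfg)
    if n_steps == 0:
        return low_rank
    if predictor is None or schedule is None:
        raise ValueError("hybrid_denoise with n_steps > 0 needs a predictor and schedule")

    n = series.n_points
    # batch all signals through the reverse chain at once
    padded = np.zeros((series.n_signals, GRID_LEN), dtype=np.complex128)
    padded[:, :n] = low_rank.data
    specs = np.fft.fftshift(np.fft.fft(padded, axis=1), axes=1) / np.sqrt(GRID_LEN)
    reals = np.real(specs)
    imags = np.imag(specs)
    scales = np.max(np.abs(reals), axis=1)
    scales[scales == 0] = 1.0
    grids = reals / scales[:, None]
    grids = _reverse_chain(grids, n_steps, predictor, schedule, rng, add_noise)
    denoised_real = np.clip(grids, -1.0, 1.0) * scales[:, None]

    values = denoised_real + 1j * imags
    fids = np.fft.ifft(np.fft.ifftshift(values, axes=1), axis=1) * np.sqrt(GRID_LEN)
    return series.with_data(fids[:, :n])


def save_checkpoint(path, predictor: DenoiseMLP, schedule: DiffusionSchedule) -> None:
    """Single-file checkpoint: parameters + schedule + preprocessing metadata."""
    state = predictor.state_dict()
    arrays = {f"param_{k}": v for k, v in state["params"].items()}
    arrays["beta"] = schedule.beta
    arrays["loss_curve"] = np.asarray(state["training_meta"]["loss_curve"], dtype=float)
    meta = state["meta"]
    arrays["meta_ints"] = np.array([meta["n_in"], meta["hidden"], meta["emb_dim"],
                                    meta["emb_hidden"], meta["t_max"], meta["seed"],
                                    state["training_meta"]["epochs"],
                                    state["training_meta"]["seed"]])
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[DenoiseMLP, DiffusionSchedule]:
    with np.load(path) as data:
        ints = data["meta_ints"].astype(int)
        meta = dict(n_in=int(ints[0]), hidden=int(ints[1]), emb_dim=int(ints[2]),
                    emb_hidden=int(ints[3]), t_max=int(ints[4]), seed=int(ints[5]))
        params = {k[len("param_"):]: data[k] for k in data.files if k.startswith("param_")}
        tmeta = {"epochs": int(ints[6]), "seed": int(ints[7]),
                 "loss_curve": list(data["loss_curve"])}
        beta = data["beta"]
    net = DenoiseMLP.from_state_dict({"meta": meta, "params": params, "training_meta": tmeta})
    alpha = 1.0 - beta
    schedule = DiffusionSchedule(beta=beta, alpha=alpha, alpha_bar=np.cumprod(alpha))
    return net, schedule
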