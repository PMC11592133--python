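"""Synthetic single-voxel MRS acquisitions with known ground truth.

Emulates the two acquisition types the denoisers are designed for:

* a resting *baseline* scan — 32 non-averaged FIDs of the same voxel
  (TR/TE = 4000/22 ms), differing only in noise and small per-shot
  frequency/phase jitter;
* a *functional* scan during a capsaicin + heat pain paradigm — one FID per
  TR across a baseline period and a stimulation period, with a
  stimulus-locked glutamate amplitude modulation and a synthetic pain-rating
  (NRS, 0-10) trace.

Lines are Lorentzian (exponential T2* decay); no J-coupling evolution,
macromolecule baseline, or residual water is simulated.  The generator's
value is that the noiseless truth is known exactly, so denoisers can be
scored against it — something real in vivo data never offers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .spectra import AcquisitionHeader, FidSeries

__all__ = [
    "MetabolitePeak",
    "SyntheticTruth",
    "Paradigm",
    "RatingTrace",
    "default_basis",
    "default_noise",
    "default_paradigm",
    "load_defaults",
    "basis_names",
    "simulate_fid",
    "clean_fid",
    "simulate_baseline_dataset",
    "simulate_functional_dataset",
    "glu_gate",
    "nrs_trace",
]


@dataclass(frozen=True)
class MetabolitePeak:
    """One Lorentzian line of a metabolite's spectral pattern."""

    name: str
    chemical_shift: float  # ppm
    relative_amplitude: float  # weight within the metabolite
    t2_star: float  # ms

    def __post_init__(self) -> None:
        if not (0.0 < self.chemical_shift < 10.0):
            raise ValueError("chemical_shift must lie in (0, 10) ppm")
        if not self.relative_amplitude > 0:
            raise ValueError("relative_amplitude must be > 0")
        if not self.t2_star > 0:
            raise ValueError("t2_star must be > 0")


@dataclass
class SyntheticTruth:
    """Everything needed to reconstruct the noiseless signal exactly."""

    amplitudes: np.ndarray  # (n_signals, n_metabolites)
    metabolites: list[str]
    noise_sd: float
    phase_jitter_sd: float  # rad
    freq_jitter_sd: float  # Hz
    seed: int
    #: per-row draws actually used (for exact reconstruction in tests)
    phase_jitter: np.ndarray = field(default=None)  # type: ignore[assignment]
    freq_jitter: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.amplitudes = np.atleast_2d(np.asarray(self.amplitudes, dtype=float))
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def glu_trajectory(self) -> np.ndarray:
        """Ground-truth glutamate amplitude per signal."""
        return self.amplitudes[:, self.metabolites.index("Glu")]


@dataclass(frozen=True)
class Paradigm:
    """Timing of the capsaicin + heat pain stimulation (minutes, tr in ms)."""

    baseline_duration: float = 3.12
    stimulation_duration: float = 22.4
    heat_onset: float = 9.0
    heat_duration: float = 4.4
    tr: float = 4000.0

    def __post_init__(self) -> None:
        for name in ("baseline_duration", "stimulation_duration", "heat_onset",
                     "heat_duration", "tr"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.heat_onset + self.heat_duration > self.stimulation_duration:
            raise ValueError("heat window must end within the stimulation period")


@dataclass
class RatingTrace:
    """Numeric pain-intensity ratings (NRS, 0-10) over time (seconds)."""

    times: np.ndarray
    nrs: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.nrs = np.asarray(self.nrs, dtype=float)
        if len(self.times) != len(self.nrs):
            raise ValueError("times and nrs must have equal length")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.nrs < 0) or np.any(self.nrs > 10):
            raise ValueError("nrs values must lie in [0, 10]")


def load_defaults() -> dict:
    """Parsed contents of the packaged defaults.yaml."""
    with resources.files("mrsdenoise.data").joinpath("defaults.yaml").open() as fh:
        return yaml.safe_load(fh)


def default_basis(config: dict | None = None) -> dict[str, list[MetabolitePeak]]:
    """Default metabolite line table, grouped by metabolite name."""
    cfg = (config or load_defaults())["basis"]
    basis: dict[str, list[MetabolitePeak]] = {}
    for name, entry in cfg.items():
        basis[name] = [
            MetabolitePeak(
                name=name,
                chemical_shift=float(p["chemical_shift"]),
                relative_amplitude=float(p["relative_amplitude"]),
                t2_star=float(p["t2_star"]),
            )
            for p in entry["peaks"]
        ]
    return basis


def default_concentrations(config: dict | None = None) -> dict[str, float]:
    cfg = (config or load_defaults())["basis"]
    return {name: float(entry["concentration"]) for name, entry in cfg.items()}


def default_noise(config: dict | None = None) -> dict[str, float]:
    return {k: float(v) for k, v in (config or load_defaults())["noise"].items()}


def default_paradigm(config: dict | None = None) -> Paradigm:
    return Paradigm(**{k: float(v) for k, v in (config or load_defaults())["paradigm"].items()})


def basis_names(basis: dict[str, list[MetabolitePeak]]) -> list[str]:
    return list(basis.keys())


def clean_fid(
    amplitudes,
    basis: dict[str, list[MetabolitePeak]],
    header: AcquisitionHeader,
    freq_shift: float = 0.0,
    phase: float = 0.0,
) -> np.ndarray:
    """Noiseless FID for one set of per-metabolite amplitudes.

    Each line contributes ``a * w * exp(-i 2 pi (cs - ref) f0 t) *
    exp(-t / T2*)``; the sign of the modulation places the line at its
    chemical shift on the decreasing ppm axis of
    :func:`~mrsdenoise.spectra.fid_to_spectrum`.  ``freq_shift`` (Hz) and
    ``phase`` (rad) model per-shot scanner instability.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    if np.any(amplitudes < 0):
        raise ValueError("amplitudes must be nonnegative")
    names = basis_names(basis)
    if len(amplitudes) != len(names):
        raise ValueError("one amplitude per metabolite required")
    t = header.time_axis
    fid = np.zeros(header.n_points, dtype=np.complex128)
    f0 = header.spectrometer_frequency
    for a, name in zip(amplitudes, names):
        if a == 0.0:
            continue
        for pk in basis[name]:
            df = (pk.chemical_shift - header.reference_ppm) * f0 + freq_shift
            decay = np.exp(-t / (pk.t2_star * 1e-3))
            fid += a * pk.relative_amplitude * np.exp(-2j * np.pi * df * t) * decay
    return fid * np.exp(1j * phase)


def simulate_fid(
    amplitudes,
    basis: dict[str, list[MetabolitePeak]],
    header: AcquisitionHeader,
    noise_sd: float = 0.0,
    phase_jitter: float = 0.0,
    freq_jitter: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """One noisy FID: clean signal + iid complex Gaussian noise per point."""
    rng = np.random.default_rng(rng)
    fid = clean_fid(amplitudes, basis, header, freq_shift=freq_jitter, phase=phase_jitter)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=(2, header.n_points))
        fid = fid + noise[0] + 1j * noise[1]
    return fid


def _jitter_draws(rng, n, phase_sd, freq_sd):
    phase = rng.normal(0.0, phase_sd, size=n) if phase_sd > 0 else np.zeros(n)
    freq = rng.normal(0.0, freq_sd, size=n) if freq_sd > 0 else np.zeros(n)
    return phase, freq


def metabolite_profiles(basis: dict[str, list[MetabolitePeak]],
                        header: AcquisitionHeader) -> np.ndarray:
    """Unit-amplitude noiseless FID of each metabolite, stacked as rows."""
    names = basis_names(basis)
    L = np.zeros((len(names), header.n_points), dtype=np.complex128)
    eye = np.eye(len(names))
    for i in range(len(names)):
        L[i] = clean_fid(eye[i], basis, header)
    return L


def _assemble(amps, basis, header, noise_sd, phase_sd, freq_sd, seed) -> tuple[FidSeries, SyntheticTruth]:
    rng = np.random.default_rng(seed)
    n_signals = amps.shape[0]
    phase_j, freq_j = _jitter_draws(rng, n_signals, phase_sd, freq_sd)
    # vectorized synthesis: row i = (a_i . profiles) * global jitter ramp + noise
    L = metabolite_profiles(basis, header)
    t = header.time_axis
    data = amps.astype(complex) @ L
    data *= np.exp(1j * (phase_j[:, None] - 2.0 * np.pi * freq_j[:, None] * t[None, :]))
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=(n_signals, 2, header.n_points))
        data += noise[:, 0, :] + 1j * noise[:, 1, :]
    truth = SyntheticTruth(
        amplitudes=amps,
        metabolites=basis_names(basis),
        noise_sd=noise_sd,
        phase_jitter_sd=phase_sd,
        freq_jitter_sd=freq_sd,
        seed=seed,
        phase_jitter=phase_j,
        freq_jitter=freq_j,
    )
    series = FidSeries(data=data, header=header)
    return series, truth


def simulate_baseline_dataset(
    n_signals: int = 32,
    basis: dict[str, list[MetabolitePeak]] | None = None,
    header: AcquisitionHeader | None = None,
    amplitudes: np.ndarray | None = None,
    noise_sd: float | None = None,
    phase_jitter_sd: float | None = None,
    freq_jitter_sd: float | None = None,
    seed: int = 0,
) -> tuple[FidSeries, SyntheticTruth]:
    """Resting acquisition: ``n_signals`` repeats of one clean FID.

    Default conditions: 32 signals, static concentrations, per-shot noise and
    small frequency/phase jitter.  ``amplitudes`` may be (n_metabolites,) for
    a static voxel or (n_signals, n_metabolites) for custom per-shot truth.
    """
    if n_signals < 1:
        raise ValueError("n_signals must be >= 1")
    cfg = load_defaults()
    basis = basis or default_basis(cfg)
    header = header or AcquisitionHeader()
    noise = default_noise(cfg)
    noise_sd = noise["noise_sd"] if noise_sd is None else noise_sd
    phase_jitter_sd = noise["phase_jitter_sd"] if phase_jitter_sd is None else phase_jitter_sd
    freq_jitter_sd = noise["freq_jitter_sd"] if freq_jitter_sd is None else freq_jitter_sd
    if amplitudes is None:
        conc = default_concentrations(cfg)
        amplitudes = np.array([conc[m] for m in basis_names(basis)])
    amps = np.atleast_2d(np.asarray(amplitudes, dtype=float))
    if amps.shape[0] == 1:
        amps = np.repeat(amps, n_signals, axis=0)
    if amps.shape[0] != n_signals:
        raise ValueError("amplitudes rows must match n_signals")
    return _assemble(amps, basis, header, noise_sd, phase_jitter_sd, freq_jitter_sd, seed)


def glu_gate(t_min: np.ndarray, paradigm: Paradigm) -> np.ndarray:
    """Stimulus gate g(t) in [0, 1] multiplying the glutamate effect.

    ``t_min`` is time in minutes from stimulation onset.  Components:

    * a raised-cosine ramp over 2 min from onset up to a sustained level of
      0.4 (capsaicin alone keeps glutamate mildly elevated for the whole
      stimulation period);
    * a heat-locked bump: raised-cosine rise over 1 min after heat onset
      adding 0.6 (so g peaks at exactly 1.0 during the heat window), then an
      exponential relaxation (time constant 3 min) back toward the sustained
      level after the heat is removed.

    The gate is 0 for t < 0 (baseline).
    """
    t = np.asarray(t_min, dtype=float)
    g = np.zeros_like(t)
    ramp_len = 2.0
    sustained = 0.4
    in_ramp = (t >= 0) & (t < ramp_len)
    g[in_ramp] = sustained * 0.5 * (1 - np.cos(np.pi * t[in_ramp] / ramp_len))
    g[t >= ramp_len] = sustained

    bump = 0.6
    rise = 1.0
    h0, h1 = paradigm.heat_onset, paradigm.heat_onset + paradigm.heat_duration
    in_rise = (t >= h0) & (t < h0 + rise)
    g[in_rise] += bump * 0.5 * (1 - np.cos(np.pi * (t[in_rise] - h0) / rise))
    in_heat = (t >= h0 + rise) & (t <= h1)
    g[in_heat] += bump
    after = t > h1
    g[after] += bump * np.exp(-(t[after] - h1) / 3.0)
    return g


def nrs_trace(times_s: np.ndarray, paradigm: Paradigm) -> RatingTrace:
    """Synthetic pain-intensity (NRS) trace on the given time grid (seconds).

    Zero during baseline, logistic rise (time constant 1 min) after heat
    onset to a plateau of 5, then a slow linear decay after the heat is
    removed — a qualitative emulation of group-average ratings, not a
    behavioral model.
    """
    t_min = np.asarray(times_s, dtype=float) / 60.0
    h0 = paradigm.heat_onset
    h1 = h0 + paradigm.heat_duration
    plateau = 5.0
    nrs = plateau / (1.0 + np.exp(-(t_min - (h0 + 1.0)) / 1.0))
    nrs[t_min < 0] = 0.0
    after = t_min > h1
    # linear decay of 0.35 NRS points per minute after heat offset
    level_h1 = plateau / (1.0 + np.exp(-(h1 - (h0 + 1.0)) / 1.0))
    nrs[after] = np.clip(level_h1 - 0.35 * (t_min[after] - h1), 0.0, 10.0)
    return RatingTrace(times=np.asarray(times_s, dtype=float), nrs=nrs)


def simulate_functional_dataset(
    paradigm: Paradigm | None = None,
    glu_effect: float = 0.10,
    basis: dict[str, list[MetabolitePeak]] | None = None,
    header: AcquisitionHeader | None = None,
    n_stimulation_signals: int = 320,
    noise_sd: float | None = None,
    phase_jitter_sd: float | None = None,
    freq_jitter_sd: float | None = None,
    seed: int = 0,
) -> tuple[FidSeries, SyntheticTruth, RatingTrace]:
    """Functional acquisition: one FID per TR through baseline + stimulation.

    The glutamate amplitude is modulated as ``Glu * (1 + glu_effect * g(t))``
    with :func:`glu_gate` peaking at exactly 1, so the peak amplitude is
    ``(1 + glu_effect)`` times the baseline level.  Returns the series, the
    ground truth (including the exact Glu trajectory) and the ratings trace
    sampled at each TR.

    Note the stimulation period is represented by ``n_stimulation_signals``
    acquisitions (default 320); at TR = 4 s these cover the first 21.3 min
    of the nominal 22.4 min stimulation block.
    """
    if glu_effect < 0:
        raise ValueError("glu_effect must be >= 0")
    cfg = load_defaults()
    paradigm = paradigm or default_paradigm(cfg)
    basis = basis or default_basis(cfg)
    header = header or AcquisitionHeader(tr=paradigm.tr)
    noise = default_noise(cfg)
    noise_sd = noise["noise_sd"] if noise_sd is None else noise_sd
    phase_jitter_sd = noise["phase_jitter_sd"] if phase_jitter_sd is None else phase_jitter_sd
    freq_jitter_sd = noise["freq_jitter_sd"] if freq_jitter_sd is None else freq_jitter_sd

    tr_s = paradigm.tr / 1000.0
    n_base = int(round(paradigm.baseline_duration * 60.0 / tr_s))
    n_total = n_base + int(n_stimulation_signals)
    # acquisition times: stimulation onset at t = 0, baseline at negative t
    times_s = (np.arange(n_total) - n_base) * tr_s

    names = basis_names(basis)
    conc = default_concentrations(cfg)
    base_amp = np.array([conc[m] for m in names])
    amps = np.repeat(base_amp[None, :], n_total, axis=0)
    gate = glu_gate(times_s / 60.0, paradigm)
    amps[:, names.index("Glu")] *= 1.0 + glu_effect * gate

    series, truth = _assemble(
        amps, basis, header, noise_sd, phase_jitter_sd, freq_jitter_sd, seed
    )
    ratings = nrs_trace(times_s, paradigm)
    return series, truth, ratings
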