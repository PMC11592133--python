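"""Core data containers and signal-domain transforms for single-voxel MRS.

The universal currency is a stack of non-averaged complex free-induction
decays (FIDs) from one voxel plus its acquisition header.  Everything else in
the package (simulation, low-rank denoising, diffusion denoising,
quantification) speaks these types.

FFT convention
--------------
The FID -> spectrum map is the *unitary* discrete Fourier transform (1/sqrt(n)
scaling in both directions) with the zero-frequency bin centered.  Unitarity
means white noise has identical standard deviation in the time and frequency
domains, which makes every SNR statement domain-agnostic.  The chemical-shift
axis is ``reference_ppm - f / spectrometer_frequency`` for frequency offsets
``f`` spanning +-spectral_width/2, ordered so ppm decreases left to right (the
conventional MRS display direction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AcquisitionHeader",
    "FidSeries",
    "Spectrum",
    "fid_to_spectrum",
    "spectrum_to_fid",
    "zero_pad",
    "apply_phase0",
    "average_signals",
    "ppm_axis_for",
]

#: Water resonates at ~4.65 ppm at body temperature; the transmitter is
#: conventionally centered on it, so it anchors the ppm axis by default.
WATER_PPM = 4.65


@dataclass(frozen=True)
class AcquisitionHeader:
    """Acquisition metadata for a single-voxel MRS scan.

    Parameters
    ----------
    spectrometer_frequency : float
        Larmor frequency in MHz (~127.8 for protons at 3 T).
    spectral_width : float
        Receiver bandwidth in Hz.
    n_points : int
        Complex time-domain samples per FID.
    tr, te : float
        Repetition and echo time in ms.
    reference_ppm : float
        Chemical shift assigned to the carrier (center of the axis).
    """

    spectrometer_frequency: float = 127.8
    spectral_width: float = 2000.0
    n_points: int = 2048
    tr: float = 4000.0
    te: float = 22.0
    reference_ppm: float = WATER_PPM

    def __post_init__(self) -> None:
        if not self.spectrometer_frequency > 0:
            raise ValueError("spectrometer_frequency must be > 0")
        if not self.spectral_width > 0:
            raise ValueError("spectral_width must be > 0")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if not self.tr > 0:
            raise ValueError("tr must be > 0")

    @property
    def dwell_time(self) -> float:
        """Sampling interval in seconds."""
        return 1.0 / self.spectral_width

    @property
    def time_axis(self) -> np.ndarray:
        """Time of each FID sample in seconds, starting at 0."""
        return np.arange(self.n_points) * self.dwell_time

    def with_n_points(self, n: int) -> "AcquisitionHeader":
        return replace(self, n_points=int(n))


def ppm_axis_for(header: AcquisitionHeader, n_points: int | None = None) -> np.ndarray:
    """Chemical-shift axis (strictly decreasing) for a centered spectrum."""
    n = header.n_points if n_points is None else int(n_points)
    freqs = np.fft.fftshift(np.fft.fftfreq(n, d=1.0 / header.spectral_width))
    return header.reference_ppm - freqs / header.spectrometer_frequency


@dataclass
class FidSeries:
    """Stack of non-averaged complex FIDs acquired from one voxel.

    ``data`` has shape (n_signals, n_points).  ``signal_index`` preserves the
    acquisition order; ``is_water_suppressed`` flags rows acquired with water
    suppression (metabolite scans) versus water-reference scans.
    """

    data: np.ndarray
    header: AcquisitionHeader
    signal_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    is_water_suppressed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 2:
            raise ValueError("FidSeries.data must be 2-D (n_signals, n_points)")
        if self.data.shape[0] < 1:
            raise ValueError("FidSeries needs at least one signal")
        if not np.all(np.isfinite(self.data.view(np.float64))):
            raise ValueError("FidSeries.data contains non-finite samples")
        n = self.n_signals
        if self.signal_index is None:
            self.signal_index = np.arange(n)
        self.signal_index = np.asarray(self.signal_index)
        if self.is_water_suppressed is None:
            self.is_water_suppressed = np.ones(n, dtype=bool)
        self.is_water_suppressed = np.asarray(self.is_water_suppressed, dtype=bool)
        if len(self.signal_index) != n or len(self.is_water_suppressed) != n:
            raise ValueError("per-row metadata length must equal n_signals")
        if self.data.shape[1] != self.header.n_points:
            raise ValueError(
                f"data has {self.data.shape[1]} points but header says "
                f"{self.header.n_points}"
            )

    @property
    def n_signals(self) -> int:
        return self.data.shape[0]

    @property
    def n_points(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "FidSeries":
        """Same metadata, new sample matrix (shape-preserving)."""
        return FidSeries(
            data=data,
            header=self.header,
            signal_index=self.signal_index.copy(),
            is_water_suppressed=self.is_water_suppressed.copy(),
        )


@dataclass
class Spectrum:
    """A single frequency-domain spectrum on a decreasing ppm axis."""

    values: np.ndarray
    ppm_axis: np.ndarray
    header: AcquisitionHeader

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=float)
        if len(self.values) != len(self.ppm_axis):
            raise ValueError("values and ppm_axis length mismatch")
        if not np.all(np.diff(self.ppm_axis) < 0):
            raise ValueError("ppm_axis must be strictly decreasing")
        if not np.all(np.isfinite(np.asarray(self.values, dtype=np.complex128).view(np.float64))):
            raise ValueError("Spectrum.values contains non-finite samples")

    @property
    def n_points(self) -> int:
        return len(self.values)


def _check_finite_complex(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.complex128)
    if not np.all(np.isfinite(x.view(np.float64))):
        raise ValueError(f"{name} contains non-finite samples")
    return x


def fid_to_spectrum(fid: np.ndarray, header: AcquisitionHeader) -> Spectrum:
    """Unitary centered DFT of a time-domain FID.

    Energy is preserved (Parseval): ``||fid||^2 == ||values||^2``.  A pure
    tone ``exp(+i 2 pi df t)`` appears at ``reference_ppm - df / f0``.
    """
    fid = _check_finite_complex(fid, "fid")
    if len(fid) < 2:
        raise ValueError("fid must have length >= 2")
    n = len(fid)
    values = np.fft.fftshift(np.fft.fft(fid)) / np.sqrt(n)
    hdr = header if header.n_points == n else header.with_n_points(n)
    return Spectrum(values=values, ppm_axis=ppm_axis_for(hdr), header=hdr)


def spectrum_to_fid(spectrum: Spectrum) -> np.ndarray:
    """Inverse of :func:`fid_to_spectrum` (unitary)."""
    vals = np.asarray(spectrum.values, dtype=np.complex128)
    n = len(vals)
    return np.fft.ifft(np.fft.ifftshift(vals)) * np.sqrt(n)


def zero_pad(fid: np.ndarray, n_target: int) -> np.ndarray:
    """Append trailing zeros up to ``n_target`` samples (spectral interpolation)."""
    fid = np.asarray(fid)
    if n_target < len(fid):
        raise ValueError(f"n_target={n_target} < len(fid)={len(fid)}")
    if n_target == len(fid):
        return fid.copy()
    out = np.zeros(n_target, dtype=np.complex128)
    out[: len(fid)] = fid
    return out


def apply_phase0(x: np.ndarray, phi: float) -> np.ndarray:
    """Zero-order phase rotation: multiply every sample by exp(i*phi)."""
    return np.asarray(x) * np.exp(1j * float(phi))


def average_signals(series: FidSeries, subset=None) -> np.ndarray:
    """Arithmetic mean of the selected rows, per time point.

    ``subset=None`` averages every row.  Signal averaging is the conventional
    SNR recovery: averaging N acquisitions divides the noise SD by sqrt(N).
    """
    if subset is None:
        idx = np.arange(series.n_signals)
    else:
        idx = np.asarray(subset, dtype=int)
        if idx.size == 0:
            raise ValueError("subset must be nonempty")
        if idx.min() < 0 or idx.max() >= series.n_signals:
            raise IndexError("subset index out of range")
    return series.data[idx].mean(axis=0)
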