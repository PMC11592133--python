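"""File formats: the HDF5 spectra container and the Philips SPAR/SDAT reader.

The package's neutral on-disk currency is a single HDF5 file:

    /fid     complex128, (n_signals, n_points)      required
    /truth   float64, (n_signals, n_metabolites)    optional (simulator truth)
    /nrs     float64, (n, 2) columns time_s, rating optional
    attrs: spectrometer_frequency_mhz, spectral_width_hz, tr_ms, te_ms,
           reference_ppm  (all required);
           metabolites (optional, with /truth); times_s (optional)

For users of real Philips exports, :func:`read_spar_sdat` parses the
key-value SPAR header and decodes the SDAT payload (VAX F-floating 32-bit
values, little-endian with swapped 16-bit words) into complex FIDs.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .simulate import RatingTrace, SyntheticTruth
from .spectra import AcquisitionHeader, FidSeries

__all__ = [
    "write_container",
    "read_container",
    "read_spar_sdat",
    "vax_to_float",
    "float_to_vax",
]

_REQUIRED_ATTRS = (
    "spectrometer_frequency_mhz",
    "spectral_width_hz",
    "tr_ms",
    "te_ms",
    "reference_ppm",
)


def write_container(
    series: FidSeries,
    path,
    truth: SyntheticTruth | None = None,
    ratings: RatingTrace | None = None,
    times_s: np.ndarray | None = None,
    overwrite: bool = False,
) -> None:
    """Write a FidSeries (plus optional ground truth / ratings) to HDF5."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    with h5py.File(path, "w") as f:
        f.create_dataset("fid", data=series.data, track_times=False)
        f.create_dataset("signal_index", data=series.signal_index, track_times=False)
        f.create_dataset("is_water_suppressed", data=series.is_water_suppressed, track_times=False)
        h = series.header
        f.attrs["spectrometer_frequency_mhz"] = h.spectrometer_frequency
        f.attrs["spectral_width_hz"] = h.spectral_width
        f.attrs["tr_ms"] = h.tr
        f.attrs["te_ms"] = h.te
        f.attrs["reference_ppm"] = h.reference_ppm
        if truth is not None:
            f.create_dataset("truth", data=truth.amplitudes, track_times=False)
            f.attrs["metabolites"] = [m.encode() for m in truth.metabolites]
            f.attrs["truth_noise_sd"] = truth.noise_sd
            f.attrs["truth_seed"] = truth.seed
        if ratings is not None:
            f.create_dataset("nrs", data=np.column_stack([ratings.times, ratings.nrs]), track_times=False)
        if times_s is not None:
            f.create_dataset("times_s", data=np.asarray(times_s, dtype=float), track_times=False)


def read_container(path):
    """Read a container; returns (FidSeries, truth_amplitudes|None,
    RatingTrace|None, times_s|None)."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        for attr in _REQUIRED_ATTRS:
            if attr not in f.attrs:
                raise KeyError(f"container missing required attribute '{attr}'")
        if "fid" not in f:
            raise KeyError("container missing required dataset '/fid'")
        header = AcquisitionHeader(
            spectrometer_frequency=float(f.attrs["spectrometer_frequency_mhz"]),
            spectral_width=float(f.attrs["spectral_width_hz"]),
            n_points=f["fid"].shape[1],
            tr=float(f.attrs["tr_ms"]),
            te=float(f.attrs["te_ms"]),
            reference_ppm=float(f.attrs["reference_ppm"]),
        )
        series = FidSeries(
            data=f["fid"][()],
            header=header,
            signal_index=f["signal_index"][()] if "signal_index" in f else None,
            is_water_suppressed=(
                f["is_water_suppressed"][()] if "is_water_suppressed" in f else None
            ),
        )
        truth = f["truth"][()] if "truth" in f else None
        ratings = None
        if "nrs" in f:
            arr = f["nrs"][()]
            ratings = RatingTrace(times=arr[:, 0], nrs=arr[:, 1])
        times = f["times_s"][()] if "times_s" in f else None
    return series, truth, ratings, times


# ----------------------------------------------------------------------
# VAX F-floating <-> IEEE, and the Philips SPAR/SDAT pair
# ----------------------------------------------------------------------

def vax_to_float(raw: bytes) -> np.ndarray:
    """Decode a VAX F-floating byte string into float64 values.

    VAX F format (as stored on disk, little-endian with the two 16-bit
    words swapped relative to IEEE ordering): after swapping the words,
    bit 31 is the sign, bits 30-23 the exponent (excess 128) and bits 22-0
    the fraction with a hidden leading 0.1 (binary).  A zero exponent with
    a clear sign bit encodes true zero.
    """
    if len(raw) % 4:
        raise ValueError("VAX payload length must be a multiple of 4")
    words = np.frombuffer(raw, dtype="<u2").reshape(-1, 2)
    swapped = (words[:, 0].astype(np.uint32) << 16) | words[:, 1].astype(np.uint32)
    sign = (swapped >> 31) & 0x1
    expo = (swapped >> 23) & 0xFF
    frac = swapped & 0x7FFFFF
    mant = 0.5 + frac.astype(np.float64) / float(1 << 24)
    out = np.where(expo == 0, 0.0, mant * np.exp2(expo.astype(np.float64) - 128.0))
    return np.where(sign == 1, -out, out)


def float_to_vax(values: np.ndarray) -> bytes:
    """Encode float64 values as VAX F-floating bytes (inverse of
    :func:`vax_to_float`, used as a round-trip oracle in tests)."""
    values = np.asarray(values, dtype=np.float64).ravel()
    out = np.zeros(len(values), dtype=np.uint32)
    nonzero = values != 0
    v = np.abs(values[nonzero])
    expo = np.floor(np.log2(v)).astype(np.int64) + 1  # mantissa in [0.5, 1)
    mant = v / np.exp2(expo.astype(np.float64))
    frac = np.round((mant - 0.5) * (1 << 24)).astype(np.int64)
    # rounding can push the mantissa to 1.0: renormalize
    carry = frac >= (1 << 23)
    frac[carry] = 0
    expo[carry] += 1
    e = expo + 128
    if np.any((e < 1) | (e > 255)):
        raise OverflowError("value outside VAX F-floating range")
    word = (e.astype(np.uint32) << 23) | frac.astype(np.uint32)
    word |= (values[nonzero] < 0).astype(np.uint32) << 31
    out[nonzero] = word
    hi = (out >> 16).astype("<u2")
    lo = (out & 0xFFFF).astype("<u2")
    return np.column_stack([hi, lo]).tobytes()


def _parse_spar(text: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("!"):
            continue
        if ":" in line:
            key, _, val = line.partition(":")
            fields[key.strip()] = val.strip()
    return fields


def read_spar_sdat(spar_path, sdat_path=None) -> FidSeries:
    """Read a Philips SPAR/SDAT pair into a FidSeries.

    The SPAR text header supplies samples per FID, row count, synthesizer
    (spectrometer) frequency and sample (bandwidth) frequency; the SDAT
    binary payload holds VAX F-floating interleaved real/imaginary pairs.
    """
    spar_path = Path(spar_path)
    if sdat_path is None:
        for suffix in (".SDAT", ".sdat"):
            cand = spar_path.with_suffix(suffix)
            if cand.exists():
                sdat_path = cand
                break
        if sdat_path is None:
            raise FileNotFoundError(f"no SDAT companion found for {spar_path}")
    fields = _parse_spar(spar_path.read_text())
    try:
        samples = int(fields["samples"])
        rows = int(fields.get("rows", fields.get("spec_num_row", "1")))
        f0_hz = float(fields["synthesizer_frequency"])
        sw = float(fields["sample_frequency"])
    except KeyError as exc:
        raise ValueError(f"SPAR header missing required field {exc}") from exc
    tr = float(fields.get("repetition_time", 4000.0))
    te = float(fields.get("echo_time", 22.0))

    raw = Path(sdat_path).read_bytes()
    expected = rows * samples * 2 * 4
    if len(raw) < expected:
        raise ValueError(
            f"SDAT payload truncated: {len(raw)} bytes < expected {expected}"
        )
    flat = vax_to_float(raw[:expected])
    cplx = flat[0::2] + 1j * flat[1::2]
    data = cplx.reshape(rows, samples)
    header = AcquisitionHeader(
        spectrometer_frequency=f0_hz / 1e6,
        spectral_width=sw,
        n_points=samples,
        tr=tr,
        te=te,
    )
    return FidSeries(data=data, header=header)
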