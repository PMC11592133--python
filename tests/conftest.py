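"""Shared fixtures: default acquisition, basis matrices, and one trained
diffusion noise predictor reused by every test that exercises the DDPM or
hybrid pipeline (training it once keeps the suite fast)."""

from __future__ import annotations

import numpy as np
import pytest

import mrsdenoise as m
from mrsdenoise.simulate import basis_names, default_concentrations
from mrsdenoise.quantify import basis_matrix


@pytest.fixture(scope="session")
def header():
    return m.AcquisitionHeader()


@pytest.fixture(scope="session")
def basis():
    return m.default_basis()


@pytest.fixture(scope="session")
def base_amplitudes(basis):
    conc = default_concentrations()
    return np.array([conc[k] for k in basis_names(basis)])


@pytest.fixture(scope="session")
def basis_mat(basis, header):
    B, names = basis_matrix(basis, header)
    return B, names


def make_training_grids(basis, header, base_amplitudes, n_sources=10,
                        n_per_source=60, seed=42):
    """Clean averaged spectra from amplitude-varied synthetic subjects,
    phase-augmented into network samples."""
    rng = np.random.default_rng(seed)
    clean = []
    for s in range(n_sources):
        amps = base_amplitudes * rng.uniform(0.85, 1.15, size=len(base_amplitudes))
        series, _ = m.simulate_baseline_dataset(amplitudes=amps, seed=100 + s)
        clean.append(m.fid_to_spectrum(m.average_signals(series), header))
    samples = m.build_training_set(clean, n_per_source=n_per_source, seed=7)
    return np.stack([s.grid.reshape(-1) for s in samples])


@pytest.fixture(scope="session")
def trained_ddpm(basis, header, base_amplitudes):
    """(predictor, schedule, held-out grids): 500 training samples from 10
    synthetic subjects, 100 held out for generalization checks."""
    grids = make_training_grids(basis, header, base_amplitudes)
    schedule = m.make_schedule()
    net = m.DenoiseMLP(seed=0)
    m.train(net, grids[:500], schedule,
            m.TrainConfig(epochs=15, batch=32, lr=1e-3, seed=1))
    return net, schedule, grids[500:]
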