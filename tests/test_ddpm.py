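"""Diffusion machinery: schedule, network-domain mapping, training, reverse chain."""

import numpy as np
import pytest

import mrsdenoise as m
from mrsdenoise.ddpm import GRID_LEN, GRID_SIDE
from mrsdenoise.simulate import clean_fid


class ZeroPredictor:
    """Stub noise predictor returning all zeros (contract-compatible)."""

    def predict(self, grid, t):
        return np.zeros_like(np.asarray(grid, dtype=float))


class OraclePredictor:
    """Stub returning a fixed noise field (the exact eps used forward)."""

    def __init__(self, eps):
        self.eps = eps

    def predict(self, grid, t):
        return self.eps.reshape(np.shape(grid))


class TestSchedule:
    def test_defaults(self):
        sch = m.make_schedule()
        assert sch.T == 1000
        assert sch.beta[0] == pytest.approx(1e-5)
        assert sch.beta[-1] == pytest.approx(1e-3)

    def test_alpha_bar_first_and_identities(self):
        sch = m.make_schedule()
        assert sch.alpha_bar[0] == pytest.approx(1 - 1e-5)
        ratios = sch.alpha_bar[1:] / sch.alpha_bar[:-1]
        assert np.allclose(ratios, sch.alpha[1:], atol=1e-12)

    def test_alpha_bar_final_matches_direct_product(self):
        sch = m.make_schedule()
        direct = np.prod(1.0 - np.linspace(1e-5, 1e-3, 1000))
        assert abs(sch.alpha_bar[-1] - direct) < 1e-12
        assert sch.alpha_bar[-1] == pytest.approx(0.6034, abs=1e-3)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            m.make_schedule(beta_start=0.0)
        with pytest.raises(ValueError):
            m.make_schedule(beta_start=1e-3, beta_end=1e-5)
        with pytest.raises(ValueError):
            m.make_schedule(T=0)


class TestNetworkDomain:
    @pytest.fixture
    def spectrum(self, header, basis, base_amplitudes):
        fid = clean_fid(base_amplitudes, basis, header)
        return m.fid_to_spectrum(fid, header)

    def test_grid_is_normalized(self, spectrum):
        sample = m.spectrum_to_sample(spectrum)
        assert sample.grid.shape == (GRID_SIDE, GRID_SIDE)
        assert np.max(np.abs(sample.grid)) == pytest.approx(1.0)
        assert sample.n_original == 2048

    def test_round_trip_recovers_padded_real_part(self, spectrum, header):
        sample = m.spectrum_to_sample(spectrum)
        back = m.sample_to_spectrum(sample, header)
        fid = m.spectrum_to_fid(spectrum)
        padded = m.fid_to_spectrum(m.zero_pad(fid, GRID_LEN),
                                   header.with_n_points(GRID_LEN))
        ref = np.real(padded.values)
        assert np.linalg.norm(back.values - ref) / np.linalg.norm(ref) < 1e-9

    def test_grid_round_trip_exact(self, spectrum, header):
        sample = m.spectrum_to_sample(spectrum)
        again = m.spectrum_to_sample(m.sample_to_spectrum(sample, header))
        assert np.allclose(again.grid, sample.grid)

    def test_zero_spectrum_rejected(self, header):
        from mrsdenoise.spectra import ppm_axis_for
        zero = m.Spectrum(values=np.zeros(2048), ppm_axis=ppm_axis_for(header),
                          header=header)
        with pytest.raises(ValueError, match="zero"):
            m.spectrum_to_sample(zero)

    def test_scale_linearity(self, spectrum, header):
        sample = m.spectrum_to_sample(spectrum)
        doubled = m.NetworkSample(grid=sample.grid, scale=2 * sample.scale,
                                  n_original=sample.n_original)
        a = m.sample_to_spectrum(sample, header).values
        b = m.sample_to_spectrum(doubled, header).values
        assert np.allclose(b, 2 * a)


class TestTrainingSet:
    def test_source_count_multiplies(self, header, basis, base_amplitudes):
        spec = m.fid_to_spectrum(clean_fid(base_amplitudes, basis, header), header)
        samples = m.build_training_set([spec] * 10, n_per_source=20, seed=0)
        assert len(samples) == 200

    def test_default_samples_per_source_is_2000(self):
        import inspect
        sig = inspect.signature(m.build_training_set)
        assert sig.parameters["n_per_source"].default == 2000

    def test_zero_phase_reproduces_unaugmented(self, header, basis, base_amplitudes):
        spec = m.fid_to_spectrum(clean_fid(base_amplitudes, basis, header), header)
        plain = m.spectrum_to_sample(spec)
        phased = m.spectrum_to_sample(spec, phase=0.0)
        assert np.array_equal(plain.grid, phased.grid)

    def test_opposite_phases_same_magnitude(self, header, basis, base_amplitudes):
        fid = clean_fid(base_amplitudes, basis, header)
        phi = 0.8
        a = m.fid_to_spectrum(m.apply_phase0(m.zero_pad(fid, GRID_LEN), phi),
                              header.with_n_points(GRID_LEN))
        b = m.fid_to_spectrum(m.apply_phase0(m.zero_pad(fid, GRID_LEN), -phi),
                              header.with_n_points(GRID_LEN))
        assert np.allclose(np.abs(a.values), np.abs(b.values))

    def test_deterministic_for_seed(self, header, basis, base_amplitudes):
        spec = m.fid_to_spectrum(clean_fid(base_amplitudes, basis, header), header)
        a = m.build_training_set([spec], n_per_source=5, seed=3)
        b = m.build_training_set([spec], n_per_source=5, seed=3)
        for x, y in zip(a, b):
            assert np.array_equal(x.grid, y.grid)


class TestForwardProcess:
    def test_zero_noise_scales_input(self):
        sch = m.make_schedule()
        s0 = np.linspace(-1, 1, 64)
        st, eps = m.forward_sample(s0, 500, sch, eps=np.zeros(64))
        assert np.allclose(st, np.sqrt(sch.alpha_bar[499]) * s0)

    @pytest.mark.parametrize("t", [10, 100, 1000])
    def test_marginal_variance(self, t):
        # oracle: Var(s_t - sqrt(abar) s0) = 1 - abar_t
        sch = m.make_schedule()
        s0 = np.full(10_000, 0.3)
        st, eps = m.forward_sample(s0, t, sch, rng=0)
        resid = st - np.sqrt(sch.alpha_bar[t - 1]) * s0
        expected = 1.0 - sch.alpha_bar[t - 1]
        assert abs(np.var(resid) - expected) / expected < 0.05

    def test_seeded_determinism(self):
        sch = m.make_schedule()
        s0 = np.linspace(0, 1, 32)
        a = m.forward_sample(s0, 7, sch, rng=11)
        b = m.forward_sample(s0, 7, sch, rng=11)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_t_out_of_range(self):
        sch = m.make_schedule(T=10)
        with pytest.raises(ValueError):
            m.forward_sample(np.zeros(4), 11, sch)
        with pytest.raises(ValueError):
            m.forward_sample(np.zeros(4), 0, sch)


class TestTraining:
    def test_small_net_learns_and_is_reproducible(self):
        # tiny 64-cell problem: loss finite everywhere, beats implicit zero
        # predictor, and is bit-reproducible for a fixed seed
        rng = np.random.default_rng(0)
        s0 = rng.uniform(-1, 1, size=(64, 64)) * 0.2
        sch = m.make_schedule(T=50)
        nets = []
        for _ in range(2):
            net = m.DenoiseMLP(n_in=64, hidden=32, emb_hidden=16, t_max=50, seed=4)
            curve = net.train_epochs(s0, sch.alpha_bar, epochs=5, batch=16,
                                     lr=1e-3, seed=9)
            assert np.all(np.isfinite(curve))
            nets.append((net, curve))
        assert nets[0][1] == nets[1][1]
        x = rng.standard_normal((3, 64)).astype(np.float32)
        assert np.array_equal(nets[0][0].predict(x, [1, 2, 3]),
                              nets[1][0].predict(x, [1, 2, 3]))

    def test_trained_predictor_beats_zero_baseline(self, trained_ddpm):
        net, sch, heldout = trained_ddpm
        rng = np.random.default_rng(2)
        t = rng.integers(1, sch.T + 1, size=len(heldout))
        eps = rng.standard_normal(heldout.shape)
        a = sch.alpha_bar[t - 1][:, None]
        st = np.sqrt(a) * heldout + np.sqrt(1 - a) * eps
        mse = np.mean((net.predict(st.astype(np.float32), t) - eps) ** 2)
        assert mse < 1.0  # zero predictor scores Var(eps) = 1

    def test_loss_curve_recorded(self, trained_ddpm):
        net, _, _ = trained_ddpm
        curve = net.training_meta["loss_curve"]
        assert len(curve) >= 15 and np.all(np.isfinite(curve))


class TestReverseProcess:
    def test_zero_predictor_last_step(self):
        sch = m.make_schedule()
        s1 = np.linspace(-0.5, 0.5, 64)
        out = m.reverse_step(s1, 1, ZeroPredictor(), sch)
        assert np.allclose(out, s1 / np.sqrt(sch.alpha[0]))

    def test_oracle_predictor_recovers_posterior_mean(self):
        # oracle: closed-form forward posterior mean mu_tilde(s_t, s_0)
        sch = m.make_schedule()
        rng = np.random.default_rng(3)
        s0 = rng.uniform(-1, 1, 64) * 0.3
        t = 400
        st, eps = m.forward_sample(s0, t, sch, rng=4)
        out = m.reverse_step(st, t, OraclePredictor(eps), sch)
        ab_t = sch.alpha_bar[t - 1]
        ab_prev = sch.alpha_bar[t - 2]
        beta = sch.beta[t - 1]
        alpha = sch.alpha[t - 1]
        mu_tilde = (np.sqrt(ab_prev) * beta / (1 - ab_t) * s0
                    + np.sqrt(alpha) * (1 - ab_prev) / (1 - ab_t) * st)
        assert np.linalg.norm(out - mu_tilde) / np.linalg.norm(mu_tilde) < 1e-9

    def test_noise_injection_seeded(self):
        sch = m.make_schedule()
        s = np.linspace(-1, 1, 64)
        a = m.reverse_step(s, 5, ZeroPredictor(), sch, rng=1, add_noise=True)
        b = m.reverse_step(s, 5, ZeroPredictor(), sch, rng=1, add_noise=True)
        c = m.reverse_step(s, 5, ZeroPredictor(), sch, rng=2, add_noise=True)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
        # t = 1 never adds noise
        d = m.reverse_step(s, 1, ZeroPredictor(), sch, rng=1, add_noise=True)
        assert np.allclose(d, s / np.sqrt(sch.alpha[0]))


class TestDenoisers:
    def test_zero_steps_is_identity(self, header, basis, base_amplitudes):
        spec = m.fid_to_spectrum(clean_fid(base_amplitudes, basis, header), header)
        out = m.ddpm_denoise(spec, 0, None, None)
        assert out is spec

    def test_ddpm_preserves_axis_and_length(self, trained_ddpm, header, basis,
                                            base_amplitudes):
        net, sch, _ = trained_ddpm
        series, _ = m.simulate_baseline_dataset(seed=0)
        spec = m.fid_to_spectrum(m.zero_pad(series.data[0], GRID_LEN),
                                 header.with_n_points(GRID_LEN))
        out = m.ddpm_denoise(spec, 10, net, sch, rng=0)
        assert out.n_points == GRID_LEN
        assert np.array_equal(out.ppm_axis, spec.ppm_axis)

    def test_ten_steps_reduce_mse_to_truth(self, trained_ddpm, header, basis,
                                           base_amplitudes):
        net, sch, _ = trained_ddpm
        clean = clean_fid(base_amplitudes, basis, header)
        ref = np.real(m.fid_to_spectrum(m.zero_pad(clean, GRID_LEN),
                                        header.with_n_points(GRID_LEN)).values)
        wins = 0
        for seed in range(10):
            series, _ = m.simulate_baseline_dataset(
                seed=300 + seed, phase_jitter_sd=0.0, freq_jitter_sd=0.0)
            noisy = m.fid_to_spectrum(m.zero_pad(series.data[0], GRID_LEN),
                                      header.with_n_points(GRID_LEN))
            den = m.ddpm_denoise(noisy, 10, net, sch, rng=seed)
            mse_raw = np.mean((np.real(noisy.values) - ref) ** 2)
            mse_den = np.mean((np.real(den.values) - ref) ** 2)
            wins += mse_den < mse_raw
        assert wins >= 7

    def test_hybrid_zero_steps_equals_csvd(self, header):
        rng = np.random.default_rng(5)
        series = m.FidSeries(
            data=rng.normal(size=(8, 256)) + 1j * rng.normal(size=(8, 256)),
            header=header.with_n_points(256))
        cfg = m.CsvdConfig(r=2, lam=500.0)
        a = m.hybrid_denoise(series, cfg, n_steps=0)
        b = m.csvd_denoise(series, cfg)
        assert np.array_equal(a.data, b.data)

    def test_hybrid_preserves_shape_and_metadata(self, trained_ddpm):
        net, sch, _ = trained_ddpm
        series, _ = m.simulate_baseline_dataset(seed=1)
        out = m.hybrid_denoise(series, m.BASELINE_CONFIG, net, sch, n_steps=2, rng=0)
        assert out.data.shape == series.data.shape
        assert np.array_equal(out.signal_index, series.signal_index)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, trained_ddpm, tmp_path):
        net, sch, heldout = trained_ddpm
        path = tmp_path / "model.npz"
        m.save_checkpoint(path, net, sch)
        net2, sch2 = m.load_checkpoint(path)
        assert np.allclose(sch2.beta, sch.beta)
        x = heldout[:4].astype(np.float32)
        assert np.array_equal(net.predict(x, [1, 10, 100, 1000]),
                              net2.predict(x, [1, 10, 100, 1000]))
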