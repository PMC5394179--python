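"""Statistical correctness of the synthetic-recording generator.

The field simulator is checked mode-by-mode against the scalar
Ornstein–Uhlenbeck closed form, the equilibrium process against its analytic
autocovariance, spike statistics against their configured burstiness, and
artifact injection against the analytic covariance of the injected
processes.
"""

import numpy as np
import pytest
from scipy.signal import lfilter

from meafield import simulate as sim
from meafield.io import Recording, make_standard_layout
from meafield.theory import REFERENCE_PARAMS as P


class TestFieldSimulator:
    def test_deterministic_under_fixed_seed(self):
        grid = sim.FieldSimulationGrid(lattice_shape=(16, 16), time_step=1.0, duration=500.0)
        lay = make_standard_layout(2, 2, 0.2)
        a = sim.simulate_field(grid, P, seed=3, sample_positions=lay.positions)
        b = sim.simulate_field(grid, P, seed=3, sample_positions=lay.positions)
        assert np.array_equal(a["traces"], b["traces"])

    def test_mode_variances_match_scalar_ou_oracle(self):
        """Sampled Fourier modes are OU processes with rate γ + α·k̂²; their
        stationary variance must match an independently simulated scalar OU."""
        grid = sim.FieldSimulationGrid(lattice_shape=(16, 16), time_step=1.0, duration=40_000.0)
        out = sim.simulate_field(grid, P, seed=5, frame_stride=1)
        F = np.fft.rfft2(out["frames"], axes=(1, 2))
        V = sim.mode_stationary_variance(grid, P)
        lam = P.gamma + P.alpha * sim.laplacian_eigenvalues(grid)
        rng = np.random.default_rng(99)
        for (i, j) in [(1, 2), (3, 4), (5, 1)]:
            emp = np.mean(np.abs(F[:, i, j]) ** 2)
            # independent scalar OU with the same rate and stationary variance
            a = np.exp(-lam[i, j])
            w = rng.normal(0, np.sqrt(V[i, j] * (1 - a * a) / 2), size=(2, 200_000))
            x = lfilter([1.0], [1.0, -a], w, axis=1)[:, 1000:]
            oracle = np.sum(np.var(x, axis=1))
            assert emp == pytest.approx(V[i, j], rel=0.15)
            assert oracle == pytest.approx(V[i, j], rel=0.05)

    def test_lattice_variance_matches_fourier_sum(self):
        """Site variance equals the Fourier-sum closed form plus Sμ²(0)."""
        grid = sim.FieldSimulationGrid(lattice_shape=(32, 32), time_step=1.0, duration=60_000.0)
        lay = make_standard_layout(3, 3, 0.2)
        eq = sim.EquilibriumProcessParams(variance=4.0, timescale=2000.0, oscillation_frequency=None)
        out = sim.simulate_field(grid, P, equilibrium=eq, seed=9, sample_positions=lay.positions)
        nx, ny = grid.lattice_shape
        V = sim.mode_stationary_variance(grid, P)
        w = np.full(V.shape, 2.0)
        w[:, 0] = 1.0
        w[:, -1] = 1.0
        field_var = (w * V).sum() / (nx * ny) ** 2
        # filtered μ has variance slightly below Sμ²(0); bound loosely
        total = out["traces"].var(axis=1).mean()
        assert total == pytest.approx(field_var + 4.0, rel=0.30)

    def test_lattice_must_dwarf_array(self):
        grid = sim.FieldSimulationGrid(lattice_shape=(8, 8), time_step=1.0, duration=100.0)
        lay = make_standard_layout(4, 4, 0.2)
        with pytest.raises(ValueError, match="extent"):
            sim.simulate_field(grid, P, seed=0, sample_positions=lay.positions)

    def test_gaussianity_and_wick_factorization(self, small_field_recording):
        """Without spikes/quantization the field is Gaussian: third moments
        vanish and fourth moments obey the Wick pair combination."""
        x = small_field_recording.potentials[:2]
        x = x - x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1)
        skew = np.mean((x / sd[:, None]) ** 3, axis=1)
        kurt = np.mean((x / sd[:, None]) ** 4, axis=1) - 3.0
        assert np.all(np.abs(skew) < 0.3)
        assert np.all(np.abs(kurt) < 0.5)
        c01 = np.mean(x[0] * x[1])
        m4 = np.mean(x[0] ** 2 * x[1] ** 2)
        wick = sd[0] ** 2 * sd[1] ** 2 + 2 * c01**2
        assert m4 == pytest.approx(wick, rel=0.15)
        m3 = np.mean(x[0] ** 2 * x[1])
        assert abs(m3) < 0.15 * sd[0] ** 2 * sd[1]


class TestEquilibriumProcess:
    def test_zero_variance_is_identically_zero(self):
        mu = sim.simulate_equilibrium_potential(
            sim.EquilibriumProcessParams(variance=0.0), 5000.0, 1.0, seed=1
        )
        assert np.all(mu == 0)

    def test_ou_autocovariance_matches_analytic(self):
        params = sim.EquilibriumProcessParams(
            variance=5.0, timescale=300.0, oscillation_frequency=None
        )
        mu = sim.simulate_equilibrium_potential(params, 400_000.0, 1.0, seed=2)
        assert np.var(mu) == pytest.approx(5.0, rel=0.2)
        for lag in (100, 300, 600):
            emp = np.mean(mu[:-lag] * mu[lag:])
            assert emp == pytest.approx(5.0 * np.exp(-lag / 300.0), abs=0.6)

    def test_slow_regime_is_flat_below_100ms(self):
        params = sim.EquilibriumProcessParams(
            variance=6.0, timescale=1000.0, oscillation_frequency=None
        )
        assert params.covariance(100.0) / params.covariance(0.0) > 0.9
        # the default damped oscillation stays in the 0-2 Hz band
        assert 0.0 < sim.EquilibriumProcessParams().oscillation_frequency <= 0.002


class TestSpikes:
    def test_empty_template_list_is_identity(self, small_field_recording):
        out, truth = sim.inject_spikes(small_field_recording, [], seed=0)
        assert truth == []
        assert np.array_equal(out.potentials, small_field_recording.potentials)

    def test_single_negative_event_by_direct_construction(self, tiny_layout):
        rec = Recording(np.zeros((4, 2000)), 1.0, tiny_layout)
        tpl = sim.SpikeTemplate(polarity="negative", rate=0.0, amplitude_range=(30.0, 30.0))
        wave = tpl.sampled_waveform(1.0)
        s = 1000
        rec.potentials[2, s - len(wave) // 2 : s - len(wave) // 2 + len(wave)] -= 30.0 * wave
        assert rec.potentials[2].min() <= -25.0
        assert abs(rec.potentials[2, s] - (-30.0)) <= 5.0

    def test_bursty_config_has_elevated_fano_factor(self):
        """Bursts (< 1 s) give overdispersed 10 s bin counts; a slowly
        modulated Poisson train stays closer to Poisson."""
        tpl_burst = sim.SpikeTemplate(
            polarity="negative", rate=5.0,
            burst_structure={"burst_length": 500.0, "intra_burst_interval": 30.0},
        )
        rng = np.random.default_rng(7)
        times = sim._event_times(tpl_burst, 600.0, rng)
        counts, _ = np.histogram(times, bins=np.arange(0, 601, 10))
        fano_burst = counts.var() / counts.mean()
        tpl_hom = sim.SpikeTemplate(polarity="positive", rate=5.0)
        t2 = sim._event_times(tpl_hom, 600.0, rng)
        c2, _ = np.histogram(t2, bins=np.arange(0, 601, 10))
        fano_hom = c2.var() / c2.mean()
        assert fano_burst > 1.5
        assert fano_burst > fano_hom

    def test_ground_truth_records_exact_samples(self, small_field_recording):
        region = list(range(4))
        tpl = sim.SpikeTemplate(polarity="positive", rate=0.5)
        out, truth = sim.inject_spikes(small_field_recording, [(region, tpl)], seed=3)
        assert len(truth) > 0
        for ev in truth:
            assert ev.electrode in region
            assert ev.deviation >= 30.0  # positive polarity, range floor
            s = int(round(ev.time / out.sampling_interval))
            assert 0 <= s < out.n_samples

    def test_amplitude_range_validation(self):
        with pytest.raises(ValueError, match="10-500"):
            sim.SpikeTemplate(amplitude_range=(5.0, 30.0))


class TestArtifacts:
    def test_all_zero_params_is_identity(self, small_field_recording):
        params = sim.ArtifactParams(
            periodic_amplitude=0.0, noise_sd=0.0, quantization_step=0.0
        )
        out = sim.inject_artifacts(small_field_recording, params, seed=0)
        assert np.array_equal(out.potentials, small_field_recording.potentials)

    def test_periodic_component_is_undamped_and_common_mode(self, tiny_layout):
        rec = Recording(np.zeros((4, 60_000)), 1.0, tiny_layout)
        params = sim.ArtifactParams(noise_sd=0.0, quantization_step=0.0)
        out = sim.inject_artifacts(rec, params, seed=4)
        added = out.potentials
        assert np.allclose(added[0], added[1])  # common mode
        x = added[0] - added[0].mean()
        # autocovariance stays at full amplitude out to 10 s and is periodic
        ac = np.array(
            [np.mean(x[: len(x) - k] * x[k:]) for k in (0, 145, 1450, 10_005)]
        )
        assert ac[0] == pytest.approx(0.12, rel=0.05)
        assert np.allclose(ac[1:], ac[0], rtol=0.05)
        half = np.mean(x[: -72] * x[72:])  # half a period away: anticorrelated
        assert half < 0

    def test_measurement_noise_variance_and_support(self, tiny_layout):
        """2 μV noise with 0.05 ms correlation: ~4 μV² at lag 0, gone by
        0.2 ms (5 samples at 25 kHz)."""
        rec = Recording(np.zeros((4, 250_000)), 0.04, tiny_layout)
        params = sim.ArtifactParams(periodic_amplitude=0.0, quantization_step=0.0)
        out = sim.inject_artifacts(rec, params, seed=5)
        x = out.potentials
        var = x.var(axis=1).mean()
        assert var == pytest.approx(4.0, rel=0.1)
        lag5 = np.mean(x[:, :-5] * x[:, 5:])
        assert abs(lag5) < 0.1 * var

    def test_quantization_rounds_to_step(self, small_field_recording):
        params = sim.ArtifactParams(periodic_amplitude=0.0, noise_sd=0.0)
        out = sim.inject_artifacts(small_field_recording, params, seed=0)
        q = params.quantization_step
        assert np.allclose(out.potentials / q, np.round(out.potentials / q), atol=1e-9)


class TestGenerateRecording:
    def test_same_seed_identical_output(self):
        grid = sim.FieldSimulationGrid(lattice_shape=(64, 64), time_step=1.0, duration=3000.0)
        cfg = sim.default_config(grid=grid, seed=8)
        r1, t1 = sim.generate_recording(cfg)
        r2, t2 = sim.generate_recording(cfg)
        assert np.array_equal(r1.potentials, r2.potentials)
        assert len(t1["spikes"]) == len(t2["spikes"])

    def test_default_config_is_paper_like(self):
        cfg = sim.default_config()
        assert cfg.model.alpha == pytest.approx(0.0025)
        assert cfg.model.gamma == pytest.approx(0.0030)
        assert cfg.model.sigma2 == pytest.approx(0.035)
        assert cfg.layout.spacing == pytest.approx(0.2)
        assert len(cfg.layout.active_indices) == 58
        assert cfg.artifacts.periodic_period == 145.0

    def test_activity_field_shape_validation(self):
        grid = sim.FieldSimulationGrid(lattice_shape=(16, 16), time_step=1.0, duration=200.0)
        with pytest.raises(ValueError, match="lattice shape"):
            sim.simulate_field(grid, P, activity_field=np.ones((8, 8)), seed=0)
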