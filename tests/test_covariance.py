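"""Covariance estimation, artifact profiles and the slow/fast split.

The estimator is held to exact agreement with a naive double loop on small
instances; artifact estimators are checked on analytically constructed
tables and on paired simulations; the slow row is checked against the
filtered equilibrium covariance by quadrature.
"""

import numpy as np
import pytest

from meafield import simulate as sim
from meafield.covariance import (
    ArtifactProfiles,
    CovarianceTable,
    decompose_slow_fast,
    default_lag_grid,
    estimate_covariance,
    estimate_periodic_artifact,
    estimate_short_lag_artifact,
    remove_artifacts,
)
from meafield.io import Recording, make_standard_layout
from meafield.theory import (
    REFERENCE_PARAMS as P,
    s_fast_theory,
    s_slow_from_equilibrium_covariance,
)


def naive_covariance(rec, lags):
    """Brute-force double loop over ordered pairs and time samples."""
    active = rec.layout.active_indices
    p = rec.potentials[active]
    p = p - p.mean(axis=1, keepdims=True)
    pos = rec.layout.positions[active]
    n = p.shape[1]
    cells = {}
    for i in range(len(active)):
        for j in range(len(active)):
            rho = round(float(np.hypot(*(pos[i] - pos[j]))), 9)
            if rho == 0 and i != j:
                continue
            for lag in lags:
                ell = int(round(lag / rec.sampling_interval))
                vals = 0.5 * (
                    np.mean(p[i, : n - ell] * p[j, ell:])
                    + np.mean(p[j, : n - ell] * p[i, ell:])
                )
                cells.setdefault((rho, lag), []).append(vals)
    return {k: np.mean(v) for k, v in cells.items()}


class TestEstimator:
    def test_zero_recording_gives_zero_table(self, tiny_layout):
        rec = Recording(np.zeros((4, 100)), 1.0, tiny_layout)
        tab = estimate_covariance(rec, [0.0, 1.0, 5.0])
        assert np.all(tab.values == 0)
        assert tab.pair_counts[0] == 4  # self pairs

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        layout = make_standard_layout(2, 2, 0.2)
        rec = Recording(rng.normal(size=(4, 100)), 1.0, layout)
        lags = [0.0, 1.0, 3.0, 7.0]
        tab = estimate_covariance(rec, lags)
        want = naive_covariance(rec, lags)
        for i, rho in enumerate(tab.separations):
            for j, lag in enumerate(tab.lags):
                assert tab.values[i, j] == pytest.approx(
                    want[(round(float(rho), 9), lag)], abs=1e-12
                )

    def test_two_electrode_toy_case(self):
        p = np.array([[1.0, 2.0, 3.0, 4.0, 5.0], [2.0, 1.0, 2.0, 1.0, 2.0]])
        layout = make_standard_layout(1, 2, 0.2)
        rec = Recording(p, 1.0, layout)
        tab = estimate_covariance(rec, [0.0, 1.0])
        want = naive_covariance(rec, [0.0, 1.0])
        for i, rho in enumerate(tab.separations):
            for j, lag in enumerate(tab.lags):
                assert tab.values[i, j] == pytest.approx(want[(round(float(rho), 9), lag)])

    def test_reference_electrodes_excluded(self, rng):
        layout = make_standard_layout(2, 2, 0.2, reference_index=0)
        rec = Recording(rng.normal(size=(4, 200)), 1.0, layout)
        tab = estimate_covariance(rec, [0.0])
        assert tab.pair_counts[0] == 3

    def test_monotone_in_separation_for_simulated_field(self, small_field_recording):
        tab = estimate_covariance(small_field_recording, [0.0])
        assert np.all(np.diff(tab.values[:, 0]) < 0)

    def test_lag_must_be_sample_multiple(self, small_field_recording):
        with pytest.raises(ValueError, match="multiple"):
            estimate_covariance(small_field_recording, [0.5 * np.pi])


class TestPeriodicArtifact:
    def _table(self, s0, step=1.0):
        lags = np.arange(len(s0)) * step
        return CovarianceTable(
            separations=np.array([0.0]),
            lags=lags,
            values=s0[None, :],
            pair_counts=np.array([10]),
            sample_counts=np.ones(len(s0)),
        )

    def test_smooth_covariance_yields_null_profile(self):
        lags = np.arange(3000)
        smooth = 5.0 * np.exp(-lags / 2000.0)
        prof = estimate_periodic_artifact(self._table(smooth))
        injected_scale = 0.12
        assert np.max(np.abs(prof.periodic_profile)) < 0.05 * injected_scale

    def test_injected_cosine_recovered_within_ten_percent(self):
        lags = np.arange(4000.0)
        s0 = 5.0 * np.exp(-lags / 2000.0) + 0.12 * np.cos(2 * np.pi * lags / 145.0 + 0.7)
        prof = estimate_periodic_artifact(self._table(s0))
        target = 0.12 * np.cos(2 * np.pi * prof.periodic_phase / 145.0 + 0.7)
        target -= target.mean()
        assert np.max(np.abs(prof.periodic_profile)) == pytest.approx(0.12, rel=0.1)
        assert np.max(np.abs(prof.periodic_profile - target)) < 0.012

    def test_folding_is_phase_consistent(self):
        lags = np.arange(4000.0)
        wave = 0.1 * np.cos(2 * np.pi * lags / 145.0 + 1.1)
        p1 = estimate_periodic_artifact(self._table(wave))
        shifted = 0.1 * np.cos(2 * np.pi * (lags + 145.0) / 145.0 + 1.1)
        p2 = estimate_periodic_artifact(self._table(shifted))
        assert np.allclose(p1.periodic_profile, p2.periodic_profile, atol=1e-9)

    def test_profile_has_zero_mean(self):
        lags = np.arange(4000.0)
        s0 = 1.0 + 0.2 * np.cos(2 * np.pi * lags / 145.0)
        prof = estimate_periodic_artifact(self._table(s0))
        assert prof.periodic_profile.mean() == pytest.approx(0.0, abs=1e-12)

    def test_needs_two_periods_beyond_long_lag_start(self):
        with pytest.raises(ValueError, match="two periods"):
            estimate_periodic_artifact(self._table(np.zeros(1100)))


class TestShortLagArtifact:
    def _table_25khz(self, s0):
        lags = np.arange(len(s0)) * 0.04
        return CovarianceTable(
            separations=np.array([0.0]),
            lags=lags,
            values=s0[None, :],
            pair_counts=np.array([10]),
            sample_counts=np.ones(len(s0)),
        )

    def test_smooth_log_covariance_yields_null_profile(self):
        lags = np.arange(1, 200) * 0.04
        s0 = np.concatenate([[10.0], 3.0 - 0.5 * np.log(lags)])
        prof = estimate_short_lag_artifact(self._table_25khz(s0))
        # away from τ=0 (where log extrapolation is floored) the residual ≈ 0
        assert np.max(np.abs(prof.short_lag_profile[1:])) < 0.02

    def test_profile_confined_to_support(self):
        lags = np.arange(1, 300) * 0.04
        s0 = np.concatenate([[12.0], 3.0 - 0.5 * np.log(lags)])
        prof = estimate_short_lag_artifact(self._table_25khz(s0), support=0.2)
        assert prof.short_lag_lags.max() <= 0.2 + 1e-12
        assert prof.short_lag_support == 0.2

    def test_unresolvable_support_rejected(self):
        lags = np.arange(10.0)  # 1 ms spacing cannot resolve 0.2 ms
        tab = CovarianceTable(
            separations=np.array([0.0]),
            lags=lags,
            values=np.ones((1, 10)),
            pair_counts=np.array([5]),
            sample_counts=np.ones(10),
        )
        with pytest.raises(ValueError, match="resolve"):
            estimate_short_lag_artifact(tab)


class TestRemovalAndDecomposition:
    def _toy_table(self):
        seps = np.array([0.0, 0.2, 1.7])
        lags = np.array([0.0, 1.0, 2.0])
        vals = np.arange(9, dtype=float).reshape(3, 3)
        return CovarianceTable(seps, lags, vals, np.array([3, 4, 2]), np.ones(3))

    def test_zero_profiles_are_identity(self):
        tab = self._toy_table()
        out = remove_artifacts(tab, ArtifactProfiles())
        assert np.array_equal(out.values, tab.values)

    def test_short_lag_profile_touches_only_rho_zero(self):
        tab = self._toy_table()
        prof = ArtifactProfiles(
            short_lag_support=1.0,
            short_lag_lags=np.array([0.0, 1.0]),
            short_lag_profile=np.array([2.0, 1.0]),
        )
        out = remove_artifacts(tab, prof)
        assert out.values[0, 0] == tab.values[0, 0] - 2.0
        assert out.values[0, 1] == tab.values[0, 1] - 1.0
        assert np.array_equal(out.values[1:], tab.values[1:])

    def test_lag_grid_mismatch_rejected(self):
        tab = self._toy_table()
        prof = ArtifactProfiles(
            short_lag_support=1.0,
            short_lag_lags=np.array([0.37]),
            short_lag_profile=np.array([1.0]),
        )
        with pytest.raises(ValueError, match="lag grid"):
            remove_artifacts(tab, prof)

    def test_fast_vanishes_at_rho_large(self):
        dec = decompose_slow_fast(self._toy_table(), rho_large=1.7)
        assert np.all(dec.fast.values[2] == 0)
        assert np.array_equal(dec.slow, self._toy_table().values[2])

    def test_default_reference_separation_is_1p7(self):
        import inspect

        sig = inspect.signature(decompose_slow_fast)
        assert sig.parameters["rho_large"].default == 1.7

    def test_missing_bin_rejected(self):
        with pytest.raises(ValueError, match="separation bin"):
            decompose_slow_fast(self._toy_table(), rho_large=0.9)

    def test_paired_simulation_artifact_removal(self):
        """Injecting then estimating+removing both artifacts reproduces the
        artifact-free covariance of the same field realization."""
        grid = sim.FieldSimulationGrid(lattice_shape=(32, 32), time_step=1.0, duration=60_000.0)
        layout = make_standard_layout(4, 4, 0.2)
        out = sim.simulate_field(grid, P, seed=303, sample_positions=layout.positions)
        clean = Recording(out["traces"], 1.0, layout)
        dirty = sim.inject_artifacts(clean, sim.ArtifactParams(), seed=304)
        lags = default_lag_grid(1.0)
        tab_free = estimate_covariance(clean, lags)
        tab_dirty = estimate_covariance(dirty, lags)
        long_lags = np.arange(0, 5001) * 1.0
        prof = estimate_periodic_artifact(
            estimate_covariance(dirty, long_lags, auto_only=True)
        )
        cleaned = remove_artifacts(tab_dirty, prof)
        diff = cleaned.values - tab_free.values
        # the 4 μV² measurement-noise variance legitimately remains at (0,0):
        # its 0.05 ms support cannot be resolved at 1 kHz sampling
        assert diff[0, 0] == pytest.approx(4.0, abs=0.5)
        mask = np.ones_like(diff, bool)
        mask[0, 0] = False
        assert np.max(np.abs(diff[mask])) < 0.15

    def test_slow_row_matches_filtered_equilibrium_covariance(self):
        """The ρ_large row equals the γ-filtered Sμ² (by quadrature) plus the
        small residual fast covariance at that separation.

        Needs a lattice much larger than the 0.91 mm correlation length so
        periodic images do not inflate covariances at ~1 mm separations.
        """
        grid = sim.FieldSimulationGrid(lattice_shape=(64, 64), time_step=1.0, duration=200_000.0)
        layout = make_standard_layout(4, 4, 0.2)
        eq = sim.EquilibriumProcessParams(
            variance=6.0, timescale=1000.0, oscillation_frequency=None
        )
        out = sim.simulate_field(grid, P, equilibrium=eq, seed=305,
                                 sample_positions=layout.positions)
        rec = Recording(out["traces"], 1.0, layout)
        lags = np.array([0.0, 10.0, 50.0, 100.0])
        tab = estimate_covariance(rec, lags)
        rho_l = float(tab.separations[-1])
        dec = decompose_slow_fast(tab, rho_large=rho_l, tol=1e-6)
        for j, tau in enumerate(lags):
            theory = s_slow_from_equilibrium_covariance(
                P.gamma, eq.covariance, tau
            ) + s_fast_theory(P, rho_l, tau)
            assert dec.slow[j] == pytest.approx(theory, rel=0.35, abs=0.3)
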