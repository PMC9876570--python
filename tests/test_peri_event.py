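"""Alignment, permutation null, z-scoring, bootstrap, noise correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ripplecortex.peri_event import (
    PeriEventEnsemble,
    align_events,
    asymmetry_index,
    bootstrap_average,
    build_null,
    ensemble_correlation,
    resample_ensemble,
    zscore_against_null,
)

RATE = 100.0


class TestAlign:
    def test_indexing_contract(self):
        sig = np.arange(1000.0)
        ens = align_events(sig, RATE, [5.0], window=1.0)
        assert ens.values.shape == (1, 201)
        assert ens.lags[100] == 0.0
        assert ens.values[0, 100] == 500.0

    def test_delta_at_centers_gives_delta_at_lag_zero(self):
        sig = np.zeros(2000)
        centers = [4.0, 9.0, 14.0]
        for c in centers:
            sig[int(c * RATE)] = 1.0
        ens = align_events(sig, RATE, centers, window=0.5)
        mean = ens.mean()
        assert mean[ens.lags == 0.0] == 1.0
        assert np.all(mean[ens.lags != 0.0] == 0.0)

    def test_edge_events_dropped_and_empty_raises(self):
        sig = np.zeros(500)
        ens = align_events(sig, RATE, [0.2, 2.5], window=1.0)
        assert ens.n_events == 1
        with pytest.raises(ValueError, match="fits"):
            align_events(sig, RATE, [0.2], window=1.0)

    def test_noiseless_stack_alignment_recovers_kernel(self):
        from ripplecortex import SynthConfig, default_masks, generate_lfp
        from ripplecortex.synthetic import generate_widefield_stack

        cfg = SynthConfig(rng_seed=8, duration_s=60.0)
        cfg.noise_sd["widefield"] = 0.0
        _, truth = generate_lfp(cfg)
        masks = default_masks((16, 16))
        stack = generate_widefield_stack(cfg, masks, truth, drift_amplitude=0.0)
        ens = align_events(stack, cfg.stack_rate, truth.ripple_times, 1.0)
        arsc = ens.values[:, :, masks["aRSC"]].mean(axis=-1)
        k2 = truth.component_temporal_kernels[1]
        spatial = truth.component_spatial_modes[1][masks["aRSC"]].mean()
        amps = truth.component_event_amplitudes[ens.event_ids, 1]
        # component 1 contributes too; project out via lstsq on both kernels
        k1 = truth.component_temporal_kernels[0]
        design = np.column_stack([k1, k2])
        coef, *_ = np.linalg.lstsq(design, arsc.T, rcond=None)
        fitted_amp2 = coef[1] / spatial
        np.testing.assert_allclose(fitted_amp2, amps, rtol=0.05, atol=0.05)


class TestNull:
    def test_surrogates_preserve_count_and_span(self, rng):
        sig = rng.standard_normal(6000)
        centers = np.sort(rng.uniform(5.0, 55.0, size=12))
        null = build_null(sig, RATE, centers, window=1.0, n_perm=30, seed=0)
        assert null.surrogate_times.shape == (30, 12)
        np.testing.assert_allclose(null.surrogate_times[:, 0], centers[0])
        np.testing.assert_allclose(
            null.surrogate_times[:, -1] - null.surrogate_times[:, 0],
            centers[-1] - centers[0],
        )

    def test_null_sd_matches_clt(self, rng):
        """CLT oracle: per-lag null SD ~ signal SD / sqrt(R)."""
        sig = 2.0 * rng.standard_normal(30000)
        centers = 10.0 + np.cumsum(2.0 + rng.exponential(2.0, size=40))
        centers = centers[centers < 280.0]
        null = build_null(sig, RATE, centers, window=0.5, n_perm=300, seed=1)
        expected = 2.0 / np.sqrt(centers.size)
        assert null.sd.mean() == pytest.approx(expected, rel=0.1)

    def test_determinism_and_validation(self, rng):
        sig = rng.standard_normal(3000)
        centers = [5.0, 10.0, 15.0, 20.0]
        n1 = build_null(sig, RATE, centers, n_perm=25, seed=7)
        n2 = build_null(sig, RATE, centers, n_perm=25, seed=7)
        np.testing.assert_array_equal(n1.surrogate_times, n2.surrogate_times)
        with pytest.raises(ValueError, match="n_perm"):
            build_null(sig, RATE, centers, n_perm=10)
        with pytest.raises(ValueError, match="centers"):
            build_null(sig, RATE, [5.0], n_perm=25)


class TestZscore:
    def _null(self, rng, sigma=1.0):
        sig = sigma * rng.standard_normal(20000)
        centers = 10.0 + np.cumsum(2.0 + rng.exponential(1.5, size=30))
        centers = centers[centers < 190.0]
        return sig, centers, build_null(sig, RATE, centers, 0.5, n_perm=100, seed=0)

    def test_null_process_calibrates_to_unit_z(self, rng):
        sig, centers, null = self._null(rng)
        zs = []
        perm_rng = np.random.default_rng(5)
        for _ in range(100):
            probe = centers[0] + np.r_[0, np.cumsum(perm_rng.permutation(np.diff(centers)))]
            ens = align_events(sig, RATE, probe, 0.5)
            zs.append(zscore_against_null(ens.mean(), null))
        zs = np.asarray(zs)
        assert abs(zs.mean()) < 0.15
        assert zs.std() == pytest.approx(1.0, abs=0.15)

    def test_implanted_kernel_z_amplitude(self, rng):
        """Constructed oracle: adding a kernel of 3 null-SD at lag 0
        raises the mean z at lag 0 by exactly 3 (z-scoring is linear)."""
        sig, centers, null = self._null(rng)
        center_idx = (null.lags.size - 1) // 2
        kernel_amp = 3.0 * null.sd[center_idx]
        sig2 = sig.copy()
        lag_grid = np.arange(-50, 51)
        bump = kernel_amp * np.exp(-(lag_grid**2) / (2 * 5.0**2))
        for c in centers:
            i = int(round(c * RATE))
            sig2[i - 50 : i + 51] += bump
        z_with = zscore_against_null(align_events(sig2, RATE, centers, 0.5).mean(), null)
        z_without = zscore_against_null(align_events(sig, RATE, centers, 0.5).mean(), null)
        assert z_with[center_idx] - z_without[center_idx] == pytest.approx(3.0, abs=1e-9)
        # and the absolute z at the kernel peak is ~3 (background is ~N(0,1))
        assert z_with[center_idx] == pytest.approx(3.0, abs=3.5)

    def test_affine_invariance(self, rng):
        sig, centers, _ = self._null(rng)
        for scale in (1.0, 37.5):
            null = build_null(sig * scale, RATE, centers, 0.5, n_perm=100, seed=0)
            ens = align_events(sig * scale, RATE, centers, 0.5)
            z = zscore_against_null(ens, null)
            if scale == 1.0:
                ref = z.values
        np.testing.assert_allclose(z.values, ref, rtol=1e-9)

    def test_zero_null_sd_rejected(self, rng):
        sig, centers, null = self._null(rng)
        null.sd[3] = 0.0
        ens = align_events(sig, RATE, centers, 0.5)
        with pytest.raises(ValueError, match="zero"):
            zscore_against_null(ens, null)


class TestBootstrap:
    def _ens(self, rng, r=80, l=21):
        return PeriEventEnsemble(rng.standard_normal((r, l)), np.arange(l) / RATE, np.arange(r))

    def test_grand_mean_is_unbiased(self, rng):
        ens = self._ens(rng)
        draws = bootstrap_average(ens, n_draws=400, draw_size=50, seed=0)
        np.testing.assert_allclose(draws.mean(axis=0), ens.mean(), atol=0.1)

    def test_reproducible_single_draw(self, rng):
        ens = self._ens(rng)
        d1 = bootstrap_average(ens, n_draws=1, seed=3)
        d2 = bootstrap_average(ens, n_draws=1, seed=3)
        np.testing.assert_array_equal(d1, d2)

    def test_draw_spread_matches_analytic_bootstrap_variance(self, rng):
        """Oracle: SD across draws ~ SD(ensemble)/sqrt(draw_size)."""
        ens = self._ens(rng, r=200)
        draws = bootstrap_average(ens, n_draws=2000, draw_size=50, seed=1)
        expected = ens.values.std(axis=0) / np.sqrt(50)
        np.testing.assert_allclose(draws.std(axis=0), expected, rtol=0.15)


class TestEnsembleCorrelation:
    def test_self_correlation_diagonal_is_exactly_one(self, rng):
        vals = rng.standard_normal((40, 15))
        ens = PeriEventEnsemble(vals, np.arange(15) / RATE, np.arange(40))
        cf = ensemble_correlation(ens, ens)
        np.testing.assert_allclose(np.diag(cf.C), 1.0, atol=1e-12)
        np.testing.assert_allclose(cf.C, cf.C.T, atol=1e-12)

    def test_shared_latent_correlation_recovered(self, rng):
        """Bivariate Gaussian oracle: implanted corr 0.6 at matched lags."""
        r, l = 200, 41
        lags = np.arange(l) / RATE
        u = rng.standard_normal((r, l))
        a = PeriEventEnsemble(
            np.sqrt(0.6) * u + np.sqrt(0.4) * rng.standard_normal((r, l)), lags, np.arange(r)
        )
        b = PeriEventEnsemble(
            np.sqrt(0.6) * u + np.sqrt(0.4) * rng.standard_normal((r, l)), lags, np.arange(r)
        )
        d = np.diag(ensemble_correlation(a, b).C)
        assert np.abs(d - 0.6).max() < 2 / np.sqrt(r)

    def test_independent_ensembles_stay_below_null_bound(self, rng):
        r, l = 150, 21
        lags = np.arange(l) / RATE
        a = PeriEventEnsemble(rng.standard_normal((r, l)), lags, np.arange(r))
        b = PeriEventEnsemble(rng.standard_normal((r, l)), lags, np.arange(r))
        c = ensemble_correlation(a, b).C
        assert np.abs(c).max() < 4 / np.sqrt(r)

    def test_mean_waveform_does_not_leak(self, rng):
        """C reflects residual processes: adding mean functions changes nothing."""
        r, l = 60, 11
        lags = np.arange(l) / RATE
        base = rng.standard_normal((r, l))
        other = rng.standard_normal((r, l))
        m = 5.0 * np.sin(np.arange(l))
        a1 = PeriEventEnsemble(base, lags, np.arange(r))
        a2 = PeriEventEnsemble(base + m, lags, np.arange(r))
        b = PeriEventEnsemble(other, lags, np.arange(r))
        np.testing.assert_allclose(
            ensemble_correlation(a1, b).C, ensemble_correlation(a2, b).C, atol=1e-10
        )

    def test_zero_variance_column_flagged_nan(self, rng):
        vals = rng.standard_normal((30, 5))
        vals[:, 2] = 1.0
        lags = np.arange(5) / RATE
        a = PeriEventEnsemble(vals, lags, np.arange(30))
        b = PeriEventEnsemble(rng.standard_normal((30, 5)), lags, np.arange(30))
        c = ensemble_correlation(a, b).C
        assert np.all(np.isnan(c[2, :]))
        assert np.all(np.isfinite(c[[0, 1, 3, 4]]))

    def test_too_few_events_rejected(self, rng):
        lags = np.arange(4) / RATE
        a = PeriEventEnsemble(rng.standard_normal((2, 4)), lags, np.arange(2))
        with pytest.raises(ValueError):
            ensemble_correlation(a, a)

    def test_self_correlation_is_positive_semidefinite(self, rng):
        vals = rng.standard_normal((50, 12))
        ens = PeriEventEnsemble(vals, np.arange(12) / RATE, np.arange(50))
        c = ensemble_correlation(ens, ens).C
        eig = np.linalg.eigvalsh(c)
        assert eig.min() > -1e-10


class TestAsymmetry:
    def _cf(self, c):
        from ripplecortex.peri_event import CorrelationFunction

        n = c.shape[0]
        lags = np.arange(n) / RATE
        return CorrelationFunction(c, lags, lags, 100)

    def test_symmetric_matrix_gives_zero(self, rng):
        m = rng.standard_normal((9, 9))
        sym = (m + m.T) / 2
        assert asymmetry_index(self._cf(sym)) == pytest.approx(0.0, abs=1e-12)

    def test_strictly_upper_matrix_gives_plus_one(self):
        c = np.triu(np.ones((7, 7)), k=1)
        assert asymmetry_index(self._cf(c)) == 1.0

    def test_sign_tracks_implanted_lag(self, rng):
        """Lagged-copy oracle: B delayed by +tau puts mass above the
        diagonal (A leads), so AI > 0; the mirror case flips the sign."""
        r, l, shift = 300, 41, 5
        lags = np.arange(l) / RATE
        lat = rng.standard_normal((r, l + 2 * shift))
        a_vals = lat[:, shift : l + shift] + 0.3 * rng.standard_normal((r, l))
        b_delayed = lat[:, :l] + 0.3 * rng.standard_normal((r, l))
        b_leading = lat[:, 2 * shift : l + 2 * shift] + 0.3 * rng.standard_normal((r, l))
        ids = np.arange(r)
        a = PeriEventEnsemble(a_vals, lags, ids)
        ai_pos = asymmetry_index(ensemble_correlation(a, PeriEventEnsemble(b_delayed, lags, ids)))
        ai_neg = asymmetry_index(ensemble_correlation(a, PeriEventEnsemble(b_leading, lags, ids)))
        assert ai_pos > 0.1
        assert ai_neg < -0.1

    def test_antisymmetry_under_transpose(self, rng):
        m = rng.standard_normal((8, 8))
        assert asymmetry_index(self._cf(m)) == pytest.approx(
            -asymmetry_index(self._cf(m.T.copy())), abs=1e-12
        )

    def test_region_outside_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="outside"):
            asymmetry_index(self._cf(rng.standard_normal((5, 5))), region=(-1.0, 1.0))


class TestResample:
    def test_linear_interpolation_identity_on_same_grid(self, rng):
        lags = np.arange(11) / RATE
        ens = PeriEventEnsemble(rng.standard_normal((4, 11)), lags, np.arange(4))
        out = resample_ensemble(ens, lags)
        np.testing.assert_allclose(out.values, ens.values)

    def test_out_of_range_grid_rejected(self, rng):
        lags = np.arange(11) / RATE
        ens = PeriEventEnsemble(rng.standard_normal((4, 11)), lags, np.arange(4))
        with pytest.raises(ValueError):
            resample_ensemble(ens, lags + 1.0)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(scale=st.floats(0.1, 100.0), offset=st.floats(-50.0, 50.0))
def test_zscore_of_mean_is_invariant_to_signal_scale(scale, offset):
    """Property: z of the event-aligned mean is unchanged by affine
    rescaling of the signal when the null is rebuilt alongside."""
    rng = np.random.default_rng(12)
    sig = rng.standard_normal(8000)
    # uneven gaps: equally spaced centers would make every interval
    # permutation identical and the null degenerate
    centers = [10.0, 17.0, 30.0, 38.5, 51.0, 62.5, 70.0]
    ref_null = build_null(sig, RATE, centers, 0.5, n_perm=40, seed=2)
    ref_z = zscore_against_null(align_events(sig, RATE, centers, 0.5).mean(), ref_null)
    sig2 = sig * scale
    null2 = build_null(sig2, RATE, centers, 0.5, n_perm=40, seed=2)
    z2 = zscore_against_null(align_events(sig2, RATE, centers, 0.5).mean(), null2)
    np.testing.assert_allclose(z2, ref_z, rtol=1e-8, atol=1e-8)
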