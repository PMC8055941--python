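"""MVAR estimation, PDC, surrogate significance and band networks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from anesthnet.connectivity import (
    PDCSpectrum,
    band_network,
    compute_pdc,
    fit_mvar,
    pdc_matrix,
    phase_randomize,
    segment_normalize,
    select_order,
    significant_pdc,
    surrogate_threshold,
)
from anesthnet.synthetic import simulate_mvar
from anesthnet.types import MVARModel, MultichannelRecording
from anesthnet.validation import random_stable_mvar


class TestSegmentNormalize:
    def test_sixty_seconds_gives_twenty_segments(self):
        rec = MultichannelRecording(
            np.random.default_rng(0).normal(size=(3, 256 * 60)),
            256.0,
            ("a", "b", "c"),
        )
        segments = segment_normalize(rec, 3.0)
        assert len(segments) == 20
        assert all(s.shape == (3, 768) for s in segments)

    def test_segments_are_centered(self):
        rec = MultichannelRecording(
            np.random.default_rng(1).normal(size=(2, 256 * 9)) + 5.0,
            256.0,
            ("a", "b"),
        )
        for seg in segment_normalize(rec, 3.0):
            assert np.abs(seg.mean(axis=1)).max() < 1e-12

    def test_pure_ramp_channel_raises_zero_variance(self):
        """Detrending removes a linear ramp entirely, leaving nothing."""
        ramp = np.linspace(0.0, 1.0, 768)
        noise = np.random.default_rng(2).normal(size=768)
        rec = MultichannelRecording(
            np.vstack([ramp, noise]), 256.0, ("ramp", "ok")
        )
        with pytest.raises(ValueError, match="ramp"):
            segment_normalize(rec, 3.0)


class TestFitMVAR:
    def test_parameter_recovery_on_known_model(self):
        """Coefficients of a stable 3-channel order-2 model within 0.05."""
        rng = np.random.default_rng(3)
        model = random_stable_mvar(rng, n_channels=3, order=2)
        rec = simulate_mvar(model, 4096, seed=4)
        fit = fit_mvar(rec.data, 2)
        assert np.abs(fit.coefficients - model.coefficients).max() < 0.05

    def test_white_noise_coefficients_near_zero(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((3, 4096))
        fit = fit_mvar(x, 1)
        se = 1.0 / np.sqrt(4096)
        assert np.abs(fit.coefficients).max() < 3.5 * se

    def test_residuals_orthogonal_to_regressors(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((2, 1024))
        fit = fit_mvar(x, 3)
        p, n = 3, 2
        X = np.concatenate(
            [x[:, p - r: x.shape[1] - r].T for r in range(1, p + 1)], axis=1
        )
        Y = x[:, p:].T
        B = np.concatenate(
            [fit.coefficients[r].T for r in range(p)], axis=0
        )
        resid = Y - X @ B
        assert np.abs(X.T @ resid).max() / len(Y) < 1e-8

    def test_rank_deficient_design_raises(self):
        x = np.random.default_rng(7).standard_normal((1, 400))
        data = np.vstack([x, x])  # duplicated channel
        with pytest.raises(np.linalg.LinAlgError, match="lower"):
            fit_mvar(data, 2)

    def test_too_short_segment_raises(self):
        with pytest.raises(ValueError, match="too short"):
            fit_mvar(np.zeros((4, 30)), 10)


class TestSelectOrder:
    def test_singleton_candidate_returned(self):
        x = np.random.default_rng(8).standard_normal((2, 768))
        chosen, optima = select_order([x], [26])
        assert chosen == 26
        assert optima == [26]

    def test_residual_det_non_increasing_in_order(self):
        x = np.random.default_rng(9).standard_normal((2, 1024))
        dets = [
            np.linalg.det(fit_mvar(x, p).innovation_cov) for p in (1, 2, 4, 8)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(dets, dets[1:]))

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_order([np.zeros((2, 100))], [])

    def test_mode_with_tie_prefers_smaller_order(self):
        rng = np.random.default_rng(10)
        model = random_stable_mvar(rng, n_channels=2, order=2)
        segs = [
            simulate_mvar(model, 1024, seed=s).data for s in range(4)
        ]
        chosen, optima = select_order(segs, range(1, 5))
        counts = {o: optima.count(o) for o in set(optima)}
        best = max(counts.values())
        assert chosen == min(o for o, c in counts.items() if c == best)


class TestComputePDC:
    def test_diagonal_model_has_identity_pdc(self):
        coeffs = np.zeros((1, 3, 3))
        np.fill_diagonal(coeffs[0], [0.5, -0.3, 0.2])
        model = MVARModel(coefficients=coeffs, innovation_cov=np.eye(3), fs=2.0)
        spec = compute_pdc(model, np.linspace(0.05, 0.95, 10))
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(spec.values[off], 0.0)
        assert np.allclose(spec.values[np.eye(3, dtype=bool)], 1.0)

    def test_unidirectional_coupling_is_asymmetric(self, oscillator_2ch):
        freqs = np.arange(1.0, 40.0, 0.5)
        spec = compute_pdc(oscillator_2ch, freqs)
        f10 = np.argmin(np.abs(freqs - 10.0))
        assert spec.values[1, 0, f10] > 0.3
        assert np.allclose(spec.values[0, 1], 0.0)

    def test_column_normalization_identity(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            model = random_stable_mvar(rng)
            spec = compute_pdc(model, np.linspace(0.01, 0.49, 17))
            colsums = np.sum(spec.values**2, axis=0)
            np.testing.assert_allclose(colsums, 1.0, atol=1e-8)

    def test_pdc_independent_of_innovation_scale(self, oscillator_2ch):
        """Original PDC uses coefficients only; covariance scaling is moot."""
        scaled = MVARModel(
            coefficients=oscillator_2ch.coefficients,
            innovation_cov=oscillator_2ch.innovation_cov * 25.0,
            fs=oscillator_2ch.fs,
        )
        freqs = np.arange(1.0, 40.0, 1.0)
        np.testing.assert_array_equal(
            compute_pdc(oscillator_2ch, freqs).values,
            compute_pdc(scaled, freqs).values,
        )

    def test_frequencies_outside_nyquist_rejected(self, oscillator_2ch):
        with pytest.raises(ValueError, match="fs/2"):
            compute_pdc(oscillator_2ch, np.array([200.0]))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_normalization_identity_property(self, seed):
        rng = np.random.default_rng(seed)
        model = random_stable_mvar(rng)
        values = pdc_matrix(
            model.coefficients, 1.0, np.linspace(0.01, 0.49, 7)
        )
        np.testing.assert_allclose(
            np.sum(values**2, axis=0), 1.0, atol=1e-8
        )


class TestSurrogates:
    def test_phase_randomization_preserves_amplitudes(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal((3, 512))
        surr = phase_randomize(x, 4, rng)
        orig = np.abs(np.fft.rfft(x, axis=1))
        for s in surr:
            np.testing.assert_allclose(
                np.abs(np.fft.rfft(s, axis=1)), orig, atol=1e-9
            )

    def test_thresholds_increase_as_alpha_decreases(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal((3, 512))
        freqs = np.arange(1.0, 40.0, 2.0)
        kw = dict(order=2, n_surrogates=100, freqs=freqs, fs=256.0)
        t50 = surrogate_threshold(x, alpha=0.5, rng=1, **kw)
        t05 = surrogate_threshold(x, alpha=0.05, rng=1, **kw)
        t01 = surrogate_threshold(x, alpha=0.01, rng=1, **kw)
        assert np.all(t50 <= t05 + 1e-12)
        assert np.all(t05 <= t01 + 1e-12)

    def test_strong_coupling_detected(self, oscillator_2ch):
        """Coupled pair flagged significant at its resonance frequency."""
        freqs = np.arange(1.0, 40.0, 1.0)
        hits = 0
        for seed in range(5):
            rec = simulate_mvar(oscillator_2ch, 768, seed=seed)
            spec = significant_pdc(
                rec.data, 2, freqs, 256.0, n_surrogates=100, rng=seed
            )
            f10 = np.argmin(np.abs(freqs - 10.0))
            hits += bool(spec.sig_mask[1, 0, f10])
        assert hits >= 4

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            surrogate_threshold(
                np.zeros((2, 100)), 1, alpha=1.5,
                freqs=np.array([0.1]), fs=1.0,
            )

    def test_few_surrogates_warns(self):
        x = np.random.default_rng(14).standard_normal((2, 256))
        with pytest.warns(UserWarning, match="low"):
            surrogate_threshold(
                x, 1, n_surrogates=10, alpha=0.05,
                freqs=np.array([10.0]), fs=256.0, rng=0,
            )


class TestBandNetwork:
    @staticmethod
    def constant_spec(c, n=3, nf=8, sig=True):
        values = np.full((n, n, nf), c)
        return PDCSpectrum(
            values=values,
            freqs=np.linspace(8.0, 12.0, nf),
            sig_mask=np.full((n, n, nf), sig),
        )

    def test_constant_field_reproduced(self):
        net = band_network(
            [self.constant_spec(0.25)], ("alpha", 8.0, 13.0), ("a", "b", "c")
        )
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(net.weights[off], 0.25)
        assert np.isclose(net.global_mean, 0.25)

    def test_fully_nonsignificant_segment_halves_weights(self):
        specs = [
            self.constant_spec(0.4),
            self.constant_spec(0.4, sig=False),
        ]
        net = band_network(specs, ("alpha", 8.0, 13.0), ("a", "b", "c"))
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(net.weights[off], 0.2)

    def test_diagonal_forced_to_zero(self):
        net = band_network(
            [self.constant_spec(0.9)], ("alpha", 8.0, 13.0), ("a", "b", "c")
        )
        assert np.all(np.diag(net.weights) == 0)

    def test_band_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            band_network(
                [self.constant_spec(0.2)], ("gamma", 50.0, 80.0),
                ("a", "b", "c"),
            )

    def test_empty_segment_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            band_network([], ("alpha", 8.0, 13.0), ("a",))


class TestOptionVariants:
    def test_global_threshold_is_scalar_broadcast(self):
        rng = np.random.default_rng(20)
        x = rng.standard_normal((3, 512))
        freqs = np.arange(1.0, 40.0, 2.0)
        thr = surrogate_threshold(
            x, 2, n_surrogates=50, alpha=0.05, freqs=freqs, fs=256.0,
            rng=0, threshold_mode="global",
        )
        off = ~np.eye(3, dtype=bool)
        assert np.unique(thr[off]).size == 1

    def test_squared_band_averaging(self):
        spec = TestBandNetwork.constant_spec(0.5)
        plain = band_network([spec], ("alpha", 8.0, 13.0), ("a", "b", "c"))
        squared = band_network(
            [spec], ("alpha", 8.0, 13.0), ("a", "b", "c"), squared=True
        )
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(squared.weights[off], plain.weights[off] ** 2)
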