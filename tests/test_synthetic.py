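"""Generator correctness: MVAR realizations, scenario models, RR series."""

import numpy as np
import pytest

from anesthnet.connectivity import pdc_matrix, mvar_spectrum
from anesthnet.synthetic import (
    GroundTruthScenario,
    build_condition_models,
    default_scenario,
    simulate_mvar,
    simulate_rr,
)
from anesthnet.types import CHANNELS_1020, MVARModel, StabilityError

import oracles


class TestSimulateMVAR:
    def test_zero_coefficient_model_gives_uncorrelated_white_noise(self):
        n = 3
        model = MVARModel(
            coefficients=np.zeros((1, n, n)), innovation_cov=np.eye(n)
        )
        rec = simulate_mvar(model, 4096, fs=256.0, seed=0)
        c = np.corrcoef(rec.data)
        off = c[~np.eye(n, dtype=bool)]
        assert np.abs(off).max() < 3.0 / np.sqrt(4096)

    def test_coupled_oscillator_peaks_at_resonance(self, oscillator_2ch):
        """Channel 2's spectrum peaks within 1 Hz of the 10 Hz driver."""
        rec = simulate_mvar(oscillator_2ch, 2**15, seed=1)
        from scipy.signal import welch

        freqs, psd = welch(rec.data[1], fs=256.0, nperseg=2048)
        band = (freqs > 2) & (freqs < 40)
        peak = freqs[band][np.argmax(psd[band])]
        assert abs(peak - 10.0) <= 1.0
        # and the closed-form model spectrum agrees about the peak location
        grid = np.arange(2.0, 40.0, 0.25)
        ref = mvar_spectrum(oscillator_2ch, grid)[1]
        assert abs(grid[np.argmax(ref)] - 10.0) <= 1.0

    def test_identical_seed_identical_output(self, oscillator_2ch):
        a = simulate_mvar(oscillator_2ch, 1000, seed=7)
        b = simulate_mvar(oscillator_2ch, 1000, seed=7)
        np.testing.assert_array_equal(a.data, b.data)

    def test_unstable_model_raises_with_spectral_radius(self):
        model = MVARModel(
            coefficients=np.array([[[1.1]]]), innovation_cov=np.eye(1)
        )
        with pytest.raises(StabilityError, match="spectral radius"):
            simulate_mvar(model, 500, seed=0)

    def test_non_positive_definite_covariance_raises(self):
        model = MVARModel(
            coefficients=np.zeros((1, 2, 2)),
            innovation_cov=np.array([[1.0, 2.0], [2.0, 1.0]]),
        )
        with pytest.raises(ValueError, match="positive definite"):
            simulate_mvar(model, 500, seed=0)

    def test_empirical_spectrum_converges_to_closed_form(self):
        """Relative L2 error of the periodogram against the model PSD < 10%."""
        from scipy.signal import welch

        coeffs = np.zeros((2, 2, 2))
        w = 2 * np.pi * 8.0 / 128.0
        coeffs[0, 0, 0], coeffs[1, 0, 0] = 2 * 0.9 * np.cos(w), -0.81
        coeffs[0, 1, 1] = 0.3
        coeffs[0, 1, 0] = 0.5
        model = MVARModel(
            coefficients=coeffs, innovation_cov=np.eye(2), fs=128.0
        )
        rec = simulate_mvar(model, 2**16, seed=3)
        freqs, psd = welch(rec.data, fs=128.0, nperseg=512)
        sel = (freqs > 0.5) & (freqs < 60.0)
        ref = mvar_spectrum(model, freqs[sel])
        err = np.linalg.norm(psd[:, sel] - ref) / np.linalg.norm(ref)
        assert err < 0.10


class TestBuildConditionModels:
    def test_single_edge_scenario_closed_form_pdc(self):
        """One F3->P3 edge at 10 Hz, gain 0.4: strong, asymmetric PDC."""
        sc = default_scenario(seed=0)
        sc.coupling_graphs = {
            c: ([("F3", "P3", 10.0, 0.4)] if c == "Bas" else [])
            for c in sc.condition_labels
        }
        models = build_condition_models(sc)
        m = models["Bas"]
        idx = {ch: i for i, ch in enumerate(m.channel_labels)}
        pdc = pdc_matrix(m.coefficients, m.fs, np.array([10.0]))[:, :, 0]
        assert pdc[idx["P3"], idx["F3"]] > 0.3
        assert pdc[idx["P3"], idx["F3"]] > pdc[idx["F3"], idx["P3"]]

    def test_empty_edge_list_gives_diagonal_model(self):
        sc = default_scenario(seed=0)
        sc.coupling_graphs = {c: [] for c in sc.condition_labels}
        models = build_condition_models(sc)
        for m in models.values():
            freqs = np.array([2.0, 10.0, 20.0])
            pdc = pdc_matrix(m.coefficients, m.fs, freqs)
            off = ~np.eye(m.n_channels, dtype=bool)
            assert np.allclose(pdc[off], 0.0)

    def test_default_scenario_models_are_stable(self, condition_models):
        for m in condition_models.values():
            assert m.is_stable()

    def test_every_programmed_edge_dominates_nonedges_in_closed_form(
        self, condition_models
    ):
        for m in condition_models.values():
            idx = {ch: i for i, ch in enumerate(m.channel_labels)}
            cells = {(idx[t], idx[s]) for s, t, f, g in m.edges}
            for s, t, f, g in m.edges:
                pdc = pdc_matrix(m.coefficients, m.fs, np.array([f]))[:, :, 0]
                edge_val = pdc[idx[t], idx[s]]
                nonedge_max = max(
                    pdc[i, j]
                    for i in range(19)
                    for j in range(19)
                    if i != j and (i, j) not in cells
                )
                assert edge_val > nonedge_max

    def test_frontal_alpha_in_edges_increase_toward_loc(self, scenario):
        frontal = {"F3", "F4", "Fp1", "Fp2"}
        counts = []
        for cond in ("Bas", "Ind1", "Ind2"):
            edges = scenario.coupling_graphs[cond]
            counts.append(
                sum(1 for s, t, f, g in edges if t in frontal and 8 <= f < 13)
            )
        assert counts[0] < counts[1] < counts[2]

    def test_ind2_edges_superset_of_baseline(self, scenario):
        bas = {(s, t, f) for s, t, f, g in scenario.coupling_graphs["Bas"]}
        ind2 = {(s, t, f) for s, t, f, g in scenario.coupling_graphs["Ind2"]}
        assert bas <= ind2

    def test_infeasible_cyclic_edge_set_raises(self):
        sc = default_scenario(seed=0)
        # strong reciprocal coupling between channels sharing a resonance
        sc.coupling_graphs = {
            c: [("P3", "P4", 10.0, 6.0), ("P4", "P3", 10.0, 6.0)]
            for c in sc.condition_labels
        }
        with pytest.raises(StabilityError, match="reduce"):
            build_condition_models(sc)

    def test_unknown_channel_in_edge_raises(self):
        sc = default_scenario(seed=0)
        sc.coupling_graphs["Bas"] = [("XX", "P3", 10.0, 0.3)]
        with pytest.raises(ValueError, match="unknown channel"):
            build_condition_models(sc)


class TestSimulateRR:
    base = {"mean_rr": 850.0, "lf_gain": 25.0, "hf_gain": 0.0, "noise_sd": 3.0}

    def test_lf_only_spectrum_peaks_in_lf_band(self):
        """With hf_gain 0, the beat-series spectrum peaks in 0.04-0.15 Hz."""
        from scipy.signal import welch

        rr = simulate_rr(self.base, 1000, seed=0)
        x = rr.intervals - rr.intervals.mean()
        fs_beat = 1000.0 / 850.0  # beats per second
        freqs, psd = welch(x, fs=fs_beat, nperseg=512)
        sel = freqs > 0.01
        peak = freqs[sel][np.argmax(psd[sel])]
        assert 0.04 <= peak <= 0.15
        hf = (freqs >= 0.15) & (freqs <= 0.4)
        lf = (freqs >= 0.04) & (freqs < 0.15)
        assert psd[hf].max() < 0.1 * psd[lf].max()

    def test_degenerate_parameters_give_constant_series(self):
        params = {"mean_rr": 900.0, "lf_gain": 0.0, "hf_gain": 0.0,
                  "noise_sd": 0.0}
        rr = simulate_rr(params, 100, seed=0)
        np.testing.assert_allclose(rr.intervals, 900.0)

    def test_ectopic_count_near_binomial_expectation(self):
        counts = [
            sum(a == "ectopic" for a in simulate_rr(
                self.base, 300, ectopic_rate=0.05, seed=s).annotations)
            for s in range(20)
        ]
        # Binomial(300, 0.05): mean 15, sd 3.77; the 20-seed mean is within 3 se
        assert abs(np.mean(counts) - 15.0) < 3 * 3.77 / np.sqrt(20)

    def test_ectopic_split_preserves_total_time(self):
        clean = simulate_rr(self.base, 300, ectopic_rate=0.0, seed=5)
        with_ect = simulate_rr(self.base, 300, ectopic_rate=0.05, seed=5)
        assert len(with_ect) > len(clean)
        assert np.isclose(with_ect.intervals.sum(), clean.intervals.sum())

    def test_positivity_under_accepted_parameters(self):
        for seed in range(10):
            params = {"mean_rr": 700.0, "lf_gain": 60.0, "hf_gain": 50.0,
                      "noise_sd": 40.0}
            rr = simulate_rr(params, 200, ectopic_rate=0.1, seed=seed)
            assert np.all(rr.intervals > 0)

    def test_interval_killing_gains_raise_naming_offender(self):
        params = {"mean_rr": 400.0, "lf_gain": 500.0, "hf_gain": 1.0,
                  "noise_sd": 1.0}
        with pytest.raises(ValueError, match="lf_gain"):
            simulate_rr(params, 100, seed=0)

    @pytest.mark.parametrize(
        "bad", [
            dict(mean_rr=100.0), dict(mean_rr=2500.0),
        ],
    )
    def test_mean_rr_bounds(self, bad):
        params = {**self.base, **bad}
        with pytest.raises(ValueError, match="mean_rr"):
            simulate_rr(params, 100, seed=0)

    def test_determinism(self):
        a = simulate_rr(self.base, 120, ectopic_rate=0.05, seed=9)
        b = simulate_rr(self.base, 120, ectopic_rate=0.05, seed=9)
        np.testing.assert_array_equal(a.intervals, b.intervals)
        assert a.annotations == b.annotations


class TestScenarioValidation:
    def test_five_conditions_required(self):
        with pytest.raises(ValueError, match="5 condition"):
            GroundTruthScenario(condition_labels=("A", "B"))

    def test_resonance_must_be_below_nyquist(self):
        with pytest.raises(ValueError, match="resonance"):
            GroundTruthScenario(
                coupling_graphs={"Bas": [("O1", "P3", 200.0, 0.3)]}
            )
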