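"""Simulation studies that quantify how well the pipeline recovers known truth.

Each function here runs a self-contained seeded experiment on synthetic
data — ground-truth network recovery, surrogate-null calibration, model-order
recovery, autonomic trend recovery, type-I error of the statistics ladder —
and returns the scalar figures of merit. They are used by the test suite and
by the reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from . import hrv as hrv_mod
from .connectivity import (
    band_network,
    compute_pdc,
    fit_mvar,
    segment_normalize,
    select_order,
    significant_pdc,
)
from .stats import compare_conditions
from .synthetic import (
    GroundTruthScenario,
    build_condition_models,
    child_seed,
    simulate_mvar,
    simulate_rr,
)
from .types import BandSet, MVARModel, MultichannelRecording


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the rank-sum identity."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    return float(
        (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def random_stable_mvar(
    rng: np.random.Generator,
    n_channels: int | None = None,
    order: int | None = None,
    max_channels: int = 6,
    max_order: int = 5,
    target_radius: float = 0.8,
) -> MVARModel:
    """Random MVAR model rescaled to a prescribed spectral radius."""
    n = int(n_channels or rng.integers(2, max_channels + 1))
    p = int(order or rng.integers(1, max_order + 1))
    coeffs = rng.normal(0.0, 0.4, size=(p, n, n)) / np.arange(
        1, p + 1
    ).reshape(-1, 1, 1)
    model = MVARModel(coefficients=coeffs, innovation_cov=np.eye(n))
    radius = model.spectral_radius()
    if radius > 0:
        # lag-r coefficients scale with the r-th power of the radius ratio
        scale = target_radius / radius
        coeffs = coeffs * (scale ** np.arange(1, p + 1)).reshape(-1, 1, 1)
    return MVARModel(coefficients=coeffs, innovation_cov=np.eye(n))


def pdc_normalization_deviation(n_models: int = 100, seed: int = 0) -> float:
    """Worst deviation of sum_i PDC(i<-j, f)^2 from 1 over random models."""
    rng = np.random.default_rng(seed)
    freqs = np.linspace(0.01, 0.49, 25)
    worst = 0.0
    for _ in range(n_models):
        model = random_stable_mvar(rng)
        spec = compute_pdc(model, freqs)
        colsum = np.sum(spec.values**2, axis=0)  # over targets
        worst = max(worst, float(np.abs(colsum - 1.0).max()))
    return worst


def network_recovery(
    seed: int = 0,
    n_subjects: int = 11,
    epoch_s: float = 30.0,
    n_surrogates: int = 200,
    alpha: float = 0.05,
    order: int = 3,
    freq_step: float = 1.0,
) -> dict:
    """Recovery of the programmed directed edges on the default scenario.

    Simulates the full five-condition cohort, runs the PDC chain per
    recording, pools band-averaged significant weights across subjects and
    conditions, and scores them against the ground-truth edge indicator.
    Returns per band: AUROC, the fraction of programmed edges whose weight
    exceeds the median non-edge weight, and the counts involved.
    """
    scenario = GroundTruthScenario(
        n_subjects=n_subjects, epoch_s=epoch_s, seed=seed
    )
    models = build_condition_models(scenario)
    bands = BandSet()
    freqs = np.arange(1.0, 40.0 + 1e-9, freq_step)
    labels = scenario.channel_labels
    idx = {ch: i for i, ch in enumerate(labels)}
    n = len(labels)
    off = [(i, j) for i in range(n) for j in range(n) if i != j]
    pos: dict = {b: [] for b in bands.names}
    neg: dict = {b: [] for b in bands.names}
    n_samples = int(round(epoch_s * scenario.fs))
    for c_i, cond in enumerate(scenario.condition_labels):
        model = models[cond]
        edge_cells = {(idx[t], idx[s]): f for s, t, f, g in model.edges}
        for s_i in range(n_subjects):
            rec = simulate_mvar(
                model, n_samples, seed=child_seed(seed, 1, s_i, c_i)
            )
            segments = segment_normalize(rec, 3.0)
            specs = [
                significant_pdc(
                    seg,
                    order,
                    freqs,
                    scenario.fs,
                    n_surrogates=n_surrogates,
                    alpha=alpha,
                    rng=child_seed(seed, 3, s_i, c_i, k),
                    channel_labels=labels,
                )
                for k, seg in enumerate(segments)
            ]
            for name, lo, hi in bands.bands:
                net = band_network(specs, (name, lo, hi), labels)
                for cell, f in edge_cells.items():
                    if lo <= f < hi:
                        pos[name].append(net.weights[cell])
                neg[name] += [
                    net.weights[c] for c in off if c not in edge_cells
                ]
    out = {}
    for name in bands.names:
        p, q = np.asarray(pos[name]), np.asarray(neg[name])
        med = float(np.median(q))
        out[name] = {
            "auroc": auroc(
                np.concatenate([p, q]),
                np.concatenate([np.ones(p.size), np.zeros(q.size)]),
            ),
            "frac_edges_above_median_nonedge": float((p > med).mean()),
            "n_edges": int(p.size),
            "median_nonedge": med,
            "min_edge": float(p.min()),
        }
    return out


def surrogate_false_positive_rate(
    n_seeds: int = 50,
    n_channels: int = 4,
    n_samples: int = 768,
    order: int = 2,
    n_surrogates: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Mean fraction of off-diagonal (pair, frequency) cells flagged on noise."""
    freqs = np.arange(1.0, 40.0 + 1e-9, 1.0)
    fs = 256.0
    rates = []
    off = ~np.eye(n_channels, dtype=bool)
    for k in range(n_seeds):
        rng = np.random.default_rng(child_seed(seed, 7, k))
        x = rng.standard_normal((n_channels, n_samples))
        spec = significant_pdc(
            x,
            order,
            freqs,
            fs,
            n_surrogates=n_surrogates,
            alpha=alpha,
            rng=child_seed(seed, 8, k),
        )
        rates.append(float(spec.sig_mask[off].mean()))
    return float(np.mean(rates))


def _order5_test_model(rng: np.random.Generator, n_channels: int = 3) -> MVARModel:
    """Random stable model with genuine lag-5 structure."""
    n = n_channels
    coeffs = np.zeros((5, n, n))
    coeffs[0] = rng.normal(0.0, 0.15, (n, n)) + 0.4 * np.eye(n)
    for r in (1, 2, 3):
        coeffs[r] = rng.normal(0.0, 0.05, (n, n))
    coeffs[4] = rng.normal(0.0, 0.05, (n, n)) + 0.3 * np.eye(n)
    model = MVARModel(coefficients=coeffs, innovation_cov=np.eye(n))
    radius = model.spectral_radius()
    if radius >= 0.95:
        coeffs *= (0.9 / radius) ** np.arange(1, 6).reshape(-1, 1, 1)
        model = MVARModel(coefficients=coeffs, innovation_cov=np.eye(n))
    return model


def order_recovery_rate(
    n_seeds: int = 20,
    candidate_orders=range(1, 11),
    n_segments: int = 20,
    seg_len: int = 2048,
    accepted=(4, 5, 6),
    seed: int = 0,
) -> float:
    """Fraction of seeded runs whose modal BIC order lands in ``accepted``."""
    hits = 0
    for k in range(n_seeds):
        rng = np.random.default_rng(child_seed(seed, 11, k))
        model = _order5_test_model(rng)
        rec = simulate_mvar(
            model, n_segments * seg_len, seed=child_seed(seed, 12, k)
        )
        segments = [
            rec.data[:, i * seg_len : (i + 1) * seg_len]
            for i in range(n_segments)
        ]
        chosen, _ = select_order(segments, candidate_orders)
        hits += chosen in accepted
    return hits / n_seeds


def autonomic_trend(
    n_cohorts: int = 20, n_subjects: int = 11, seed: int = 0
) -> dict:
    """Cohort-mean HRV contrasts between deep induction and baseline.

    For each seeded cohort the full cardiac chain runs per subject and
    condition; returns the across-cohort means of Ro(Ind2) - Ro(Bas) and
    2UV%(Bas) - 2UV%(Ind2) and the fraction of cohorts where each contrast
    has the programmed sign.
    """
    ro_diffs, uv_diffs = [], []
    for c in range(n_cohorts):
        scenario = GroundTruthScenario(
            n_subjects=n_subjects, seed=child_seed(seed, 21, c)
        )
        ro = {"Bas": [], "Ind2": []}
        uv = {"Bas": [], "Ind2": []}
        for s_i in range(n_subjects):
            for cond in ("Bas", "Ind2"):
                series = simulate_rr(
                    scenario.rr_params[cond],
                    scenario.n_beats,
                    ectopic_rate=scenario.ectopic_rate,
                    seed=child_seed(scenario.seed, 2, s_i, cond),
                    condition=cond,
                )
                indices = hrv_mod.analyze_rr(series)
                ro[cond].append(indices["Ro"])
                uv[cond].append(indices["2UV"])
        ro_diffs.append(np.mean(ro["Ind2"]) - np.mean(ro["Bas"]))
        uv_diffs.append(np.mean(uv["Bas"]) - np.mean(uv["Ind2"]))
    ro_diffs, uv_diffs = np.asarray(ro_diffs), np.asarray(uv_diffs)
    return {
        "mean_ro_ind2_minus_bas": float(ro_diffs.mean()),
        "mean_2uv_bas_minus_ind2": float(uv_diffs.mean()),
        "frac_cohorts_ro_increase": float((ro_diffs > 0).mean()),
        "frac_cohorts_2uv_decrease": float((uv_diffs > 0).mean()),
    }


def stats_type1_error(
    n_tables: int = 2000,
    n_subjects: int = 11,
    n_conditions: int = 5,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Omnibus rejection rate of the testing ladder on null normal tables."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_tables):
        table = rng.standard_normal((n_subjects, n_conditions))
        report = compare_conditions(table, alpha=alpha)
        rejections += report.omnibus_p < alpha
    return rejections / n_tables
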