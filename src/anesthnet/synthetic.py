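"""Ground-truth-known synthetic cohorts for the five anesthesia stages.

Both signal families the pipeline consumes are generated here:

* multichannel EEG-like signals from stable MVAR processes whose diagonal
  oscillators set per-region band power and whose off-diagonal coupling
  terms encode a known directed edge list, per condition (Bas, Ind1, Ind2,
  Rec1, Rec2);
* RR-interval series as a mean level plus beat-domain low-frequency
  (~0.1 Hz) and high-frequency (~0.25 Hz) oscillations plus white noise,
  with optional injected ectopic beats.

The default scenario encodes the qualitative physiology of propofol
induction: posterior alpha that gives way to widespread delta, frontal
alpha-band in-edges that accumulate toward loss of consciousness, parietal
beta out-edges that rise and persist into recovery, and a cardiac side with
progressive bradycardia, rising regularity and falling vagal variability at
deep induction. Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as anio
from .types import (
    BEAT_ECTOPIC,
    BEAT_NORMAL,
    CHANNELS_1020,
    CONDITIONS,
    MVARModel,
    MultichannelRecording,
    RRSeries,
    StabilityError,
)

# ---------------------------------------------------------------------------
# scenario definition


#: Per-condition dominant rhythm (peak frequency Hz, pole radius). Keys are
#: ROI names, with "other" covering electrodes outside every ROI (Fz);
#: individual channel labels may appear as keys and override their ROI (used
#: for the persistent midline-parietal beta generator that sources the beta
#: out-edges during deep sedation and early recovery).
DEFAULT_RHYTHMS = {
    "Bas": {
        "frontal": (18.0, 0.85),
        "central": (10.0, 0.85),
        "parietal": (10.0, 0.88),
        "occipital": (10.0, 0.90),
        "temporal": (6.0, 0.85),
        "other": (10.0, 0.84),
    },
    "Ind1": {
        "frontal": (2.5, 0.88),
        "central": (20.0, 0.85),
        "parietal": (10.0, 0.86),
        "occipital": (10.0, 0.86),
        "temporal": (4.0, 0.85),
        "other": (6.0, 0.84),
    },
    "Ind2": {
        "frontal": (2.0, 0.90),
        "central": (2.0, 0.88),
        "parietal": (2.5, 0.88),
        "Pz": (20.0, 0.86),
        "occipital": (2.5, 0.88),
        "temporal": (3.0, 0.86),
        "other": (2.5, 0.86),
    },
    "Rec1": {
        "frontal": (4.0, 0.86),
        "central": (3.0, 0.87),
        "parietal": (6.0, 0.85),
        "Pz": (16.0, 0.85),
        "occipital": (10.0, 0.86),
        "temporal": (5.0, 0.84),
        "other": (5.0, 0.84),
    },
    "Rec2": {
        "frontal": (16.0, 0.84),
        "central": (10.0, 0.85),
        "parietal": (10.0, 0.87),
        "occipital": (10.0, 0.88),
        "temporal": (6.0, 0.84),
        "other": (8.0, 0.84),
    },
}

_F_DELTA, _F_THETA, _F_ALPHA, _F_BETA = 2.5, 6.0, 10.0, 20.0

#: Baseline directed coupling (source, target, resonance Hz, gain). All
#: default coupling graphs are acyclic under one fixed node order, so the
#: coupled models keep exactly the diagonal oscillator poles and remain
#: stable for any gain profile (feedback loops between channels that share a
#: resonance would split the poles outward by ~sqrt(loop gain)). Beta
#: out-edges source from Pz, whose rhythm stays in the beta range in deep
#: sedation; delta edges emerge with induction from delta-resonant sources.
_BAS_EDGES = [
    ("O1", "P3", _F_ALPHA, 0.35),
    ("O2", "P4", _F_ALPHA, 0.35),
    ("P3", "F3", _F_ALPHA, 0.30),
    ("Pz", "Cz", _F_BETA, 0.30),
    ("T3", "C3", _F_THETA, 0.30),
    ("T4", "C4", _F_THETA, 0.30),
]
_IND1_EXTRA = [
    ("P4", "F4", _F_ALPHA, 0.35),
    ("Pz", "Fz", _F_DELTA, 0.30),
    ("Pz", "C4", _F_BETA, 0.30),
    ("F7", "T3", _F_THETA, 0.30),
]
_IND2_EXTRA = [
    ("T5", "Fp1", _F_ALPHA, 0.35),
    ("T6", "Fp2", _F_ALPHA, 0.35),
    ("Pz", "C3", _F_BETA, 0.30),
    ("P3", "Fz", _F_DELTA, 0.30),
    ("P4", "Fz", _F_DELTA, 0.30),
]

DEFAULT_COUPLING = {
    "Bas": list(_BAS_EDGES),
    "Ind1": _BAS_EDGES + _IND1_EXTRA,
    "Ind2": _BAS_EDGES + _IND1_EXTRA + _IND2_EXTRA,
    "Rec1": _BAS_EDGES
    + [
        ("P4", "F4", _F_ALPHA, 0.35),
        ("Pz", "C3", _F_BETA, 0.30),
        ("F7", "T3", _F_THETA, 0.30),
    ],
    "Rec2": _BAS_EDGES + [("Pz", "C3", _F_BETA, 0.30)],
}

#: Per-condition RR generator parameters (ms / ms / ms / ms): progressive
#: bradycardia, maximal regularity (low noise, low HF) just before loss of
#: consciousness, a complexity overshoot in early recovery.
DEFAULT_RR_PARAMS = {
    "Bas": {"mean_rr": 850.0, "lf_gain": 25.0, "hf_gain": 35.0, "noise_sd": 20.0},
    "Ind1": {"mean_rr": 900.0, "lf_gain": 30.0, "hf_gain": 25.0, "noise_sd": 14.0},
    "Ind2": {"mean_rr": 980.0, "lf_gain": 35.0, "hf_gain": 12.0, "noise_sd": 6.0},
    "Rec1": {"mean_rr": 1000.0, "lf_gain": 25.0, "hf_gain": 35.0, "noise_sd": 26.0},
    "Rec2": {"mean_rr": 1010.0, "lf_gain": 28.0, "hf_gain": 20.0, "noise_sd": 12.0},
}


@dataclass
class GroundTruthScenario:
    """Full specification of a synthetic five-condition cohort."""

    condition_labels: tuple = CONDITIONS
    coupling_graphs: dict = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_COUPLING.items()}
    )
    band_power_profile: dict = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_RHYTHMS.items()
        }
    )
    rr_params: dict = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_RR_PARAMS.items()
        }
    )
    fs: float = 256.0
    channel_labels: tuple = CHANNELS_1020
    n_subjects: int = 11
    epoch_s: float = 60.0
    n_beats: int = 300
    ectopic_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.condition_labels) != 5:
            raise ValueError("exactly 5 condition labels are required")
        for cond, edges in self.coupling_graphs.items():
            for src, tgt, f_hz, gain in edges:
                if not np.isfinite(gain):
                    raise ValueError(f"{cond}: non-finite gain on {src}->{tgt}")
                if not 0.0 < f_hz < self.fs / 2:
                    raise ValueError(
                        f"{cond}: resonance {f_hz} Hz outside (0, fs/2)"
                    )


def default_scenario(seed: int = 0, **overrides) -> GroundTruthScenario:
    return GroundTruthScenario(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# MVAR construction and simulation


def _ar2_coeffs(f_hz: float, rho: float, fs: float) -> tuple[float, float]:
    """AR(2) coefficients of a damped oscillator at f_hz with pole radius rho."""
    w = 2.0 * np.pi * f_hz / fs
    return 2.0 * rho * np.cos(w), -(rho**2)


def _balance_channel_variance(
    coeffs: np.ndarray, target_sd: float = 30.0
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale channels so each has stationary sd ``target_sd`` (in uV).

    Coupled resonant chains otherwise amplify variance by orders of magnitude
    along the chain, which no real montage shows and which makes the
    (scale-sensitive) PDC of downstream channels vanish. The similarity
    transform ``A_r -> D A_r D^-1`` with ``D = diag(target_sd / sd_i)`` and
    innovation covariance ``D D`` preserves the sparsity pattern, the poles
    and therefore the location of every PDC peak.
    """
    from scipy.linalg import solve_discrete_lyapunov

    p, n, _ = coeffs.shape
    comp = np.zeros((n * p, n * p))
    comp[:n, :] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        comp[n:, :-n] = np.eye(n * (p - 1))
    Q = np.zeros((n * p, n * p))
    Q[:n, :n] = np.eye(n)
    gamma0 = solve_discrete_lyapunov(comp, Q)
    sd = np.sqrt(np.diag(gamma0)[:n])
    d = target_sd / sd
    balanced = np.einsum("i,rij,j->rij", d, coeffs, 1.0 / d)
    innovation_cov = np.diag(d**2)
    return balanced, innovation_cov


#: resonance sharpness of the coupling band-pass filters
_COUPLING_RHO = 0.8
#: closed-form PDC floor each programmed edge is calibrated toward
_PDC_FLOOR = 0.2
#: cap on the gain multiplier applied during calibration
_GAIN_CAP = 4.0


def _assemble_condition(
    scenario: GroundTruthScenario,
    cond: str,
    gains: list,
    labels: tuple,
    roi,
) -> np.ndarray:
    """Coefficient stack for one condition at the given per-edge gains.

    Edge coupling is injected at innovation scale: the band-passed source
    signal is renormalized to standard deviation ``gain`` (in innovation
    units), so a gain of 0.3 adds an input comparable to 30% of the target's
    own driving noise regardless of how strongly the source oscillates. The
    source band power depends on the assembled model, so the normalization is
    iterated to its fixed point (exact in a few passes on an acyclic graph).
    """
    from .connectivity import a_bar

    idx = {ch: i for i, ch in enumerate(labels)}
    n = len(labels)
    fs = scenario.fs
    rhythms = scenario.band_power_profile[cond]
    diag = np.zeros((2, n, n))
    for ch, i in idx.items():
        key = ch if ch in rhythms else (roi.roi_of(ch) or "other")
        f_hz, rho = rhythms[key]
        a1, a2 = _ar2_coeffs(f_hz, rho, fs)
        diag[0, i, i] = a1
        diag[1, i, i] = a2
    edges = scenario.coupling_graphs.get(cond, [])
    grid = np.arange(0.25, fs / 2, 0.25)
    df = grid[1] - grid[0]
    w = np.exp(-2j * np.pi * grid / fs)
    coeffs = diag.copy()
    for _ in range(6):
        H = np.linalg.inv(a_bar(coeffs, fs, grid))
        psd = np.sum(np.abs(H) ** 2, axis=2).T  # unit-innovation channel PSDs
        coeffs = diag.copy()
        for (src, tgt, f_hz, _), gain in zip(edges, gains):
            if src not in idx or tgt not in idx:
                raise ValueError(
                    f"edge {src}->{tgt} references unknown channel"
                )
            b1, b2 = _ar2_coeffs(f_hz, _COUPLING_RHO, fs)
            band_power = np.abs(b1 * w + b2 * w**2) ** 2
            sd_band = np.sqrt(
                np.sum(band_power * psd[idx[src]]) * 2.0 * df / fs
            )
            c = gain / sd_band
            coeffs[0, idx[tgt], idx[src]] += c * b1
            coeffs[1, idx[tgt], idx[src]] += c * b2
    return coeffs


def build_condition_models(
    scenario: GroundTruthScenario, channel_labels: tuple | None = None
) -> dict:
    """Per-condition stable MVAR(2) models encoding the scenario's ground truth.

    Diagonal entries are AR(2) oscillators set by the condition's rhythm
    profile; each coupling edge adds a band-pass pair of lag-1/lag-2 terms
    from source to target, resonant at the edge frequency, so the closed-form
    PDC of the constructed model peaks there. Edge gains are calibrated (with
    a capped multiplier) until every programmed edge reaches a closed-form
    PDC floor at its resonance, then channels are rescaled to a common
    stationary amplitude. Edge metadata is kept on each model for later
    recovery scoring.
    """
    from .connectivity import pdc_matrix
    from .types import ROILayout

    labels = tuple(channel_labels or scenario.channel_labels)
    roi = ROILayout()
    idx = {ch: i for i, ch in enumerate(labels)}
    n = len(labels)
    models = {}
    for cond in scenario.condition_labels:
        edges = scenario.coupling_graphs.get(cond, [])
        base = [gain for *_, gain in edges]
        gains = list(base)
        coeffs = None
        for _ in range(25):
            coeffs = _assemble_condition(scenario, cond, gains, labels, roi)
            pre = MVARModel(coefficients=coeffs, innovation_cov=np.eye(n))
            if not pre.is_stable():
                raise StabilityError(
                    f"condition {cond}: edge set cannot be stabilized at the "
                    f"requested gains (spectral radius "
                    f"{pre.spectral_radius():.3f}); reduce edge gains"
                )
            if not edges:
                break
            balanced, _ = _balance_channel_variance(coeffs)
            vals = [
                pdc_matrix(balanced, scenario.fs, np.array([f_hz]))[
                    idx[tgt], idx[src], 0
                ]
                for src, tgt, f_hz, _ in edges
            ]
            adjustable = [
                v < _PDC_FLOOR and g < cap_g - 1e-9
                for v, g, cap_g in zip(
                    vals, gains, (_GAIN_CAP * b for b in base)
                )
            ]
            if not any(adjustable):
                break
            gains = [
                min(_GAIN_CAP * b, g * min(1.4, _PDC_FLOOR / v))
                if v < _PDC_FLOOR
                else g
                for g, v, b in zip(gains, vals, base)
            ]
        coeffs, innovation_cov = _balance_channel_variance(coeffs)
        model = MVARModel(
            coefficients=coeffs,
            innovation_cov=innovation_cov,
            fs=scenario.fs,
            edges=[(src, tgt, f_hz, gain) for src, tgt, f_hz, gain in edges],
            channel_labels=labels,
        )
        models[cond] = model
    return models


def simulate_mvar(
    model: MVARModel,
    n_samples: int,
    fs: float | None = None,
    seed: int | None = None,
    condition: str = "",
    subject_id: str = "",
) -> MultichannelRecording:
    """Stationary realization of a stable MVAR model with Gaussian innovations.

    A burn-in of ``max(10 * order, 200)`` samples is generated and discarded
    so the emitted samples are drawn from the stationary distribution.
    Identical seeds give identical output.
    """
    model.require_stable()
    if n_samples <= 10 * model.order:
        raise ValueError("n_samples must exceed 10x the model order")
    fs = float(fs if fs is not None else model.fs)
    try:
        chol = np.linalg.cholesky(model.innovation_cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "innovation covariance is not positive definite"
        ) from exc
    rng = np.random.default_rng(seed)
    p, n, _ = model.coefficients.shape
    burn = max(10 * p, 200)
    total = n_samples + burn
    innov = rng.standard_normal((total, n)) @ chol.T
    x = np.zeros((total, n))
    A = model.coefficients
    for t in range(p, total):
        acc = innov[t].copy()
        for r in range(1, p + 1):
            acc += A[r - 1] @ x[t - r]
        x[t] = acc
    labels = model.channel_labels or tuple(f"ch{i}" for i in range(n))
    return MultichannelRecording(
        data=x[burn:].T,
        fs=fs,
        channel_labels=labels,
        condition=condition,
        subject_id=subject_id,
    )


# ---------------------------------------------------------------------------
# RR simulation


def simulate_rr(
    params: dict,
    n_beats: int,
    ectopic_rate: float = 0.0,
    seed: int | None = None,
    condition: str = "",
    subject_id: str = "",
) -> RRSeries:
    """RR series with beat-domain LF/HF oscillations, noise and ectopy.

    ``intervals = mean_rr + lf_gain * sin(2 pi f_lf t + phi1)
    + hf_gain * sin(2 pi f_hf t + phi2) + N(0, noise_sd)`` with beat times
    approximated on the mean-RR lattice (a beat-domain simplification of
    pulse-frequency modulation). Each injected ectopic event splits one
    interval into a short-long pair (0.4 / 0.6 of the original), with the
    short beat flagged; total time is preserved and the series grows by one
    beat per event.
    """
    mean_rr = float(params["mean_rr"])
    lf_gain = float(params.get("lf_gain", 0.0))
    hf_gain = float(params.get("hf_gain", 0.0))
    noise_sd = float(params.get("noise_sd", 0.0))
    f_lf = float(params.get("lf_hz", 0.1))
    f_hf = float(params.get("hf_hz", 0.25))
    if not 300.0 <= mean_rr <= 2000.0:
        raise ValueError("mean_rr must lie in [300, 2000] ms")
    if not 0.0 <= ectopic_rate < 0.2:
        raise ValueError("ectopic_rate must lie in [0, 0.2)")
    if n_beats < 50:
        raise ValueError("n_beats must be >= 50")
    for name, gain in (("lf_gain", lf_gain), ("hf_gain", hf_gain)):
        if gain < 0:
            raise ValueError(f"{name} must be non-negative")
    # worst-case trough: both oscillators at -gain plus a 6-sigma noise dip;
    # the 0.4 ectopic split shortens it further
    trough = 0.4 * (mean_rr - lf_gain - hf_gain - 6.0 * noise_sd)
    if trough <= 0:
        offender = max(
            ("lf_gain", lf_gain), ("hf_gain", hf_gain), ("noise_sd", noise_sd),
            key=lambda kv: kv[1],
        )[0]
        raise ValueError(
            f"parameters would drive RR intervals <= 0 ms; reduce {offender}"
        )
    rng = np.random.default_rng(seed)
    phi1, phi2 = rng.uniform(0.0, 2.0 * np.pi, size=2)
    t = np.arange(n_beats) * mean_rr / 1000.0  # beat times, s
    intervals = (
        mean_rr
        + lf_gain * np.sin(2.0 * np.pi * f_lf * t + phi1)
        + hf_gain * np.sin(2.0 * np.pi * f_hf * t + phi2)
        + noise_sd * rng.standard_normal(n_beats)
    )
    annotations = [BEAT_NORMAL] * n_beats
    n_ect = rng.binomial(n_beats, ectopic_rate) if ectopic_rate > 0 else 0
    if n_ect:
        positions = np.sort(
            rng.choice(n_beats, size=n_ect, replace=False)
        )[::-1]
        intervals = list(intervals)
        for pos in positions:
            full = intervals[pos]
            intervals[pos : pos + 1] = [0.4 * full, 0.6 * full]
            annotations[pos : pos + 1] = [BEAT_ECTOPIC, BEAT_NORMAL]
        intervals = np.asarray(intervals)
    intervals = np.maximum(np.asarray(intervals, float), 1.0)
    return RRSeries(
        intervals=intervals,
        annotations=annotations,
        condition=condition,
        subject_id=subject_id,
    )


# ---------------------------------------------------------------------------
# cohort fixtures


def child_seed(root_seed: int, *key) -> int:
    """Deterministic per-(stage, subject, condition) seed below 2**31.

    Key parts may be ints or strings; strings are hashed stably (not with
    Python's randomized ``hash``).
    """
    import zlib

    parts = [
        int(k) & 0xFFFFFFFF
        if isinstance(k, (int, np.integer))
        else zlib.crc32(str(k).encode())
        for k in key
    ]
    ss = np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, *parts])
    return int(ss.generate_state(1)[0] % (2**31))


def _subject_ids(n: int) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(n)]


def write_fixture_set(
    scenario: GroundTruthScenario, out_dir, n_subjects: int | None = None
) -> dict:
    """Write one EDF and one RR CSV per subject x condition, plus a manifest.

    The manifest records every file together with the ground truth needed for
    recovery scoring: the directed edge list per condition and the RR
    generator parameters. Subject realizations differ only through seeds;
    the generating models are shared within a condition.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_subjects = int(n_subjects or scenario.n_subjects)
    models = build_condition_models(scenario)
    n_samples = int(round(scenario.epoch_s * scenario.fs))
    records = []
    for s_idx, subject in enumerate(_subject_ids(n_subjects)):
        for c_idx, cond in enumerate(scenario.condition_labels):
            rec = simulate_mvar(
                models[cond],
                n_samples,
                seed=child_seed(scenario.seed, 1, s_idx, c_idx),
                condition=cond,
                subject_id=subject,
            )
            edf_path = out_dir / f"{subject}_{cond}.edf"
            anio.write_edf(rec, edf_path)
            rr = simulate_rr(
                scenario.rr_params[cond],
                scenario.n_beats,
                ectopic_rate=scenario.ectopic_rate,
                seed=child_seed(scenario.seed, 2, s_idx, c_idx),
                condition=cond,
                subject_id=subject,
            )
            rr_path = out_dir / f"{subject}_{cond}_rr.csv"
            anio.write_rr_csv(rr, rr_path)
            records.append(
                {
                    "subject": subject,
                    "condition": cond,
                    "eeg_file": edf_path.name,
                    "rr_file": rr_path.name,
                }
            )
    manifest = {
        "seed": scenario.seed,
        "fs": scenario.fs,
        "n_subjects": n_subjects,
        "conditions": list(scenario.condition_labels),
        "channel_labels": list(scenario.channel_labels),
        "records": records,
        "ground_truth": {
            "edges": {
                cond: [list(e) for e in scenario.coupling_graphs[cond]]
                for cond in scenario.condition_labels
            },
            "rr_params": scenario.rr_params,
        },
    }
    anio.write_manifest(manifest, out_dir / "manifest.json")
    return manifest
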