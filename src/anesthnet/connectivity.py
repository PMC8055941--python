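"""Directed frequency-domain connectivity: MVAR estimation and PDC.

The estimation chain is: 3-s segments (detrended, normalized) -> ordinary
least squares MVAR fit at a BIC-selected order -> partial directed coherence
(PDC)

    pi_ij(f) = |A_bar_ij(f)| / sqrt(sum_k |A_bar_kj(f)|^2),
    A_bar(f) = I - sum_r A_r exp(-i 2 pi f r / fs),

-> per-cell significance against phase-randomization surrogates -> band
averaging of significant values into electrode-level directed networks with
ROI and global summaries.

PDC quantifies the direct influence of source channel j on target channel i
at frequency f, normalized over the outflow of the source column, so
``sum_i pi_ij(f)^2 == 1`` exactly at every frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .types import BandSet, MVARModel, MultichannelRecording, ROILayout


# ---------------------------------------------------------------------------
# closed-form quantities from coefficients


def a_bar(coefficients: np.ndarray, fs: float, freqs: np.ndarray) -> np.ndarray:
    """Frequency-domain coefficient matrix A_bar(f), shape (F, n, n)."""
    coeffs = np.asarray(coefficients, float)
    p, n, _ = coeffs.shape
    freqs = np.atleast_1d(np.asarray(freqs, float))
    lags = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * np.outer(freqs, lags) / fs)  # (F, p)
    return np.eye(n) - np.einsum("fp,pij->fij", phase, coeffs)


def pdc_matrix(coefficients: np.ndarray, fs: float, freqs: np.ndarray) -> np.ndarray:
    """Closed-form PDC magnitude, shape (n_targets, n_sources, n_freqs)."""
    A = a_bar(coefficients, fs, freqs)  # (F, n, n)
    denom = np.sqrt(np.sum(np.abs(A) ** 2, axis=1, keepdims=True))
    pdc = np.abs(A) / denom
    return np.transpose(pdc, (1, 2, 0))


def mvar_spectrum(model: MVARModel, freqs: np.ndarray) -> np.ndarray:
    """Closed-form power spectral density of a stable MVAR model.

    Returns the per-channel PSD (channels x freqs), in power per Hz, from
    S(f) = H(f) Sigma H(f)^H with H = A_bar^{-1}.
    """
    model.require_stable()
    A = a_bar(model.coefficients, model.fs, freqs)
    H = np.linalg.inv(A)
    S = H @ model.innovation_cov @ np.conj(np.transpose(H, (0, 2, 1)))
    psd = np.real(np.einsum("fii->fi", S)).T / model.fs * 2.0
    return psd


@dataclass
class PDCSpectrum:
    """PDC magnitudes (target x source x frequency) with significance mask."""

    values: np.ndarray
    freqs: np.ndarray
    sig_mask: np.ndarray | None = None
    channel_labels: tuple = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.freqs = np.asarray(self.freqs, float)
        if self.sig_mask is None:
            self.sig_mask = np.ones_like(self.values, dtype=bool)


@dataclass
class ConnectivityNetwork:
    """Per-band directed network of segment-averaged significant PDC."""

    band: str
    weights: np.ndarray  # target x source, diagonal forced to 0
    n_segments: int
    channel_labels: tuple
    global_mean: float = field(init=False)
    roi_means: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        np.fill_diagonal(self.weights, 0.0)
        n = self.weights.shape[0]
        off = ~np.eye(n, dtype=bool)
        self.global_mean = float(self.weights[off].mean()) if n > 1 else 0.0


# ---------------------------------------------------------------------------
# segmentation and estimation


def segment_normalize(
    rec: MultichannelRecording, seg_len_s: float = 3.0
) -> list[np.ndarray]:
    """Split into non-overlapping segments; detrend, center, divide by variance.

    Each segment is linearly detrended per channel, the residual mean removed,
    and the result divided by its variance. A zero-variance channel within a
    segment is an error (the segment carries no signal to model).
    """
    seg_len = int(round(seg_len_s * rec.fs))
    n_segments = rec.n_samples // seg_len
    if n_segments < 1:
        raise ValueError(
            f"recording of {rec.n_samples} samples shorter than one "
            f"{seg_len}-sample segment"
        )
    segments = []
    for s in range(n_segments):
        raw = rec.data[:, s * seg_len : (s + 1) * seg_len]
        pre_var = raw.var(axis=1)
        seg = sps.detrend(raw, axis=1, type="linear")
        seg = seg - seg.mean(axis=1, keepdims=True)
        var = seg.var(axis=1)
        # a channel that detrending reduces to numerical dust carries no
        # signal beyond its linear trend
        bad = np.where(var <= 1e-18 * np.maximum(pre_var, 1.0))[0]
        if bad.size:
            label = rec.channel_labels[bad[0]]
            raise ValueError(
                f"zero-variance channel {label!r} in segment {s}; "
                "cannot normalize"
            )
        seg /= var[:, None]
        segments.append(seg)
    return segments


def _lag_design(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Lag-stacked regression (X, Y) for one segment (channels x samples).

    X has shape (T - p, n*p) with lag blocks [lag1 | lag2 | ... | lagp],
    Y has shape (T - p, n).
    """
    n, T = x.shape
    p = order
    X = np.concatenate(
        [x[:, p - r : T - r].T for r in range(1, p + 1)], axis=1
    )
    Y = x[:, p:].T
    return X, Y


def fit_mvar(
    segment: np.ndarray,
    order: int,
    fs: float = 1.0,
    channel_labels: tuple = (),
) -> MVARModel:
    """OLS fit of an MVAR(p) model to one segment (channels x samples).

    One least-squares equation per channel on the shared lag-stacked design;
    the innovation covariance is the residual covariance (MLE scaling) and
    BIC = n_eff log det(Sigma) + log(n_eff) n^2 p.
    """
    x = np.asarray(segment, float)
    n, T = x.shape
    if T <= n * order + 1:
        raise ValueError(
            f"segment too short ({T} samples) for order {order} with "
            f"{n} channels"
        )
    X, Y = _lag_design(x, order)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient regressor matrix at order {order}; "
            "try a lower model order"
        )
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ B
    n_eff = Y.shape[0]
    sigma = resid.T @ resid / n_eff
    sign, logdet = np.linalg.slogdet(sigma)
    bic = n_eff * logdet + np.log(n_eff) * (n * n * order)
    coeffs = np.stack(
        [B[(r - 1) * n : r * n, :].T for r in range(1, order + 1)]
    )
    return MVARModel(
        coefficients=coeffs,
        innovation_cov=sigma,
        fs=fs,
        n_samples_fit=T,
        bic=float(bic),
        channel_labels=tuple(channel_labels),
    )


def select_order(
    segments: list[np.ndarray],
    candidate_orders,
    fs: float = 1.0,
) -> tuple[int, list[int]]:
    """Study-wide MVAR order: mode of per-segment BIC minimizers.

    Returns ``(chosen_order, per_segment_optima)``; ties in the mode break
    toward the smaller order.
    """
    candidates = sorted(int(p) for p in candidate_orders)
    if not candidates:
        raise ValueError("empty candidate order range")
    optima = []
    for seg in segments:
        bics = [fit_mvar(seg, p, fs=fs).bic for p in candidates]
        optima.append(candidates[int(np.argmin(bics))])
    orders, counts = np.unique(optima, return_counts=True)
    chosen = int(orders[np.argmax(counts)])  # np.unique sorts ascending
    return chosen, optima


def compute_pdc(model: MVARModel, freqs: np.ndarray) -> PDCSpectrum:
    """PDC spectrum of a fitted model on a frequency grid (Hz)."""
    freqs = np.asarray(freqs, float)
    if np.any(freqs <= 0) or np.any(freqs >= model.fs / 2):
        raise ValueError("frequencies must lie strictly inside (0, fs/2)")
    values = pdc_matrix(model.coefficients, model.fs, freqs)
    return PDCSpectrum(
        values=values, freqs=freqs, channel_labels=model.channel_labels
    )


# ---------------------------------------------------------------------------
# surrogate significance


def phase_randomize(
    x: np.ndarray, n_surrogates: int, rng: np.random.Generator
) -> np.ndarray:
    """Amplitude-preserving independent-phase surrogates, shape (S, n, T).

    Each channel's Fourier amplitudes are kept and phases redrawn
    independently per channel and surrogate, destroying all cross-channel
    phase relations (the null of no directed coupling). DC and Nyquist bins
    keep zero phase so the surrogates remain real-valued.
    """
    x = np.asarray(x, float)
    n, T = x.shape
    spec = np.fft.rfft(x, axis=1)
    mags = np.abs(spec)
    nf = mags.shape[1]
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_surrogates, n, nf))
    phases[:, :, 0] = 0.0
    if T % 2 == 0:
        phases[:, :, -1] = 0.0
    surr = np.fft.irfft(mags * np.exp(1j * phases), n=T, axis=2)
    return surr


def _batched_mvar_pdc(
    batch: np.ndarray, order: int, fs: float, freqs: np.ndarray
) -> np.ndarray:
    """Fit MVAR(p) to a batch (S, n, T) and return PDC (S, n, n, F).

    Normal-equation solve, vectorized over the batch; used for surrogate
    ensembles where thousands of refits are needed.
    """
    S, n, T = batch.shape
    p = order
    X = np.concatenate(
        [batch[:, :, p - r : T - r] for r in range(1, p + 1)], axis=1
    )  # (S, n*p, T-p)
    Y = batch[:, :, p:]  # (S, n, T-p)
    G = X @ np.transpose(X, (0, 2, 1))  # (S, np, np)
    C = X @ np.transpose(Y, (0, 2, 1))  # (S, np, n)
    B = np.linalg.solve(G, C)  # (S, np, n)
    # coefficient stacks: A[s, r, i, j] = B[s, r*n + j, i]
    coeffs = np.transpose(B.reshape(S, p, n, n), (0, 1, 3, 2))
    lags = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * np.outer(freqs, lags) / fs)  # (F, p)
    A = np.eye(n) - np.einsum("fp,spij->sfij", phase, coeffs)
    denom = np.sqrt(np.sum(np.abs(A) ** 2, axis=2, keepdims=True))
    pdc = np.abs(A) / denom  # (S, F, n, n)
    return np.transpose(pdc, (0, 2, 3, 1))


def surrogate_threshold(
    segment: np.ndarray,
    order: int,
    n_surrogates: int = 200,
    alpha: float = 0.05,
    freqs: np.ndarray | None = None,
    fs: float = 1.0,
    rng: np.random.Generator | int | None = None,
    threshold_mode: str = "per_cell",
) -> np.ndarray:
    """PDC significance threshold from phase-randomization surrogates.

    Each surrogate is an independent per-channel phase randomization of the
    segment, refit with the same MVAR order. With ``threshold_mode
    "per_cell"`` (default) the threshold is the ``1 - alpha`` empirical
    quantile of the surrogate PDC in every (target, source, frequency)
    cell; with ``"global"`` a single quantile is pooled over all
    off-diagonal cells and frequencies and broadcast.
    """
    if threshold_mode not in ("per_cell", "global"):
        raise ValueError("threshold_mode must be per_cell or global")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_surrogates < 20:
        warnings.warn(
            f"n_surrogates={n_surrogates} is low for quantile estimation; "
            ">= 20/alpha recommended",
            stacklevel=2,
        )
    if freqs is None:
        raise ValueError("a frequency grid is required")
    rng = np.random.default_rng(rng)
    freqs = np.asarray(freqs, float)
    surr = phase_randomize(np.asarray(segment, float), n_surrogates, rng)
    pdc = _batched_mvar_pdc(surr, order, fs, freqs)  # (S, n, n, F)
    if threshold_mode == "global":
        n = pdc.shape[1]
        off = ~np.eye(n, dtype=bool)
        thr = float(np.quantile(pdc[:, off, :], 1.0 - alpha))
        return np.full(pdc.shape[1:], thr)
    return np.quantile(pdc, 1.0 - alpha, axis=0)


def significant_pdc(
    segment: np.ndarray,
    order: int,
    freqs: np.ndarray,
    fs: float,
    n_surrogates: int = 200,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
    channel_labels: tuple = (),
) -> PDCSpectrum:
    """Fit one segment, compute PDC and its surrogate significance mask."""
    model = fit_mvar(segment, order, fs=fs, channel_labels=channel_labels)
    spec = compute_pdc(model, freqs)
    thr = surrogate_threshold(
        segment, order, n_surrogates, alpha, freqs=freqs, fs=fs, rng=rng
    )
    spec.sig_mask = spec.values > thr
    return spec


# ---------------------------------------------------------------------------
# band reduction


def band_network(
    pdc_list: list[PDCSpectrum],
    band: tuple[str, float, float],
    channel_labels: tuple,
    roi: ROILayout | None = None,
    squared: bool = False,
) -> ConnectivityNetwork:
    """Reduce per-segment PDC spectra to one per-band directed network.

    Within each segment, non-significant cells are zeroed, PDC is averaged
    over the band's frequency bins (half-open ``[lo, hi)``), and the
    resulting matrices are averaged across segments. The diagonal is removed
    for network analysis; ``global_mean`` is the off-diagonal mean and
    ``roi_means`` holds directed ROI->ROI averages.
    """
    if not pdc_list:
        raise ValueError("at least one segment PDC spectrum is required")
    name, lo, hi = band
    mats = []
    for spec in pdc_list:
        sel = (spec.freqs >= lo) & (spec.freqs < hi)
        if not np.any(sel):
            raise ValueError(
                f"band {name} [{lo}, {hi}) Hz outside the frequency grid"
            )
        masked = np.where(spec.sig_mask, spec.values, 0.0)
        if squared:
            masked = masked**2
        mats.append(masked[:, :, sel].mean(axis=2))
    weights = np.mean(mats, axis=0)
    net = ConnectivityNetwork(
        band=name,
        weights=weights,
        n_segments=len(pdc_list),
        channel_labels=tuple(channel_labels),
    )
    if roi is not None:
        net.roi_means = roi_pair_means(net.weights, channel_labels, roi)
    return net


def roi_pair_means(
    weights: np.ndarray, channel_labels: tuple, roi: ROILayout
) -> dict:
    """Directed ROI->ROI mean weights, diagonal cells excluded."""
    idx = {ch: i for i, ch in enumerate(channel_labels)}
    out = {}
    for src_name, src_members in roi.rois.items():
        for tgt_name, tgt_members in roi.rois.items():
            cells = [
                weights[idx[t], idx[s]]
                for s in src_members
                for t in tgt_members
                if s in idx and t in idx and idx[s] != idx[t]
            ]
            if cells:
                out[(src_name, tgt_name)] = float(np.mean(cells))
    return out


def analyze_recording(
    rec: MultichannelRecording,
    bands: BandSet,
    roi: ROILayout | None = None,
    order: int | None = None,
    candidate_orders=range(2, 9),
    seg_len_s: float = 3.0,
    n_surrogates: int = 200,
    alpha: float = 0.05,
    freqs: np.ndarray | None = None,
    seed: int | None = None,
) -> dict:
    """Full connectivity analysis of one recording.

    Segments, selects the MVAR order by per-segment BIC mode unless a fixed
    ``order`` is given, computes surrogate-masked PDC per segment and reduces
    to one :class:`ConnectivityNetwork` per band. Returns
    ``{"order": p, "networks": {band_name: network}}``.
    """
    if freqs is None:
        freqs = np.arange(1.0, 40.0 + 1e-9, 0.5)
    segments = segment_normalize(rec, seg_len_s=seg_len_s)
    if order is None:
        order, _ = select_order(segments, candidate_orders, fs=rec.fs)
    rng = np.random.default_rng(seed)
    pdc_list = [
        significant_pdc(
            seg,
            order,
            freqs,
            rec.fs,
            n_surrogates=n_surrogates,
            alpha=alpha,
            rng=rng,
            channel_labels=rec.channel_labels,
        )
        for seg in segments
    ]
    networks = {
        name: band_network(
            pdc_list, (name, lo, hi), rec.channel_labels, roi=roi
        )
        for name, lo, hi in bands.bands
    }
    return {"order": order, "networks": networks}
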