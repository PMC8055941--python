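"""EEG preprocessing and relative band power.

The preprocessing chain mirrors standard clinical EEG practice: average
re-referencing (each sample has the instantaneous mean over channels
removed) followed by zero-phase 0.5-48 Hz band-pass filtering. Power
analysis then divides the epoch into non-overlapping 2-s segments, computes
an FFT periodogram per segment and channel, and reports relative power (RP)
per band as band power over total power in the 1-40 Hz analysis range,
averaged across segments and optionally over ROI electrode groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .types import BandSet, MultichannelRecording, ROILayout


@dataclass
class RelativePowerResult:
    """Channel x band and ROI x band relative-power proportions."""

    rp: np.ndarray  # channels x bands, each entry in [0, 1]
    roi_rp: dict  # roi name -> per-band array
    band_names: tuple
    channel_labels: tuple
    segment_count: int


def preprocess_eeg(
    rec: MultichannelRecording,
    band: tuple[float, float] = (0.5, 48.0),
    filter_order: int = 6,
    average_reference: bool = True,
) -> MultichannelRecording:
    """Average re-reference then zero-phase band-pass filter.

    Requires at least two channels and a sampling rate comfortably above
    twice the upper band edge. ``average_reference=False`` skips the
    re-referencing step: the common average makes the channel set exactly
    rank-deficient (channels sum to zero), which a full multichannel MVAR
    fit cannot tolerate, so the connectivity branch runs on the original
    reference.
    """
    if rec.n_channels < 2:
        raise ValueError("average re-referencing requires >= 2 channels")
    lo, hi = band
    if rec.fs < 2.0 * hi + 2.0:
        raise ValueError(
            f"sampling rate {rec.fs} Hz too low for a {hi} Hz band edge"
        )
    if average_reference:
        referenced = rec.data - rec.data.mean(axis=0, keepdims=True)
    else:
        referenced = rec.data
    sos = sps.butter(
        filter_order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos"
    )
    filtered = sps.sosfiltfilt(sos, referenced, axis=1)
    return MultichannelRecording(
        data=filtered,
        fs=rec.fs,
        channel_labels=rec.channel_labels,
        condition=rec.condition,
        subject_id=rec.subject_id,
    )


def filter_epoch(
    rec: MultichannelRecording,
    band: tuple[float, float] = (1.0, 40.0),
    filter_order: int = 2,
) -> MultichannelRecording:
    """Zero-phase 2nd-order (12 dB/octave) band-pass for the power analysis."""
    sos = sps.butter(
        filter_order, band, btype="bandpass", fs=rec.fs, output="sos"
    )
    return MultichannelRecording(
        data=sps.sosfiltfilt(sos, rec.data, axis=1),
        fs=rec.fs,
        channel_labels=rec.channel_labels,
        condition=rec.condition,
        subject_id=rec.subject_id,
    )


def segment_fixed(
    rec: MultichannelRecording, seg_len_s: float = 2.0, n_segments: int = 30
) -> list[np.ndarray]:
    """Exactly ``n_segments`` contiguous non-overlapping segments from the start."""
    seg_len = int(round(seg_len_s * rec.fs))
    needed = seg_len * n_segments
    if rec.n_samples < needed:
        raise ValueError(
            f"recording too short: {rec.n_samples} samples available, "
            f"{needed} required for {n_segments} x {seg_len_s} s"
        )
    return [
        rec.data[:, s * seg_len : (s + 1) * seg_len] for s in range(n_segments)
    ]


def relative_power(
    segments: list[np.ndarray],
    fs: float,
    bands: BandSet | None = None,
    analysis_band: tuple[float, float] = (1.0, 40.0),
    roi: ROILayout | None = None,
    channel_labels: tuple = (),
    window: str | None = None,
    denominator: str = "analysis_band",
) -> RelativePowerResult:
    """Relative power per channel and band from FFT periodograms.

    For each segment and channel the one-sided periodogram is computed (plain
    FFT by default, optionally Hann-windowed) and RP(band) is the power
    summed over the band's half-open ``[f_lo, f_hi)`` bins divided by the
    power summed over the analysis band (``denominator="analysis_band"``) or
    over the union of the named bands only (``"union_of_bands"``). RPs are
    averaged across segments; ROI values are means over member channels
    present in the montage.
    """
    if denominator not in ("analysis_band", "union_of_bands"):
        raise ValueError("denominator must be analysis_band or union_of_bands")
    bands = bands or BandSet()
    a_lo, a_hi = analysis_band
    nyq = fs / 2.0
    for name, lo, hi in bands.bands:
        if hi > nyq:
            raise ValueError(f"band {name} upper edge {hi} Hz above Nyquist")
        if lo < a_lo or hi > a_hi:
            raise ValueError(
                f"band {name} outside the analysis band {analysis_band}"
            )
    if not segments:
        raise ValueError("at least one segment is required")
    seg_len = segments[0].shape[1]
    win = sps.get_window(window, seg_len) if window else None
    rp_accum = None
    for seg in segments:
        if seg.shape[1] != seg_len:
            raise ValueError("segments must be equal length")
        freqs, psd = sps.periodogram(
            seg, fs=fs, window=win if win is not None else "boxcar", axis=1
        )
        if denominator == "analysis_band":
            in_denom = (freqs >= a_lo) & (freqs < a_hi)
        else:
            in_denom = np.zeros_like(freqs, dtype=bool)
            for _, lo, hi in bands.bands:
                in_denom |= (freqs >= lo) & (freqs < hi)
        total = psd[:, in_denom].sum(axis=1)
        if np.any(total <= 0):
            raise ValueError("zero total power in analysis band")
        rp_seg = np.empty((seg.shape[0], len(bands.bands)))
        for b, (name, lo, hi) in enumerate(bands.bands):
            sel = (freqs >= lo) & (freqs < hi)
            rp_seg[:, b] = psd[:, sel].sum(axis=1) / total
        rp_accum = rp_seg if rp_accum is None else rp_accum + rp_seg
    rp = rp_accum / len(segments)
    roi_rp = {}
    if roi is not None and channel_labels:
        idx = {ch: i for i, ch in enumerate(channel_labels)}
        for roi_name, members in roi.rois.items():
            rows = [idx[ch] for ch in members if ch in idx]
            if rows:
                roi_rp[roi_name] = rp[rows].mean(axis=0)
    return RelativePowerResult(
        rp=rp,
        roi_rp=roi_rp,
        band_names=bands.names,
        channel_labels=tuple(channel_labels),
        segment_count=len(segments),
    )
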