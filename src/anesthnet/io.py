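"""File exchange: 16-bit EDF for multichannel EEG, CSV for RR series.

EDF is the exchange format for the EEG side (one data record per second,
16-bit samples, physical dimension microvolts). Reading goes through MNE's
EDF reader; writing is a minimal EDF(+)-conforming writer sufficient for
integer sampling rates and identical per-channel rates. Header date/time
fields are fixed so that rewriting the same data yields byte-identical
files.

RR series travel as two-column CSV (``rr_ms,annotation``), one beat per row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import BEAT_NORMAL, MultichannelRecording, RRSeries

_EDF_DIG_MIN = -32768
_EDF_DIG_MAX = 32767


def _ascii_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field too long: {s!r} (max {width})")
    return s.ljust(width).encode("ascii")


def write_edf(rec: MultichannelRecording, path) -> Path:
    """Write a recording as 16-bit EDF, one data record per second.

    The signal is truncated to a whole number of 1-second records. Amplitudes
    are expressed in microvolts; quantization error is bounded by half a
    digital step of the per-channel physical range.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record
    n_records = rec.n_samples // spr
    if n_records == 0:
        raise ValueError("recording shorter than one 1-second EDF record")
    n_sig = rec.n_channels
    data = rec.data[:, : n_records * spr]

    # symmetric physical range per channel, padded to avoid clipping
    phys_max = np.maximum(np.max(np.abs(data), axis=1), 1e-6) * 1.0000001
    phys_min = -phys_max

    header = b"".join(
        [
            _ascii_field("0", 8),
            _ascii_field(f"subject {rec.subject_id}".strip(), 80),
            _ascii_field(f"condition {rec.condition}".strip(), 80),
            _ascii_field("01.01.00", 8),
            _ascii_field("00.00.00", 8),
            _ascii_field(256 * (1 + n_sig), 8),
            _ascii_field("", 44),
            _ascii_field(n_records, 8),
            _ascii_field(1, 8),
            _ascii_field(n_sig, 4),
        ]
    )

    def sig_fields(values, width):
        return b"".join(_ascii_field(v, width) for v in values)

    header += sig_fields(rec.channel_labels, 16)
    header += sig_fields([""] * n_sig, 80)  # transducer
    header += sig_fields(["uV"] * n_sig, 8)
    header += sig_fields([f"{v:.6g}" for v in phys_min], 8)
    header += sig_fields([f"{v:.6g}" for v in phys_max], 8)
    header += sig_fields([_EDF_DIG_MIN] * n_sig, 8)
    header += sig_fields([_EDF_DIG_MAX] * n_sig, 8)
    header += sig_fields([""] * n_sig, 80)  # prefilter
    header += sig_fields([spr] * n_sig, 8)
    header += sig_fields([""] * n_sig, 32)

    # re-parse the physical range exactly as a reader will, so that the
    # digital scaling matches the truncated ASCII header values
    pmin = np.array([float(f"{v:.6g}") for v in phys_min])
    pmax = np.array([float(f"{v:.6g}") for v in phys_max])
    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (pmax - pmin)
    digital = np.round(
        (data - pmin[:, None]) * scale[:, None] + _EDF_DIG_MIN
    )
    digital = np.clip(digital, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())
    return path


def read_edf(path, condition: str = "", subject_id: str = "") -> MultichannelRecording:
    """Read an EDF file into a :class:`MultichannelRecording` (microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # MNE converts uV channels to volts
    return MultichannelRecording(
        data=data_uv,
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        condition=condition,
        subject_id=subject_id,
    )


def write_rr_csv(series: RRSeries, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {"rr_ms": series.intervals, "annotation": series.annotations}
    )
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_rr_csv(path, condition: str = "", subject_id: str = "") -> RRSeries:
    df = pd.read_csv(path)
    if "rr_ms" not in df.columns:
        raise ValueError(f"{path}: RR CSV must have an 'rr_ms' column")
    ann = (
        df["annotation"].astype(str).tolist()
        if "annotation" in df.columns
        else [BEAT_NORMAL] * len(df)
    )
    return RRSeries(
        intervals=df["rr_ms"].to_numpy(dtype=float),
        annotations=ann,
        condition=condition,
        subject_id=subject_id,
    )


def write_manifest(manifest: dict, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
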