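"""Heart-rate-variability indices: symbolic dynamics and conditional entropy.

The tachogram (RR-interval series) is cleaned of ectopic beats, reduced to a
250 +/- 50 beat segment, quantized into 6 uniform levels over its dynamic
range, and analyzed two ways:

* symbolic dynamics over all overlapping 3-beat windows: 0V% (no variation,
  a cardiac sympathetic marker), 1V% (one variation), 2LV% (two like
  variations) and 2UV% (two unlike variations, vagal markers);
* corrected conditional entropy (CCE): the conditional Shannon entropy of
  the next symbol given the previous L-1, plus a correction term
  ``perc(L) * SE(1)`` that charges patterns observed only once, so the curve
  has an interior minimum. The regularity index ``Ro = 1 - min_L CCE(L) /
  SE(1)`` runs from 0 (maximal complexity) to 1 (fully predictable rhythm).

All entropies are in bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import BEAT_ECTOPIC, BEAT_INTERPOLATED, BEAT_NORMAL, RRSeries


@dataclass
class SymbolicResult:
    p0v: float
    p1v: float
    p2lv: float
    p2uv: float
    n_patterns: int
    n_levels: int


@dataclass
class ComplexityResult:
    cce_curve: np.ndarray  # CCE(L), L = 1..L_max
    se1: float
    cce_min: float
    ro: float
    degenerate: bool = False


def clean_rr(
    series: RRSeries,
    deviation_threshold: float = 0.2,
    neighborhood: int = 10,
    max_ectopic_fraction: float = 0.2,
) -> RRSeries:
    """Replace ectopic beats by linear interpolation of adjacent normal beats.

    A beat is treated as ectopic when annotated so, or when its interval
    deviates more than ``deviation_threshold`` from the median of its
    ``neighborhood`` nearest beats. Flagged intervals are replaced by the
    linear interpolation between the surrounding normal intervals and
    re-annotated as interpolated; series length is preserved.
    """
    x = series.intervals
    n = x.size
    if n < 10:
        raise ValueError("at least 10 beats are required for cleaning")
    flagged = np.array(
        [a == BEAT_ECTOPIC for a in series.annotations], dtype=bool
    )
    half = neighborhood // 2
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        nb = np.delete(x[lo:hi], i - lo)
        med = np.median(nb)
        if med > 0 and abs(x[i] - med) / med > deviation_threshold:
            flagged[i] = True
    frac = flagged.mean()
    if frac > max_ectopic_fraction:
        raise ValueError(
            f"{frac:.0%} of beats flagged ectopic; series unusable "
            f"(limit {max_ectopic_fraction:.0%})"
        )
    if not flagged.any():
        return RRSeries(
            intervals=x.copy(),
            annotations=list(series.annotations),
            condition=series.condition,
            subject_id=series.subject_id,
        )
    good = np.where(~flagged)[0]
    if good.size < 2:
        raise ValueError("too few normal beats to interpolate")
    cleaned = x.copy()
    bad = np.where(flagged)[0]
    cleaned[bad] = np.interp(bad, good, x[good])
    annotations = [
        BEAT_INTERPOLATED if flagged[i] else BEAT_NORMAL for i in range(n)
    ]
    return RRSeries(
        intervals=cleaned,
        annotations=annotations,
        condition=series.condition,
        subject_id=series.subject_id,
    )


def select_segment(
    series: RRSeries, target: int = 250, tolerance: int = 50
) -> RRSeries:
    """First contiguous run of ``min(len, target)`` beats within tolerance."""
    n = len(series)
    if n < target - tolerance:
        raise ValueError(
            f"series of {n} beats shorter than the minimum usable "
            f"{target - tolerance}"
        )
    length = min(n, target)
    return RRSeries(
        intervals=series.intervals[:length],
        annotations=series.annotations[:length],
        condition=series.condition,
        subject_id=series.subject_id,
    )


def symbolize(series: RRSeries | np.ndarray, n_levels: int = 6) -> np.ndarray:
    """Uniform quantization of the full dynamic range into ``n_levels`` bins.

    Symbols are bin indices 0..n_levels-1; the maximum maps into the top
    bin. A constant series maps to all zeros.
    """
    x = series.intervals if isinstance(series, RRSeries) else np.asarray(series, float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return np.zeros(x.size, dtype=int)
    sym = np.floor((x - lo) / (hi - lo) * n_levels).astype(int)
    return np.minimum(sym, n_levels - 1)


def symbolic_indices(symbols: np.ndarray, n_levels: int = 6) -> SymbolicResult:
    """Classify all overlapping 3-symbol windows into 0V/1V/2LV/2UV.

    A 'variation' is a nonzero difference between consecutive symbols: none
    -> 0V, exactly one -> 1V, two with equal sign -> 2LV, two with opposite
    signs -> 2UV. Percentages sum to 100 exactly.
    """
    s = np.asarray(symbols, dtype=int)
    if s.size < 3:
        raise ValueError("at least 3 symbols are required")
    a, b, c = s[:-2], s[1:-1], s[2:]
    v1 = b - a
    v2 = c - b
    n_var = (v1 != 0).astype(int) + (v2 != 0).astype(int)
    zero_v = n_var == 0
    one_v = n_var == 1
    two_like = (n_var == 2) & (v1 * v2 > 0)
    two_unlike = (n_var == 2) & (v1 * v2 < 0)
    n_pat = s.size - 2
    return SymbolicResult(
        p0v=100.0 * zero_v.sum() / n_pat,
        p1v=100.0 * one_v.sum() / n_pat,
        p2lv=100.0 * two_like.sum() / n_pat,
        p2uv=100.0 * two_unlike.sum() / n_pat,
        n_patterns=n_pat,
        n_levels=n_levels,
    )


def _pattern_entropy(s: np.ndarray, L: int) -> tuple[float, float]:
    """Shannon entropy (bits) of length-L patterns and the once-only fraction."""
    n = s.size - L + 1
    base = int(s.max()) + 1
    codes = np.zeros(n, dtype=np.int64)
    for k in range(L):
        codes = codes * base + s[k : k + n]
    _, counts = np.unique(codes, return_counts=True)
    p = counts / n
    se = float(-(p * np.log2(p)).sum())
    perc = float(counts[counts == 1].size / n)
    return se, perc


def corrected_conditional_entropy(
    symbols: np.ndarray, l_max: int = 12
) -> ComplexityResult:
    """CCE curve, its minimum, and the regularity index Ro.

    ``CCE(L) = SE(L) - SE(L-1) + perc(L) * SE(1)`` with ``CCE(1) = SE(1)``;
    ``perc(L)`` is the fraction of length-L patterns occurring exactly once,
    which drives the curve back up once patterns become unique, guaranteeing
    an interior minimum on finite data. ``Ro = 1 - min_L CCE(L) / SE(1)``.
    A constant sequence has SE(1) = 0 and is reported as degenerate with
    Ro = 1.
    """
    s = np.asarray(symbols, dtype=int)
    if s.size < l_max + 1:
        raise ValueError(
            f"sequence of {s.size} symbols shorter than l_max + 1 = {l_max + 1}"
        )
    se1, _ = _pattern_entropy(s, 1)
    if se1 == 0.0:
        return ComplexityResult(
            cce_curve=np.zeros(l_max),
            se1=0.0,
            cce_min=0.0,
            ro=1.0,
            degenerate=True,
        )
    cce = np.empty(l_max)
    cce[0] = se1
    prev_se = se1
    for L in range(2, l_max + 1):
        se, perc = _pattern_entropy(s, L)
        cce[L - 1] = (se - prev_se) + perc * se1
        prev_se = se
    cce_min = float(cce.min())
    ro = 1.0 - cce_min / se1
    return ComplexityResult(
        cce_curve=cce, se1=se1, cce_min=cce_min, ro=float(np.clip(ro, 0.0, 1.0))
    )


def mean_hr(series: RRSeries) -> float:
    """Mean heart rate in beats per minute: 60000 / mean RR (ms)."""
    if len(series) < 1:
        raise ValueError("empty RR series")
    return 60000.0 / float(series.intervals.mean())


def analyze_rr(
    series: RRSeries,
    n_levels: int = 6,
    l_max: int = 12,
    target: int = 250,
    tolerance: int = 50,
) -> dict:
    """Full cardiac chain: clean, select segment, symbolic + complexity + HR.

    Returns a flat dict of scalar indices (HR, 0V, 1V, 2LV, 2UV, Ro, CCEmin).
    """
    cleaned = clean_rr(series)
    segment = select_segment(cleaned, target=target, tolerance=tolerance)
    symbols = symbolize(segment, n_levels=n_levels)
    sym = symbolic_indices(symbols, n_levels=n_levels)
    cmplx = corrected_conditional_entropy(symbols, l_max=l_max)
    return {
        "HR": mean_hr(segment),
        "0V": sym.p0v,
        "1V": sym.p1v,
        "2LV": sym.p2lv,
        "2UV": sym.p2uv,
        "Ro": cmplx.ro,
        "CCEmin": cmplx.cce_min,
    }
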