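"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written in the most literal way possible (explicit loops,
Floyd-Warshall, dictionary pattern counting) and deliberately shares no code
with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------- graphs
# adjacency convention here: adj[i][j] == 1 means an edge i -> j


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist = np.full((n, n), math.inf)
    for i in range(n):
        dist[i, i] = 0.0
        for j in range(n):
            if i != j and adj[i, j]:
                dist[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    dist = floyd_warshall(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and math.isfinite(dist[i, j]) and dist[i, j] > 0:
                total += 1.0 / dist[i, j]
    return total / (n * (n - 1))


def char_path_length(adj: np.ndarray) -> float:
    n = adj.shape[0]
    dist = floyd_warshall(adj)
    finite = [
        dist[i, j]
        for i in range(n)
        for j in range(n)
        if i != j and math.isfinite(dist[i, j])
    ]
    return sum(finite) / len(finite) if finite else math.nan


def local_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    accum = 0.0
    for i in range(n):
        neighbors = [
            j for j in range(n) if j != i and (adj[i, j] or adj[j, i])
        ]
        if len(neighbors) < 2:
            continue
        sub = adj[np.ix_(neighbors, neighbors)]
        accum += global_efficiency(sub)
    return accum / n


def clustering_coefficient(adj: np.ndarray) -> float:
    """Directed clustering (Fagiolo) by explicit triangle enumeration."""
    n = adj.shape[0]
    coeffs = []
    for i in range(n):
        t = 0
        for j in range(n):
            for k in range(n):
                if j == i or k == i or j == k:
                    continue
                # all directed 3-cycles through (i, j, k) in either sense
                t += (adj[i, j] + adj[j, i]) * (adj[j, k] + adj[k, j]) * (
                    adj[k, i] + adj[i, k]
                )
        t /= 2.0
        d_tot = int(adj[i, :].sum() + adj[:, i].sum())
        d_bi = int(sum(adj[i, j] and adj[j, i] for j in range(n)))
        denom = d_tot * (d_tot - 1) - 2 * d_bi
        coeffs.append(t / denom if denom > 0 else 0.0)
    return float(np.mean(coeffs))


def degree_metrics(adj: np.ndarray, weights: np.ndarray) -> dict:
    n = adj.shape[0]
    out = {
        "in_degree": adj.sum(axis=0).astype(float),
        "out_degree": adj.sum(axis=1).astype(float),
        "in_strength": weights.sum(axis=0),
        "out_strength": weights.sum(axis=1),
    }
    out["degree"] = out["in_degree"] + out["out_degree"]
    out["strength"] = out["in_strength"] + out["out_strength"]
    tot = out["in_degree"] + out["out_degree"]
    frac = np.full(n, np.nan)
    for i in range(n):
        if tot[i] > 0:
            frac[i] = out["in_degree"][i] / tot[i]
    out["in_degree_fraction"] = frac
    return out


# --------------------------------------------------------------- symbolic


def classify_window(a: int, b: int, c: int) -> str:
    v1, v2 = b - a, c - b
    if v1 == 0 and v2 == 0:
        return "0V"
    if (v1 == 0) != (v2 == 0):
        return "1V"
    if (v1 > 0 and v2 > 0) or (v1 < 0 and v2 < 0):
        return "2LV"
    return "2UV"


def symbolic_percentages(symbols) -> dict:
    counts = {"0V": 0, "1V": 0, "2LV": 0, "2UV": 0}
    windows = 0
    for a, b, c in zip(symbols, symbols[1:], symbols[2:]):
        counts[classify_window(a, b, c)] += 1
        windows += 1
    return {k: 100.0 * v / windows for k, v in counts.items()}


# --------------------------------------------------------------- entropy


def shannon_entropy_of_patterns(symbols, length: int) -> tuple[float, float]:
    """Entropy (bits) of length-L patterns and the fraction occurring once."""
    counts: dict = {}
    n = len(symbols) - length + 1
    for i in range(n):
        key = tuple(symbols[i : i + length])
        counts[key] = counts.get(key, 0) + 1
    se = 0.0
    once = 0
    for c in counts.values():
        p = c / n
        se -= p * math.log2(p)
        if c == 1:
            once += 1
    return se, once / n


def cce_curve(symbols, l_max: int) -> list:
    se1, _ = shannon_entropy_of_patterns(symbols, 1)
    curve = [se1]
    prev = se1
    for L in range(2, l_max + 1):
        se, perc = shannon_entropy_of_patterns(symbols, L)
        curve.append(se - prev + perc * se1)
        prev = se
    return curve


# ---------------------------------------------------------------- spectra


def mvar_psd_channel(coeffs: np.ndarray, fs: float, freqs) -> np.ndarray:
    """Closed-form per-channel PSD of an MVAR process, unit innovations."""
    p, n, _ = coeffs.shape
    psd = np.zeros((len(freqs), n))
    for fi, f in enumerate(freqs):
        a = np.eye(n, dtype=complex)
        for r in range(1, p + 1):
            a -= coeffs[r - 1] * np.exp(-2j * np.pi * f * r / fs)
        h = np.linalg.inv(a)
        s = h @ h.conj().T
        psd[fi] = np.real(np.diag(s)) / fs * 2.0
    return psd.T
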