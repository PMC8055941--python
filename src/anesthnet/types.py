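"""Core containers shared across the EEG and HRV analysis stages.

The unit of work on the EEG side is a :class:`MultichannelRecording` (labeled
channels x samples at a fixed sampling rate, tagged with the anesthesia
condition). On the cardiac side it is an :class:`RRSeries` (beat-to-beat
intervals in milliseconds with per-beat annotations). MVAR models connect the
two roles of the package: they generate synthetic multichannel signals and
they are the estimation target from which partial directed coherence (PDC)
is derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The five anesthesia stages, in protocol order: baseline, first induction
#: period, pre-loss-of-consciousness, first recovery period, pre-recovery of
#: consciousness.
CONDITIONS = ("Bas", "Ind1", "Ind2", "Rec1", "Rec2")

#: 19-channel 10-20 montage used throughout.
CHANNELS_1020 = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)

BEAT_NORMAL = "normal"
BEAT_ECTOPIC = "ectopic"
BEAT_INTERPOLATED = "interpolated"


class StabilityError(ValueError):
    """Raised when an MVAR model is not stable (spectral radius >= 1)."""


@dataclass
class MVARModel:
    """Multivariate autoregressive model of order ``p``.

    ``coefficients`` is a ``(p, n, n)`` stack of lag matrices ``A_r`` such
    that ``x[t] = sum_r A_r @ x[t - r] + e[t]`` with innovations ``e`` of
    covariance ``innovation_cov``.
    """

    coefficients: np.ndarray
    innovation_cov: np.ndarray
    fs: float = 1.0
    n_samples_fit: int = 0
    bic: float = float("nan")
    #: intended coupling edges (source_label, target_label, f_hz, gain) when
    #: the model was constructed from a ground-truth scenario
    edges: list = field(default_factory=list)
    channel_labels: tuple = ()

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 3 or (
            self.coefficients.shape[1] != self.coefficients.shape[2]
        ):
            raise ValueError("coefficients must be a (p, n, n) stack")
        self.innovation_cov = np.asarray(self.innovation_cov, dtype=float)
        if not np.allclose(self.innovation_cov, self.innovation_cov.T):
            raise ValueError("innovation covariance must be symmetric")

    @property
    def order(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coefficients.shape[1]

    def companion(self) -> np.ndarray:
        """Companion (state-transition) matrix of the stacked VAR(1) form."""
        p, n, _ = self.coefficients.shape
        comp = np.zeros((n * p, n * p))
        comp[:n, :] = np.concatenate(list(self.coefficients), axis=1)
        if p > 1:
            comp[n:, :-n] = np.eye(n * (p - 1))
        return comp

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))

    def is_stable(self, tol: float = 1e-10) -> bool:
        return self.spectral_radius() < 1.0 - tol

    def require_stable(self) -> None:
        rho = self.spectral_radius()
        if rho >= 1.0:
            raise StabilityError(
                f"MVAR model is unstable: spectral radius {rho:.4f} >= 1"
            )


@dataclass
class MultichannelRecording:
    """Labeled channels x samples matrix with sampling rate and condition tag."""

    data: np.ndarray
    fs: float
    channel_labels: tuple
    condition: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels must match data rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel_labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class RRSeries:
    """Beat-to-beat interval series (tachogram) in milliseconds."""

    intervals: np.ndarray
    annotations: list
    condition: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.annotations = list(self.annotations)
        if self.intervals.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        if len(self.annotations) != self.intervals.size:
            raise ValueError("annotations must match intervals length")
        if np.any(self.intervals <= 0):
            raise ValueError("all RR intervals must be positive")

    def __len__(self) -> int:
        return int(self.intervals.size)


@dataclass(frozen=True)
class BandSet:
    """Ordered set of named frequency bands, half-open ``[f_lo, f_hi)``."""

    bands: tuple = (
        ("delta", 1.0, 4.0),
        ("theta", 4.0, 8.0),
        ("alpha", 8.0, 13.0),
        ("beta", 13.0, 30.0),
    )

    def __post_init__(self) -> None:
        edges = []
        for name, lo, hi in self.bands:
            if not lo < hi:
                raise ValueError(f"band {name}: f_lo must be < f_hi")
            edges.append((lo, hi))
        edges.sort()
        for (_, hi_prev), (lo_next, _) in zip(edges, edges[1:]):
            if lo_next < hi_prev:
                raise ValueError("bands must not overlap")

    @property
    def names(self) -> tuple:
        return tuple(b[0] for b in self.bands)

    def range_of(self, name: str) -> tuple:
        for bname, lo, hi in self.bands:
            if bname == name:
                return lo, hi
        raise KeyError(f"unknown band {name!r}")


#: Default ROI layout over the 10-20 montage. Fz belongs to no ROI.
DEFAULT_ROI_MAP = {
    "frontal": ("F3", "F4", "Fp1", "Fp2"),
    "central": ("C3", "C4", "Cz"),
    "parietal": ("P3", "P4", "Pz"),
    "occipital": ("O1", "O2"),
    "temporal": ("T4", "T6", "F8", "T5", "T3", "F7"),
}


@dataclass(frozen=True)
class ROILayout:
    """Named electrode groups; no electrode may belong to two ROIs."""

    roi_map: tuple = tuple((k, v) for k, v in DEFAULT_ROI_MAP.items())

    def __post_init__(self) -> None:
        seen: set = set()
        for _, members in self.roi_map:
            for ch in members:
                if ch in seen:
                    raise ValueError(f"electrode {ch} assigned to two ROIs")
                seen.add(ch)

    @property
    def rois(self) -> dict:
        return {name: tuple(members) for name, members in self.roi_map}

    def roi_of(self, channel: str) -> str | None:
        for name, members in self.roi_map:
            if channel in members:
                return name
        return None
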