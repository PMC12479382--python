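"""Core data containers shared across the pipeline stages.

All containers are plain dataclasses around numpy arrays / pandas frames.
Time series are stored frames x parcels; parcel identifiers are 1-based
strings in files (Schaefer convention) and positional 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: The six resting-state networks analyzed; the limbic network (LIM) is
#: excluded for its lower reproducibility and signal-to-noise ratio.
ANALYZED_NETWORKS: tuple[str, ...] = ("VIS", "ASM", "DAN", "SAL", "FPN", "DMN")


@dataclass
class ParcelTimeSeries:
    """One scan's parcellated BOLD signal plus acquisition metadata.

    Parameters
    ----------
    data:
        Frames x parcels real matrix (arbitrary signal units).
    tr_seconds:
        Repetition time in seconds (1.8 s in the emulated acquisition).
    parcel_ids:
        Ordered parcel identifiers, one per column.
    motion:
        Optional frames x 6 rigid-body motion parameters.
    fd:
        Optional per-frame framewise displacement in mm.
    noise_signals:
        Optional frames x m nuisance channels (physiological-noise
        proxies used for component-based correction).
    frame_mask:
        Boolean per frame; True marks a retained (non-scrubbed) frame.
    """

    data: np.ndarray
    tr_seconds: float
    parcel_ids: Sequence[str]
    motion: np.ndarray | None = None
    fd: np.ndarray | None = None
    noise_signals: np.ndarray | None = None
    frame_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a frames x parcels matrix")
        n_frames, n_parcels = self.data.shape
        if n_frames < 10:
            raise ValueError(f"need at least 10 frames, got {n_frames}")
        if len(self.parcel_ids) != n_parcels:
            raise ValueError("parcel_ids length must match parcel count")
        if len(set(self.parcel_ids)) != n_parcels:
            raise ValueError("parcel_ids must be unique")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        for name in ("motion", "fd", "noise_signals", "frame_mask"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape[0] != n_frames:
                    raise ValueError(f"{name} length must equal frame count")
                setattr(self, name, arr)
        if self.motion is not None and self.motion.shape[1] != 6:
            raise ValueError("motion must have exactly 6 columns")
        if self.frame_mask is None:
            self.frame_mask = np.ones(n_frames, dtype=bool)
        else:
            self.frame_mask = np.asarray(self.frame_mask, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]

    @property
    def n_retained(self) -> int:
        return int(self.frame_mask.sum())

    def retained(self) -> np.ndarray:
        """Data restricted to retained (unscrubbed) frames."""
        return self.data[self.frame_mask]

    def replace_data(self, data: np.ndarray) -> "ParcelTimeSeries":
        """Copy of this scan with ``data`` swapped in."""
        return ParcelTimeSeries(
            data=data,
            tr_seconds=self.tr_seconds,
            parcel_ids=list(self.parcel_ids),
            motion=None if self.motion is None else self.motion.copy(),
            fd=None if self.fd is None else self.fd.copy(),
            noise_signals=(
                None if self.noise_signals is None else self.noise_signals.copy()
            ),
            frame_mask=self.frame_mask.copy(),
        )


@dataclass
class NetworkAtlas:
    """Parcel -> resting-state-network lookup for the analyzed networks.

    ``mapping`` covers analyzed parcels only; parcels carrying labels
    outside :data:`ANALYZED_NETWORKS` (e.g. LIM) live in ``excluded``.
    """

    mapping: Mapping[str, str]
    excluded: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {l for l in self.mapping.values() if l not in ANALYZED_NETWORKS}
        if bad:
            raise ValueError(f"unknown network labels in atlas: {sorted(bad)}")
        for net in ANALYZED_NETWORKS:
            if not any(l == net for l in self.mapping.values()):
                raise ValueError(f"network {net} has no parcels")

    @property
    def networks(self) -> tuple[str, ...]:
        return ANALYZED_NETWORKS

    def parcels_of(self, network: str) -> list[str]:
        if network not in ANALYZED_NETWORKS:
            raise KeyError(f"unknown network label: {network}")
        return [p for p, l in self.mapping.items() if l == network]

    def indices_of(self, network: str, parcel_ids: Sequence[str]) -> np.ndarray:
        """Column indices of ``network``'s parcels within ``parcel_ids``."""
        members = set(self.parcels_of(network))
        return np.array([i for i, p in enumerate(parcel_ids) if p in members])


@dataclass
class ConfoundSet:
    """Nuisance regressors with per-column provenance.

    ``provenance`` names the rule that produced each column (e.g.
    ``motion24`` or ``spike``); ``rank`` is the numerical rank of the
    regressor matrix, reported so downstream code can log degeneracy.
    """

    regressors: np.ndarray
    labels: list[str]
    provenance: list[str]

    def __post_init__(self) -> None:
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        if self.regressors.size == 0:
            self.regressors = self.regressors.reshape(self.regressors.shape[0], 0)
        k = self.regressors.shape[1]
        if len(self.labels) != k or len(self.provenance) != k:
            raise ValueError("labels/provenance must match column count")

    @property
    def n_frames(self) -> int:
        return self.regressors.shape[0]

    @property
    def n_columns(self) -> int:
        return self.regressors.shape[1]

    @property
    def rank(self) -> int:
        if self.n_columns == 0:
            return 0
        return int(np.linalg.matrix_rank(self.regressors))

    @property
    def degenerate_columns(self) -> list[str]:
        """Labels of all-zero columns (flagged, not dropped)."""
        if self.n_columns == 0:
            return []
        zero = ~self.regressors.any(axis=0)
        return [l for l, z in zip(self.labels, zero) if z]

    @staticmethod
    def concatenate(sets: Sequence["ConfoundSet"]) -> "ConfoundSet":
        sets = [s for s in sets if s is not None]
        if not sets:
            raise ValueError("nothing to concatenate")
        frames = {s.n_frames for s in sets}
        if len(frames) > 1:
            raise ValueError("confound sets disagree on frame count")
        return ConfoundSet(
            regressors=np.hstack([s.regressors for s in sets]),
            labels=[l for s in sets for l in s.labels],
            provenance=[p for s in sets for p in s.provenance],
        )


@dataclass
class FCMatrix:
    """Parcel x parcel Fisher-z functional connectivity.

    Pearson correlations are capped at ``|r| <= 1 - cap_epsilon`` before
    the atanh transform so degenerate duplicates stay finite. The
    diagonal is undefined and stored as zero with ``diagonal_excluded``
    set.
    """

    values: np.ndarray
    parcel_ids: Sequence[str]
    cap_epsilon: float = 1e-5
    diagonal_excluded: bool = True
    n_capped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("FC matrix contains non-finite entries")
        if np.max(np.abs(v - v.T)) > 1e-12:
            raise ValueError("FC matrix must be symmetric to 1e-12")
        if len(self.parcel_ids) != v.shape[0]:
            raise ValueError("parcel_ids length must match matrix size")

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]


@dataclass
class SeedMap:
    """Per-parcel Fisher-z correlation with one network's mean series."""

    network_label: str
    values: np.ndarray
    parcel_ids: Sequence[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("seed map contains non-finite values")
        if len(self.values) != len(self.parcel_ids):
            raise ValueError("seed map length must equal parcel count")


@dataclass
class GradientSet:
    """Diffusion-map embedding scores with their eigenvalue spectrum.

    ``scores`` is parcels x k (k = 10 computed by default, the first 3
    analyzed); ``eigenvalues`` are the nontrivial transition-operator
    eigenvalues in descending order; ``variance_explained`` is each
    eigenvalue over the sum of all computed eigenvalues.
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    parcel_ids: Sequence[str]
    alpha: float = 0.5
    aligned_to: str | None = None
    variance_explained: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.scores.shape[1] != len(self.eigenvalues):
            raise ValueError("one eigenvalue per component required")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be in descending order")
        if np.any(self.eigenvalues < -1e-12):
            raise ValueError("eigenvalues must be nonnegative")
        if self.variance_explained is None:
            total = self.eigenvalues.sum()
            if total > 0:
                self.variance_explained = self.eigenvalues / total
            else:
                self.variance_explained = np.zeros_like(self.eigenvalues)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class DispersionSummary:
    """Within/between-network spread in 3-D gradient space.

    within: network -> sum of squared Euclidean distances of the
    network's parcels to the network centroid. between: unordered
    network pair -> Euclidean distance between the two centroids.
    """

    within: dict[str, float]
    between: dict[tuple[str, str], float]
    centroids: dict[str, np.ndarray]

    def between_of(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        key = (a, b) if (a, b) in self.between else (b, a)
        return self.between[key]


@dataclass
class ContrastResult:
    """One contrast applied to one metric."""

    contrast: str
    metric: str
    estimate: float
    statistic: float
    stat_name: str  # "F" or "t"
    df: tuple[float, ...]
    p: float
    q: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError("p must lie in [0, 1]")
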