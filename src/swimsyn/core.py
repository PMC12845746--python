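"""Shared in-memory containers passed between pipeline stages.

All arrays are plain ``numpy.ndarray``; containers are lightweight frozen-ish
dataclasses with validation in ``__post_init__``. Muscle order is significant
everywhere and carried as an explicit tuple of labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, DataError

#: Muscle montage used by default throughout the package (right-side lower
#: limb + trunk montage typical for flutter-kick studies).
DEFAULT_MUSCLES: tuple[str, ...] = (
    "tibialis_anterior",
    "gastrocnemius_medialis",
    "gastrocnemius_lateralis",
    "adductor_longus",
    "adductor_magnus",
    "biceps_femoris",
    "gluteus_maximus",
    "rectus_abdominis",
    "latissimus_dorsi",
    "trapezius",
)

#: Number of points each kick cycle is resampled to.
N_CYCLE_POINTS = 100

#: Names of the three kick-cycle phases, in order.
PHASES: tuple[str, ...] = ("up_swing", "downward", "transition")


@dataclass
class EmgRecording:
    """Raw multichannel sEMG trial with cycle/phase event timestamps.

    Parameters
    ----------
    samples
        ``(n_muscles, n_samples)`` array in microvolts.
    fs
        Sampling rate in Hz. Must exceed twice the 400 Hz band-pass edge.
    muscle_labels
        Channel names, same order as the rows of ``samples``.
    events
        ``(label, time_s)`` pairs; labels are ``cycle_start``, ``phase1_end``,
        ``phase2_end``, ``cycle_end``.
    """

    samples: np.ndarray
    fs: float
    muscle_labels: tuple[str, ...]
    events: list[tuple[str, float]]
    subject_id: str = ""
    group: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.muscle_labels = tuple(self.muscle_labels)
        if self.samples.ndim != 2:
            raise DataError("samples must be a 2-D (muscles x samples) array")
        if self.samples.shape[0] != len(self.muscle_labels):
            raise DataError(
                f"{self.samples.shape[0]} channels but "
                f"{len(self.muscle_labels)} muscle labels"
            )
        if self.fs <= 2 * 400.0:
            raise DataError(
                f"fs={self.fs} Hz too low: the 20-400 Hz band must lie below Nyquist"
            )
        t_max = self.samples.shape[1] / self.fs
        for label, t in self.events:
            if not 0.0 <= t <= t_max:
                raise DataError(f"event {label!r} at {t} s outside [0, {t_max}] s")

    @property
    def n_muscles(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs


@dataclass
class MvcReference:
    """Per-muscle maximum-voluntary-contraction normalisation denominators.

    ``values`` maps muscle label -> peak windowed-RMS amplitude in microvolts;
    all values must be strictly positive.
    """

    values: dict[str, float]

    def __post_init__(self) -> None:
        from .errors import InvalidMvcError

        if not self.values:
            raise InvalidMvcError("empty MVC reference")
        for label, v in self.values.items():
            if not np.isfinite(v) or v <= 0:
                raise InvalidMvcError(f"MVC value for {label!r} must be > 0, got {v}")

    def __getitem__(self, label: str) -> float:
        return self.values[label]


@dataclass
class EnvelopeCycle:
    """MVC-normalised, time-normalised activity for one kick cycle.

    ``activity`` is ``(n_muscles, 100)``, dimensionless (fraction of MVC);
    ``phase_bounds_idx`` are the two interior column indices separating
    up-swing / downward / transition.
    """

    activity: np.ndarray
    muscle_labels: tuple[str, ...]
    phase_bounds_idx: tuple[int, int]
    subject_id: str = ""
    group: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        self.muscle_labels = tuple(self.muscle_labels)
        if self.activity.ndim != 2 or self.activity.shape[1] != N_CYCLE_POINTS:
            raise DataError(
                f"activity must be (n_muscles, {N_CYCLE_POINTS}), "
                f"got {self.activity.shape}"
            )
        if not np.all(np.isfinite(self.activity)):
            raise DataError("activity contains non-finite values")
        if np.any(self.activity < 0):
            raise DataError("activity contains negative values")
        b1, b2 = self.phase_bounds_idx
        if not 0 < b1 < b2 < N_CYCLE_POINTS:
            raise DataError(f"phase bounds {self.phase_bounds_idx} not in (0, 100)")

    @property
    def n_muscles(self) -> int:
        return self.activity.shape[0]


@dataclass
class SynergySet:
    """NMF factorisation of one envelope cycle.

    ``weights`` is ``(n_muscles, k)`` with unit-Euclidean-norm columns,
    ``activations`` is ``(k, 100)``; ``vaf`` is the uncentred variance
    accounted for by ``weights @ activations``.
    """

    weights: np.ndarray
    activations: np.ndarray
    vaf: float
    k: int
    muscle_labels: tuple[str, ...]
    restarts_used: int = 0
    converged_selection: bool = True
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    subject_id: str = ""
    group: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.activations = np.asarray(self.activations, dtype=float)
        self.muscle_labels = tuple(self.muscle_labels)
        if self.weights.shape[1] != self.k or self.activations.shape[0] != self.k:
            raise DataError("weights/activations inconsistent with order k")
        if np.any(self.weights < 0) or np.any(self.activations < 0):
            raise DataError("synergy factors must be nonnegative")
        norms = np.linalg.norm(self.weights, axis=0)
        if not np.allclose(norms[norms > 0], 1.0, atol=1e-9):
            raise DataError("weight columns must have unit Euclidean norm")

    def reconstruction(self) -> np.ndarray:
        return self.weights @ self.activations


@dataclass
class ReferenceSynergies:
    """Cluster centroids of the reference condition's weight vectors."""

    centroids: np.ndarray  # (n_clusters, n_muscles), unit-norm rows
    muscle_labels: tuple[str, ...]
    n_clusters: int
    gap_curve: "object" = None  # pandas DataFrame: k, log_wk, gap, sd
    source: str = ""

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.muscle_labels = tuple(self.muscle_labels)
        if np.any(self.centroids < 0):
            raise DataError("centroids must be nonnegative")
        if self.centroids.shape[0] != self.n_clusters or self.n_clusters < 1:
            raise DataError("centroid count inconsistent with n_clusters")

    def check_alignment(self, labels: tuple[str, ...]) -> None:
        if tuple(labels) != self.muscle_labels:
            raise AlignmentError(
                "muscle ordering differs between synergy set and reference"
            )
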