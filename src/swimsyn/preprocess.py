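"""Raw sEMG -> MVC-normalised, time-normalised envelope cycles.

The chain per channel: zero-phase 4th-order Butterworth band-pass (20-400 Hz),
full-wave rectification, zero-phase 4th-order Butterworth low-pass (20 Hz)
linear envelope (clipped at zero), division by the muscle's MVC reference,
and linear-interpolation resampling of the selected kick cycle to 100 points.

The MVC reference for a muscle is the maximum, over calibration trials, of
the maximal 1 s sliding-window RMS of the band-passed signal ("stable 1 s
window" operationalised as the window maximising RMS, which is deterministic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .config import PreprocessParams
from .core import N_CYCLE_POINTS, EmgRecording, EnvelopeCycle, MvcReference
from .errors import (
    DegenerateSegmentError,
    EventStreamError,
    InvalidBandError,
    InvalidMvcError,
)


def bandpass_filter(
    x: np.ndarray,
    fs: float,
    low: float = 20.0,
    high: float = 400.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass; ``order`` is the design order."""
    if not 0 < low < high < fs / 2:
        raise InvalidBandError(
            f"need 0 < low < high < fs/2, got low={low}, high={high}, fs={fs}"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def linear_envelope(
    x: np.ndarray, fs: float, cutoff: float = 20.0, order: int = 4
) -> np.ndarray:
    """Full-wave rectify then zero-phase low-pass; clipped at zero.

    Zero-phase filtering can ring slightly negative near sharp onsets; the
    clip keeps envelopes valid NMF input.
    """
    if not 0 < cutoff < fs / 2:
        raise InvalidBandError(f"cutoff {cutoff} Hz must lie in (0, fs/2)")
    sos = sps.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    return np.clip(sps.sosfiltfilt(sos, np.abs(np.asarray(x, dtype=float))), 0.0, None)


def _max_window_rms(x: np.ndarray, n_window: int) -> float:
    """Maximum RMS over all length-``n_window`` sliding windows."""
    sq = np.asarray(x, dtype=float) ** 2
    c = np.concatenate(([0.0], np.cumsum(sq)))
    sums = c[n_window:] - c[:-n_window]
    return float(np.sqrt(sums.max() / n_window))


def mvc_reference(
    mvc_trials: dict[str, list[np.ndarray]],
    fs: float,
    window_s: float = 1.0,
    *,
    bandpass: bool = True,
    params: PreprocessParams | None = None,
) -> MvcReference:
    """Per-muscle normalisation denominator from MVC calibration trials.

    For each muscle: band-pass each trial (unless ``bandpass=False``, for
    already-preprocessed inputs), take the maximal sliding-window RMS, and
    keep the best trial. A trial exactly ``window_s`` long contributes its
    whole-trial RMS.
    """
    params = params or PreprocessParams()
    n_window = int(round(fs * window_s))
    values: dict[str, float] = {}
    for label, trials in mvc_trials.items():
        if not trials:
            raise InvalidMvcError(f"no MVC trials for muscle {label!r}")
        best = 0.0
        for trial in trials:
            trial = np.asarray(trial, dtype=float)
            if trial.size < n_window:
                raise InvalidMvcError(
                    f"MVC trial for {label!r} shorter than the {window_s} s window"
                )
            if bandpass:
                trial = bandpass_filter(
                    trial, fs, params.band_low_hz, params.band_high_hz, params.band_order
                )
            best = max(best, _max_window_rms(trial, n_window))
        if best <= 0:
            raise InvalidMvcError(f"all-zero MVC trials for muscle {label!r}")
        values[label] = best
    return MvcReference(values)


@dataclass(frozen=True)
class CycleSegment:
    """Half-open sample range of one kick cycle with interior phase bounds."""

    start: int
    end: int
    phase_bounds: tuple[int, int]  # absolute sample indices within the recording

    @property
    def n_samples(self) -> int:
        return self.end - self.start


def segment_cycles(recording: EmgRecording) -> list[CycleSegment]:
    """Cycles between consecutive ``cycle_start`` events, with phase marks.

    Sample ranges are half-open and 0-based; phase marks (``phase1_end``,
    ``phase2_end``) must fall strictly inside their cycle, in order.
    """
    fs = recording.fs
    starts = sorted(t for label, t in recording.events if label == "cycle_start")
    if len(starts) < 2:
        raise EventStreamError("need >= 2 cycle_start events for a complete cycle")
    phase1 = sorted(t for label, t in recording.events if label == "phase1_end")
    phase2 = sorted(t for label, t in recording.events if label == "phase2_end")
    segments = []
    for t0, t1 in zip(starts[:-1], starts[1:]):
        if t1 <= t0:
            raise EventStreamError("cycle_start events not strictly increasing")
        p1 = [t for t in phase1 if t0 < t < t1]
        p2 = [t for t in phase2 if t0 < t < t1]
        if len(p1) != 1 or len(p2) != 1 or p2[0] <= p1[0]:
            raise EventStreamError(
                f"cycle [{t0}, {t1}) s needs ordered interior phase1_end/phase2_end"
            )
        start, end = int(round(t0 * fs)), int(round(t1 * fs))
        b1, b2 = int(round(p1[0] * fs)), int(round(p2[0] * fs))
        if not start < b1 < b2 < end:
            raise EventStreamError("phase boundaries collapse onto cycle bounds")
        segments.append(CycleSegment(start, end, (b1, b2)))
    return segments


def representative_cycle(segments: list[CycleSegment]) -> CycleSegment:
    """The median-duration cycle (lower median; ties broken by earlier start)."""
    if not segments:
        raise EventStreamError("no cycles to choose from")
    ordered = sorted(segments, key=lambda s: (s.n_samples, s.start))
    return ordered[(len(ordered) - 1) // 2]


def normalize_cycle(
    envelopes: np.ndarray,
    mvc: MvcReference,
    muscle_labels: tuple[str, ...],
    phase_samples: tuple[int, int],
    *,
    subject_id: str = "",
    group: str = "",
    timepoint: str = "",
) -> EnvelopeCycle:
    """Divide by MVC per muscle and resample each row to 100 points.

    ``phase_samples`` are 0-based sample offsets within the cycle; they are
    rescaled proportionally (fraction of cycle elapsed, rounded to the
    nearest of the 100 indices, kept interior).
    """
    envelopes = np.asarray(envelopes, dtype=float)
    n = envelopes.shape[1]
    if n < 2:
        raise DegenerateSegmentError("cycle must contain >= 2 samples")
    for label in muscle_labels:
        if label not in mvc.values:
            raise KeyError(f"muscle {label!r} missing from MVC reference")
    denom = np.array([mvc[label] for label in muscle_labels])
    scaled = envelopes / denom[:, None]
    grid = np.linspace(0.0, n - 1, N_CYCLE_POINTS)
    resampled = np.stack([np.interp(grid, np.arange(n), row) for row in scaled])
    idx = tuple(
        int(np.clip(round(p / n * N_CYCLE_POINTS), 1, N_CYCLE_POINTS - 1))
        for p in phase_samples
    )
    return EnvelopeCycle(
        activity=np.clip(resampled, 0.0, None),
        muscle_labels=tuple(muscle_labels),
        phase_bounds_idx=idx,
        subject_id=subject_id,
        group=group,
        timepoint=timepoint,
    )


def preprocess_recording(
    recording: EmgRecording,
    mvc: MvcReference,
    params: PreprocessParams | None = None,
) -> EnvelopeCycle:
    """Full chain for one recording -> one representative envelope cycle."""
    params = params or PreprocessParams()
    fs = recording.fs
    filtered = np.stack(
        [
            bandpass_filter(
                ch, fs, params.band_low_hz, params.band_high_hz, params.band_order
            )
            for ch in recording.samples
        ]
    )
    envelopes = np.stack(
        [
            linear_envelope(ch, fs, params.envelope_cutoff_hz, params.envelope_order)
            for ch in filtered
        ]
    )
    seg = representative_cycle(segment_cycles(recording))
    cyc = envelopes[:, seg.start : seg.end]
    phase_rel = (seg.phase_bounds[0] - seg.start, seg.phase_bounds[1] - seg.start)
    return normalize_cycle(
        cyc,
        mvc,
        recording.muscle_labels,
        phase_rel,
        subject_id=recording.subject_id,
        group=recording.group,
        timepoint=recording.timepoint,
    )
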