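"""Phase-wise iEMG and RMS per muscle.

Computed on the rectified band-passed signal at the original sampling rate,
in microvolt units (not MVC-normalised): iEMG in uV*s, RMS in uV. Phase
windows partition the representative kick cycle into up-swing / downward /
transition half-open sample ranges, so per-phase iEMG sums exactly to the
whole-cycle iEMG.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PreprocessParams
from .core import PHASES, EmgRecording
from .errors import DataError, DegenerateSegmentError
from .preprocess import CycleSegment, bandpass_filter


def iemg(rectified: np.ndarray, fs: float, *, include_dt: bool = True) -> float:
    """Integrated EMG of a rectified series.

    With ``include_dt`` (default) the discrete sum is scaled by 1/fs so the
    result is in uV*s; ``include_dt=False`` gives the bare sample sum.
    """
    x = np.asarray(rectified, dtype=float)
    if x.size == 0:
        raise DataError("iemg of empty series")
    if np.any(x < 0):
        raise DataError("iemg input must be rectified (nonnegative)")
    total = float(x.sum())
    return total / fs if include_dt else total


def rms(x: np.ndarray) -> float:
    """Root-mean-square amplitude, sqrt(mean(x^2))."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise DataError("rms of empty series")
    return float(np.sqrt(np.mean(x**2)))


def phase_metrics(
    recording: EmgRecording,
    segment: CycleSegment,
    params: PreprocessParams | None = None,
    *,
    include_dt: bool = True,
) -> pd.DataFrame:
    """Tidy table: one row per phase x muscle with iEMG and RMS.

    The signal is band-passed and full-wave rectified; each phase is the
    half-open sample range between consecutive boundaries of the cycle.
    """
    params = params or PreprocessParams()
    b1, b2 = segment.phase_bounds
    bounds = [segment.start, b1, b2, segment.end]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi <= lo:
            raise DegenerateSegmentError(f"empty phase segment [{lo}, {hi})")
    rows = []
    for m, label in enumerate(recording.muscle_labels):
        rect = np.abs(
            bandpass_filter(
                recording.samples[m],
                recording.fs,
                params.band_low_hz,
                params.band_high_hz,
                params.band_order,
            )
        )
        for phase, lo, hi in zip(PHASES, bounds[:-1], bounds[1:]):
            seg = rect[lo:hi]
            rows.append(
                {
                    "subject_id": recording.subject_id,
                    "group": recording.group,
                    "timepoint": recording.timepoint,
                    "phase": phase,
                    "muscle": label,
                    "iemg": iemg(seg, recording.fs, include_dt=include_dt),
                    "rms": rms(seg),
                }
            )
    return pd.DataFrame(rows)
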