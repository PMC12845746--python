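"""Activation-timing metrics of a synergy's coefficient profile.

Each 100-point activation profile is reduced to three fractions of the
normalised kick cycle: activation duration T (fraction of points at or above
a relative threshold, default 20% of the profile's max), peak moment Tmax
(argmax, earliest on ties), and onset Tstart (start of the longest contiguous
supra-threshold burst, treating the cycle as circular — kick bursts commonly
span the cycle wrap). Times map index i to i/99; durations count points/100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import N_CYCLE_POINTS
from .errors import DegenerateActivationError, InvalidParameterError


@dataclass(frozen=True)
class ActivationTiming:
    duration: float      # fraction of cycle in [0, 1]
    peak_time: float     # fraction in [0, 1]
    onset_time: float    # fraction in [0, 1]
    synergy_ref: int = -1
    subject_id: str = ""
    group: str = ""
    timepoint: str = ""


def _longest_circular_run(mask: np.ndarray) -> tuple[int, int]:
    """(start, length) of the longest True run on a circular mask.

    Ties break to the earliest start in [0, n); an all-True mask is the whole
    circle starting at 0.
    """
    n = mask.size
    if mask.all():
        return 0, n
    doubled = np.concatenate([mask, mask])
    best_start, best_len = 0, 0
    run_start, run_len = None, 0
    for i, v in enumerate(doubled):
        if v:
            if run_start is None:
                run_start = i
                run_len = 0
            run_len += 1
        else:
            if run_start is not None and run_start < n and run_len > best_len:
                best_start, best_len = run_start, min(run_len, n)
            run_start, run_len = None, 0
    if run_start is not None and run_start < n and run_len > best_len:
        best_start, best_len = run_start, min(run_len, n)
    return best_start, best_len


def timing(
    activation: np.ndarray,
    threshold_frac: float = 0.20,
    **provenance,
) -> ActivationTiming:
    """Timing metrics for one activation profile (scale-invariant)."""
    c = np.asarray(activation, dtype=float)
    if c.size != N_CYCLE_POINTS:
        raise InvalidParameterError(
            f"activation must have {N_CYCLE_POINTS} points, got {c.size}"
        )
    if np.any(c < 0):
        raise InvalidParameterError("activation must be nonnegative")
    if not 0 < threshold_frac <= 1:
        raise InvalidParameterError("threshold_frac must lie in (0, 1]")
    cmax = c.max()
    if cmax <= 0:
        raise DegenerateActivationError("identically-zero activation")
    mask = c >= threshold_frac * cmax
    start, length = _longest_circular_run(mask)
    return ActivationTiming(
        duration=float(mask.sum()) / N_CYCLE_POINTS,
        peak_time=float(int(np.argmax(c))) / (N_CYCLE_POINTS - 1),
        onset_time=float(start) / (N_CYCLE_POINTS - 1),
        **provenance,
    )
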