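"""Synthetic sEMG study generator.

Emulates the statistical structure of a two-group (EXP/CON), pre/post
flutter-kick sEMG study: each subject's kick-cycle envelopes are built from a
known set of muscle synergies (nonnegative weight vectors sharing burst-like
activation profiles), amplitude-modulated onto band-limited carrier noise to
produce raw 2000 Hz signals, together with per-muscle MVC calibration trials.
Ground truth (weights, burst parameters, applied intervention effects) is
retained so every downstream stage can be validated by parameter recovery.

Intervention effects are multiplicative and applied to the experimental
group's post-intervention arm only: selected muscle weights of one synergy
are scaled up (then the column is re-normalised) and the burst width of
another synergy is scaled down.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SynthParams
from .core import DEFAULT_MUSCLES, N_CYCLE_POINTS, EmgRecording, EnvelopeCycle
from .errors import DataError, InvalidDesignError, InvalidParameterError
from .preprocess import bandpass_filter

GROUPS = ("EXP", "CON")
TIMEPOINTS = ("pre", "post")


def _rng(seed: int, *tags: int) -> np.random.Generator:
    """Deterministic child generator keyed by integer tags."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, tags)]))


# --------------------------------------------------------------------------
# ground truth


@dataclass
class EffectSpec:
    """Multiplicative intervention effects, applied to one group x timepoint.

    ``weight_multipliers[syn][muscle] = factor`` scales that muscle's weight in
    synergy ``syn`` (column re-normalised afterwards); ``width_multipliers[syn]``
    scales that synergy's burst width.
    """

    weight_multipliers: dict[int, dict[int, float]] = field(default_factory=dict)
    width_multipliers: dict[int, float] = field(default_factory=dict)
    group: str = "EXP"
    timepoint: str = "post"

    def is_null(self) -> bool:
        return not self.weight_multipliers and not self.width_multipliers


@dataclass
class GroundTruth:
    """Known synergy structure generating one condition's envelopes."""

    weights_true: np.ndarray       # (n_muscles, n_syn), unit-norm columns
    burst_centers: np.ndarray      # (n_syn,), cycle fraction in [0, 1)
    burst_widths: np.ndarray       # (n_syn,), Gaussian SD in cycle fraction
    phase_bounds: tuple[float, float]
    dominant: tuple[tuple[int, ...], ...]
    noise_sd: float
    seed: int
    effect_spec: EffectSpec = field(default_factory=EffectSpec)

    def __post_init__(self) -> None:
        self.weights_true = np.asarray(self.weights_true, dtype=float)
        self.burst_centers = np.asarray(self.burst_centers, dtype=float)
        self.burst_widths = np.asarray(self.burst_widths, dtype=float)
        if np.any(self.weights_true < 0):
            raise DataError("ground-truth weights must be nonnegative")
        norms = np.linalg.norm(self.weights_true, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise DataError("ground-truth weight columns must be unit norm")
        b1, b2 = self.phase_bounds
        if not 0.0 < b1 < b2 < 1.0:
            raise DataError(f"phase_bounds {self.phase_bounds} must increase in (0,1)")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be nonnegative")

    @property
    def n_muscles(self) -> int:
        return self.weights_true.shape[0]

    @property
    def n_syn(self) -> int:
        return self.weights_true.shape[1]

    @property
    def activations_true(self) -> np.ndarray:
        return bump_activations(self.burst_centers, self.burst_widths)

    @property
    def phase_bounds_idx(self) -> tuple[int, int]:
        b1, b2 = self.phase_bounds
        return (int(round(b1 * N_CYCLE_POINTS)), int(round(b2 * N_CYCLE_POINTS)))


def bump_activations(centers: np.ndarray, widths: np.ndarray) -> np.ndarray:
    """Circular Gaussian burst profiles on the 100-point normalised cycle.

    The cycle is periodic (the kick wraps), so distance to the burst centre is
    taken modulo 1; each row peaks at 1.0 at its centre.
    """
    t = np.arange(N_CYCLE_POINTS) / N_CYCLE_POINTS
    d = np.abs(t[None, :] - np.asarray(centers, dtype=float)[:, None])
    d = np.minimum(d, 1.0 - d)
    return np.exp(-0.5 * (d / np.asarray(widths, dtype=float)[:, None]) ** 2)


# canonical burst placement for the 3-synergy kick model: plantar-flexor
# synergy peaks mid/late up-swing, postural synergy peaks late downward,
# propulsion synergy peaks early up-swing.
_CANONICAL_CENTERS_3 = (0.65, 0.90, 0.12)


def make_ground_truth(
    n_muscles: int,
    n_syn: int,
    seed: int,
    *,
    phase_bounds: tuple[float, float] = (0.40, 0.80),
    noise_sd: float = 0.02,
) -> GroundTruth:
    """Draw a synergy ground truth: sparse dominant weights + distinct bursts.

    Each synergy gets 2-4 dominant muscles (weight drawn in [0.5, 0.9) before
    normalisation) chosen by a disjoint partition of a random muscle
    permutation; the remaining weights are small ([0.05, 0.2), physiological
    crosstalk level). Burst centres are distinct; widths are drawn in
    [0.05, 0.09) cycle fractions — distinct bursts, so the generating order
    is identifiable from the envelopes.
    """
    if n_syn < 1 or n_syn > n_muscles:
        raise InvalidDesignError(
            f"need 1 <= n_syn <= n_muscles, got n_syn={n_syn}, n_muscles={n_muscles}"
        )
    rng = _rng(seed, 0)
    perm = rng.permutation(n_muscles)
    chunks = np.array_split(perm, n_syn)
    dominant = tuple(tuple(int(m) for m in chunk[:4]) for chunk in chunks)

    W = rng.uniform(0.05, 0.20, size=(n_muscles, n_syn))
    for j, doms in enumerate(dominant):
        W[list(doms), j] = rng.uniform(0.5, 0.9, size=len(doms))
    W /= np.linalg.norm(W, axis=0, keepdims=True)

    if n_syn == 3:
        base = np.asarray(_CANONICAL_CENTERS_3)
    else:
        base = (np.arange(n_syn) + 0.5) / n_syn
    centers = (base + rng.uniform(-0.03, 0.03, size=n_syn)) % 1.0
    widths = rng.uniform(0.05, 0.09, size=n_syn)
    return GroundTruth(
        weights_true=W,
        burst_centers=centers,
        burst_widths=widths,
        phase_bounds=phase_bounds,
        dominant=dominant,
        noise_sd=noise_sd,
        seed=seed,
    )


def default_effect_spec(truth: GroundTruth, params: SynthParams) -> EffectSpec:
    """Build the study's default intervention effects from the ground truth.

    Scales the weights of the propulsion-like synergy's two prime movers
    (its two highest-weighted muscles) and shrinks the burst width of the
    postural-like synergy, mirroring the adaptations the analysis is
    designed to detect.
    """
    if not params.effects_enabled:
        return EffectSpec()
    wsyn = params.effect_weight_synergy % truth.n_syn
    dsyn = params.effect_width_synergy % truth.n_syn
    doms = list(truth.dominant[wsyn])
    doms.sort(key=lambda m: -truth.weights_true[m, wsyn])
    targets = tuple(doms[:2])
    return EffectSpec(
        weight_multipliers={wsyn: {int(m): params.weight_effect_multiplier for m in targets}},
        width_multipliers={dsyn: params.width_effect_multiplier},
    )


def apply_effects(truth: GroundTruth, spec: EffectSpec) -> GroundTruth:
    """Return a copy of ``truth`` with multiplicative effects applied."""
    W = truth.weights_true.copy()
    for syn, muls in spec.weight_multipliers.items():
        for m, f in muls.items():
            W[m, syn] *= f
        W[:, syn] /= np.linalg.norm(W[:, syn])
    widths = truth.burst_widths.copy()
    for syn, f in spec.width_multipliers.items():
        widths[syn] *= f
    return dataclasses.replace(truth, weights_true=W, burst_widths=widths)


def perturb_truth(
    truth: GroundTruth,
    rng: np.random.Generator,
    weight_sigma: float,
    center_sd: float,
    width_sigma: float,
) -> GroundTruth:
    """Individual-variability copy: additive Gaussian weight jitter (clipped
    at zero, columns re-normalised), Gaussian burst-centre shift, lognormal
    width jitter."""
    W = np.clip(
        truth.weights_true
        + rng.normal(0.0, weight_sigma, size=truth.weights_true.shape),
        0.0,
        None,
    )
    W /= np.linalg.norm(W, axis=0, keepdims=True)
    centers = (truth.burst_centers + rng.normal(0.0, center_sd, truth.n_syn)) % 1.0
    widths = truth.burst_widths * np.exp(rng.normal(0.0, width_sigma, truth.n_syn))
    return dataclasses.replace(
        truth, weights_true=W, burst_centers=centers, burst_widths=widths
    )


# --------------------------------------------------------------------------
# signal synthesis


def synthesize_envelope_cycle(
    truth: GroundTruth,
    subject_scale: float,
    noise_sd: float,
    seed: int,
    *,
    muscle_labels: tuple[str, ...] | None = None,
    subject_id: str = "",
    group: str = "",
    timepoint: str = "",
) -> EnvelopeCycle:
    """Noisy MVC-normalised envelope cycle: max(0, scale * W @ C + eps)."""
    if subject_scale <= 0:
        raise InvalidParameterError("subject_scale must be positive")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be nonnegative")
    clean = subject_scale * truth.weights_true @ truth.activations_true
    if noise_sd > 0:
        rng = _rng(seed, 1)
        clean = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    activity = np.clip(clean, 0.0, None)
    if muscle_labels is None:
        muscle_labels = tuple(f"m{i:02d}" for i in range(truth.n_muscles))
    return EnvelopeCycle(
        activity=activity,
        muscle_labels=muscle_labels,
        phase_bounds_idx=truth.phase_bounds_idx,
        subject_id=subject_id,
        group=group,
        timepoint=timepoint,
    )


def _band_limited_carrier(
    rng: np.random.Generator, n_channels: int, n_samples: int, fs: float
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed 20-400 Hz, per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    carrier = np.stack([bandpass_filter(ch, fs) for ch in white])
    rms = np.sqrt(np.mean(carrier**2, axis=1, keepdims=True))
    return carrier / np.where(rms > 0, rms, 1.0)


def synthesize_raw_trial(
    envelope: EnvelopeCycle,
    fs: float,
    cycle_duration: float,
    seed: int,
    *,
    gain_uv: np.ndarray | float = 1.0,
    n_cycles: int = 2,
    pad_s: float = 0.25,
) -> EmgRecording:
    """Raw sEMG trial: stretched envelope amplitude-modulating carrier noise.

    The 100-point envelope is linearly time-stretched to ``cycle_duration``,
    tiled ``n_cycles`` times and padded with silence; each muscle's signal is
    ``gain_uv * envelope * carrier`` with a unit-RMS 20-400 Hz carrier, so the
    local RMS in microvolts tracks ``gain_uv * envelope``. Event timestamps
    (cycle_start per cycle, phase1_end/phase2_end per cycle, final cycle_end)
    are emitted on the same clock.
    """
    if cycle_duration <= 0:
        raise InvalidParameterError("cycle_duration must be positive")
    if fs < 1000.0:
        raise InvalidParameterError("fs must be >= 1000 Hz")
    if n_cycles < 2:
        raise InvalidParameterError("need >= 2 cycle repeats for a complete cycle")
    n_m = envelope.n_muscles
    n_cyc = int(round(fs * cycle_duration))
    n_pad = int(round(fs * pad_s))
    grid = np.linspace(0.0, N_CYCLE_POINTS - 1, n_cyc)
    stretched = np.stack(
        [np.interp(grid, np.arange(N_CYCLE_POINTS), row) for row in envelope.activity]
    )
    env = np.concatenate(
        [np.zeros((n_m, n_pad)), np.tile(stretched, (1, n_cycles)), np.zeros((n_m, n_pad))],
        axis=1,
    )
    rng = _rng(seed, 2)
    carrier = _band_limited_carrier(rng, n_m, env.shape[1], fs)
    gains = np.broadcast_to(np.atleast_1d(np.asarray(gain_uv, dtype=float)), (n_m,))
    samples = gains[:, None] * env * carrier

    t0 = n_pad / fs
    b1, b2 = envelope.phase_bounds_idx
    events: list[tuple[str, float]] = []
    for c in range(n_cycles):
        start = t0 + c * cycle_duration
        events.append(("cycle_start", start))
        events.append(("phase1_end", start + (b1 / N_CYCLE_POINTS) * cycle_duration))
        events.append(("phase2_end", start + (b2 / N_CYCLE_POINTS) * cycle_duration))
    events.append(("cycle_end", t0 + n_cycles * cycle_duration))
    return EmgRecording(
        samples=samples,
        fs=fs,
        muscle_labels=envelope.muscle_labels,
        events=events,
        subject_id=envelope.subject_id,
        group=envelope.group,
        timepoint=envelope.timepoint,
    )


def make_mvc_trials(
    gain_uv: np.ndarray,
    fs: float,
    seed: int,
    *,
    n_trials: int = 3,
    trial_s: float = 2.0,
    efforts: tuple[float, ...] = (0.9, 1.0, 0.95),
) -> list[np.ndarray]:
    """Per-muscle MVC calibration trials: constant-envelope modulated carrier.

    Returns ``n_trials`` arrays of shape ``(n_muscles, n_samples)``; trial
    ``i`` is produced at relative effort ``efforts[i % len(efforts)]`` so the
    max-over-trials windowed-RMS rule recovers approximately ``gain_uv``.
    """
    gain_uv = np.asarray(gain_uv, dtype=float)
    n_samples = int(round(fs * trial_s))
    trials = []
    for i in range(n_trials):
        rng = _rng(seed, 3, i)
        carrier = _band_limited_carrier(rng, gain_uv.size, n_samples, fs)
        effort = efforts[i % len(efforts)]
        trials.append(effort * gain_uv[:, None] * carrier)
    return trials


# --------------------------------------------------------------------------
# full study


@dataclass
class SynthDataset:
    """Complete simulated study: recordings, MVC trials and ground truth."""

    recordings: list[EmgRecording]
    mvc_trials: dict[tuple[str, str], dict[str, list[np.ndarray]]]
    truth: GroundTruth
    effect_spec: EffectSpec
    params: SynthParams
    seed: int
    # per-condition ground truths and scales, for recovery checks
    condition_truths: dict[tuple[str, str], GroundTruth]
    subject_scales: dict[str, float]
    subject_groups: dict[str, str]
    muscle_labels: tuple[str, ...]


def make_study(params: SynthParams, seed: int) -> SynthDataset:
    """Generate the full two-group pre/post dataset under ``params``.

    One recording per subject x timepoint; the experimental group's post
    arm receives the intervention effects (if enabled). All randomness is
    derived deterministically from ``seed``.
    """
    n_m = params.n_muscles
    labels = DEFAULT_MUSCLES if n_m == len(DEFAULT_MUSCLES) else tuple(
        f"m{i:02d}" for i in range(n_m)
    )
    truth = make_ground_truth(
        n_m,
        params.n_synergies,
        seed,
        phase_bounds=params.phase_bounds,
        noise_sd=params.noise_sd,
    )
    effect = default_effect_spec(truth, params)
    truth = dataclasses.replace(truth, effect_spec=effect)

    recordings: list[EmgRecording] = []
    mvc_trials: dict[tuple[str, str], dict[str, list[np.ndarray]]] = {}
    condition_truths: dict[tuple[str, str], GroundTruth] = {}
    subject_scales: dict[str, float] = {}
    subject_groups: dict[str, str] = {}

    for gi, group in enumerate(GROUPS):
        for si in range(params.n_per_group):
            subject_id = f"{group}{si + 1:02d}"
            srng = _rng(seed, 10, gi, si)
            scale = srng.uniform(*params.subject_scale_range)
            gains = srng.uniform(*params.mvc_gain_range_uv, size=n_m)
            subj_truth = perturb_truth(
                truth,
                srng,
                params.subject_weight_jitter,
                params.burst_center_jitter,
                params.burst_width_jitter,
            )
            subject_scales[subject_id] = float(scale)
            subject_groups[subject_id] = group
            for ti, timepoint in enumerate(TIMEPOINTS):
                trng = _rng(seed, 11, gi, si, ti)
                tp_truth = perturb_truth(
                    subj_truth,
                    trng,
                    params.timepoint_weight_jitter,
                    0.75 * params.burst_center_jitter,
                    0.75 * params.burst_width_jitter,
                )
                if group == effect.group and timepoint == effect.timepoint:
                    tp_truth = apply_effects(tp_truth, effect)
                condition_truths[(subject_id, timepoint)] = tp_truth
                env_seed = int(
                    np.random.SeedSequence([seed, 12, gi, si, ti]).generate_state(1)[0]
                    % (2**31)
                )
                envelope = synthesize_envelope_cycle(
                    tp_truth,
                    scale,
                    params.noise_sd,
                    env_seed,
                    muscle_labels=labels,
                    subject_id=subject_id,
                    group=group,
                    timepoint=timepoint,
                )
                recordings.append(
                    synthesize_raw_trial(
                        envelope,
                        params.fs_hz,
                        params.cycle_duration_s,
                        env_seed + 1,
                        gain_uv=gains,
                        n_cycles=params.n_cycles,
                        pad_s=params.pad_s,
                    )
                )
                trial_arrays = make_mvc_trials(
                    gains,
                    params.fs_hz,
                    env_seed + 2,
                    n_trials=params.mvc_n_trials,
                    trial_s=params.mvc_trial_s,
                )
                mvc_trials[(subject_id, timepoint)] = {
                    label: [tr[m] for tr in trial_arrays]
                    for m, label in enumerate(labels)
                }
    return SynthDataset(
        recordings=recordings,
        mvc_trials=mvc_trials,
        truth=truth,
        effect_spec=effect,
        params=params,
        seed=seed,
        condition_truths=condition_truths,
        subject_scales=subject_scales,
        subject_groups=subject_groups,
        muscle_labels=labels,
    )


# --------------------------------------------------------------------------
# serialization (long-format CSV schemas; also the interface for real data)


def write_study(ds: SynthDataset, outdir: str | Path) -> None:
    """Write emg.csv, events.csv, mvc.csv, truth.json and study.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    emg_frames = []
    event_rows = []
    for rec in ds.recordings:
        n = rec.samples.shape[1]
        for m, label in enumerate(rec.muscle_labels):
            emg_frames.append(
                pd.DataFrame(
                    {
                        "subject_id": rec.subject_id,
                        "group": rec.group,
                        "timepoint": rec.timepoint,
                        "muscle": label,
                        "sample_index": np.arange(n),
                        "value_uv": rec.samples[m],
                    }
                )
            )
        for label, t in rec.events:
            event_rows.append(
                {
                    "subject_id": rec.subject_id,
                    "timepoint": rec.timepoint,
                    "event": label,
                    "time_s": t,
                }
            )
    pd.concat(emg_frames, ignore_index=True).to_csv(
        outdir / "emg.csv", index=False, float_format="%.4f"
    )
    pd.DataFrame(event_rows).to_csv(
        outdir / "events.csv", index=False, float_format="%.6f"
    )

    mvc_frames = []
    for (subject_id, timepoint), per_muscle in ds.mvc_trials.items():
        for label, trials in per_muscle.items():
            for trial_idx, arr in enumerate(trials):
                mvc_frames.append(
                    pd.DataFrame(
                        {
                            "subject_id": subject_id,
                            "timepoint": timepoint,
                            "muscle": label,
                            "trial": trial_idx,
                            "sample_index": np.arange(arr.size),
                            "value_uv": arr,
                        }
                    )
                )
    pd.concat(mvc_frames, ignore_index=True).to_csv(
        outdir / "mvc.csv", index=False, float_format="%.4f"
    )

    truth = ds.truth
    truth_json = {
        "weights_true": truth.weights_true.tolist(),
        "burst_centers": truth.burst_centers.tolist(),
        "burst_widths": truth.burst_widths.tolist(),
        "phase_bounds": list(truth.phase_bounds),
        "dominant": [list(d) for d in truth.dominant],
        "noise_sd": truth.noise_sd,
        "seed": truth.seed,
        "effect_spec": {
            "weight_multipliers": {
                str(k): {str(m): f for m, f in v.items()}
                for k, v in ds.effect_spec.weight_multipliers.items()
            },
            "width_multipliers": {
                str(k): v for k, v in ds.effect_spec.width_multipliers.items()
            },
            "group": ds.effect_spec.group,
            "timepoint": ds.effect_spec.timepoint,
        },
    }
    (outdir / "truth.json").write_text(json.dumps(truth_json, indent=2, sort_keys=True))
    study_json = {
        "fs_hz": ds.params.fs_hz,
        "muscle_labels": list(ds.muscle_labels),
        "groups": {s: g for s, g in sorted(ds.subject_groups.items())},
        "seed": ds.seed,
        "n_per_group": ds.params.n_per_group,
    }
    (outdir / "study.json").write_text(json.dumps(study_json, indent=2, sort_keys=True))


def read_study(indir: str | Path) -> tuple[
    list[EmgRecording], dict[tuple[str, str], dict[str, list[np.ndarray]]], dict
]:
    """Read recordings + MVC trials back from the long-format CSV schema."""
    indir = Path(indir)
    meta = json.loads((indir / "study.json").read_text())
    fs = float(meta["fs_hz"])
    labels = tuple(meta["muscle_labels"])

    emg = pd.read_csv(indir / "emg.csv")
    events = pd.read_csv(indir / "events.csv")
    recordings = []
    for (subject_id, timepoint), grp in emg.groupby(
        ["subject_id", "timepoint"], sort=True
    ):
        wide = grp.pivot(index="sample_index", columns="muscle", values="value_uv")
        samples = wide[list(labels)].to_numpy().T
        ev = events[
            (events.subject_id == subject_id) & (events.timepoint == timepoint)
        ]
        ev_list = [(r.event, float(r.time_s)) for r in ev.itertuples()]
        recordings.append(
            EmgRecording(
                samples=samples,
                fs=fs,
                muscle_labels=labels,
                events=ev_list,
                subject_id=str(subject_id),
                group=meta["groups"][str(subject_id)],
                timepoint=str(timepoint),
            )
        )

    mvc = pd.read_csv(indir / "mvc.csv")
    mvc_trials: dict[tuple[str, str], dict[str, list[np.ndarray]]] = {}
    for (subject_id, timepoint, muscle, _trial), grp in mvc.groupby(
        ["subject_id", "timepoint", "muscle", "trial"], sort=True
    ):
        key = (str(subject_id), str(timepoint))
        mvc_trials.setdefault(key, {}).setdefault(str(muscle), []).append(
            grp.sort_values("sample_index")["value_uv"].to_numpy()
        )
    return recordings, mvc_trials, meta
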