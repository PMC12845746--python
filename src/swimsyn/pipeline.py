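"""In-memory orchestration of the full analysis.

Functional core used by both the CLI stages and the test-bench: raw
recordings + MVC trials -> envelope cycles -> synergy sets -> reference
clustering and matching -> timing metrics -> one long outcome table ->
mixed-ANOVA results. All stage randomness is derived from a single root
seed via named, CRC-tagged seed sequences, so a rerun with the same
configuration is bit-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import anova as anova_mod
from . import cluster as cluster_mod
from . import nmf as nmf_mod
from . import timing as timing_mod
from .config import PipelineConfig
from .core import EmgRecording, EnvelopeCycle, ReferenceSynergies, SynergySet
from .errors import DataError
from .preprocess import (
    mvc_reference,
    preprocess_recording,
    representative_cycle,
    segment_cycles,
)
from .timedomain import phase_metrics


def derive_seed(root: int, *tags: str) -> int:
    """Deterministic child seed (< 2**31) from a root seed and string tags."""
    crcs = [zlib.crc32(t.encode()) for t in tags]
    state = np.random.SeedSequence([int(root), *crcs]).generate_state(1)[0]
    return int(state % (2**31))


def preprocess_dataset(
    recordings: list[EmgRecording],
    mvc_trials: dict[tuple[str, str], dict[str, list[np.ndarray]]],
    cfg: PipelineConfig,
) -> list[EnvelopeCycle]:
    """One MVC-normalised 100-point envelope cycle per recording."""
    envelopes = []
    for rec in recordings:
        key = (rec.subject_id, rec.timepoint)
        if key not in mvc_trials:
            raise DataError(f"no MVC trials for subject {key}")
        mvc = mvc_reference(
            mvc_trials[key],
            rec.fs,
            cfg.preprocess.mvc_window_s,
            params=cfg.preprocess,
        )
        envelopes.append(preprocess_recording(rec, mvc, cfg.preprocess))
    return envelopes


def extract_synergies(
    envelopes: list[EnvelopeCycle], cfg: PipelineConfig
) -> list[SynergySet]:
    """Per-condition NMF with VAF-threshold order selection."""
    out = []
    for env in envelopes:
        seed = derive_seed(cfg.seed, "nmf", env.subject_id, env.timepoint)
        out.append(
            nmf_mod.select_order(
                env.activity,
                seed,
                cfg.synergy,
                muscle_labels=env.muscle_labels,
                subject_id=env.subject_id,
                group=env.group,
                timepoint=env.timepoint,
            )
        )
    return out


def reference_and_match(
    synergies: list[SynergySet], cfg: PipelineConfig
) -> tuple[ReferenceSynergies, list[cluster_mod.MatchResult], pd.DataFrame]:
    """Cluster the reference condition, match everyone, and build the census."""
    ref_sets = [
        s
        for s in synergies
        if s.group == cfg.cluster.reference_group
        and s.timepoint == cfg.cluster.reference_timepoint
    ]
    if not ref_sets:
        raise DataError(
            f"no synergy sets in reference condition "
            f"{cfg.cluster.reference_group}/{cfg.cluster.reference_timepoint}"
        )
    reference = cluster_mod.build_reference(
        ref_sets, cfg.cluster, derive_seed(cfg.seed, "cluster")
    )
    matches = [
        cluster_mod.match_to_reference(s, reference, cfg.cluster.match_threshold)
        for s in synergies
    ]
    census = cluster_mod.synergy_census(matches, reference.n_clusters)
    return reference, matches, census


def timedomain_table(
    recordings: list[EmgRecording], cfg: PipelineConfig
) -> pd.DataFrame:
    """Phase-wise iEMG/RMS rows for every recording's representative cycle."""
    frames = []
    for rec in recordings:
        seg = representative_cycle(segment_cycles(rec))
        frames.append(phase_metrics(rec, seg, cfg.preprocess))
    return pd.concat(frames, ignore_index=True)


def timing_table(
    synergies: list[SynergySet],
    matches: list[cluster_mod.MatchResult],
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """ActivationTiming rows for every matched synergy."""
    rows = []
    for syn, match in zip(synergies, matches):
        for i, ref in sorted(match.assignments.items()):
            t = timing_mod.timing(
                syn.activations[i],
                cfg.timing.threshold_frac,
                synergy_ref=ref,
                subject_id=syn.subject_id,
                group=syn.group,
                timepoint=syn.timepoint,
            )
            rows.append(
                {
                    "subject_id": t.subject_id,
                    "group": t.group,
                    "timepoint": t.timepoint,
                    "synergy_ref": ref,
                    "duration": t.duration,
                    "peak_time": t.peak_time,
                    "onset_time": t.onset_time,
                }
            )
    return pd.DataFrame(rows)


def outcome_long_table(
    timedomain: pd.DataFrame,
    synergies: list[SynergySet],
    matches: list[cluster_mod.MatchResult],
    timing_df: pd.DataFrame,
) -> pd.DataFrame:
    """Stack every outcome into (subject_id, group, timepoint, outcome, value).

    Outcomes: iemg_/rms_ per phase x muscle, weight per reference synergy x
    muscle (from matched synergies only), the three timing parameters per
    reference synergy, and the per-condition synergy count.
    """
    frames = []
    td = timedomain.copy()
    for metric in ("iemg", "rms"):
        f = td[["subject_id", "group", "timepoint", "phase", "muscle", metric]].copy()
        f["outcome"] = metric + "_" + f.pop("phase") + "_" + f.pop("muscle")
        f = f.rename(columns={metric: "value"})
        frames.append(f[["subject_id", "group", "timepoint", "outcome", "value"]])

    rows = []
    for syn, match in zip(synergies, matches):
        rows.append(
            {
                "subject_id": syn.subject_id,
                "group": syn.group,
                "timepoint": syn.timepoint,
                "outcome": "n_synergies",
                "value": float(syn.k),
            }
        )
        for i, ref in match.assignments.items():
            for m, label in enumerate(syn.muscle_labels):
                rows.append(
                    {
                        "subject_id": syn.subject_id,
                        "group": syn.group,
                        "timepoint": syn.timepoint,
                        "outcome": f"weight_syn{ref + 1}_{label}",
                        "value": float(syn.weights[m, i]),
                    }
                )
    frames.append(pd.DataFrame(rows))

    if not timing_df.empty:
        t = timing_df.copy()
        for metric, name in (("duration", "T"), ("peak_time", "Tmax"), ("onset_time", "Tstart")):
            f = t[["subject_id", "group", "timepoint", "synergy_ref", metric]].copy()
            f["outcome"] = name + "_syn" + (f.pop("synergy_ref") + 1).astype(str)
            f = f.rename(columns={metric: "value"})
            frames.append(f[["subject_id", "group", "timepoint", "outcome", "value"]])
    return pd.concat(frames, ignore_index=True)


@dataclass
class StudyResults:
    """Everything the end-to-end analysis produces, in memory."""

    envelopes: list[EnvelopeCycle]
    synergies: list[SynergySet]
    reference: ReferenceSynergies
    matches: list[cluster_mod.MatchResult]
    census: pd.DataFrame
    timedomain: pd.DataFrame
    timing: pd.DataFrame
    outcomes: pd.DataFrame
    anova: pd.DataFrame
    simple_effects: pd.DataFrame


def run_study_analysis(
    recordings: list[EmgRecording],
    mvc_trials: dict[tuple[str, str], dict[str, list[np.ndarray]]],
    cfg: PipelineConfig,
    *,
    with_timedomain: bool = True,
) -> StudyResults:
    """Raw study -> full results (the CLI's run-all, without the file round
    trips)."""
    envelopes = preprocess_dataset(recordings, mvc_trials, cfg)
    synergies = extract_synergies(envelopes, cfg)
    reference, matches, census = reference_and_match(synergies, cfg)
    td = (
        timedomain_table(recordings, cfg)
        if with_timedomain
        else pd.DataFrame(
            columns=["subject_id", "group", "timepoint", "phase", "muscle", "iemg", "rms"]
        )
    )
    tim = timing_table(synergies, matches, cfg)
    outcomes = outcome_long_table(td, synergies, matches, tim)
    results, simple = anova_mod.anova_all_outcomes(outcomes, cfg.anova.alpha)
    return StudyResults(
        envelopes=envelopes,
        synergies=synergies,
        reference=reference,
        matches=matches,
        census=census,
        timedomain=td,
        timing=tim,
        outcomes=outcomes,
        anova=results,
        simple_effects=simple,
    )
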