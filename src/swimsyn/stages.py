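"""File-based pipeline stages with provenance manifests.

Each stage reads the previous stage's artifacts from the output directory,
writes its own, and finishes by writing ``manifests/<stage>.json`` recording
the SHA-256 digests of its inputs, the parameters and derived seed used, and
the files produced. A stage checks for its upstream manifest before running,
so running stages out of order raises DependencyError.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import synth as synth_mod
from .anova import anova_all_outcomes
from .cluster import MatchResult
from .config import PipelineConfig
from .core import EnvelopeCycle, SynergySet
from .errors import DependencyError
from .pipeline import (
    derive_seed,
    extract_synergies,
    outcome_long_table,
    preprocess_dataset,
    reference_and_match,
    timedomain_table,
    timing_table,
)

STAGES = ("simulate", "preprocess", "metrics", "synergy", "cluster", "timing", "anova")

_UPSTREAM = {
    "simulate": (),
    "preprocess": ("simulate",),
    "metrics": ("simulate",),
    "synergy": ("preprocess",),
    "cluster": ("synergy",),
    "timing": ("cluster",),
    "anova": ("metrics", "cluster", "timing"),
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _check_upstream(outdir: Path, stage: str) -> None:
    for dep in _UPSTREAM[stage]:
        manifest = outdir / "manifests" / f"{dep}.json"
        if not manifest.exists():
            raise DependencyError(
                f"stage {stage!r} requires {dep!r}; missing {manifest}"
            )


def _write_manifest(
    outdir: Path,
    stage: str,
    cfg: PipelineConfig,
    seed: int,
    inputs: list[Path],
    outputs: list[Path],
) -> None:
    mdir = outdir / "manifests"
    mdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "params": dataclasses.asdict(cfg),
        "inputs": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(inputs)},
        "outputs": [str(p.relative_to(outdir)) for p in sorted(outputs)],
    }
    (mdir / f"{stage}.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _read_envelopes(outdir: Path) -> list[EnvelopeCycle]:
    envs = []
    for csv in sorted((outdir / "envelopes").glob("*.csv")):
        meta = json.loads(csv.with_suffix(".json").read_text())
        wide = pd.read_csv(csv, index_col=0)
        envs.append(
            EnvelopeCycle(
                activity=wide.to_numpy(),
                muscle_labels=tuple(wide.index),
                phase_bounds_idx=tuple(meta["phase_bounds_idx"]),
                subject_id=meta["subject_id"],
                group=meta["group"],
                timepoint=meta["timepoint"],
            )
        )
    return envs


def _read_synergies(outdir: Path) -> list[SynergySet]:
    sets = []
    for meta_path in sorted((outdir / "synergy").glob("*_meta.json")):
        meta = json.loads(meta_path.read_text())
        stem = meta_path.name[: -len("_meta.json")]
        W = pd.read_csv(outdir / "synergy" / f"{stem}_weights.csv", index_col=0)
        C = pd.read_csv(outdir / "synergy" / f"{stem}_activations.csv", index_col=0)
        sets.append(
            SynergySet(
                weights=W.to_numpy(),
                activations=C.to_numpy(),
                vaf=meta["vaf"],
                k=meta["k"],
                muscle_labels=tuple(W.index),
                restarts_used=meta["restarts_used"],
                converged_selection=meta["converged_selection"],
                subject_id=meta["subject_id"],
                group=meta["group"],
                timepoint=meta["timepoint"],
            )
        )
    return sets


def run_stage(stage: str, cfg: PipelineConfig, outdir: str | Path) -> list[Path]:
    """Execute one named stage; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stage not in STAGES:
        raise DependencyError(f"unknown stage {stage!r}; choose from {STAGES}")
    _check_upstream(outdir, stage)
    fmt = "%.10g"
    outputs: list[Path] = []
    inputs: list[Path] = []
    seed = derive_seed(cfg.seed, stage)

    if stage == "simulate":
        ds = synth_mod.make_study(cfg.synth, cfg.seed)
        synth_mod.write_study(ds, outdir / "raw")
        outputs = sorted((outdir / "raw").glob("*"))

    elif stage == "preprocess":
        inputs = sorted((outdir / "raw").glob("*"))
        recordings, mvc_trials, _ = synth_mod.read_study(outdir / "raw")
        envdir = outdir / "envelopes"
        envdir.mkdir(exist_ok=True)
        for env in preprocess_dataset(recordings, mvc_trials, cfg):
            stem = f"{env.subject_id}_{env.timepoint}"
            csv = envdir / f"{stem}.csv"
            pd.DataFrame(
                env.activity,
                index=list(env.muscle_labels),
                columns=[f"t{i:02d}" for i in range(env.activity.shape[1])],
            ).to_csv(csv, float_format=fmt)
            sidecar = csv.with_suffix(".json")
            sidecar.write_text(
                json.dumps(
                    {
                        "subject_id": env.subject_id,
                        "group": env.group,
                        "timepoint": env.timepoint,
                        "phase_bounds_idx": list(env.phase_bounds_idx),
                    },
                    indent=2,
                    sort_keys=True,
                )
            )
            outputs += [csv, sidecar]

    elif stage == "metrics":
        inputs = sorted((outdir / "raw").glob("*"))
        recordings, _, _ = synth_mod.read_study(outdir / "raw")
        td = timedomain_table(recordings, cfg)
        path = outdir / "timedomain.csv"
        td.to_csv(path, index=False, float_format=fmt)
        outputs = [path]

    elif stage == "synergy":
        inputs = sorted((outdir / "envelopes").glob("*"))
        syndir = outdir / "synergy"
        syndir.mkdir(exist_ok=True)
        for syn in extract_synergies(_read_envelopes(outdir), cfg):
            stem = f"{syn.subject_id}_{syn.timepoint}"
            wpath = syndir / f"{stem}_weights.csv"
            cpath = syndir / f"{stem}_activations.csv"
            mpath = syndir / f"{stem}_meta.json"
            pd.DataFrame(
                syn.weights,
                index=list(syn.muscle_labels),
                columns=[f"syn{i + 1}" for i in range(syn.k)],
            ).to_csv(wpath, float_format=fmt)
            pd.DataFrame(
                syn.activations,
                index=[f"syn{i + 1}" for i in range(syn.k)],
                columns=[f"t{i:02d}" for i in range(syn.activations.shape[1])],
            ).to_csv(cpath, float_format=fmt)
            mpath.write_text(
                json.dumps(
                    {
                        "subject_id": syn.subject_id,
                        "group": syn.group,
                        "timepoint": syn.timepoint,
                        "k": syn.k,
                        "vaf": syn.vaf,
                        "restarts_used": syn.restarts_used,
                        "converged_selection": syn.converged_selection,
                    },
                    indent=2,
                    sort_keys=True,
                )
            )
            outputs += [wpath, cpath, mpath]

    elif stage == "cluster":
        inputs = sorted((outdir / "synergy").glob("*"))
        synergies = _read_synergies(outdir)
        reference, matches, census = reference_and_match(synergies, cfg)
        cdir = outdir / "cluster"
        cdir.mkdir(exist_ok=True)
        cent = cdir / "reference_centroids.csv"
        pd.DataFrame(
            reference.centroids,
            index=[f"syn{i + 1}" for i in range(reference.n_clusters)],
            columns=list(reference.muscle_labels),
        ).to_csv(cent, float_format=fmt)
        gap = cdir / "gap_curve.csv"
        reference.gap_curve.to_csv(gap, index=False, float_format=fmt)
        match_rows = []
        for m, syn in zip(matches, synergies):
            for i in range(syn.k):
                match_rows.append(
                    {
                        "subject_id": m.subject_id,
                        "group": m.group,
                        "timepoint": m.timepoint,
                        "synergy_index": i,
                        "ref_index": m.assignments.get(i, -1),
                        "r": m.correlations.get(i, float("nan")),
                    }
                )
        mpath = cdir / "matches.csv"
        pd.DataFrame(match_rows).to_csv(mpath, index=False, float_format=fmt)
        cpath = cdir / "census.csv"
        census.to_csv(cpath, index=False, float_format=fmt)
        outputs = [cent, gap, mpath, cpath]

    elif stage == "timing":
        inputs = sorted((outdir / "synergy").glob("*")) + [
            outdir / "cluster" / "matches.csv"
        ]
        synergies = _read_synergies(outdir)
        matches = _matches_from_csv(outdir, synergies)
        tim = timing_table(synergies, matches, cfg)
        path = outdir / "timing.csv"
        tim.to_csv(path, index=False, float_format=fmt)
        outputs = [path]

    elif stage == "anova":
        inputs = [
            outdir / "timedomain.csv",
            outdir / "cluster" / "matches.csv",
            outdir / "timing.csv",
        ]
        td = pd.read_csv(outdir / "timedomain.csv")
        synergies = _read_synergies(outdir)
        matches = _matches_from_csv(outdir, synergies)
        tim = pd.read_csv(outdir / "timing.csv")
        outcomes = outcome_long_table(td, synergies, matches, tim)
        results, simple = anova_all_outcomes(outcomes, cfg.anova.alpha)
        rpath = outdir / "anova_results.csv"
        spath = outdir / "simple_effects.csv"
        results.to_csv(rpath, index=False, float_format=fmt)
        simple.to_csv(spath, index=False, float_format=fmt)
        outputs = [rpath, spath]

    _write_manifest(outdir, stage, cfg, seed, inputs, outputs)
    return outputs


def _matches_from_csv(outdir: Path, synergies: list[SynergySet]) -> list[MatchResult]:
    df = pd.read_csv(outdir / "cluster" / "matches.csv")
    matches = []
    for syn in synergies:
        sub = df[
            (df.subject_id == syn.subject_id) & (df.timepoint == syn.timepoint)
        ]
        assignments = {
            int(r.synergy_index): int(r.ref_index)
            for r in sub.itertuples()
            if r.ref_index >= 0
        }
        correlations = {
            int(r.synergy_index): float(r.r)
            for r in sub.itertuples()
            if r.ref_index >= 0 and np.isfinite(r.r)
        }
        unmatched = tuple(
            sorted(int(r.synergy_index) for r in sub.itertuples() if r.ref_index < 0)
        )
        matches.append(
            MatchResult(
                subject_id=syn.subject_id,
                group=syn.group,
                timepoint=syn.timepoint,
                n_synergies=syn.k,
                assignments=assignments,
                correlations=correlations,
                unmatched=unmatched,
            )
        )
    return matches


def run_all(cfg: PipelineConfig, outdir: str | Path) -> None:
    for stage in STAGES:
        run_stage(stage, cfg, outdir)
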