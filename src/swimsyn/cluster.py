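"""Reference-synergy construction and correlation matching.

Weight vectors from the reference condition (control group, pre-intervention
by default) are clustered with best-of-repeats Lloyd K-means (squared
Euclidean); the cluster count is chosen by the Gap statistic with a uniform
bounding-box reference distribution, using the first k satisfying
``Gap(k) >= Gap(k+1) - sd(k+1)``. Every subject's synergies are then assigned
one-to-one to reference centroids greedily by Pearson correlation of muscle
weights, with an r >= 0.6 acceptance threshold; leftovers are unmatched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ClusterParams
from .core import ReferenceSynergies, SynergySet
from .errors import DataError, InvalidParameterError


@dataclass
class KMeansResult:
    centroids: np.ndarray  # (k, n_dims)
    labels: np.ndarray     # (n_vectors,)
    inertia: float         # total within-cluster squared Euclidean distance


def _lloyd(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100
) -> KMeansResult:
    """One Lloyd run from a random (Forgy) initialisation."""
    n = X.shape[0]
    centroids = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        # re-seed each empty cluster with the worst-fit point of a
        # multi-member cluster (so no donor cluster is emptied in turn)
        counts = np.bincount(new_labels, minlength=k)
        for j in np.flatnonzero(counts == 0):
            fit_d2 = d2[np.arange(n), new_labels].copy()
            fit_d2[counts[new_labels] <= 1] = -np.inf
            worst = int(fit_d2.argmax())
            counts[new_labels[worst]] -= 1
            new_labels[worst] = j
            counts[j] += 1
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            centroids[j] = X[labels == j].mean(axis=0)
    d2 = ((X - centroids[labels]) ** 2).sum()
    return KMeansResult(centroids=centroids, labels=labels, inertia=float(d2))


def kmeans(
    vectors: np.ndarray, k: int, n_repeats: int = 1000, seed: int = 0
) -> KMeansResult:
    """Best of ``n_repeats`` randomly initialised Lloyd runs (lowest inertia)."""
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2:
        raise InvalidParameterError("vectors must be 2-D")
    if not 1 <= k <= X.shape[0]:
        raise InvalidParameterError(f"need 1 <= k <= n_vectors, got k={k}")
    ss = np.random.SeedSequence([int(seed), k])
    best: KMeansResult | None = None
    for child in ss.spawn(n_repeats):
        res = _lloyd(X, k, np.random.default_rng(child))
        if best is None or res.inertia < best.inertia:
            best = res
    return best


def gap_select(
    vectors: np.ndarray,
    k_max: int,
    B: int = 100,
    seed: int = 0,
    *,
    n_repeats: int = 1000,
    ref_repeats: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Cluster count by the Gap statistic.

    ``Gap(k) = mean_b log(W*_kb) - log(W_k)`` with W the best K-means
    dispersion and reference sets drawn uniformly on the data's bounding box;
    ``sd(k)`` is the reference log-dispersion SD scaled by sqrt(1 + 1/B).
    Returns the smallest k with ``Gap(k) >= Gap(k+1) - sd(k+1)`` (else
    ``k_max``), plus the full gap curve.
    """
    X = np.asarray(vectors, dtype=float)
    if k_max >= X.shape[0]:
        raise InvalidParameterError("k_max must be < number of vectors")
    if np.allclose(X, X[0]):  # degenerate: all points identical
        curve = pd.DataFrame({"k": [1], "log_wk": [-np.inf], "gap": [np.inf], "sd": [0.0]})
        return 1, curve
    ks = np.arange(1, k_max + 1)
    log_wk = np.array(
        [np.log(max(kmeans(X, k, n_repeats, seed).inertia, 1e-300)) for k in ks]
    )
    lo, hi = X.min(axis=0), X.max(axis=0)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    log_wstar = np.empty((B, k_max))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=X.shape)
        ref_seed = int(rng.integers(2**31))
        for i, k in enumerate(ks):
            log_wstar[b, i] = np.log(
                max(kmeans(ref, k, ref_repeats, ref_seed).inertia, 1e-300)
            )
    gap = log_wstar.mean(axis=0) - log_wk
    sd = log_wstar.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    curve = pd.DataFrame({"k": ks, "log_wk": log_wk, "gap": gap, "sd": sd})
    for i in range(k_max - 1):
        if gap[i] >= gap[i + 1] - sd[i + 1]:
            return int(ks[i]), curve
    return int(k_max), curve


def build_reference(
    synergy_sets: list[SynergySet],
    params: ClusterParams | None = None,
    seed: int = 0,
) -> ReferenceSynergies:
    """Cluster the reference condition's weight vectors into centroids.

    Centroids are re-normalised to unit Euclidean norm after averaging and
    ordered deterministically by the index of their peak muscle weight.
    """
    params = params or ClusterParams()
    if not synergy_sets:
        raise DataError("no synergy sets to build a reference from")
    labels = synergy_sets[0].muscle_labels
    for s in synergy_sets:
        if s.muscle_labels != labels:
            raise DataError("inconsistent muscle labels across synergy sets")
    X = np.concatenate([s.weights.T for s in synergy_sets], axis=0)
    k_max = min(params.k_max, X.shape[0] - 1)
    n_clusters, curve = gap_select(
        X,
        k_max,
        params.gap_b,
        seed,
        n_repeats=params.n_repeats,
        ref_repeats=params.gap_ref_repeats,
    )
    km = kmeans(X, n_clusters, params.n_repeats, seed)
    C = np.clip(km.centroids, 0.0, None)
    norms = np.linalg.norm(C, axis=1, keepdims=True)
    C = C / np.where(norms > 0, norms, 1.0)
    order = np.lexsort((-np.max(C, axis=1), np.argmax(C, axis=1)))
    return ReferenceSynergies(
        centroids=C[order],
        muscle_labels=labels,
        n_clusters=n_clusters,
        gap_curve=curve,
        source=f"{params.reference_group}/{params.reference_timepoint}",
    )


@dataclass
class MatchResult:
    """One subject-condition's synergy-to-reference assignment."""

    subject_id: str
    group: str
    timepoint: str
    n_synergies: int
    assignments: dict[int, int] = field(default_factory=dict)  # synergy -> ref
    correlations: dict[int, float] = field(default_factory=dict)
    unmatched: tuple[int, ...] = ()


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


def match_to_reference(
    synergies: SynergySet,
    reference: ReferenceSynergies,
    threshold: float = 0.6,
) -> MatchResult:
    """Greedy one-to-one assignment by descending Pearson correlation.

    Repeatedly takes the highest remaining (synergy, reference) pair with
    r >= threshold; ties break to the lower reference index, then the lower
    synergy index. Synergies left over are unmatched.
    """
    reference.check_alignment(synergies.muscle_labels)
    k, n_ref = synergies.k, reference.n_clusters
    r = np.array(
        [
            [_pearson(synergies.weights[:, i], reference.centroids[j]) for j in range(n_ref)]
            for i in range(k)
        ]
    )
    free_syn = set(range(k))
    free_ref = set(range(n_ref))
    assignments: dict[int, int] = {}
    correlations: dict[int, float] = {}
    while free_syn and free_ref:
        best = None
        for i in sorted(free_syn):
            for j in sorted(free_ref):
                if best is None or r[i, j] > r[best] + 1e-12:
                    best = (i, j)
                elif abs(r[i, j] - r[best]) <= 1e-12 and (j, i) < (best[1], best[0]):
                    best = (i, j)
        i, j = best
        if r[i, j] < threshold:
            break
        assignments[i] = j
        correlations[i] = float(r[i, j])
        free_syn.remove(i)
        free_ref.remove(j)
    return MatchResult(
        subject_id=synergies.subject_id,
        group=synergies.group,
        timepoint=synergies.timepoint,
        n_synergies=k,
        assignments=assignments,
        correlations=correlations,
        unmatched=tuple(sorted(free_syn)),
    )


def synergy_census(matches: list[MatchResult], n_references: int) -> pd.DataFrame:
    """Per group x timepoint synergy bookkeeping.

    Columns: number of subjects, mean and SD of per-subject extracted synergy
    count, occurrence count per reference synergy, and the unmatched count.
    Conservation holds by construction: the per-reference counts plus the
    unmatched count equal the total synergies submitted.
    """
    rows = []
    keys = sorted({(m.group, m.timepoint) for m in matches})
    for group, timepoint in keys:
        sub = [m for m in matches if (m.group, m.timepoint) == (group, timepoint)]
        n_syn = np.array([m.n_synergies for m in sub], dtype=float)
        row = {
            "group": group,
            "timepoint": timepoint,
            "n_subjects": len(sub),
            "nsyn_mean": float(n_syn.mean()),
            "nsyn_sd": float(n_syn.std(ddof=1)) if len(sub) > 1 else 0.0,
        }
        for j in range(n_references):
            row[f"n_syn{j + 1}"] = sum(
                1 for m in sub for ref in m.assignments.values() if ref == j
            )
        row["n_unmatched"] = sum(len(m.unmatched) for m in sub)
        rows.append(row)
    return pd.DataFrame(rows)
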