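"""K-means, Gap statistic, reference matching and the synergy census."""

from __future__ import annotations

import numpy as np
import pytest

from swimsyn.cluster import (
    MatchResult,
    gap_select,
    kmeans,
    match_to_reference,
    synergy_census,
)
from swimsyn.core import ReferenceSynergies, SynergySet
from swimsyn.errors import AlignmentError, InvalidParameterError


def _clouds(rng, centers, n_each, spread):
    return np.concatenate(
        [c + spread * rng.standard_normal((n_each, len(c))) for c in centers]
    )


class TestKmeans:
    def test_k1_closed_form(self, rng):
        X = rng.standard_normal((20, 4))
        res = kmeans(X, 1, n_repeats=3, seed=0)
        np.testing.assert_allclose(res.centroids[0], X.mean(axis=0))
        assert res.inertia == pytest.approx(((X - X.mean(axis=0)) ** 2).sum())

    def test_k_equals_n_zero_dispersion(self, rng):
        X = rng.standard_normal((6, 3))
        res = kmeans(X, 6, n_repeats=20, seed=1)
        assert res.inertia == pytest.approx(0.0, abs=1e-18)

    def test_separated_clouds_recover_labels(self, rng):
        centers = [np.zeros(5), 10 * np.ones(5)]
        X = _clouds(rng, centers, 15, 0.3)
        res = kmeans(X, 2, n_repeats=20, seed=2)
        a, b = res.labels[:15], res.labels[15:]
        assert len(set(a)) == 1 and len(set(b)) == 1 and a[0] != b[0]

    def test_dispersion_non_increasing_in_k(self, rng):
        X = rng.standard_normal((30, 4))
        inertias = [kmeans(X, k, n_repeats=30, seed=3).inertia for k in range(1, 6)]
        assert all(b <= a + 1e-9 for a, b in zip(inertias, inertias[1:]))

    def test_matches_sklearn_inertia(self, rng):
        """Independent oracle: best-of-repeats inertia is no worse than
        scikit-learn's KMeans on the same data."""
        from sklearn.cluster import KMeans

        X = rng.standard_normal((40, 6))
        ours = kmeans(X, 3, n_repeats=300, seed=4)
        sk = KMeans(n_clusters=3, n_init=50, random_state=0).fit(X)
        assert ours.inertia <= sk.inertia_ * 1.005

    def test_invalid_k_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            kmeans(rng.standard_normal((3, 2)), 4)


class TestGapSelect:
    def test_identical_points_degenerate(self):
        X = np.ones((10, 4))
        k, curve = gap_select(X, 3, B=5, seed=0, n_repeats=5, ref_repeats=2)
        assert k == 1

    def test_three_separated_clouds(self, rng):
        centers = [np.zeros(6), 8 * np.ones(6), np.r_[8.0 * np.ones(3), np.zeros(3)]]
        hits = 0
        for rep in range(5):
            X = _clouds(np.random.default_rng(100 + rep), centers, 15, 0.4)
            k, _ = gap_select(X, 6, B=30, seed=rep, n_repeats=50, ref_repeats=5)
            hits += k == 3
        assert hits >= 3

    def test_single_cloud_selects_one(self):
        hits = 0
        for rep in range(5):
            X = np.random.default_rng(200 + rep).standard_normal((40, 6))
            k, _ = gap_select(X, 5, B=30, seed=rep, n_repeats=50, ref_repeats=5)
            hits += k == 1
        assert hits >= 3

    def test_kmax_bound_enforced(self, rng):
        with pytest.raises(InvalidParameterError):
            gap_select(rng.standard_normal((5, 2)), 5, B=3)


def _ref(centroids, labels=None):
    centroids = np.asarray(centroids, dtype=float)
    labels = labels or tuple(f"m{i}" for i in range(centroids.shape[1]))
    return ReferenceSynergies(
        centroids=centroids, muscle_labels=labels, n_clusters=centroids.shape[0]
    )


def _synset(weights, labels=None, **prov):
    weights = np.asarray(weights, dtype=float)
    weights = weights / np.linalg.norm(weights, axis=0, keepdims=True)
    k = weights.shape[1]
    labels = labels or tuple(f"m{i}" for i in range(weights.shape[0]))
    return SynergySet(
        weights=weights,
        activations=np.ones((k, 100)),
        vaf=1.0,
        k=k,
        muscle_labels=labels,
        **prov,
    )


class TestMatching:
    CENTROIDS = np.array(
        [
            [0.9, 0.1, 0.1, 0.1],
            [0.1, 0.9, 0.1, 0.1],
            [0.1, 0.1, 0.9, 0.1],
        ]
    )

    def test_identical_matches_r1(self):
        syn = _synset(self.CENTROIDS[:1].T)
        res = match_to_reference(syn, _ref(self.CENTROIDS))
        assert res.assignments == {0: 0}
        assert res.correlations[0] == pytest.approx(1.0)

    def test_permutation_recovered(self):
        perm = [2, 0, 1]
        syn = _synset(self.CENTROIDS[perm].T)
        res = match_to_reference(syn, _ref(self.CENTROIDS))
        assert res.assignments == {i: perm[i] for i in range(3)}
        assert all(r == pytest.approx(1.0) for r in res.correlations.values())
        assert res.unmatched == ()

    def test_uncorrelated_vector_unmatched(self):
        # flat weight profile: zero variance against any centroid pattern
        syn = _synset(np.array([[0.5, 0.5, 0.5, 0.5]]).T)
        res = match_to_reference(syn, _ref(self.CENTROIDS), threshold=0.6)
        assert res.assignments == {}
        assert res.unmatched == (0,)

    def test_matching_permutation_invariant(self, rng):
        W = np.abs(rng.standard_normal((4, 3))) + 0.05
        syn = _synset(W)
        shuffled = _synset(W[:, [2, 0, 1]])
        ref = _ref(self.CENTROIDS)
        a = match_to_reference(syn, ref)
        b = match_to_reference(shuffled, ref)
        pairs_a = sorted((r, round(c, 12)) for r, c in
                         zip(a.assignments.values(), a.correlations.values()))
        pairs_b = sorted((r, round(c, 12)) for r, c in
                         zip(b.assignments.values(), b.correlations.values()))
        assert pairs_a == pairs_b

    def test_muscle_order_mismatch_errors(self):
        syn = _synset(self.CENTROIDS.T, labels=("a", "b", "c", "d"))
        with pytest.raises(AlignmentError):
            match_to_reference(syn, _ref(self.CENTROIDS, ("d", "c", "b", "a")))


class TestCensus:
    def _match(self, group, tp, assignments, unmatched=()):
        return MatchResult(
            subject_id=f"{group}x",
            group=group,
            timepoint=tp,
            n_synergies=len(assignments) + len(unmatched),
            assignments=assignments,
            correlations={i: 0.9 for i in assignments},
            unmatched=unmatched,
        )

    def test_all_matched_counts(self):
        matches = [
            self._match("EXP", "pre", {0: 0, 1: 1, 2: 2}) for _ in range(15)
        ]
        census = synergy_census(matches, 3)
        row = census.iloc[0]
        assert row["nsyn_mean"] == 3.0 and row["nsyn_sd"] == 0.0
        assert row[["n_syn1", "n_syn2", "n_syn3"]].sum() == 45
        assert row["n_unmatched"] == 0

    def test_conservation_with_unmatched(self):
        matches = [
            self._match("CON", "pre", {0: 0, 1: 2}, unmatched=(2,)),
            self._match("CON", "pre", {0: 1, 1: 0, 2: 2}),
        ]
        census = synergy_census(matches, 3)
        row = census.iloc[0]
        total = row[["n_syn1", "n_syn2", "n_syn3"]].sum() + row["n_unmatched"]
        assert total == sum(m.n_synergies for m in matches)

    def test_unmatching_one_shifts_counts(self):
        a = synergy_census([self._match("EXP", "pre", {0: 0, 1: 1, 2: 2})], 3).iloc[0]
        b = synergy_census(
            [self._match("EXP", "pre", {0: 0, 1: 1}, unmatched=(2,))], 3
        ).iloc[0]
        assert b["n_unmatched"] == a["n_unmatched"] + 1
        assert b["n_syn3"] == a["n_syn3"] - 1
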