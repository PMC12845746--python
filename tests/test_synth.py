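"""Synthetic-study generator: construction contracts and determinism."""

from __future__ import annotations


import numpy as np
import pytest

from swimsyn.errors import InvalidDesignError, InvalidParameterError
from swimsyn.synth import (
    apply_effects,
    make_ground_truth,
    make_mvc_trials,
    make_study,
    read_study,
    synthesize_envelope_cycle,
    synthesize_raw_trial,
    write_study,
)


class TestMakeGroundTruth:
    @pytest.mark.parametrize("n_muscles,n_syn", [(10, 3), (10, 1), (8, 4)])
    def test_shapes_and_invariants(self, n_muscles, n_syn):
        t = make_ground_truth(n_muscles, n_syn, seed=7)
        assert t.weights_true.shape == (n_muscles, n_syn)
        assert t.activations_true.shape == (n_syn, 100)
        np.testing.assert_allclose(
            np.linalg.norm(t.weights_true, axis=0), 1.0, atol=1e-9
        )
        assert np.all(t.activations_true >= 0)
        b1, b2 = t.phase_bounds
        assert 0 < b1 < b2 < 1

    def test_distinct_peaks_per_synergy(self):
        t = make_ground_truth(10, 3, seed=7)
        peaks = t.activations_true.argmax(axis=1)
        assert len(set(peaks)) == 3

    def test_dominant_structure(self):
        t = make_ground_truth(10, 3, seed=7)
        for j, doms in enumerate(t.dominant):
            assert 2 <= len(doms) <= 4
            others = [m for m in range(10) if m not in doms]
            # dominant muscles out-weigh the rest of their column
            assert t.weights_true[list(doms), j].min() > t.weights_true[others, j].max()

    def test_single_synergy_has_global_max(self):
        t = make_ground_truth(10, 1, seed=1)
        row = t.activations_true[0]
        assert row.argmax() == np.flatnonzero(row == row.max())[0]

    def test_seed_determinism(self):
        a = make_ground_truth(10, 3, seed=7)
        b = make_ground_truth(10, 3, seed=7)
        np.testing.assert_array_equal(a.weights_true, b.weights_true)
        np.testing.assert_array_equal(a.burst_centers, b.burst_centers)

    def test_too_many_synergies_rejected(self):
        with pytest.raises(InvalidDesignError):
            make_ground_truth(5, 6, seed=0)


class TestSynthesizeEnvelope:
    def test_zero_noise_is_exact_product(self, truth10x3):
        env = synthesize_envelope_cycle(truth10x3, 0.7, 0.0, seed=3)
        expected = 0.7 * truth10x3.weights_true @ truth10x3.activations_true
        np.testing.assert_allclose(env.activity, expected, atol=1e-12)

    def test_zero_noise_rank_bounded_by_n_syn(self, truth10x3):
        env = synthesize_envelope_cycle(truth10x3, 0.7, 0.0, seed=3)
        assert np.linalg.matrix_rank(env.activity, tol=1e-10) <= 3

    def test_noise_reproducible_and_bounded(self, truth10x3):
        a = synthesize_envelope_cycle(truth10x3, 0.7, 0.05, seed=11)
        b = synthesize_envelope_cycle(truth10x3, 0.7, 0.05, seed=11)
        np.testing.assert_array_equal(a.activity, b.activity)
        clean = synthesize_envelope_cycle(truth10x3, 0.7, 0.0, seed=11)
        mad = np.abs(a.activity - clean.activity).mean()
        assert mad <= 3 * 0.05

    def test_negative_noise_rejected(self, truth10x3):
        with pytest.raises(InvalidParameterError):
            synthesize_envelope_cycle(truth10x3, 0.7, -0.1, seed=1)


class TestSynthesizeRawTrial:
    def test_zero_envelope_gives_zero_signal(self, truth10x3):
        env = synthesize_envelope_cycle(truth10x3, 1.0, 0.0, seed=1)
        env.activity[:] = 0.0
        rec = synthesize_raw_trial(env, 2000.0, 0.5, seed=2)
        assert np.all(rec.samples == 0.0)

    def test_constant_envelope_rms_tracks_carrier(self, truth10x3):
        env = synthesize_envelope_cycle(truth10x3, 1.0, 0.0, seed=1)
        env.activity[:] = 1.0
        rec = synthesize_raw_trial(env, 2000.0, 1.0, seed=2, pad_s=0.0)
        # unit-RMS carrier modulated by a constant 1 envelope
        rms = np.sqrt(np.mean(rec.samples**2, axis=1))
        np.testing.assert_allclose(rms, 1.0, rtol=0.15)

    def test_seed_determinism(self, truth10x3):
        env = synthesize_envelope_cycle(truth10x3, 0.6, 0.02, seed=4)
        a = synthesize_raw_trial(env, 2000.0, 0.6, seed=9)
        b = synthesize_raw_trial(env, 2000.0, 0.6, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_event_stream_layout(self, truth10x3):
        env = synthesize_envelope_cycle(truth10x3, 0.6, 0.0, seed=4)
        rec = synthesize_raw_trial(env, 2000.0, 0.6, seed=9, n_cycles=3, pad_s=0.25)
        names = [e[0] for e in rec.events]
        assert names.count("cycle_start") == 3
        assert names.count("phase1_end") == 3
        assert names[-1] == "cycle_end"

    def test_invalid_duration_rejected(self, truth10x3):
        env = synthesize_envelope_cycle(truth10x3, 0.6, 0.0, seed=4)
        with pytest.raises(InvalidParameterError):
            synthesize_raw_trial(env, 2000.0, -0.5, seed=9)


class TestEffects:
    def test_weight_effect_preserves_unit_norm(self, truth10x3):
        from swimsyn.synth import EffectSpec

        spec = EffectSpec(weight_multipliers={2: {0: 2.0}}, width_multipliers={1: 0.5})
        out = apply_effects(truth10x3, spec)
        np.testing.assert_allclose(np.linalg.norm(out.weights_true, axis=0), 1.0)
        # boosted muscle's share strictly increases, width strictly shrinks
        assert out.weights_true[0, 2] > truth10x3.weights_true[0, 2]
        assert out.burst_widths[1] == pytest.approx(0.5 * truth10x3.burst_widths[1])


class TestMakeStudy:
    def test_design_counts(self, small_study, small_cfg):
        n = small_cfg.synth.n_per_group
        assert len(small_study.recordings) == 2 * n * 2  # groups x subjects x times
        assert len(small_study.mvc_trials) == 2 * n * 2

    def test_null_effects_leave_pre_post_statistically_alike(self):
        from swimsyn.config import SynthParams

        p = SynthParams(n_per_group=2, effects_enabled=False)
        ds = make_study(p, seed=9)
        assert ds.effect_spec.is_null()
        # no systematic pre/post difference in ground-truth widths
        for sid in ds.subject_groups:
            pre = ds.condition_truths[(sid, "pre")]
            post = ds.condition_truths[(sid, "post")]
            ratio = post.burst_widths / pre.burst_widths
            assert np.all(ratio > 0.5) and np.all(ratio < 2.0)

    def test_mvc_peak_tracks_subject_gain(self, small_study, small_cfg):
        # MVC trials exist for every muscle with positive amplitude
        for (_sid, _tp), per_muscle in small_study.mvc_trials.items():
            assert set(per_muscle) == set(small_study.muscle_labels)
            for trials in per_muscle.values():
                assert len(trials) == small_cfg.synth.mvc_n_trials
                assert all(np.max(np.abs(t)) > 0 for t in trials)

    def test_csv_round_trip_and_byte_determinism(self, small_cfg, tmp_path):
        ds1 = make_study(small_cfg.synth, small_cfg.seed)
        ds2 = make_study(small_cfg.synth, small_cfg.seed)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_study(ds1, d1)
        write_study(ds2, d2)
        for name in ("emg.csv", "events.csv", "mvc.csv", "truth.json", "study.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
        recordings, mvc, meta = read_study(d1)
        assert len(recordings) == len(ds1.recordings)
        orig = {(r.subject_id, r.timepoint): r for r in ds1.recordings}
        for rec in recordings:
            ref = orig[(rec.subject_id, rec.timepoint)]
            assert rec.group == ref.group
            np.testing.assert_allclose(rec.samples, ref.samples, atol=1e-3)
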