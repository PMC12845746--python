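"""Mixed 2x2 ANOVA: oracle equivalence, SS conservation, invariances.

The oracle is a deliberately naive cell-means decomposition written with
explicit loops, independent of the pipeline implementation; pingouin's
mixed_anova provides a second, external check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from swimsyn.anova import (
    anova_all_outcomes,
    effect_band,
    mixed_anova_2x2,
    simple_effects,
)
from swimsyn.errors import InvalidParameterError, UnbalancedDesignError


def brute_force_mixed_anova(table: pd.DataFrame) -> dict:
    """Independent cell-means oracle (loops, no shared code)."""
    groups = sorted(table["group"].unique())
    times = sorted(table["timepoint"].unique(), key=lambda t: (t != "pre", t))
    y = {}
    for _, row in table.iterrows():
        y[(row["group"], row["subject_id"], row["timepoint"])] = row["value"]
    subjects = {g: sorted({s for (gg, s, _) in y if gg == g}) for g in groups}
    all_vals = list(y.values())
    grand = sum(all_vals) / len(all_vals)

    def cell_mean(g, t):
        vals = [y[(g, s, t)] for s in subjects[g]]
        return sum(vals) / len(vals)

    def subj_mean(g, s):
        return sum(y[(g, s, t)] for t in times) / len(times)

    def group_mean(g):
        return sum(cell_mean(g, t) for t in times) / len(times)

    n_total = sum(len(subjects[g]) for g in groups)
    time_mean = {
        t: sum(y[(g, s, t)] for g in groups for s in subjects[g]) / n_total
        for t in times
    }
    ss_group = sum(
        len(times) * len(subjects[g]) * (group_mean(g) - grand) ** 2 for g in groups
    )
    ss_subj = sum(
        len(times) * (subj_mean(g, s) - group_mean(g)) ** 2
        for g in groups
        for s in subjects[g]
    )
    ss_time = sum(n_total * (time_mean[t] - grand) ** 2 for t in times)
    ss_int = sum(
        len(subjects[g]) * (cell_mean(g, t) - group_mean(g) - time_mean[t] + grand) ** 2
        for g in groups
        for t in times
    )
    ss_err = sum(
        (y[(g, s, t)] - cell_mean(g, t) - subj_mean(g, s) + group_mean(g)) ** 2
        for g in groups
        for s in subjects[g]
        for t in times
    )
    df_b, df_w = n_total - 2, n_total - 2
    out = {}
    for name, ss_eff, ss_e, df_e in (
        ("group", ss_group, ss_subj, df_b),
        ("time", ss_time, ss_err, df_w),
        ("interaction", ss_int, ss_err, df_w),
    ):
        F = (ss_eff / 1) / (ss_e / df_e)
        out[name] = {
            "F": F,
            "p": float(stats.f.sf(F, 1, df_e)),
            "eta_p2": ss_eff / (ss_eff + ss_e),
        }
    return out


def _random_table(seed, n_per_group=4, effect=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for g in ("EXP", "CON"):
        for s in range(n_per_group):
            base = rng.normal(10, 2)
            for t in ("pre", "post"):
                val = base + rng.normal(0, 1)
                if g == "EXP" and t == "post":
                    val += effect
                rows.append(
                    {"subject_id": f"{g}{s}", "group": g, "timepoint": t, "value": val}
                )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_identical_shift_kills_interaction(self):
        df = _random_table(0)
        pre = df[df.timepoint == "pre"].copy()
        post = pre.copy()
        post["timepoint"] = "post"
        post["value"] += 3.0
        res = mixed_anova_2x2(pd.concat([pre, post]))
        assert res.effects["interaction"].F == pytest.approx(0.0, abs=1e-18)
        assert res.effects["interaction"].p == pytest.approx(1.0)

    def test_fully_constant_data_all_f_zero(self):
        rows = [
            {"subject_id": f"{g}{s}", "group": g, "timepoint": t, "value": 5.0}
            for g in ("EXP", "CON")
            for s in range(3)
            for t in ("pre", "post")
        ]
        res = mixed_anova_2x2(pd.DataFrame(rows))
        for eff in ("group", "time", "interaction"):
            assert res.effects[eff].F == 0.0

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_agrees_with_brute_force_oracle(self, seed):
        df = _random_table(seed, n_per_group=4, effect=1.5)
        res = mixed_anova_2x2(df)
        oracle = brute_force_mixed_anova(df)
        for eff in ("group", "time", "interaction"):
            assert res.effects[eff].F == pytest.approx(oracle[eff]["F"], abs=1e-8)
            assert res.effects[eff].p == pytest.approx(oracle[eff]["p"], abs=1e-8)
            assert res.effects[eff].eta_p2 == pytest.approx(
                oracle[eff]["eta_p2"], abs=1e-8
            )

    @pytest.mark.parametrize("seed", [6, 7])
    def test_agrees_with_pingouin(self, seed):
        pg = pytest.importorskip("pingouin")
        df = _random_table(seed, n_per_group=6, effect=1.0)
        res = mixed_anova_2x2(df)
        out = pg.mixed_anova(
            data=df, dv="value", within="timepoint", between="group",
            subject="subject_id",
        ).set_index("Source")
        assert res.effects["group"].F == pytest.approx(out.loc["group", "F"], rel=1e-6)
        assert res.effects["time"].F == pytest.approx(
            out.loc["timepoint", "F"], rel=1e-6
        )
        assert res.effects["interaction"].F == pytest.approx(
            out.loc["Interaction", "F"], rel=1e-6
        )

    def test_ss_conservation(self):
        df = _random_table(11, n_per_group=5, effect=2.0)
        res = mixed_anova_2x2(df)
        total = (
            res.ss["group"]
            + res.ss["subjects_within_group"]
            + res.ss["time"]
            + res.ss["interaction"]
            + res.ss["error"]
        )
        assert total == pytest.approx(res.ss["total"], rel=1e-9)

    def test_subject_relabel_invariance(self):
        df = _random_table(13)
        res_a = mixed_anova_2x2(df)
        # permute subject labels within each group
        mapping = {"EXP0": "EXP2", "EXP2": "EXP0", "CON1": "CON3", "CON3": "CON1"}
        df2 = df.copy()
        df2["subject_id"] = df2["subject_id"].map(lambda s: mapping.get(s, s))
        res_b = mixed_anova_2x2(df2)
        for eff in ("group", "time", "interaction"):
            assert res_a.effects[eff].F == pytest.approx(res_b.effects[eff].F)

    def test_missing_cell_rejected(self):
        df = _random_table(1).iloc[:-1]
        with pytest.raises(UnbalancedDesignError):
            mixed_anova_2x2(df)


class TestEffectBand:
    @pytest.mark.parametrize(
        "eta,band",
        [
            (0.14, "large"),
            (0.06, "medium"),
            (0.01, "small"),
            (0.005, "below-small"),
            (0.5, "large"),
        ],
    )
    def test_cut_points(self, eta, band):
        assert effect_band(eta) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            effect_band(1.5)


class TestSimpleEffects:
    def test_identical_pre_post_adjusted_p_one(self):
        df = _random_table(3)
        piv = df.pivot_table(index=["group", "subject_id"], columns="timepoint",
                             values="value").reset_index()
        piv["post"] = piv["pre"]
        flat = piv.melt(
            id_vars=["group", "subject_id"], value_vars=["pre", "post"],
            var_name="timepoint", value_name="value",
        )
        out = simple_effects(flat, "within-group")
        assert all(se.p_adjusted == pytest.approx(1.0) for se in out)

    def test_bonferroni_cap(self):
        # raw p multiplied by m and capped at 1
        df = _random_table(5)
        out = simple_effects(df, "within-group", m=50)
        assert all(se.p_adjusted <= 1.0 for se in out)

    def test_injected_effect_detected_in_exp_only(self):
        df = _random_table(7, n_per_group=10, effect=5.0)
        out = {se.contrast: se for se in simple_effects(df, "within-group")}
        exp = next(v for k, v in out.items() if k.startswith("EXP"))
        con = next(v for k, v in out.items() if k.startswith("CON"))
        assert exp.p_adjusted < 0.05
        assert con.p_adjusted > 0.05
        assert exp.mean_difference == pytest.approx(5.0, abs=2.0)


class TestAnovaRunner:
    def test_incomplete_subject_dropped(self):
        df = _random_table(9)
        df["outcome"] = "metric"
        df = df[~((df.subject_id == "EXP0") & (df.timepoint == "post"))]
        res, _ = anova_all_outcomes(df)
        assert (res["n"] == 7).all()

    def test_one_result_row_per_effect(self):
        df = _random_table(10)
        df["outcome"] = "metric"
        res, _ = anova_all_outcomes(df)
        assert sorted(res["effect"]) == ["group", "interaction", "time"]
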