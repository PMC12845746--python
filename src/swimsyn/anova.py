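"""2 x 2 mixed-design repeated-measures ANOVA with partial eta squared.

One between-subject factor (group: EXP vs CON) and one within-subject factor
(time: pre vs post). Sums of squares decompose as: group tested against
subjects-within-group; time and group x time tested against the
time x subjects-within-group residual. With only two within-subject levels
sphericity holds trivially, so no correction is applied. Effect size is
partial eta squared, SS_effect / (SS_effect + SS_error-of-that-effect),
banded at the conventional 0.01 / 0.06 / 0.14 cut points (closed on the
left). Simple effects are Bonferroni-adjusted t-tests: paired pre-vs-post
within each group, independent EXP-vs-CON at each timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError, UnbalancedDesignError

EFFECTS = ("group", "time", "interaction")
_BANDS = ((0.14, "large"), (0.06, "medium"), (0.01, "small"))


def effect_band(eta_p2: float) -> str:
    """Qualitative band for a partial eta squared value."""
    if not 0.0 <= eta_p2 <= 1.0:
        raise InvalidParameterError(f"eta_p2 must lie in [0, 1], got {eta_p2}")
    for cut, name in _BANDS:
        if eta_p2 >= cut:
            return name
    return "below-small"


@dataclass
class EffectResult:
    effect: str
    F: float
    df: tuple[int, int]
    p: float
    eta_p2: float
    band: str


@dataclass
class SimpleEffect:
    contrast: str
    mean_difference: float
    p_adjusted: float


@dataclass
class AnovaResult:
    effects: dict[str, EffectResult]
    n_per_group: dict[str, int]
    grand_mean: float
    ss: dict[str, float] = field(default_factory=dict)
    simple_effects: list[SimpleEffect] = field(default_factory=list)


def _cell_matrix(table: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str], list[str]]:
    """Pivot long table to (n_subjects, 2) values ordered pre, post."""
    required = {"subject_id", "group", "timepoint", "value"}
    missing = required - set(table.columns)
    if missing:
        raise InvalidParameterError(f"table missing columns: {sorted(missing)}")
    times = sorted(table["timepoint"].unique(), key=lambda t: (t != "pre", t))
    if len(times) != 2:
        raise UnbalancedDesignError(f"need exactly 2 timepoints, got {times}")
    pivot = table.pivot_table(
        index=["group", "subject_id"], columns="timepoint", values="value", aggfunc="first"
    )
    if pivot.isna().any().any():
        raise UnbalancedDesignError("missing subject x timepoint cell")
    counts = table.groupby(["subject_id", "timepoint"]).size()
    if (counts != 1).any():
        raise UnbalancedDesignError("duplicate value for a subject x timepoint cell")
    pivot = pivot[times]
    groups = [g for g, _ in pivot.index]
    subjects = [s for _, s in pivot.index]
    return pivot.to_numpy(dtype=float), groups, subjects, times


def mixed_anova_2x2(table: pd.DataFrame) -> AnovaResult:
    """Mixed repeated-measures ANOVA on a long table.

    ``table`` has columns subject_id, group, timepoint, value; each subject
    appears in one group with exactly one value per timepoint and every group
    has at least two subjects.
    """
    Y, groups, _subjects, _times = _cell_matrix(table)
    group_levels = sorted(set(groups))
    if len(group_levels) != 2:
        raise UnbalancedDesignError(f"need exactly 2 groups, got {group_levels}")
    g_idx = np.array([group_levels.index(g) for g in groups])
    n_g = np.array([(g_idx == i).sum() for i in range(2)])
    if np.any(n_g < 2):
        raise UnbalancedDesignError("need >= 2 subjects per group")
    N = Y.shape[0]
    r = 2  # within-subject levels

    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    group_means = np.array([Y[g_idx == i].mean() for i in range(2)])
    time_means = Y.mean(axis=0)
    cell_means = np.array([Y[g_idx == i].mean(axis=0) for i in range(2)])

    ss_total = float(((Y - grand) ** 2).sum())
    ss_group = float(r * (n_g * (group_means - grand) ** 2).sum())
    ss_subj = float(r * ((subj_means - group_means[g_idx]) ** 2).sum())
    ss_time = float(N * ((time_means - grand) ** 2).sum())
    ss_cells = float((n_g[:, None] * (cell_means - grand) ** 2).sum())
    ss_inter = ss_cells - ss_group - ss_time
    ss_within = float(((Y - subj_means[:, None]) ** 2).sum())
    ss_error = ss_within - ss_time - ss_inter

    df_group, df_subj = 1, N - 2
    df_time, df_inter, df_error = 1, 1, N - 2

    def f_test(ss_eff: float, df_eff: int, ss_err: float, df_err: int) -> tuple:
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        if ms_err <= 0:
            # degenerate zero-variance error stratum: F=0 when effect is
            # also zero, else infinite evidence
            F = 0.0 if ss_eff <= 1e-300 else np.inf
        else:
            F = max(ms_eff / ms_err, 0.0)
        p = float(stats.f.sf(F, df_eff, df_err)) if np.isfinite(F) else 0.0
        denom = ss_eff + ss_err
        eta = ss_eff / denom if denom > 0 else 0.0
        eta = min(max(eta, 0.0), 1.0)
        return F, p, eta

    results = {}
    for name, ss_eff, df_eff, ss_err, df_err in (
        ("group", ss_group, df_group, ss_subj, df_subj),
        ("time", ss_time, df_time, ss_error, df_error),
        ("interaction", ss_inter, df_inter, ss_error, df_error),
    ):
        ss_eff = max(ss_eff, 0.0)
        F, p, eta = f_test(ss_eff, df_eff, max(ss_err, 0.0), df_err)
        results[name] = EffectResult(
            effect=name, F=float(F), df=(df_eff, df_err), p=p,
            eta_p2=float(eta), band=effect_band(float(eta)),
        )
    return AnovaResult(
        effects=results,
        n_per_group={group_levels[i]: int(n_g[i]) for i in range(2)},
        grand_mean=float(grand),
        ss={
            "group": ss_group,
            "subjects_within_group": ss_subj,
            "time": ss_time,
            "interaction": ss_inter,
            "error": ss_error,
            "total": ss_total,
        },
    )


def simple_effects(
    table: pd.DataFrame,
    which: str = "within-group",
    alpha: float = 0.05,
    m: int | None = None,
) -> list[SimpleEffect]:
    """Bonferroni-adjusted pairwise contrasts.

    ``within-group``: paired t-test pre vs post per group; ``between-group``:
    independent t-test EXP-style group contrast at each timepoint. Adjusted
    p = min(1, raw p * m); m defaults to the number of contrasts in the
    family (2 here).
    """
    if which not in ("within-group", "between-group"):
        raise InvalidParameterError(f"unknown simple-effects family {which!r}")
    Y, groups, _subjects, times = _cell_matrix(table)
    group_levels = sorted(set(groups))
    g_idx = np.array([group_levels.index(g) for g in groups])
    out: list[SimpleEffect] = []
    if which == "within-group":
        contrasts = [(i, g) for i, g in enumerate(group_levels)]
    else:
        contrasts = list(enumerate(times))
    m = m if m is not None else len(contrasts)
    if m < 1:
        raise InvalidParameterError("Bonferroni m must be >= 1")
    for idx, name in contrasts:
        if which == "within-group":
            block = Y[g_idx == idx]
            diff = block[:, 1] - block[:, 0]
            if np.allclose(diff, 0.0):
                p = 1.0
            else:
                p = float(stats.ttest_rel(block[:, 1], block[:, 0]).pvalue)
            label = f"{name}: {times[1]} - {times[0]}"
            md = float(diff.mean())
        else:
            a = Y[g_idx == 0, idx]
            b = Y[g_idx == 1, idx]
            if np.allclose(a.mean(), b.mean()) and a.std() + b.std() == 0:
                p = 1.0
            else:
                p = float(stats.ttest_ind(a, b).pvalue)
            label = f"{name}: {group_levels[0]} - {group_levels[1]}"
            md = float(a.mean() - b.mean())
        if not np.isfinite(p):
            p = 1.0
        out.append(SimpleEffect(contrast=label, mean_difference=md,
                                p_adjusted=min(1.0, p * m)))
    return out


def anova_all_outcomes(
    long: pd.DataFrame,
    alpha: float = 0.05,
    *,
    min_per_group: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the mixed ANOVA for every outcome in a long table.

    ``long`` has columns subject_id, group, timepoint, outcome, value.
    Subjects missing either timepoint for an outcome are dropped for that
    outcome (e.g. a synergy that went unmatched at one session); outcomes
    left with fewer than ``min_per_group`` complete subjects in a group are
    skipped. Simple effects are emitted for outcomes whose interaction is
    significant at ``alpha``. Returns (results, simple-effects) tables.
    """
    res_rows = []
    se_rows = []
    for outcome, sub in long.groupby("outcome", sort=True):
        counts = sub.groupby("subject_id")["timepoint"].nunique()
        complete = counts[counts == 2].index
        sub = sub[sub["subject_id"].isin(complete)]
        if sub.empty:
            continue
        per_group = sub.groupby("group")["subject_id"].nunique()
        if len(per_group) < 2 or (per_group < min_per_group).any():
            continue
        res = mixed_anova_2x2(sub[["subject_id", "group", "timepoint", "value"]])
        for eff in EFFECTS:
            e = res.effects[eff]
            res_rows.append(
                {
                    "outcome": outcome,
                    "effect": eff,
                    "F": e.F,
                    "df1": e.df[0],
                    "df2": e.df[1],
                    "p": e.p,
                    "eta_p2": e.eta_p2,
                    "band": e.band,
                    "n": int(per_group.sum()),
                }
            )
        if res.effects["interaction"].p < alpha:
            for which in ("within-group", "between-group"):
                for se in simple_effects(sub, which, alpha):
                    se_rows.append(
                        {
                            "outcome": outcome,
                            "family": which,
                            "contrast": se.contrast,
                            "mean_difference": se.mean_difference,
                            "p_adjusted": se.p_adjusted,
                        }
                    )
    return pd.DataFrame(res_rows), pd.DataFrame(se_rows)
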