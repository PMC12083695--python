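"""The study's statistical battery on the tidy measurement table.

A mixed-design (repeated-measures) ANOVA with one between-subjects factor
(experimental group) and one within-subjects factor (time: baseline vs
24 h) is computed from the classic sums-of-squares decomposition on the
subject x time pivot.  Post hoc per-group baseline-vs-24 h contrasts use
the pooled within-subject error term by default (as GraphPad-style RM-ANOVA
post hocs do), with Bonferroni and Sidak corrections.  Infarct volumes are
compared by Welch two-sample t-tests and a one-way ANOVA; baseline equality
across the five groups is checked by a one-way ANOVA with pairwise
Bonferroni contrasts.

With only two within-subject levels sphericity holds trivially, so no
epsilon correction is applied (this is noted in every result).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

TIMEPOINTS = ("baseline", "h24")


@dataclass
class RmAnovaResult:
    """Mixed-design ANOVA table plus the pieces post hoc contrasts need."""

    effects: pd.DataFrame  # one row per effect: SS, df, MS, F, p
    ss_total: float
    ss_between_subjects: float
    ss_within_subjects: float
    ms_error_within: float
    df_error_within: int
    group_labels: list
    group_n: dict
    group_diff_means: dict  # mean(h24 - baseline) per group
    data_wide: pd.DataFrame  # subject x (group, baseline, h24) after exclusions
    n_excluded: int
    note: str = "two within levels: sphericity automatic"
    degenerate: bool = False


def _mixed_anova_arrays(y: np.ndarray, groups: np.ndarray) -> dict:
    """Classic mixed-design SS decomposition.

    ``y`` is (n_subjects, 2) responses at (baseline, 24 h); ``groups`` the
    between-subjects labels.  Between- and within-subject halves are
    computed independently, so the partition
    SS_total = SS_between_subjects + SS_within_subjects is a real
    consistency check rather than a definition.
    """
    y = np.asarray(y, dtype=float)
    n, t = y.shape
    labels, ginv = np.unique(groups, return_inverse=True)
    g = labels.size
    grand = y.mean()
    subj_mean = y.mean(axis=1)
    time_mean = y.mean(axis=0)
    n_g = np.bincount(ginv)
    gmean = np.bincount(ginv, weights=subj_mean) / n_g
    cell = np.vstack([np.bincount(ginv, weights=y[:, j]) / n_g for j in range(t)]).T

    ss_total = ((y - grand) ** 2).sum()
    ss_between_subj = t * ((subj_mean - grand) ** 2).sum()
    ss_within_subj = ((y - subj_mean[:, None]) ** 2).sum()
    ss_group = t * (n_g * (gmean - grand) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_group
    ss_time = n * ((time_mean - grand) ** 2).sum()
    ss_cells = (n_g[:, None] * (cell - grand) ** 2).sum()
    ss_inter = ss_cells - ss_group - ss_time
    ss_err_within = ss_within_subj - ss_time - ss_inter

    df_group, df_subj = g - 1, n - g
    df_time, df_inter, df_err = t - 1, g - 1, (n - g) * (t - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ms_group = ss_group / df_group if df_group else np.nan
        ms_subj = ss_subj_within / df_subj if df_subj else np.nan
        ms_time = ss_time / df_time
        ms_inter = ss_inter / df_inter if df_inter else np.nan
        ms_err = ss_err_within / df_err if df_err else np.nan
        f_group = ms_group / ms_subj
        f_time = ms_time / ms_err
        f_inter = ms_inter / ms_err
    return {
        "labels": labels,
        "n_g": dict(zip(labels.tolist(), n_g.tolist())),
        "ss": {
            "group": ss_group,
            "subjects_within_groups": ss_subj_within,
            "time": ss_time,
            "group_x_time": ss_inter,
            "error_within": ss_err_within,
            "total": ss_total,
            "between_subjects": ss_between_subj,
            "within_subjects": ss_within_subj,
        },
        "df": {
            "group": df_group,
            "subjects_within_groups": df_subj,
            "time": df_time,
            "group_x_time": df_inter,
            "error_within": df_err,
        },
        "ms_err": ms_err,
        "F": {"group": f_group, "time": f_time, "group_x_time": f_inter},
        "df_den": {"group": df_subj, "time": df_err, "group_x_time": df_err},
    }


def rm_anova(
    table: pd.DataFrame,
    response: str,
    subject: str = "animal",
    between: str = "group",
    within: str = "timepoint",
) -> RmAnovaResult:
    """Mixed-design RM-ANOVA of one response on the tidy study table.

    Subjects missing either timepoint are excluded listwise with a warning;
    a degenerate all-constant response is flagged rather than raising.
    """
    cols = [subject, between, within, response]
    df = table[cols].dropna(subset=[response])
    wide = df.pivot_table(index=[subject, between], columns=within, values=response)
    missing = [tp for tp in TIMEPOINTS if tp not in wide.columns]
    if missing:
        raise ValueError(f"missing timepoint level(s): {missing}")
    wide = wide[list(TIMEPOINTS)]
    n_before = len(wide)
    wide = wide.dropna()
    n_excluded = n_before - len(wide)
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} subject(s) missing a timepoint", stacklevel=2)
    wide = wide.reset_index()
    groups = wide[between].to_numpy()
    counts = pd.Series(groups).value_counts()
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 subjects with both timepoints")
    if counts.size < 2:
        raise ValueError("need at least 2 groups")
    y = wide[list(TIMEPOINTS)].to_numpy(dtype=float)

    dec = _mixed_anova_arrays(y, groups)
    degenerate = dec["ss"]["total"] <= 1e-300
    rows = []
    for eff in ("group", "time", "group_x_time"):
        f = dec["F"][eff]
        dfn, dfd = dec["df"][eff], dec["df_den"][eff]
        p = float(sps.f.sf(f, dfn, dfd)) if np.isfinite(f) else np.nan
        rows.append(
            {
                "effect": eff,
                "SS": dec["ss"][eff],
                "df_num": dfn,
                "df_den": dfd,
                "F": f if np.isfinite(f) else np.nan,
                "p": p,
            }
        )
    for eff in ("subjects_within_groups", "error_within"):
        rows.append(
            {
                "effect": eff,
                "SS": dec["ss"][eff],
                "df_num": dec["df"][eff],
                "df_den": np.nan,
                "F": np.nan,
                "p": np.nan,
            }
        )
    diffs = wide[TIMEPOINTS[1]] - wide[TIMEPOINTS[0]]
    diff_means = {g: float(diffs[wide[between] == g].mean()) for g in dec["labels"]}
    return RmAnovaResult(
        effects=pd.DataFrame(rows),
        ss_total=float(dec["ss"]["total"]),
        ss_between_subjects=float(dec["ss"]["between_subjects"]),
        ss_within_subjects=float(dec["ss"]["within_subjects"]),
        ms_error_within=float(dec["ms_err"]),
        df_error_within=int(dec["df"]["error_within"]),
        group_labels=list(dec["labels"]),
        group_n=dec["n_g"],
        group_diff_means=diff_means,
        data_wide=wide,
        n_excluded=n_excluded,
        degenerate=bool(degenerate),
    )


def correct_pvalues(p: np.ndarray, k: int, method: str) -> np.ndarray:
    """Bonferroni (p*k capped at 1) or Sidak (1 - (1-p)^k) correction."""
    p = np.asarray(p, dtype=float)
    if method == "bonferroni":
        return np.minimum(1.0, p * k)
    if method == "sidak":
        return 1.0 - (1.0 - p) ** k
    raise ValueError(f"unknown correction {method!r}")


def posthoc_time_contrasts(
    result: RmAnovaResult,
    correction: str = "sidak",
    error: str = "pooled",
) -> pd.DataFrame:
    """Per-group baseline-vs-24 h contrasts after the RM-ANOVA.

    ``error="pooled"`` tests each group's mean change against the ANOVA's
    pooled within-subject error (se = sqrt(2 MS_err / n_g), df = N - g),
    the convention of RM-ANOVA post hocs; ``error="paired"`` runs an
    ordinary per-group paired t-test instead.  Both Bonferroni and Sidak
    corrected p values are reported; ``correction`` selects which one the
    ``significant`` column uses (alpha = 0.05).
    """
    if correction not in ("bonferroni", "sidak"):
        raise ValueError(f"unknown correction {correction!r}")
    if error not in ("pooled", "paired"):
        raise ValueError(f"unknown error term {error!r}")
    k = len(result.group_labels)
    rows = []
    wide = result.data_wide
    for g in result.group_labels:
        sub = wide[wide["group"] == g]
        d = (sub[TIMEPOINTS[1]] - sub[TIMEPOINTS[0]]).to_numpy(dtype=float)
        est = float(d.mean())
        if error == "pooled":
            se = float(np.sqrt(2.0 * result.ms_error_within / d.size))
            dof = result.df_error_within
        else:
            se = float(d.std(ddof=1) / np.sqrt(d.size))
            dof = d.size - 1
        t = est / se if se > 0 else (0.0 if est == 0 else np.inf)
        p = float(2.0 * sps.t.sf(abs(t), dof)) if np.isfinite(t) else 0.0
        rows.append({"group": g, "estimate": est, "se": se, "t": t, "df": dof, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = correct_pvalues(out["p_raw"].to_numpy(), k, "bonferroni")
    out["p_sidak"] = correct_pvalues(out["p_raw"].to_numpy(), k, "sidak")
    out["correction"] = correction
    out["p_corrected"] = out[f"p_{correction}"]
    out["significant"] = out["p_corrected"] < 0.05
    return out


def baseline_equality_check(
    table: pd.DataFrame, response: str, n_groups_required: int = 5
) -> dict:
    """One-way ANOVA across all groups at baseline, plus pairwise Bonferroni.

    Confirms the groups were statistically indistinguishable before the
    intervention.
    """
    base = table[(table["timepoint"] == "baseline")].dropna(subset=[response])
    groups = sorted(base["group"].unique())
    if len(groups) != n_groups_required:
        raise ValueError(
            f"baseline check requires all {n_groups_required} groups, found {len(groups)}"
        )
    samples = [base.loc[base["group"] == g, response].to_numpy(dtype=float) for g in groups]
    f, p = sps.f_oneway(*samples)
    pairs = []
    npairs = len(groups) * (len(groups) - 1) // 2
    for i, gi in enumerate(groups):
        for gj in groups[i + 1 :]:
            t, pr = sps.ttest_ind(samples[i], samples[groups.index(gj)])
            pairs.append(
                {
                    "group_a": gi,
                    "group_b": gj,
                    "t": float(t),
                    "p_raw": float(pr),
                    "p_bonferroni": float(min(1.0, pr * npairs)),
                }
            )
    return {"F": float(f), "p": float(p), "pairwise": pd.DataFrame(pairs)}


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    return float((a.mean() - b.mean()) / pooled) if pooled > 0 else np.nan


def infarct_group_tests(
    table: pd.DataFrame,
    volume_col: str = "corrected_volume_mm3",
    pairs: list[tuple] | None = None,
    equal_var: bool = False,
) -> dict:
    """Welch two-sample t-tests between groups plus a one-way ANOVA.

    One volume per animal.  Default pairs contrast every group against
    every other.  Zero-variance pairs with equal means return t=0, p=1
    flagged ``degenerate``; unequal means with no variance at all raise.
    """
    df = table.dropna(subset=[volume_col]).drop_duplicates(subset=["animal"])
    groups = sorted(df["group"].unique())
    by = {g: df.loc[df["group"] == g, volume_col].to_numpy(dtype=float) for g in groups}
    for g, v in by.items():
        if v.size < 2:
            raise ValueError(f"group {g} has fewer than 2 animals")
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    rows = []
    for a, b in pairs:
        va, vb = by[a], by[b]
        degenerate = va.var(ddof=1) == 0 and vb.var(ddof=1) == 0
        if degenerate:
            if va.mean() != vb.mean():
                raise ValueError(f"zero variance in both groups {a} and {b} with unequal means")
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(va, vb, equal_var=equal_var)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_a": float(va.mean()),
                "mean_b": float(vb.mean()),
                "t": float(t),
                "p": float(p),
                "cohens_d": _cohens_d(va, vb),
                "welch": not equal_var,
                "degenerate": degenerate,
            }
        )
    samples = [by[g] for g in groups]
    if all(s.var(ddof=1) == 0 for s in samples) and len({s.mean() for s in samples}) == 1:
        f_val, p_anova, eta2 = 0.0, 1.0, 0.0
    else:
        f_val, p_anova = sps.f_oneway(*samples)
        grand = np.concatenate(samples).mean()
        ss_b = sum(s.size * (s.mean() - grand) ** 2 for s in samples)
        ss_t = sum(((s - grand) ** 2).sum() for s in samples)
        eta2 = float(ss_b / ss_t) if ss_t > 0 else np.nan
    return {
        "t_tests": pd.DataFrame(rows),
        "anova": {"F": float(f_val), "p": float(p_anova), "eta_squared": eta2},
    }
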