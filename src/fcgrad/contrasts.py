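"""Pre/post x drug statistical contrasts and brain-behavior models.

Four named contrasts over any per-scan metric:

- ``Synergy`` — group-by-time interaction from a two-way repeated
  measures ANOVA (drug vs placebo between subjects, post vs pre within);
- ``GroupPost`` — between-group ANCOVA on post scores with the
  pre score as covariate;
- ``Meditation`` — post-vs-pre change within the placebo group;
- ``PsychMed`` — post-vs-pre change within the drug group.

The two within-group contrasts are change models with the group's
centered baseline as covariate (a baseline covariate can only enter a
model in which it varies; see the methods note for why this reading
was chosen over alternatives).

Multiplicity is handled by Benjamini-Hochberg FDR within each metric
family (e.g. all 15 network pairs, or all parcels). Brain-behavior
associations are ordinary least squares with score, group, and their
interaction as predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .types import ContrastResult

CONTRAST_NAMES = ("Synergy", "GroupPost", "Meditation", "PsychMed")
GROUPS = ("drug", "placebo")
SESSIONS = ("pre", "post")
ALPHA_LEVEL = 0.05


@dataclass
class Design:
    """Long-format metric table for a two-group pre/post design.

    ``table`` columns: subject, group (drug/placebo), session (pre/post),
    metric, value. Every subject must have both sessions for any metric
    it appears under.
    """

    table: pd.DataFrame
    _wide_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        required = {"subject", "group", "session", "metric", "value"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        bad_groups = set(self.table["group"]) - set(GROUPS)
        if bad_groups:
            raise ValueError(f"unknown groups: {sorted(bad_groups)}")
        bad_sessions = set(self.table["session"]) - set(SESSIONS)
        if bad_sessions:
            raise ValueError(f"unknown sessions: {sorted(bad_sessions)}")

    @property
    def metrics(self) -> list[str]:
        return sorted(self.table["metric"].unique())

    def wide(self, metric: str) -> pd.DataFrame:
        """Per-subject pre/post/group frame for one metric."""
        if metric in self._wide_cache:
            return self._wide_cache[metric]
        sub = self.table[self.table["metric"] == metric]
        if sub.empty:
            raise KeyError(f"metric not in design: {metric}")
        wide = sub.pivot_table(
            index=["subject", "group"], columns="session", values="value"
        ).reset_index()
        if wide[["pre", "post"]].isna().any().any():
            missing = wide.loc[wide[["pre", "post"]].isna().any(axis=1), "subject"]
            raise ValueError(
                f"subjects missing a session for {metric}: {missing.tolist()}"
            )
        self._wide_cache[metric] = wide
        return wide

    @staticmethod
    def from_values(
        values: dict[tuple[str, str, str], float], groups: dict[str, str]
    ) -> "Design":
        """Build from a (subject, session, metric) -> value mapping."""
        rows = [
            {
                "subject": s,
                "group": groups[s],
                "session": sess,
                "metric": m,
                "value": v,
            }
            for (s, sess, m), v in values.items()
        ]
        return Design(pd.DataFrame(rows))


def _coef_t_p(fit, idx: int) -> tuple[float, float, float]:
    """(estimate, t, p) for one coefficient, with the 0/0 case of an
    exact fit (zero residual variance) resolved to t=0, p=1 when the
    coefficient itself is zero."""
    est = float(fit.params[idx])
    t = float(fit.tvalues[idx])
    p = float(fit.pvalues[idx])
    scale = max(float(np.max(np.abs(fit.model.endog))), 1.0)
    exact_fit = fit.ssr <= 1e-20 * scale**2 * fit.nobs
    if not np.isfinite(t) or exact_fit:
        if abs(est) < 1e-8 * scale:
            t, p = 0.0, 1.0
        else:
            t, p = np.inf, 0.0
    return est, t, p


def _pooled_two_sample_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    """(t, estimate a-b, df) with pooled variance."""
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    se = np.sqrt(sp2 * (1 / na + 1 / nb))
    est = a.mean() - b.mean()
    t = est / se if se > 0 else 0.0
    return float(t), float(est), df


def synergy_rm_anova(design: Design, metric: str) -> ContrastResult:
    """Group-by-time interaction F from the 2x2 mixed-design ANOVA.

    Computed via the orthogonal decomposition of the 2x2 mixed design
    (Type-III sums of squares, exact under imbalance): the interaction
    test is the pooled two-sample t on per-subject (post - pre)
    differences, squared. ``estimate`` is the difference of group mean
    changes (drug minus placebo).
    """
    wide = design.wide(metric)
    diffs = {g: None for g in GROUPS}
    for g in GROUPS:
        d = wide.loc[wide["group"] == g]
        if len(d) < 2:
            raise ValueError(f"need >= 2 subjects in group {g}")
        diffs[g] = (d["post"] - d["pre"]).to_numpy()
    t, est, df = _pooled_two_sample_t(diffs["drug"], diffs["placebo"])
    f_stat = t**2
    p = float(stats.f.sf(f_stat, 1, df)) if np.isfinite(f_stat) else 1.0
    if f_stat == 0.0:
        p = 1.0
    return ContrastResult(
        contrast="Synergy",
        metric=metric,
        estimate=est,
        statistic=float(f_stat),
        stat_name="F",
        df=(1, df),
        p=p,
    )


def rm_anova_effects(design: Design, metric: str) -> dict[str, ContrastResult]:
    """Interaction plus both main effects of the 2x2 mixed ANOVA.

    time: unweighted mean of the two groups' mean changes against zero;
    group: pooled t on per-subject (pre+post)/2 means. All three tests
    share the between-subject error df = n - 2.
    """
    wide = design.wide(metric)
    d_drug = (wide.loc[wide["group"] == "drug", "post"]
              - wide.loc[wide["group"] == "drug", "pre"]).to_numpy()
    d_plac = (wide.loc[wide["group"] == "placebo", "post"]
              - wide.loc[wide["group"] == "placebo", "pre"]).to_numpy()
    n1, n2 = len(d_drug), len(d_plac)
    df = n1 + n2 - 2

    out = {"interaction": synergy_rm_anova(design, metric)}

    # time main effect: unweighted grand mean change (Type-III under imbalance)
    sp2_d = (((d_drug - d_drug.mean()) ** 2).sum()
             + ((d_plac - d_plac.mean()) ** 2).sum()) / df
    est_time = 0.5 * (d_drug.mean() + d_plac.mean())
    se_time = np.sqrt(sp2_d * 0.25 * (1 / n1 + 1 / n2))
    t_time = est_time / se_time if se_time > 0 else 0.0
    f_time = t_time**2
    out["time"] = ContrastResult(
        contrast="Synergy",
        metric=f"{metric}:time",
        estimate=float(est_time),
        statistic=float(f_time),
        stat_name="F",
        df=(1, df),
        p=1.0 if f_time == 0 else float(stats.f.sf(f_time, 1, df)),
    )

    m_drug = wide.loc[wide["group"] == "drug", ["pre", "post"]].mean(axis=1).to_numpy()
    m_plac = wide.loc[wide["group"] == "placebo", ["pre", "post"]].mean(axis=1).to_numpy()
    t_g, est_g, df_g = _pooled_two_sample_t(m_drug, m_plac)
    f_g = t_g**2
    out["group"] = ContrastResult(
        contrast="Synergy",
        metric=f"{metric}:group",
        estimate=est_g,
        statistic=float(f_g),
        stat_name="F",
        df=(1, df_g),
        p=1.0 if f_g == 0 else float(stats.f.sf(f_g, 1, df_g)),
    )
    return out


def ancova_group_post(design: Design, metric: str) -> ContrastResult:
    """Between-group comparison of post scores adjusting for pre scores.

    OLS fit of post ~ intercept + group + pre; reports the
    group-indicator coefficient (drug minus placebo) with df = n - 3.
    """
    wide = design.wide(metric)
    if wide["pre"].nunique() == 1:
        raise ValueError("pre scores are constant; ANCOVA covariate is degenerate")
    y = wide["post"].to_numpy()
    g = (wide["group"] == "drug").astype(float).to_numpy()
    x = sm.add_constant(np.column_stack([g, wide["pre"].to_numpy()]))
    fit = sm.OLS(y, x).fit()
    est, t, p = _coef_t_p(fit, 1)
    return ContrastResult(
        contrast="GroupPost",
        metric=metric,
        estimate=est,
        statistic=t,
        stat_name="t",
        df=(float(fit.df_resid),),
        p=p,
    )


def within_group_ancova(design: Design, metric: str, group: str) -> ContrastResult:
    """Post-vs-pre change within one group, covarying centered baseline.

    Fits (post - pre) ~ intercept + (pre - mean(pre)) within the named
    group and tests the intercept: the expected change at the group's
    average baseline. ``Meditation`` is this test on placebo,
    ``PsychMed`` on drug.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group: {group}")
    wide = design.wide(metric)
    sub = wide.loc[wide["group"] == group]
    if sub.empty:
        raise ValueError(f"group {group} absent from design")
    change = (sub["post"] - sub["pre"]).to_numpy()
    base = sub["pre"].to_numpy()
    base_c = base - base.mean()
    if np.allclose(base_c, 0):
        x = np.ones((len(change), 1))
    else:
        x = sm.add_constant(base_c)
    fit = sm.OLS(change, x).fit()
    name = "Meditation" if group == "placebo" else "PsychMed"
    est, t, p = _coef_t_p(fit, 0)
    return ContrastResult(
        contrast=name,
        metric=metric,
        estimate=est,
        statistic=t,
        stat_name="t",
        df=(float(fit.df_resid),),
        p=p,
    )


def run_contrast(design: Design, metric: str, contrast: str) -> ContrastResult:
    """Dispatch one of the four named contrasts."""
    if contrast == "Synergy":
        return synergy_rm_anova(design, metric)
    if contrast == "GroupPost":
        return ancova_group_post(design, metric)
    if contrast == "Meditation":
        return within_group_ancova(design, metric, "placebo")
    if contrast == "PsychMed":
        return within_group_ancova(design, metric, "drug")
    raise ValueError(f"unknown contrast: {contrast!r}; expected one of {CONTRAST_NAMES}")


def fdr_bh(
    p_values: np.ndarray, q_level: float = ALPHA_LEVEL
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejected mask, q-values).

    q-values are the step-up-adjusted p-values, made monotone by the
    reverse cumulative minimum; rejection is q <= q_level.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q <= q_level, q


def attach_fdr(
    results: list[ContrastResult], q_level: float = ALPHA_LEVEL
) -> list[ContrastResult]:
    """BH across one family of results; fills each ``q`` in place."""
    rej, q = fdr_bh(np.array([r.p for r in results]), q_level)
    for r, qi in zip(results, q):
        r.q = float(qi)
    return results


def parcelwise_contrast(
    maps: pd.DataFrame,
    groups: dict[str, str],
    contrast: str,
    q_level: float = ALPHA_LEVEL,
) -> pd.DataFrame:
    """One contrast per parcel, BH-FDR across all parcels.

    ``maps``: long frame with columns subject, session, parcel, value
    (e.g. global FC per parcel per scan). Returns one row per parcel
    with estimate, statistic, p, q, rejected. Parcel-level FDR stands
    in for voxel-level cluster inference, which needs smoothness
    estimates unavailable at parcel resolution.
    """
    if contrast not in CONTRAST_NAMES:
        raise ValueError(f"unknown contrast: {contrast!r}")
    long = maps.rename(columns={"parcel": "metric"})
    design = Design(
        long.assign(group=long["subject"].map(groups))[
            ["subject", "group", "session", "metric", "value"]
        ]
    )
    results = [run_contrast(design, m, contrast) for m in design.metrics]
    attach_fdr(results, q_level)
    return pd.DataFrame(
        {
            "parcel": [r.metric for r in results],
            "contrast": contrast,
            "estimate": [r.estimate for r in results],
            "statistic": [r.statistic for r in results],
            "stat": [r.stat_name for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "rejected": [r.q <= q_level for r in results],
        }
    )


@dataclass
class AssociationResult:
    """OLS brain-behavior association for one questionnaire."""

    questionnaire: str
    coef_score: float
    coef_group: float
    coef_interaction: float
    interaction_t: float
    interaction_p: float
    interaction_q: float | None
    per_group_pearson: dict[str, tuple[float, float]]
    per_group_spearman: dict[str, tuple[float, float]]


def association_ols(
    fc_change: pd.Series,
    scores: pd.DataFrame,
    groups: dict[str, str],
    delta_mode: bool = False,
    q_level: float = ALPHA_LEVEL,
) -> list[AssociationResult]:
    """fc_change ~ score + group + score x group, per questionnaire.

    ``fc_change``: per-subject scalar indexed by subject. ``scores``:
    long frame with columns subject, questionnaire, day, value; day 2 is
    the post-drug assessment, day 1 the baseline. In delta mode the
    predictor is the day-2 minus day-1 score. BH-FDR is applied across
    the questionnaire family to the interaction p-values; per-group
    Pearson and Spearman follow-up correlations are reported.
    """
    required = {"subject", "questionnaire", "day", "value"}
    if missing := required - set(scores.columns):
        raise ValueError(f"scores table missing columns: {sorted(missing)}")
    out: list[AssociationResult] = []
    for quest in sorted(scores["questionnaire"].unique()):
        sub = scores[scores["questionnaire"] == quest]
        day2 = sub[sub["day"] == 2].set_index("subject")["value"]
        if delta_mode:
            day1 = sub[sub["day"] == 1].set_index("subject")["value"]
            predictor = (day2 - day1).dropna()
        else:
            predictor = day2
        common = fc_change.index.intersection(predictor.index)
        per_group_n = pd.Series({s: groups[s] for s in common}).value_counts()
        if (per_group_n < 4).any() or len(per_group_n) < 2:
            raise ValueError(f"need >= 4 subjects per group for {quest}")
        y = fc_change.loc[common].to_numpy()
        s_vals = predictor.loc[common].to_numpy()
        g = np.array([1.0 if groups[s] == "drug" else 0.0 for s in common])
        x = np.column_stack([np.ones_like(y), s_vals, g, s_vals * g])
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError(
                f"collinear design for {quest}: score/group/interaction "
                "are not jointly estimable (e.g. scores constant within a group)"
            )
        fit = sm.OLS(y, x).fit()
        pearson: dict[str, tuple[float, float]] = {}
        spearman: dict[str, tuple[float, float]] = {}
        for grp in GROUPS:
            sel = np.array([groups[s] == grp for s in common])
            pr = stats.pearsonr(s_vals[sel], y[sel])
            sr = stats.spearmanr(s_vals[sel], y[sel])
            pearson[grp] = (float(pr.statistic), float(pr.pvalue))
            spearman[grp] = (float(sr.statistic), float(sr.pvalue))
        out.append(
            AssociationResult(
                questionnaire=quest,
                coef_score=float(fit.params[1]),
                coef_group=float(fit.params[2]),
                coef_interaction=float(fit.params[3]),
                interaction_t=float(fit.tvalues[3]),
                interaction_p=float(fit.pvalues[3]),
                interaction_q=None,
                per_group_pearson=pearson,
                per_group_spearman=spearman,
            )
        )
    _, qvals = fdr_bh(np.array([r.interaction_p for r in out]), q_level)
    for r, qi in zip(out, qvals):
        r.interaction_q = float(qi)
    return out
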