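"""Split-plot (two-way mixed-design) repeated-measures ANOVA and post-hocs.

The design is one between-subject factor (group, g levels with s subjects
each) crossed with one within-subject factor (time, t levels). The
classical partition of the total sum of squares is

    SS_total = SS_group + SS_subj(group) + SS_time + SS_group:time + SS_resid

with degrees of freedom g-1, g(s-1), t-1, (g-1)(t-1) and g(s-1)(t-1).
The group effect is tested against subject-within-group variance,
F = MS_group / MS_subj(group); time and interaction are tested against the
residual. No sphericity correction is applied by default.

Post-hoc comparisons follow Fisher's LSD convention (unadjusted pairwise
tests after the omnibus ANOVA). For a between-group comparison at a fixed
time point the appropriate error term mixes the two variance components:

    MS_cell = (MS_subj(group) + (t - 1) MS_resid) / t

with Satterthwaite degrees of freedom. Rank transformation is available for
non-parametric outcomes, and a pooled-variance unpaired t-test serves
two-sample endpoints such as histology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaEffect",
    "MixedAnovaResult",
    "PostHocRow",
    "TTestResult",
    "rank_transform",
    "mixed_anova",
    "fisher_lsd",
    "unpaired_t",
]


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    ss: float
    df: int
    ms: float
    F: float | None = None
    p: float | None = None


@dataclass
class MixedAnovaResult:
    """F/p/df for group, time and group x time, plus the error terms."""

    group: AnovaEffect
    subject_within_group: AnovaEffect
    time: AnovaEffect
    interaction: AnovaEffect
    residual: AnovaEffect
    ss_total: float
    n_groups: int
    n_subjects_per_group: int
    n_times: int
    group_labels: tuple = ()
    time_labels: tuple = ()

    def effects(self):
        return [self.group, self.subject_within_group, self.time,
                self.interaction, self.residual]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(effect=e.name, SS=e.ss, df=e.df, MS=e.ms, F=e.F, p=e.p)
                for e in self.effects()
            ]
        )

    def report(self) -> str:
        lines = []
        for e in (self.group, self.time, self.interaction):
            if e.F is None:
                continue
            err = (
                self.subject_within_group if e.name == "group" else self.residual
            )
            lines.append(
                f"{e.name}: F({e.df},{err.df}) = {e.F:.3f}, p = {e.p:.3f}"
            )
        return "\n".join(lines)


@dataclass(frozen=True)
class PostHocRow:
    """One between-group comparison at a fixed time point."""

    time: str
    mean_difference: float
    se: float
    t: float
    df: float
    p: float
    significant: bool


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def rank_transform(values):
    """Ascending ranks 1..n with midranks for ties; NaN stays NaN.

    Ranks are invariant under any strictly increasing transform of the
    inputs, which is what licenses parametric machinery on the ranks.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if not finite.any():
        raise ValueError("rank_transform requires at least one finite value")
    out = np.full(v.shape, np.nan)
    out[finite] = sps.rankdata(v[finite], method="average")
    return out


def _pivot_design(table, value_col, between, within, subject):
    """Validate balance/completeness and pivot to a (g, s, t) array."""
    t = table[[subject, between, within, value_col]].dropna(subset=[value_col])
    dup = t.duplicated([subject, within])
    if dup.any():
        raise ValueError("duplicate subject x time records")
    groups_of = t.groupby(subject)[between].nunique()
    if (groups_of > 1).any():
        bad = groups_of[groups_of > 1].index.tolist()
        raise ValueError(f"subjects in more than one group: {bad}")
    group_labels = tuple(pd.unique(t[between]))
    time_labels = tuple(pd.unique(t[within]))
    g, tt = len(group_labels), len(time_labels)
    if g < 2 or tt < 1:
        raise ValueError(f"need >= 2 groups and >= 1 time; got g={g}, t={tt}")
    cell_counts = t.groupby([between, within]).size()
    missing = [
        (gl, tl)
        for gl in group_labels
        for tl in time_labels
        if (gl, tl) not in cell_counts.index
    ]
    if missing:
        raise ValueError(f"design incomplete; empty cells: {missing}")
    wide = t.pivot(index=subject, columns=within, values=value_col)
    if wide.isna().any().any():
        bad = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"incomplete subjects (use complete_case_filter): {bad}")
    subj_group = t.drop_duplicates(subject).set_index(subject)[between]
    per_group = subj_group.value_counts()
    if per_group.nunique() > 1:
        raise ValueError(
            f"unbalanced design; subjects per group: {per_group.to_dict()}"
        )
    s = int(per_group.iloc[0])
    if s < 2:
        raise ValueError("need >= 2 subjects per group")
    Y = np.empty((g, s, tt))
    for gi, gl in enumerate(group_labels):
        members = subj_group[subj_group == gl].index
        Y[gi] = wide.loc[members, list(time_labels)].to_numpy()
    return Y, group_labels, time_labels


def mixed_anova(
    table: pd.DataFrame,
    value_col: str = "value",
    between: str = "group",
    within: str = "time",
    subject: str = "subject",
) -> MixedAnovaResult:
    """Balanced split-plot repeated-measures ANOVA.

    Requires a complete balanced design (every subject observed at every
    time, equal group sizes); incomplete or unbalanced input is rejected
    with the offending subjects or cells listed.
    """
    Y, group_labels, time_labels = _pivot_design(
        table, value_col, between, within, subject
    )
    g, s, t = Y.shape
    grand = Y.mean()
    subj_means = Y.mean(axis=2)  # (g, s)
    group_means = Y.mean(axis=(1, 2))  # (g,)
    time_means = Y.mean(axis=(0, 1))  # (t,)
    cell_means = Y.mean(axis=1)  # (g, t)

    ss_total = float(np.sum((Y - grand) ** 2))
    ss_group = float(s * t * np.sum((group_means - grand) ** 2))
    ss_between_subj = float(t * np.sum((subj_means - grand) ** 2))
    ss_subj = ss_between_subj - ss_group
    ss_time = float(g * s * np.sum((time_means - grand) ** 2))
    ss_cells = float(s * np.sum((cell_means - grand) ** 2))
    ss_inter = ss_cells - ss_group - ss_time
    ss_resid = ss_total - ss_between_subj - ss_time - ss_inter
    # guard against tiny negative round-off
    ss_subj = max(ss_subj, 0.0)
    ss_inter = max(ss_inter, 0.0)
    ss_resid = max(ss_resid, 0.0)

    df_group = g - 1
    df_subj = g * (s - 1)
    df_time = t - 1
    df_inter = (g - 1) * (t - 1)
    df_resid = g * (s - 1) * (t - 1)

    ms_group = ss_group / df_group
    ms_subj = ss_subj / df_subj
    # t = 1 degenerates to a between-subject one-way layout: the within
    # effects carry no df and are not tested
    ms_time = ss_time / df_time if df_time > 0 else 0.0
    ms_inter = ss_inter / df_inter if df_inter > 0 else 0.0
    ms_resid = ss_resid / df_resid if df_resid > 0 else 0.0

    def _test(ms, df, ms_err, df_err):
        if df == 0 or df_err == 0:
            return None, None
        if ms_err == 0:
            return (np.inf if ms > 0 else 0.0), (0.0 if ms > 0 else 1.0)
        F = ms / ms_err
        return F, float(sps.f.sf(F, df, df_err))

    F_g, p_g = _test(ms_group, df_group, ms_subj, df_subj)
    F_t, p_t = _test(ms_time, df_time, ms_resid, df_resid)
    F_i, p_i = _test(ms_inter, df_inter, ms_resid, df_resid)

    return MixedAnovaResult(
        group=AnovaEffect("group", ss_group, df_group, ms_group, F_g, p_g),
        subject_within_group=AnovaEffect(
            "subject(group)", ss_subj, df_subj, ms_subj
        ),
        time=AnovaEffect("time", ss_time, df_time, ms_time, F_t, p_t),
        interaction=AnovaEffect(
            "group:time", ss_inter, df_inter, ms_inter, F_i, p_i
        ),
        residual=AnovaEffect("residual", ss_resid, df_resid, ms_resid),
        ss_total=ss_total,
        n_groups=g,
        n_subjects_per_group=s,
        n_times=t,
        group_labels=group_labels,
        time_labels=time_labels,
    )


def fisher_lsd(
    table: pd.DataFrame,
    anova: MixedAnovaResult,
    alpha: float = 0.05,
    value_col: str = "value",
    between: str = "group",
    within: str = "time",
    subject: str = "subject",
    mode: str = "combined",
):
    """Fisher's LSD between-group comparison at each time point.

    ``mode="combined"`` (default) uses the split-plot error term appropriate
    for a between-group contrast at a fixed within level,
    ``MS_cell = (MS_subj(group) + (t-1) MS_resid) / t`` with Satterthwaite
    degrees of freedom. ``mode="ttest"`` instead runs a plain per-time
    unpaired t-test. P-values are unadjusted, per the LSD convention.
    Two-arm designs only.
    """
    if anova.n_groups != 2:
        raise ValueError("Fisher's LSD here supports exactly two groups")
    if mode not in ("combined", "ttest"):
        raise ValueError(f"unknown mode {mode!r}")
    Y, group_labels, time_labels = _pivot_design(
        table, value_col, between, within, subject
    )
    g, s, t = Y.shape
    ms_subj = anova.subject_within_group.ms
    df_subj = anova.subject_within_group.df
    ms_resid = anova.residual.ms
    df_resid = anova.residual.df
    rows = []
    for ti, tl in enumerate(time_labels):
        a, b = Y[0, :, ti], Y[1, :, ti]
        diff = float(a.mean() - b.mean())
        if mode == "ttest":
            res = unpaired_t(a, b)
            tval, dfc, p = res.t, res.df, res.p
            se = (
                abs(diff / tval)
                if tval not in (0.0,) and np.isfinite(tval)
                else float("nan")
            )
        else:
            ms_cell = (ms_subj + (t - 1) * ms_resid) / t
            se = float(np.sqrt(ms_cell * (1.0 / s + 1.0 / s)))
            num = (ms_subj + (t - 1) * ms_resid) ** 2
            den = ms_subj**2 / df_subj
            if df_resid > 0:
                den += ((t - 1) * ms_resid) ** 2 / df_resid
            dfc = float(num / den) if den > 0 else float(df_subj + df_resid)
            if se == 0:
                tval = 0.0 if diff == 0 else np.inf * np.sign(diff)
                p = 1.0 if diff == 0 else 0.0
            else:
                tval = diff / se
                p = float(2 * sps.t.sf(abs(tval), dfc))
        rows.append(
            PostHocRow(
                time=str(tl),
                mean_difference=diff,
                se=se,
                t=float(tval),
                df=float(dfc),
                p=float(p),
                significant=bool(p < alpha),
            )
        )
    return rows


def unpaired_t(a, b) -> TTestResult:
    """Pooled-variance two-sided two-sample t-test.

    Degenerate zero-variance inputs are resolved explicitly: equal means
    give p = 1; unequal means give p = 0 with a degenerate flag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs n >= 2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return TTestResult(0.0, df, 1.0, degenerate=True)
        return TTestResult(float(np.sign(diff) * np.inf), df, 0.0, degenerate=True)
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = float(2 * sps.t.sf(abs(t), df))
    return TTestResult(float(t), float(df), p)
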