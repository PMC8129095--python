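"""Slice classification and group statistics for the excitability study.

Slices are classified per concentration: any IID means "interictal activity";
otherwise more spikes than the wild-type mean + 2 SD threshold means "high
spikes"; otherwise "no abnormal activity".  Group comparisons use two-way
mixed ANOVA (between: genotype; within: agonist concentration; subject:
slice), with a log10 or joint-rank transform when a Shapiro-Wilk gate flags
non-normality, Tukey HSD post-hoc tests, and t / Mann-Whitney two-group
tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "INTERICTAL",
    "HIGH_SPIKES",
    "NO_ABNORMAL",
    "AnovaResult",
    "high_spike_threshold",
    "classify_slice",
    "classify_cohort",
    "proportion_table",
    "shapiro_gate",
    "mixed_anova",
    "tukey_hsd",
    "two_group_test",
]

INTERICTAL = "interictal_activity"
HIGH_SPIKES = "high_spikes"
NO_ABNORMAL = "no_abnormal_activity"


def high_spike_threshold(wt_counts) -> float:
    """Mean + 2 sample SDs (n-1) of wild-type spike counts at one concentration."""
    counts = np.asarray(wt_counts, dtype=float)
    if len(counts) < 2:
        raise ValueError("need at least 2 wild-type counts to form a threshold")
    return float(counts.mean() + 2.0 * counts.std(ddof=1))


def classify_slice(iid_count: int, spike_count: int, threshold: float) -> str:
    """Classification precedence: any IID wins; then strictly more spikes
    than the threshold; else no abnormal activity."""
    if iid_count < 0 or spike_count < 0:
        raise ValueError("counts must be non-negative")
    if iid_count >= 1:
        return INTERICTAL
    if spike_count > threshold:
        return HIGH_SPIKES
    return NO_ABNORMAL


def classify_cohort(summary: pd.DataFrame, wt_label: str = "WT") -> pd.DataFrame:
    """Classify every slice x concentration row of a cohort summary.

    ``summary`` needs columns genotype, ka_nm, spike_count, iid_count.
    Thresholds are computed from the wild-type slices at each concentration.
    Returns a copy with ``threshold`` and ``slice_class`` columns.
    """
    out = summary.copy()
    thresholds = (out[out["genotype"] == wt_label]
                  .groupby("ka_nm")["spike_count"]
                  .apply(lambda c: high_spike_threshold(c.to_numpy())))
    out["threshold"] = out["ka_nm"].map(thresholds)
    out["slice_class"] = [
        classify_slice(int(r.iid_count), int(r.spike_count), r.threshold)
        for r in out.itertuples()
    ]
    return out


def proportion_table(classified: pd.DataFrame) -> pd.DataFrame:
    """Per genotype x concentration proportions of the three slice classes."""
    counts = (classified.groupby(["genotype", "ka_nm", "slice_class"])
              .size().unstack("slice_class", fill_value=0))
    for label in (INTERICTAL, HIGH_SPIKES, NO_ABNORMAL):
        if label not in counts.columns:
            counts[label] = 0
    counts = counts[[INTERICTAL, HIGH_SPIKES, NO_ABNORMAL]]
    totals = counts.sum(axis=1)
    props = counts.div(totals, axis=0)
    props["n"] = totals
    return props.reset_index()


def shapiro_gate(values) -> str:
    """Route a sample to parametric/non-parametric analysis.

    'non_normal' iff Shapiro-Wilk p <= 0.05; degenerate (constant) samples
    are routed non_normal.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(x) == 0:
        return "non_normal"
    with np.errstate(all="ignore"):
        p = _stats.shapiro(x).pvalue
    return "non_normal" if p <= 0.05 else "normal"


@dataclass
class AnovaResult:
    """Mixed-ANOVA effects table plus the transform that was applied."""

    table: pd.DataFrame  # index: between/within/interaction; F, df1, df2, p
    transform: str

    def pvalue(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])

    def summary(self) -> str:
        lines = [f"Two-way mixed ANOVA (transform={self.transform})",
                 f"{'effect':<14}{'F':>10}{'df1':>6}{'df2':>6}{'p':>12}"]
        for effect, row in self.table.iterrows():
            lines.append(f"{effect:<14}{row['F']:>10.4f}{int(row['df1']):>6}"
                         f"{int(row['df2']):>6}{row['p']:>12.4g}")
        return "\n".join(lines)


def _dummies(codes: np.ndarray) -> np.ndarray:
    """Drop-first indicator matrix for an integer-coded factor."""
    levels = np.unique(codes)
    return (codes[:, None] == levels[None, 1:]).astype(float)


def _sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def mixed_anova(data: pd.DataFrame, dv: str, between: str = "genotype",
                within: str = "ka_nm", subject: str = "slice_id",
                transform: str = "none") -> AnovaResult:
    """Two-way mixed ANOVA with subjects nested in the between factor.

    The between effect is tested against the subject-within-group stratum;
    the within and interaction effects against the residual.  Sums of squares
    are sequential (subjects, then within, then interaction), which reduces
    to the classical partition on balanced data and degrades gracefully when
    the clear-gamma gate removes individual subject x level cells.

    ``transform``: 'none', 'log10' (requires a positive dv) or 'rank'
    (joint mid-ranks over all observations, so the result is invariant to any
    strictly monotone transform of the dv).
    """
    if transform not in {"none", "log10", "rank"}:
        raise ValueError(f"unknown transform {transform!r}")
    df = data[[dv, between, within, subject]].dropna().copy()
    geno_per_subject = df.groupby(subject)[between].nunique()
    if (geno_per_subject > 1).any():
        raise ValueError("a subject appears in more than one between-group level")
    y = df[dv].to_numpy(dtype=float)
    if transform == "log10":
        if np.any(y <= 0):
            raise ValueError("log10 transform requires a strictly positive dv")
        y = np.log10(y)
    elif transform == "rank":
        y = _stats.rankdata(y)

    g = pd.factorize(df[between])[0]
    k = pd.factorize(df[within])[0]
    s = pd.factorize(df[subject])[0]
    n_g, n_k, n_s, n = len(np.unique(g)), len(np.unique(k)), len(np.unique(s)), len(y)

    intercept = np.ones((n, 1))
    Xg = _dummies(g)
    Xs = _dummies(s)  # spans the genotype space (subjects nested in genotype)
    Xk = _dummies(k)
    Xgk = np.column_stack([Xg[:, i] * Xk[:, j]
                           for i in range(Xg.shape[1])
                           for j in range(Xk.shape[1])]) if n_g > 1 and n_k > 1 else np.empty((n, 0))

    sst = float(((y - y.mean()) ** 2).sum())
    sse_g = _sse(np.hstack([intercept, Xg]), y)
    sse_s = _sse(np.hstack([intercept, Xs]), y)
    sse_sk = _sse(np.hstack([intercept, Xs, Xk]), y)
    sse_full = _sse(np.hstack([intercept, Xs, Xk, Xgk]), y)

    ss_between = sst - sse_g
    ss_subj = sse_g - sse_s
    ss_within = sse_s - sse_sk
    ss_inter = sse_sk - sse_full
    ss_resid = sse_full

    df_between = n_g - 1
    df_subj = n_s - n_g
    df_within = n_k - 1
    df_inter = (n_g - 1) * (n_k - 1)
    df_resid = n - n_s - df_within - df_inter
    if df_subj <= 0 or df_resid <= 0:
        raise ValueError("not enough subjects/observations for the error strata")

    def f_and_p(ss_eff, df_eff, ss_err, df_err):
        ms_err = ss_err / df_err
        ms_eff = ss_eff / df_eff
        if ms_err <= 0:
            return (0.0, 1.0) if ms_eff <= 0 else (np.inf, 0.0)
        f = ms_eff / ms_err
        return float(f), float(_stats.f.sf(f, df_eff, df_err))

    rows = {}
    for name, (ss_eff, df_eff, ss_err, df_err) in {
        "between": (ss_between, df_between, ss_subj, df_subj),
        "within": (ss_within, df_within, ss_resid, df_resid),
        "interaction": (ss_inter, df_inter, ss_resid, df_resid),
    }.items():
        f, p = f_and_p(ss_eff, df_eff, ss_err, df_err)
        rows[name] = {"SS": max(ss_eff, 0.0), "F": f, "df1": df_eff,
                      "df2": df_err, "p": p}
    table = pd.DataFrame(rows).T[["SS", "F", "df1", "df2", "p"]]
    return AnovaResult(table=table, transform=transform)


def tukey_hsd(groups: dict[str, np.ndarray] | list[np.ndarray]) -> pd.DataFrame:
    """Studentised-range pairwise comparisons; symmetric in group order.

    Returns a long table (group_a, group_b, p_adj).
    """
    if isinstance(groups, dict):
        names = list(groups)
        arrays = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        arrays = [np.asarray(a, dtype=float) for a in groups]
        names = [f"group{i}" for i in range(len(arrays))]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least 2 observations")
    res = _stats.tukey_hsd(*arrays)
    rows = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        rows.append({"group_a": names[i], "group_b": names[j],
                     "p_adj": float(res.pvalue[i, j])})
    return pd.DataFrame(rows)


def two_group_test(values_a, values_b, paired: bool = False,
                   method: str = "auto") -> tuple[float, float, str]:
    """Two-sided two-group comparison with a normality gate.

    ``method='auto'`` runs Student's t-test when both samples pass the
    Shapiro-Wilk gate, otherwise Mann-Whitney U (Wilcoxon signed-rank when
    paired).  Explicit ``method`` in {'ttest', 'mannwhitney'} overrides the
    gate.  Returns (statistic, p, test_name).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    if method == "auto":
        # samples too small for the normality gate default to the t-test
        normal = all(len(x) < 3 or shapiro_gate(x) == "normal"
                     for x in (a, b))
        method = "ttest" if normal else "mannwhitney"
    if method == "ttest":
        if paired:
            res = _stats.ttest_rel(a, b)
        else:
            res = _stats.ttest_ind(a, b)
        name = "ttest"
    elif method == "mannwhitney":
        if paired:
            res = _stats.wilcoxon(a, b)
            name = "wilcoxon"
        else:
            res = _stats.mannwhitneyu(a, b, alternative="two-sided",
                                      method="asymptotic")
            name = "mannwhitney"
    else:
        raise ValueError(f"unknown method {method!r}")
    p = float(res.pvalue)
    if np.isnan(p):  # degenerate, e.g. both groups constant and equal
        p = 1.0
    return float(res.statistic), p, name
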