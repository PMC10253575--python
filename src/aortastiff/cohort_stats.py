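"""Case-control statistics: normality-gated group comparisons, correlation
matrices, ROC analysis with the Youden-optimal threshold, and assembly of a
full study report.

Conventions mirror standard clinical reporting: continuous variables are
summarized as mean +/- SD and compared by unpaired t test when both groups
pass Shapiro-Wilk normality (alpha = 0.05), otherwise as median [IQR] with
the Wilcoxon rank-sum (Mann-Whitney) test; categorical variables use
Fisher's exact test.  No multiple-testing correction is applied.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .errors import InvalidArgumentError

__all__ = [
    "GroupComparison",
    "ROCResult",
    "CorrelationMatrix",
    "StudyReport",
    "compare_groups",
    "compare_paired",
    "correlation_matrix",
    "roc_analysis",
    "study_report",
]

_ALPHA = 0.05

#: Measures where a *lower* value indicates disease (stiffer aorta); their
#: ROC scores are negated so that "higher score = more likely patient".
LOWER_IS_STIFFER = frozenset({"distensibility"})


def _fmt_mean_sd(x: np.ndarray) -> str:
    return f"{np.mean(x):.2f} ± {np.std(x, ddof=1):.2f}"


def _fmt_median_iqr(x: np.ndarray) -> str:
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    return f"{med:.2f} [{q25:.2f}–{q75:.2f}]"


@dataclass(frozen=True)
class GroupComparison:
    """One Table-1-style row: per-group summary, test used, p-value."""

    measure: str
    summaries: dict[str, str]
    test: str                 # "t" | "wilcoxon" | "fisher" | "none"
    p_value: float
    normal: bool | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise InvalidArgumentError("p-value outside [0, 1]")


def compare_groups(x, y, kind: str = "continuous", measure: str = "",
                   labels: tuple[str, str] = ("CAD", "control"),
                   alpha: float = _ALPHA) -> GroupComparison:
    """Compare two groups with the normality-gated test family.

    For ``kind="continuous"``, ``x`` and ``y`` are the per-group samples
    (>= 3 each).  For ``kind="categorical"``, ``x`` is a 2x2 count table
    and ``y`` is ignored.
    """
    if kind == "categorical":
        table = np.asarray(x, int)
        if table.shape != (2, 2):
            raise InvalidArgumentError("categorical comparison needs a 2x2 table")
        _, p = stats.fisher_exact(table)
        summaries = {labels[0]: f"{table[0, 0]}/{table[0].sum()}",
                     labels[1]: f"{table[1, 0]}/{table[1].sum()}"}
        return GroupComparison(measure=measure, summaries=summaries,
                               test="fisher", p_value=float(p))

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 3 or y.size < 3:
        raise InvalidArgumentError("need >= 3 observations per group")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return GroupComparison(
            measure=measure,
            summaries={labels[0]: _fmt_mean_sd(x), labels[1]: _fmt_mean_sd(y)},
            test="none", p_value=float("nan"))
    normal = (stats.shapiro(x).pvalue >= alpha
              and stats.shapiro(y).pvalue >= alpha)
    if normal:
        res = stats.ttest_ind(x, y, equal_var=True)
        summaries = {labels[0]: _fmt_mean_sd(x), labels[1]: _fmt_mean_sd(y)}
        return GroupComparison(measure=measure, summaries=summaries,
                               test="t", p_value=float(res.pvalue), normal=True)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    summaries = {labels[0]: _fmt_median_iqr(x), labels[1]: _fmt_median_iqr(y)}
    return GroupComparison(measure=measure, summaries=summaries,
                           test="wilcoxon", p_value=float(res.pvalue),
                           normal=False)


def compare_paired(x, y, measure: str = "", alpha: float = _ALPHA
                   ) -> GroupComparison:
    """Within-subject comparison of two methods: paired t test when the
    differences pass normality, Wilcoxon signed-rank otherwise."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise InvalidArgumentError("need >= 3 complete pairs")
    d = x - y
    if np.ptp(d) == 0:
        return GroupComparison(measure=measure,
                               summaries={"diff": _fmt_mean_sd(d)},
                               test="none", p_value=float("nan"))
    if stats.shapiro(d).pvalue >= alpha:
        res = stats.ttest_rel(x, y)
        return GroupComparison(measure=measure,
                               summaries={"diff": _fmt_mean_sd(d)},
                               test="paired-t", p_value=float(res.pvalue),
                               normal=True)
    res = stats.wilcoxon(x, y)
    return GroupComparison(measure=measure,
                           summaries={"diff": _fmt_median_iqr(d)},
                           test="signed-rank", p_value=float(res.pvalue),
                           normal=False)


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise-complete correlation matrix with p-values and the method
    used per cell ("spearman" or "pearson"; "undefined" for all-tied)."""

    labels: tuple[str, ...]
    coef: pd.DataFrame
    p_values: pd.DataFrame
    method: pd.DataFrame


def correlation_matrix(table: pd.DataFrame, method: str = "spearman",
                       alpha: float = _ALPHA, min_pairs: int = 4
                       ) -> CorrelationMatrix:
    """Correlation matrix over the columns of ``table``.

    ``method="spearman"`` (default, the convention for the stiffness
    panel), ``"pearson"``, or ``"auto"`` (Pearson when both margins pass
    Shapiro-Wilk normality on the pairwise-complete subset, Spearman
    otherwise).  Missing values are handled pairwise-complete.
    """
    cols = tuple(table.columns)
    k = len(cols)
    coef = np.eye(k)
    pval = np.zeros((k, k))
    used = np.full((k, k), "", object)
    np.fill_diagonal(used, "-")
    for i in range(k):
        for j in range(i + 1, k):
            sub = table[[cols[i], cols[j]]].dropna()
            x = sub.iloc[:, 0].to_numpy(float)
            y = sub.iloc[:, 1].to_numpy(float)
            if x.size < min_pairs:
                c, p, m = np.nan, np.nan, "insufficient"
            elif np.ptp(x) == 0 or np.ptp(y) == 0:
                c, p, m = np.nan, np.nan, "undefined"
            else:
                m = method
                if method == "auto":
                    m = ("pearson"
                         if stats.shapiro(x).pvalue >= alpha
                         and stats.shapiro(y).pvalue >= alpha else "spearman")
                if m == "pearson":
                    r = stats.pearsonr(x, y)
                else:
                    r = stats.spearmanr(x, y)
                c, p = float(r.statistic), float(r.pvalue)
            coef[i, j] = coef[j, i] = c
            pval[i, j] = pval[j, i] = p
            used[i, j] = used[j, i] = m
    return CorrelationMatrix(
        labels=cols,
        coef=pd.DataFrame(coef, index=cols, columns=cols),
        p_values=pd.DataFrame(pval, index=cols, columns=cols),
        method=pd.DataFrame(used, index=cols, columns=cols))


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC with the Youden-optimal operating point.

    ``threshold`` is an observed score value; a subject is called positive
    when its (oriented) score is >= threshold.  ``direction`` records the
    orientation on the original measurement scale.
    """

    auc: float
    threshold: float
    sensitivity: float        # %
    specificity: float        # %
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    direction: str = ">="

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise InvalidArgumentError("AUC outside [0, 1]")
        for v in (self.sensitivity, self.specificity):
            if not 0.0 <= v <= 100.0:
                raise InvalidArgumentError("sens/spec outside [0, 100]%")


def roc_analysis(scores, labels, positive=1) -> ROCResult:
    """Empirical ROC analysis with Youden-optimal threshold.

    AUC is computed by the trapezoidal rule over the full empirical curve
    (equal to the tie-corrected Mann-Whitney U statistic divided by
    n1*n2).  The optimal threshold maximizes Youden's J = sensitivity +
    specificity - 1; ties are broken toward the lower threshold (the more
    sensitive rule).  Higher scores must indicate the positive class.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    ok = np.isfinite(scores)
    scores, labels = scores[ok], labels[ok]
    y = (labels == positive).astype(int)
    if y.sum() == 0 or y.sum() == y.size:
        raise InvalidArgumentError("ROC needs both classes present")
    fpr, tpr, thr = roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    finite = np.isfinite(thr)
    j_max = j[finite].max()
    cand = np.where(finite & (j >= j_max - 1e-12))[0]
    best = cand[np.argmin(thr[cand])]
    return ROCResult(auc=auc, threshold=float(thr[best]),
                     sensitivity=float(100.0 * tpr[best]),
                     specificity=float(100.0 * (1.0 - fpr[best])),
                     fpr=fpr, tpr=tpr, thresholds=thr)


@dataclass
class StudyReport:
    """Structured full-study output: group comparisons, ROC block for the
    four stiffness measures, stiffness correlation matrix, and correlations
    of the multi-plane PWV with clinical covariates."""

    comparisons: list[GroupComparison] = field(default_factory=list)
    roc: dict[str, ROCResult] = field(default_factory=dict)
    stiffness_correlations: CorrelationMatrix | None = None
    covariate_correlations: dict[str, dict[str, tuple[float, float, str]]] = \
        field(default_factory=dict)
    groups: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out: dict = {"groups": self.groups, "comparisons": [], "roc": {}}
        for c in self.comparisons:
            out["comparisons"].append({
                "measure": c.measure, "summaries": c.summaries,
                "test": c.test, "p_value": _r(c.p_value)})
        for name, r in self.roc.items():
            out["roc"][name] = {
                "auc": _r(r.auc), "threshold": _r(r.threshold),
                "sensitivity_pct": _r(r.sensitivity),
                "specificity_pct": _r(r.specificity),
                "direction": r.direction}
        if self.stiffness_correlations is not None:
            cm = self.stiffness_correlations
            out["stiffness_correlations"] = {
                "labels": list(cm.labels),
                "rho": [[_r(v) for v in row] for row in cm.coef.to_numpy()],
                "p": [[_r(v) for v in row] for row in cm.p_values.to_numpy()]}
        out["covariate_correlations"] = {
            scope: {cov: {"coef": _r(c), "p": _r(p), "method": m}
                    for cov, (c, p, m) in d.items()}
            for scope, d in self.covariate_correlations.items()}
        return out

    def render_text(self) -> str:
        lines = ["Study report", "============", ""]
        lines.append("Group comparisons")
        for c in self.comparisons:
            parts = "  ".join(f"{g}: {s}" for g, s in c.summaries.items())
            lines.append(f"  {c.measure:<18} {parts}  [{c.test}] p={c.p_value:.4g}")
        lines.append("")
        lines.append("ROC analysis (patients vs controls)")
        lines.append(f"  {'measure':<18}{'threshold':>10}{'AUC':>7}"
                     f"{'sens%':>8}{'spec%':>8}")
        for name, r in self.roc.items():
            thr = r.threshold if r.direction == ">=" else -r.threshold
            lines.append(f"  {name:<18}{thr:>10.2f}{r.auc:>7.2f}"
                         f"{r.sensitivity:>8.1f}{r.specificity:>8.1f}"
                         f"   (positive if {r.direction} threshold)")
        if self.stiffness_correlations is not None:
            lines.append("")
            lines.append("Stiffness correlation matrix (Spearman rho)")
            lines.append(self.stiffness_correlations.coef.round(2).to_string())
        if self.covariate_correlations:
            lines.append("")
            lines.append("Multi-plane PWV vs covariates (coef, p)")
            for scope, d in self.covariate_correlations.items():
                row = "  ".join(f"{cov}: {c:+.2f} (p={p:.3g}, {m})"
                                for cov, (c, p, m) in d.items())
                lines.append(f"  {scope:<10} {row}")
        return "\n".join(lines) + "\n"


def _r(v, nd=6):
    return None if v is None or not np.isfinite(v) else round(float(v), nd)


_MEASURES = ("cf_pwv", "pwv_2d", "pwv_4d", "distensibility")
_COVARIATES = ("age", "lvmi", "infarcted_segments")


def study_report(table: pd.DataFrame, group_col: str = "group",
                 positive_group: str = "CAD",
                 measures: tuple[str, ...] = _MEASURES) -> StudyReport:
    """Full case-control analysis of a cohort panel table.

    ``table`` needs a group column plus the stiffness-measure columns;
    covariate columns (age, lvmi, infarcted_segments) are analyzed when
    present.  Raises on an empty group: a case-control analysis with one
    group is not meaningful.
    """
    groups = table[group_col].unique().tolist()
    if positive_group not in groups or len(groups) < 2:
        raise InvalidArgumentError(
            f"need both groups present, found {groups}")
    neg = [g for g in groups if g != positive_group][0]
    pos_tab = table[table[group_col] == positive_group]
    neg_tab = table[table[group_col] == neg]
    if len(pos_tab) < 3 or len(neg_tab) < 3:
        raise InvalidArgumentError("need >= 3 subjects per group")

    report = StudyReport(groups={positive_group: len(pos_tab), neg: len(neg_tab)})

    for m in measures:
        if m not in table.columns:
            continue
        report.comparisons.append(compare_groups(
            pos_tab[m].dropna(), neg_tab[m].dropna(), measure=m,
            labels=(positive_group, neg)))

    y = (table[group_col] == positive_group).astype(int).to_numpy()
    for m in measures:
        if m not in table.columns:
            continue
        sign = -1.0 if m in LOWER_IS_STIFFER else 1.0
        scores = sign * table[m].to_numpy(float)
        res = roc_analysis(scores, y, positive=1)
        if sign < 0:
            res = ROCResult(auc=res.auc, threshold=-res.threshold,
                            sensitivity=res.sensitivity,
                            specificity=res.specificity, fpr=res.fpr,
                            tpr=res.tpr, thresholds=res.thresholds,
                            direction="<=")
        report.roc[m] = res

    present = [m for m in measures if m in table.columns]
    if len(present) >= 2:
        report.stiffness_correlations = correlation_matrix(
            table[present], method="spearman")

    covs = [c for c in _COVARIATES if c in table.columns]
    if covs and "pwv_4d" in table.columns:
        for scope, sub in (("pooled", table), (positive_group, pos_tab),
                           (neg, neg_tab)):
            d: dict[str, tuple[float, float, str]] = {}
            for cov in covs:
                pair = sub[["pwv_4d", cov]].dropna()
                if len(pair) < 4 or pair[cov].nunique() < 2:
                    continue
                cm = correlation_matrix(pair, method="auto")
                d[cov] = (float(cm.coef.iloc[0, 1]),
                          float(cm.p_values.iloc[0, 1]),
                          str(cm.method.iloc[0, 1]))
            report.covariate_correlations[scope] = d
    return report
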