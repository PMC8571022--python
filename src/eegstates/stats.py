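"""Group-level statistics on per-subject microstate parameters.

The battery mirrors a standard clinical-EEG workflow: a Shapiro-Wilk
normality gate choosing between the pooled-variance independent t-test and
the Mann-Whitney U test for every group comparison; Pearson correlation and
OLS regression of parameters against symptom severity; ANCOVA
(group x severity interaction) for parameters that correlate; and
observed-versus-expected transition tests with multiplicity adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .containers import MicrostateParameters, TestResult, TransitionTable

__all__ = [
    "SubjectRecord",
    "cohens_d",
    "normality_gated_compare",
    "pearson_with_p",
    "simple_regression",
    "ancova_group_interaction",
    "compare_observed_expected_transitions",
    "compare_transitions_between_groups",
    "adjust_pvalues",
    "group_comparison_report",
    "CLASS_NAMES",
    "PARAM_FAMILIES",
]

CLASS_NAMES = ("A", "B", "C", "D")
PARAM_FAMILIES = ("duration", "occurrence", "coverage")


@dataclass
class SubjectRecord:
    """One subject's parameters plus clinical metadata."""

    subject_id: str
    group: str  # "RBD" or "HC"
    rbdqhk_score: float  # 0-100 severity questionnaire total
    age: float
    sex: str
    parameters: MicrostateParameters
    transitions: TransitionTable | None = None

    def __post_init__(self) -> None:
        if not self.group:
            raise ValueError("group must be non-empty")
        if not 0 <= self.rbdqhk_score <= 100:
            raise ValueError("severity score must lie in [0, 100]")

    def parameter(self, family: str, class_idx: int) -> float:
        if family == "duration":
            return float(self.parameters.duration_ms[class_idx])
        if family == "occurrence":
            return float(self.parameters.occurrence_per_s[class_idx])
        if family == "coverage":
            return float(self.parameters.coverage_pct[class_idx])
        raise KeyError(family)


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with the pooled SD weighted by (n_x - 1, n_y - 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled SD")
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def normality_gated_compare(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.05, welch: bool = False
) -> TestResult:
    """Shapiro-Wilk-gated two-sample comparison.

    Both samples are tested for normality; if both pass at ``alpha`` the
    comparison is a two-sided independent t-test (pooled variance unless
    ``welch``), otherwise a two-sided asymptotic Mann-Whitney U. Constant
    samples (Shapiro-Wilk undefined) fall through to Mann-Whitney and are
    flagged in the test name.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs >= 3 observations")
    gate_ok = True
    flag = ""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        # Shapiro-Wilk is undefined on constant data
        gate_ok = False
        flag = "+constant-sample"
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pw_x = scipy.stats.shapiro(x).pvalue
                pw_y = scipy.stats.shapiro(y).pvalue
            if not (np.isfinite(pw_x) and np.isfinite(pw_y)):
                raise ValueError
            gate_ok = pw_x >= alpha and pw_y >= alpha
        except ValueError:
            gate_ok = False
            flag = "+constant-sample"
    if gate_ok:
        res = scipy.stats.ttest_ind(x, y, equal_var=not welch)
        name = "welch-t" if welch else "student-t"
    else:
        res = scipy.stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        name = "mann-whitney" + flag
    try:
        d = cohens_d(x, y)
    except ValueError:
        d = np.nan
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_name=name,
        effect_size=d,
        n_per_group=(len(x), len(y)),
    )


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Pearson r with the two-sided t-distribution p-value (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r, p = scipy.stats.pearsonr(x, y)
    return TestResult(statistic=float(r), p_value=float(p), test_name="pearson")


def simple_regression(y: np.ndarray, x: np.ndarray) -> TestResult:
    """OLS of y on x; reports the slope and its two-sided t-test p-value."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0:
        raise ValueError("degenerate design: x is constant")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    resid_sw = np.nan
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            resid_sw = float(scipy.stats.shapiro(fit.resid).pvalue)
    except ValueError:
        pass
    return TestResult(
        statistic=float(fit.params[1]),
        p_value=float(fit.pvalues[1]),
        test_name="ols-slope",
        extra={
            "intercept": float(fit.params[0]),
            "r_squared": float(fit.rsquared),
            "t_slope": float(fit.tvalues[1]),
            "resid_shapiro_p": resid_sw,
            "max_leverage": float(np.max(fit.get_influence().hat_matrix_diag)),
        },
    )


def ancova_group_interaction(
    y: np.ndarray, x: np.ndarray, group: np.ndarray
) -> TestResult:
    """ANCOVA testing whether the y~x slope differs between groups.

    Fits y ~ group + x + group:x and reports the F statistic and p-value of
    the interaction term; main effects are carried in ``extra``.
    """
    df = pd.DataFrame({"y": np.asarray(y, float), "x": np.asarray(x, float), "g": group})
    groups = df["g"].unique()
    if len(groups) < 2:
        raise ValueError("ANCOVA needs at least two groups")
    for g_ in groups:
        sub = df[df["g"] == g_]
        if len(sub) < 3:
            raise ValueError(f"group {g_} has fewer than 3 subjects")
        if sub["x"].std() == 0:
            raise ValueError(f"group {g_} has zero variance in the covariate")
    fit = smf.ols("y ~ C(g) * x", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    row = table.loc["C(g):x"]
    return TestResult(
        statistic=float(row["F"]),
        p_value=float(row["PR(>F)"]),
        test_name="ancova-interaction",
        extra={
            "F_group": float(table.loc["C(g)", "F"]),
            "p_group": float(table.loc["C(g)", "PR(>F)"]),
            "F_x": float(table.loc["x", "F"]),
            "p_x": float(table.loc["x", "PR(>F)"]),
        },
    )


def adjust_pvalues(p_list, method: str = "holm") -> np.ndarray:
    """Multiple-testing adjustment: 'holm' (default), 'bonferroni' or 'bh'."""
    p = np.asarray(p_list, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"holm": "holm", "bonferroni": "bonferroni", "bh": "fdr_bh"}[method]
    return multipletests(p, method=key)[1]


def _offdiag_pairs(K: int):
    return [(i, j) for i in range(K) for j in range(K) if i != j]


def compare_observed_expected_transitions(
    records: list[SubjectRecord],
    paired: bool = False,
    adjust: str = "holm",
) -> pd.DataFrame:
    """Test, per ordered class pair, observed vs null-expected percentages.

    For each pair the subjects' observed percentages are compared against
    their expected-under-independence percentages with an unpaired t-test
    (the conventional reporting; a paired t-test is available via
    ``paired=True``). Cohen's d and adjusted p-values are attached.
    """
    recs = [r for r in records if r.transitions is not None]
    if len(recs) < 2:
        raise ValueError("need at least 2 subjects with transition tables")
    K = recs[0].transitions.n_classes
    rows = []
    for i, j in _offdiag_pairs(K):
        obs = np.array([r.transitions.observed_pct[i, j] for r in recs])
        exp = np.array([r.transitions.expected_pct[i, j] for r in recs])
        if np.any(~np.isfinite(obs)) or np.any(~np.isfinite(exp)):
            raise ValueError(f"missing transition cell ({i},{j})")
        if paired:
            t, p = scipy.stats.ttest_rel(obs, exp)
        else:
            t, p = scipy.stats.ttest_ind(obs, exp, equal_var=True)
        rows.append(
            {
                "from": CLASS_NAMES[i] if K <= 4 else str(i),
                "to": CLASS_NAMES[j] if K <= 4 else str(j),
                "observed_mean": obs.mean(),
                "expected_mean": exp.mean(),
                "t": float(t),
                "p": float(p),
                "cohens_d": cohens_d(obs, exp),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = adjust_pvalues(out["p"].to_numpy(), method=adjust)
    return out


def compare_transitions_between_groups(
    records: list[SubjectRecord],
    group_a: str = "RBD",
    group_b: str = "HC",
    adjust: str = "holm",
) -> pd.DataFrame:
    """Between-group comparison of observed transition percentages per cell,
    with the normality-gated test and multiplicity adjustment."""
    a = [r for r in records if r.group == group_a and r.transitions is not None]
    b = [r for r in records if r.group == group_b and r.transitions is not None]
    if not a or not b:
        raise ValueError("both groups must have transition tables")
    K = a[0].transitions.n_classes
    rows = []
    for i, j in _offdiag_pairs(K):
        xa = np.array([r.transitions.observed_pct[i, j] for r in a])
        xb = np.array([r.transitions.observed_pct[i, j] for r in b])
        res = normality_gated_compare(xa, xb)
        rows.append(
            {
                "from": CLASS_NAMES[i] if K <= 4 else str(i),
                "to": CLASS_NAMES[j] if K <= 4 else str(j),
                f"mean_{group_a}": xa.mean(),
                f"mean_{group_b}": xb.mean(),
                "test": res.test_name,
                "statistic": res.statistic,
                "p": res.p_value,
                "cohens_d": res.effect_size,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = adjust_pvalues(out["p"].to_numpy(), method=adjust)
    return out


@dataclass
class GroupReport:
    """Tidy results of the full statistical battery."""

    parameters: pd.DataFrame
    correlations: pd.DataFrame
    regressions: pd.DataFrame
    ancova: pd.DataFrame
    transitions_vs_expected: dict[str, pd.DataFrame] = field(default_factory=dict)
    transitions_between_groups: pd.DataFrame | None = None


def group_comparison_report(
    records: list[SubjectRecord],
    group_a: str = "RBD",
    group_b: str = "HC",
    alpha: float = 0.05,
    adjust: str = "holm",
) -> GroupReport:
    """Run the full battery over a cohort of subject records.

    - the 12 parameter cells (4 classes x duration/occurrence/coverage)
      compared between groups through the normality gate;
    - pooled Pearson correlation of every parameter with the severity
      score, plus within-group OLS regressions;
    - ANCOVA (group x score interaction) for parameters whose pooled
      correlation is significant at ``alpha``;
    - observed-vs-expected transition tests within each group and the
      between-group observed-transition comparison, Holm-adjusted.
    """
    ga = [r for r in records if r.group == group_a]
    gb = [r for r in records if r.group == group_b]
    if not ga or not gb:
        raise ValueError(f"both groups required; got {len(ga)} {group_a}, {len(gb)} {group_b}")

    param_rows, corr_rows, reg_rows, anc_rows = [], [], [], []
    scores = np.array([r.rbdqhk_score for r in records], dtype=float)
    for family in PARAM_FAMILIES:
        for ci, cname in enumerate(CLASS_NAMES):
            xa = np.array([r.parameter(family, ci) for r in ga])
            xb = np.array([r.parameter(family, ci) for r in gb])
            res = normality_gated_compare(xa, xb, alpha=alpha)
            param_rows.append(
                {
                    "parameter": family,
                    "class": cname,
                    f"mean_{group_a}": np.nanmean(xa),
                    f"mean_{group_b}": np.nanmean(xb),
                    "test": res.test_name,
                    "statistic": res.statistic,
                    "p": res.p_value,
                    "cohens_d": res.effect_size,
                    "significant": res.p_value < alpha,
                }
            )
            pooled = np.array([r.parameter(family, ci) for r in records])
            finite = np.isfinite(pooled) & np.isfinite(scores)
            rr = pearson_with_p(pooled[finite], scores[finite])
            corr_rows.append(
                {
                    "parameter": family,
                    "class": cname,
                    "r": rr.statistic,
                    "p": rr.p_value,
                    "significant": rr.p_value < alpha,
                }
            )
            for gname, grp in ((group_a, ga), (group_b, gb)):
                gy = np.array([r.rbdqhk_score for r in grp], dtype=float)
                gx = np.array([r.parameter(family, ci) for r in grp])
                ok = np.isfinite(gx) & np.isfinite(gy)
                if ok.sum() >= 3 and np.std(gx[ok]) > 0:
                    reg = simple_regression(gy[ok], gx[ok])
                    reg_rows.append(
                        {
                            "parameter": family,
                            "class": cname,
                            "group": gname,
                            "beta": reg.statistic,
                            "p": reg.p_value,
                        }
                    )
            if rr.p_value < alpha:
                grp_lab = np.array([r.group for r in records])
                anc = ancova_group_interaction(
                    scores[finite], pooled[finite], grp_lab[finite]
                )
                anc_rows.append(
                    {
                        "parameter": family,
                        "class": cname,
                        "F_interaction": anc.statistic,
                        "p_interaction": anc.p_value,
                    }
                )

    trans_vs_exp = {}
    between = None
    if all(r.transitions is not None for r in records):
        trans_vs_exp = {
            group_a: compare_observed_expected_transitions(ga, adjust=adjust),
            group_b: compare_observed_expected_transitions(gb, adjust=adjust),
        }
        between = compare_transitions_between_groups(
            records, group_a=group_a, group_b=group_b, adjust=adjust
        )
    return GroupReport(
        parameters=pd.DataFrame(param_rows),
        correlations=pd.DataFrame(corr_rows),
        regressions=pd.DataFrame(reg_rows),
        ancova=pd.DataFrame(anc_rows),
        transitions_vs_expected=trans_vs_exp,
        transitions_between_groups=between,
    )
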