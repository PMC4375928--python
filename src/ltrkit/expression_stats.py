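"""Expression statistics: detectability tables, association tests, ANOVA/Tukey
and heatmap clustering order.

Detectability is strict (> 0 in the targeted-assembly RPKMS metric): a sample
"expresses" the transcript only when at least one read assembled.  The 2x2
group-by-detectability table feeds a Pearson chi-squared independence test,
continuity-corrected by default; goodness-of-fit tests against an analytic
null are uncorrected.  Group contrasts across co-family lncRNAs use one-way
ANOVA with Tukey's HSD post hoc on log2(x+1)-transformed abundances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy

from .errors import DegenerateTableError, InputError
from .io_formats import ExpressionMatrix

#: Survival-stratification cutoff (FPKM) taken as an external constant; the
#: threshold-derivation procedure and the survival models are out of scope.
SURVIVAL_CUTOFF_FPKM = 5.6

#: Strict detectability threshold for RPKMS-based classification.
DETECTION_THRESHOLD = 0.0


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts laid out rows = group, columns = (detectable, not detectable)."""

    a: int  # group 1, detectable
    b: int  # group 1, not detectable
    c: int  # group 2, detectable
    d: int  # group 2, not detectable

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InputError("negative contingency count")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p: float
    corrected: bool = False

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0):
            raise InputError("p-value outside [0, 1]")


def build_detection_table(
    expr: ExpressionMatrix,
    group_labels: dict[str, str],
    gene: str,
    threshold: float = DETECTION_THRESHOLD,
    groups: tuple[str, str] | None = None,
) -> ContingencyTable2x2:
    """Cross-tabulate two sample groups by detectability of one gene.

    A sample is detectable iff its abundance is strictly greater than the
    threshold.  Every sample must carry one of exactly two group labels.
    """
    if gene not in expr.values.columns:
        raise InputError(f"gene {gene!r} not in matrix")
    labels = []
    for sample in expr.samples:
        if sample not in group_labels:
            raise InputError(f"sample {sample!r} has no group label")
        labels.append(group_labels[sample])
    uniq = groups if groups is not None else tuple(dict.fromkeys(labels))
    if len(set(labels) - set(uniq)) > 0 or len(uniq) != 2:
        raise InputError("samples must fall into exactly two groups")
    g1, g2 = uniq
    values = expr.values[gene].to_numpy()
    det = values > threshold
    lab = np.array(labels)
    return ContingencyTable2x2(
        a=int(np.sum(det & (lab == g1))),
        b=int(np.sum(~det & (lab == g1))),
        c=int(np.sum(det & (lab == g2))),
        d=int(np.sum(~det & (lab == g2))),
    )


def chi2_independence(
    table: ContingencyTable2x2, continuity: bool = True
) -> TestResult:
    """Pearson chi-squared test of independence on a 2x2 table (df = 1).

    continuity=True applies the Yates 0.5 correction to |O - E|.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero row or column margin")
    res = stats.chi2_contingency(arr, correction=continuity)
    return TestResult(float(res[0]), 1, float(res[1]), corrected=continuity)


def chi2_goodness_of_fit(observed, expected_probs) -> TestResult:
    """Chi-squared goodness of fit of observed counts to analytic proportions.

    No continuity correction; df = number of categories - 1.
    """
    obs = np.asarray(observed, dtype=float)
    probs = np.asarray(expected_probs, dtype=float)
    if obs.shape != probs.shape:
        raise InputError("observed and expected_probs length mismatch")
    if not np.isclose(probs.sum(), 1.0):
        raise InputError("expected_probs must sum to 1")
    total = obs.sum()
    if total <= 0:
        raise InputError("observed total must be > 0")
    expected = total * probs
    if (expected == 0).any():
        raise InputError("zero expected count")
    res = stats.chisquare(obs, f_exp=expected)
    return TestResult(float(res.statistic), len(obs) - 1, float(res.pvalue))


def paired_t_test(x, y) -> TestResult:
    """Paired t-test: one-sample t on per-pair differences, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("paired samples must have equal length")
    n = len(x)
    if n < 2:
        raise InputError("need at least 2 pairs")
    diffs = x - y
    # constant nonzero differences: t is infinite, the test is degenerate;
    # identical vectors (all-zero differences) yield t = 0, p = 1 instead
    if np.allclose(diffs, diffs[0]) and not np.allclose(diffs, 0.0):
        raise InputError("zero-variance differences")
    res = stats.ttest_rel(x, y)
    p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    statistic = 0.0 if np.isnan(res.statistic) else float(res.statistic)
    return TestResult(statistic, n - 1, p)


def pearson_r(x, y) -> float:
    """Product-moment correlation; undefined for constant inputs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise InputError("need equal-length vectors of length >= 3")
    if np.isclose(x.std(), 0.0) or np.isclose(y.std(), 0.0):
        raise InputError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class TukeyComparison:
    group1: str
    group2: str
    mean_diff: float
    p_adj: float
    significant: bool


@dataclass(frozen=True)
class AnovaTukeyResult:
    f_statistic: float
    p: float
    df_between: int
    df_within: int
    comparisons: tuple[TukeyComparison, ...]


def anova_tukey(
    groups: dict[str, "np.ndarray | list[float]"],
    log_transform: bool = True,
    alpha: float = 0.05,
) -> AnovaTukeyResult:
    """One-way ANOVA with Tukey HSD post hoc across named groups.

    Abundances are analysed on the log2(x + 1) scale by default, the scale on
    which co-family lncRNA expression contrasts are displayed.
    """
    if len(groups) < 2:
        raise InputError("need >= 2 groups")
    names = list(groups)
    data = []
    for name in names:
        vals = np.asarray(groups[name], dtype=float)
        if len(vals) < 2:
            raise InputError(f"group {name!r} has n < 2")
        data.append(np.log2(vals + 1.0) if log_transform else vals)
    f_res = stats.f_oneway(*data)
    f_stat = float(f_res.statistic)
    p = float(f_res.pvalue)
    if np.isnan(f_stat):  # all groups identical and constant
        f_stat, p = 0.0, 1.0
    tk = stats.tukey_hsd(*data)
    comps = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p_adj = float(tk.pvalue[i, j])
            comps.append(
                TukeyComparison(
                    names[i],
                    names[j],
                    float(np.mean(data[i]) - np.mean(data[j])),
                    p_adj,
                    p_adj < alpha,
                )
            )
    n_total = sum(len(d) for d in data)
    return AnovaTukeyResult(
        f_stat, p, len(names) - 1, n_total - len(names), tuple(comps)
    )


def cluster_order(matrix: ExpressionMatrix, axis: str = "rows") -> list[str]:
    """Dendrogram leaf order from agglomerative clustering of rows or columns,
    centroid linkage, Euclidean distance."""
    df = matrix.values if axis == "rows" else matrix.values.T
    ids = list(df.index)
    if len(ids) < 2:
        return ids
    obs = df.to_numpy(dtype=float)
    link = hierarchy.linkage(obs, method="centroid", metric="euclidean")
    order = hierarchy.leaves_list(link)
    return [ids[i] for i in order]
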