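"""Nonparametric statistical layer for longitudinal QA comparisons.

Implements the rank-based battery the analysis relies on: Friedman's test
across timepoints (chi-square approximation, average ranks for ties),
pairwise Wilcoxon signed-rank post-hoc with Bonferroni adjustment, the
Wilcoxon signed-rank test itself (exact null enumeration for small
samples, tie-corrected normal approximation with continuity correction
otherwise), Spearman rank correlation (exact permutation p for small n),
and the two-way fixed-raters average-measures intraclass correlation
ICC(3,k) with the conventional interpretation bands
(<0.50 poor, 0.50-0.75 moderate, 0.75-0.90 good, >=0.90 excellent).

All tests are two-sided; the significance threshold used by the pipeline
is alpha = 0.05.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: ICC interpretation bands: upper edge (exclusive) -> label.
ICC_BANDS = ((0.50, "poor"), (0.75, "moderate"), (0.90, "good"), (np.inf, "excellent"))


@dataclasses.dataclass(frozen=True)
class TestResult:
    """One statistical test outcome."""

    method: str
    statistic: float
    p: float
    df: float | None = None
    p_adj: float | None = None
    comparison: str = ""
    n: int = 0
    note: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError(f"p-value {self.p} outside [0, 1]")
        if self.p_adj is not None and (self.p_adj > 1 or self.p_adj < self.p - 1e-12):
            raise ValueError("adjusted p must lie in [p, 1]")


@dataclasses.dataclass(frozen=True)
class IccResult:
    """Intraclass correlation with its model label and interpretation band."""

    icc: float
    model: str
    band: str
    n_subjects: int = 0
    n_raters: int = 0


@dataclasses.dataclass
class RepeatedMeasuresMatrix:
    """Subjects x conditions values for within-subject testing.

    Subjects with any missing condition are excluded listwise on
    construction; the exclusion count is retained for reporting.
    """

    values: np.ndarray
    subjects: list[str]
    conditions: list[str]
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("matrix must be 2-D (subjects x conditions)")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 conditions")
        keep = ~np.isnan(self.values).any(axis=1)
        if not keep.all():
            self.n_excluded += int((~keep).sum())
            self.values = self.values[keep]
            self.subjects = [s for s, k in zip(self.subjects, keep) if k]

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        subject: str,
        condition: str,
        value: str,
        condition_order: Sequence | None = None,
    ) -> "RepeatedMeasuresMatrix":
        wide = df.pivot_table(index=subject, columns=condition, values=value, aggfunc="mean")
        if condition_order is not None:
            wide = wide.reindex(columns=list(condition_order))
        return cls(
            values=wide.to_numpy(dtype=float),
            subjects=[str(s) for s in wide.index],
            conditions=[str(c) for c in wide.columns],
        )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# Friedman


def friedman(matrix: RepeatedMeasuresMatrix) -> TestResult:
    """Friedman chi-square across conditions (average ranks, tie-corrected).

    With exactly two conditions the rank test degenerates; the paired
    Wilcoxon signed-rank test is run instead and labelled as such.
    """
    n, k = matrix.values.shape
    if n < 2:
        raise ValueError(f"Friedman test needs >= 2 complete subjects, got {n}")
    if k == 2:
        res = wilcoxon_signed_rank(matrix.values[:, 0], matrix.values[:, 1])
        return dataclasses.replace(
            res,
            comparison=" vs ".join(matrix.conditions),
            note="two conditions: delegated to Wilcoxon signed-rank",
        )
    ranks = sps.rankdata(matrix.values, axis=1)
    col_rank_sums = ranks.sum(axis=0)
    ssbn = float((col_rank_sums**2).sum())
    chisq = 12.0 / (n * k * (k + 1)) * ssbn - 3.0 * n * (k + 1)
    # tie correction: average ranks shrink the statistic's denominator
    ties = 0.0
    for row in matrix.values:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    c = 1.0 - ties / (n * k * (k**2 - 1))
    if c <= 0:
        # every row fully tied: no evidence of any difference
        return TestResult(
            method="friedman", statistic=0.0, df=float(k - 1), p=1.0,
            comparison="|".join(matrix.conditions), n=n, note="all rows fully tied",
        )
    chisq /= c
    chisq = max(chisq, 0.0)
    p = float(sps.chi2.sf(chisq, k - 1))
    return TestResult(
        method="friedman",
        statistic=float(chisq),
        df=float(k - 1),
        p=p,
        comparison="|".join(matrix.conditions),
        n=n,
    )


def posthoc_pairwise(
    matrix: RepeatedMeasuresMatrix, baseline: str | None = None
) -> list[TestResult]:
    """Pairwise Wilcoxon signed-rank post-hoc with Bonferroni adjustment.

    With ``baseline`` given, only baseline-vs-each comparisons form the
    family; otherwise all condition pairs.  Adjusted p = min(1, m x p).
    """
    conds = matrix.conditions
    if baseline is not None:
        if baseline not in conds:
            raise ValueError(f"baseline {baseline!r} not among conditions {conds}")
        pairs = [(baseline, c) for c in conds if c != baseline]
    else:
        pairs = list(itertools.combinations(conds, 2))
    m = len(pairs)
    results = []
    for a, b in pairs:
        ia, ib = conds.index(a), conds.index(b)
        res = wilcoxon_signed_rank(matrix.values[:, ia], matrix.values[:, ib])
        results.append(
            dataclasses.replace(
                res,
                p_adj=min(1.0, res.p * m),
                comparison=f"{a} vs {b}",
                note=(res.note + f"; family size {m}").lstrip("; "),
            )
        )
    return results


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _signed_rank_exact_sf_cdf(ranks: np.ndarray, w: float) -> tuple[float, float]:
    """P(W <= w) and P(W >= w) for the exact signed-rank null.

    The null distribution is the convolution over ranks of fair coin
    contributions {0, r}; computed by dynamic programming over the integer
    rank-sum support (ranks are integers when |differences| are untied).
    """
    total = int(ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in ranks.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w_int = int(round(w))
    cdf = float(counts[: w_int + 1].sum())
    sf = float(counts[w_int:].sum())
    return cdf, sf


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float] | None = None, exact_max_n: int = 25
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired values (or on ``x``
    as differences when ``y`` is None).

    Zero differences are dropped; tied absolute differences get average
    ranks.  The p-value is exact (full enumeration of the signed-rank
    null) for n <= ``exact_max_n`` without ties, and a tie-corrected
    normal approximation with continuity correction otherwise.  When all
    differences are zero the result is p = 1 with a warning, not an error.
    """
    x = np.asarray(x, dtype=np.float64)
    d = x if y is None else x - np.asarray(y, dtype=np.float64)
    if y is not None and len(x) != len(np.asarray(y)):
        raise ValueError("paired samples must have equal length")
    if d.size < 1:
        raise ValueError("need at least one pair")
    nonzero = d[d != 0]
    n = nonzero.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return TestResult(
            method="wilcoxon-degenerate", statistic=0.0, p=1.0, n=0,
            note="all differences zero",
        )
    ranks = sps.rankdata(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())
    has_ties = np.unique(np.abs(nonzero)).size < n

    if n <= exact_max_n and not has_ties:
        cdf, sf = _signed_rank_exact_sf_cdf(ranks, w_plus)
        p = min(1.0, 2.0 * min(cdf, sf))
        return TestResult(
            method="wilcoxon-exact", statistic=w_plus, p=p, n=int(n),
        )
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction on the variance
    _, counts = np.unique(np.abs(nonzero), return_counts=True)
    var -= float((counts**3 - counts).sum()) / 48.0
    if var <= 0:
        warnings.warn("no variance after tie correction; p = 1", stacklevel=2)
        return TestResult(
            method="wilcoxon-normal", statistic=w_plus, p=1.0, n=int(n),
            note="zero variance",
        )
    diff = w_plus - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return TestResult(
        method="wilcoxon-normal", statistic=w_plus, p=p, n=int(n),
        note="tie-corrected normal approximation, continuity-corrected",
    )


# ---------------------------------------------------------------------------
# ICC


def icc_average_fixed(ratings: np.ndarray, absolute: bool = False) -> IccResult:
    """Average-measures fixed-raters intraclass correlation from two-way
    ANOVA mean squares.

    Default is the consistency form ICC(3,k) = (MS_subjects - MS_error) /
    MS_subjects, which ignores constant rater offsets; ``absolute=True``
    gives the absolute-agreement average-measures form instead.  Negative
    values are reported as computed and classified "poor".
    """
    grid = np.asarray(ratings, dtype=np.float64)
    if grid.ndim != 2 or grid.shape[0] < 2 or grid.shape[1] < 2:
        raise ValueError("need a complete subjects x raters grid, >= 2 each")
    if np.isnan(grid).any():
        raise ValueError("grid must be complete (no missing ratings)")
    n, k = grid.shape
    grand = grid.mean()
    ss_subj = k * ((grid.mean(axis=1) - grand) ** 2).sum()
    ss_raters = n * ((grid.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((grid - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_raters
    ms_subj = ss_subj / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_subj == 0 and ms_err == 0:
        raise ValueError("degenerate table: no variance anywhere")
    if ms_subj == 0:
        raise ValueError("degenerate table: zero between-subject variance")
    if absolute:
        ms_raters = ss_raters / (k - 1)
        icc = (ms_subj - ms_err) / (ms_subj + (ms_raters - ms_err) / n)
        model = "two-way, fixed raters, absolute agreement, average measures"
    else:
        icc = (ms_subj - ms_err) / ms_subj
        model = "two-way, fixed raters, consistency, average measures (ICC(3,k))"
    return IccResult(
        icc=float(icc), model=model, band=classify_icc(float(icc)),
        n_subjects=n, n_raters=k,
    )


def classify_icc(value: float) -> str:
    for edge, label in ICC_BANDS:
        if value < edge:
            return label
    return "excellent"


# ---------------------------------------------------------------------------
# Spearman


def spearman(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 9
) -> TestResult:
    """Spearman rank correlation with two-sided p.

    Computed as the Pearson correlation of average ranks.  For
    n <= ``exact_max_n`` the p-value is exact, by full permutation of one
    rank vector; otherwise the t approximation with n-2 df is used.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("correlation undefined for constant input")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    rs = float((rxc * ryc).sum() / denom)

    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(ryc)))
        r_all = perms @ rxc / denom
        p = float(np.mean(np.abs(r_all) >= abs(rs) - 1e-12))
        return TestResult(method="spearman-exact", statistic=rs, p=p, n=int(n))
    if abs(rs) >= 1.0:
        return TestResult(method="spearman-t", statistic=rs, p=0.0, df=float(n - 2), n=int(n))
    t = rs * np.sqrt((n - 2) / (1.0 - rs**2))
    p = min(1.0, 2.0 * float(sps.t.sf(abs(t), n - 2)))
    return TestResult(method="spearman-t", statistic=rs, p=p, df=float(n - 2), n=int(n))


# ---------------------------------------------------------------------------
# Bonferroni


def bonferroni(pvals: Sequence[float], family_size: int | None = None) -> list[float]:
    """Bonferroni adjustment: min(1, p x m), m defaulting to len(pvals)."""
    pvals = list(pvals)
    for p in pvals:
        if not 0 <= p <= 1:
            raise ValueError(f"p-value {p} outside [0, 1]")
    m = len(pvals) if family_size is None else int(family_size)
    if m < 1:
        raise ValueError("family size must be >= 1")
    return [min(1.0, p * m) for p in pvals]
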