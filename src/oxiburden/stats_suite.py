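"""Group comparisons with normality routing, rank correlation and ROC analysis.

Continuous variables are routed by per-group Shapiro–Wilk tests (α = 0.05):
both groups normal → independent two-sample t-test with mean (SD) summaries,
otherwise Mann–Whitney U with median [IQR].  Categorical 2×2 comparisons use
Fisher's exact test for small samples (n ≤ 40) or sparse tables (any
expected cell below 5, Cochran's rule), otherwise the Pearson chi-square
test.

The AUROC is the Mann–Whitney pair-count statistic (ties count ½): the
probability that a random positive outranks a random negative.  Its standard
error follows Hanley & McNeil, the 95% CI uses normal quantiles clipped to
[0, 1], and the p-value tests AUROC = 0.5 against that SE.  The operating
cutoff maximises Youden's J = sensitivity + specificity − 1, ties broken
toward higher specificity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    kind: str  # continuous | categorical
    test: str  # t_test | mann_whitney | fisher | chi_square
    p_value: float
    summaries: dict[str, str]
    #: raw per-group statistics backing the formatted summaries
    stats: dict[str, dict[str, float]]


@dataclass(frozen=True)
class RocSummary:
    predictor: str
    auroc: float
    ci_low: float
    ci_high: float
    p_value: float
    optimal_cutoff: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int
    degenerate: bool = False


# ---------------------------------------------------------------------------
# group comparisons


def _summary_normal(x: np.ndarray) -> tuple[str, dict[str, float]]:
    m, s = float(np.mean(x)), float(np.std(x, ddof=1))
    return f"{m:.1f} ({s:.1f})", {"mean": m, "sd": s, "n": len(x)}


def _summary_rank(x: np.ndarray) -> tuple[str, dict[str, float]]:
    q1, med, q3 = (float(q) for q in np.percentile(x, [25, 50, 75]))
    return f"{med:.1f} [{q1:.1f}–{q3:.1f}]", {
        "median": med,
        "q1": q1,
        "q3": q3,
        "n": len(x),
    }


def route_and_compare(
    values_by_group: dict[str, np.ndarray],
    variable_kind: str,
    variable: str = "",
    shapiro_alpha: float = 0.05,
) -> GroupComparison:
    """Compare one variable between two groups with test routing.

    Continuous: each group's normality is assessed by Shapiro–Wilk; the
    t-test is used only when both groups pass.  Categorical: groups hold 0/1
    indicator arrays; the 2×2 table is tested by Fisher's exact test when the
    sample is small (n ≤ 40) or any expected cell is < 5, else Pearson
    chi-square.
    """
    if len(values_by_group) != 2:
        raise StatsError(f"{variable}: exactly two groups required")
    (ga, xa), (gb, xb) = (
        (g, np.asarray(v, dtype=float)) for g, v in values_by_group.items()
    )

    if variable_kind == "continuous":
        if len(xa) < 3 or len(xb) < 3:
            raise StatsError(f"{variable}: each group needs n >= 3")
        if np.ptp(xa) == 0 and np.ptp(xb) == 0 and xa[0] == xb[0]:
            # identical constants: no evidence of any difference
            sa, ra = _summary_normal(xa)
            sb, rb = _summary_normal(xb)
            return GroupComparison(
                variable=variable,
                kind="continuous",
                test="t_test",
                p_value=1.0,
                summaries={ga: sa, gb: sb},
                stats={ga: ra, gb: rb},
            )
        # a zero-variance group cannot be called normal; route to the rank test
        normal = all(
            np.ptp(x) > 0 and stats.shapiro(x).pvalue > shapiro_alpha
            for x in (xa, xb)
        )
        if normal:
            p = float(stats.ttest_ind(xa, xb, equal_var=True).pvalue)
            sa, ra = _summary_normal(xa)
            sb, rb = _summary_normal(xb)
            test = "t_test"
        else:
            p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
            sa, ra = _summary_rank(xa)
            sb, rb = _summary_rank(xb)
            test = "mann_whitney"
        return GroupComparison(
            variable=variable,
            kind="continuous",
            test=test,
            p_value=p,
            summaries={ga: sa, gb: sb},
            stats={ga: ra, gb: rb},
        )

    if variable_kind == "categorical":
        table = np.array(
            [
                [float(np.sum(xa == 1)), float(np.sum(xa == 0))],
                [float(np.sum(xb == 1)), float(np.sum(xb == 0))],
            ]
        )
        n = table.sum()
        if n == 0 or table.sum(axis=1).min() == 0:
            raise StatsError(f"{variable}: empty group")
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
        if table.sum(axis=0).min() == 0:
            # one margin empty: no association testable
            test, p = "fisher", 1.0
        elif n <= 40 or (expected < 5).any():
            # Cochran's guidance: exact test for small samples or sparse cells
            test = "fisher"
            p = float(stats.fisher_exact(table).pvalue)
        else:
            test = "chi_square"
            p = float(stats.chi2_contingency(table, correction=False).pvalue)
        summaries = {}
        raw = {}
        for g, x in ((ga, xa), (gb, xb)):
            k, m = int(np.sum(x == 1)), len(x)
            summaries[g] = f"{k} ({100 * k / m:.0f}%)"
            raw[g] = {"count": k, "n": m}
        return GroupComparison(
            variable=variable,
            kind="categorical",
            test=test,
            p_value=p,
            summaries=summaries,
            stats=raw,
        )

    raise StatsError(f"unknown variable kind {variable_kind!r}")


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise StatsError("spearman needs paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("spearman undefined for constant input")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# ROC


def _pair_count_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC as the normalised Mann–Whitney U statistic via average ranks.

    Equals (#{pos > neg} + ½·#{ties}) / (n_pos · n_neg).
    """
    ranks = stats.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_analysis(
    scores: np.ndarray,
    labels: np.ndarray,
    predictor: str = "",
    direction: str = "greater",
) -> RocSummary:
    """ROC summary of one predictor against a binary outcome.

    ``direction='greater'`` (default) means higher predictor values indicate
    the positive class; ``'less'`` flips the predictor.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise StatsError(f"{predictor}: labels must be binary")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise StatsError(f"{predictor}: both outcome classes must be present")
    if direction == "less":
        scores = -scores
    elif direction != "greater":
        raise StatsError(f"unknown direction {direction!r}")

    degenerate = bool(np.ptp(scores) == 0)
    a = _pair_count_auroc(scores, labels)

    # Hanley & McNeil asymptotic standard error
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a)
        + (n_pos - 1) * (q1 - a * a)
        + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    z975 = stats.norm.ppf(0.975)
    ci_low = float(np.clip(a - z975 * se, 0.0, 1.0))
    ci_high = float(np.clip(a + z975 * se, 0.0, 1.0))
    if se > 0:
        p = float(2.0 * stats.norm.sf(abs(a - 0.5) / se))
    else:
        p = 1.0 if a == 0.5 else 0.0

    # Youden's J over candidate cutoffs (midpoints between unique scores,
    # plus sentinels); positive call is score > cutoff
    uniq = np.unique(scores)
    candidates = np.concatenate(
        ([uniq[0] - 1.0], 0.5 * (uniq[:-1] + uniq[1:]), [uniq[-1] + 1.0])
    )
    pos_scores = scores[labels == 1]
    neg_scores = scores[labels == 0]
    sens = (pos_scores[None, :] > candidates[:, None]).mean(axis=1)
    spec = (neg_scores[None, :] <= candidates[:, None]).mean(axis=1)
    j = sens + spec - 1.0
    # ties toward higher specificity = larger cutoff
    best = np.flatnonzero(j == j.max())[-1]
    cutoff = float(candidates[best])
    if direction == "less":
        cutoff = -cutoff
    return RocSummary(
        predictor=predictor,
        auroc=a,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
        optimal_cutoff=cutoff,
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        n_pos=n_pos,
        n_neg=n_neg,
        degenerate=degenerate,
    )


def roc_table(
    predictors: dict[str, np.ndarray],
    labels: np.ndarray,
    directions: dict[str, str] | None = None,
) -> list[RocSummary]:
    """One :class:`RocSummary` per predictor column against a common label."""
    labels = np.asarray(labels).astype(int)
    if labels.sum() < 2 or (labels == 0).sum() < 2:
        raise StatsError("roc_table needs at least 2 patients per class")
    directions = directions or {}
    out = []
    for name, values in predictors.items():
        out.append(
            roc_analysis(
                np.asarray(values, dtype=float),
                labels,
                predictor=name,
                direction=directions.get(name, "greater"),
            )
        )
    return out
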