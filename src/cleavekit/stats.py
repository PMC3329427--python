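"""Comparative and correlational statistics over timing features and trees.

The two exact tests the analyses lean on — the two-sample Wilcoxon rank-sum
test and Fisher's exact test for 2x2 tables — are implemented here in full
(exact enumeration of the rank-sum null distribution; hypergeometric
two-sided tail summation) so the pipeline's p-values are self-contained and
auditable.  Ordinary building blocks (Pearson correlation, the logistic
Wald test's normal quantiles) come from scipy.

All results are returned as :class:`StatResult`, a small record carrying the
estimate, test statistic, p-value, sample sizes, method tag and any flags
(degenerate data, separation, ...).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ArgumentError
from .lineage import LineageTree

logger = logging.getLogger(__name__)


@dataclass
class StatResult:
    """Outcome of one statistical test."""

    estimate: float | None
    statistic: float | None
    p_value: float | None
    n: tuple[int, ...]
    method: str
    flags: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value out of [0,1]: {self.p_value}")


@dataclass
class GroupSummary:
    """Robust per-group summary of one feature: median +/- MAD, n."""

    feature: str
    group: str
    median: float
    mad: float
    n: int


def median_abs_deviation(values) -> float:
    """Unscaled median absolute deviation about the median."""
    arr = np.asarray(values, dtype=float)
    return float(np.median(np.abs(arr - np.median(arr))))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _rank_sum_exact_counts(n1: int, n2: int) -> np.ndarray:
    """Distribution of the rank-sum of sample 1 under H0 (no ties).

    counts[w] = number of the C(n1+n2, n1) equally likely rank assignments
    whose sample-1 rank sum is w.  Classic dynamic programme over ranks.
    """
    n = n1 + n2
    max_w = n1 * n + 1  # rank sums are <= n1*n
    counts = np.zeros((n1 + 1, max_w), dtype=float)
    counts[0, 0] = 1.0
    for rank in range(1, n + 1):
        for k in range(min(rank, n1), 0, -1):
            counts[k, rank:] += counts[k - 1, :-rank].copy() if rank else counts[k - 1]
    return counts[n1]


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> StatResult:
    """Two-sided two-sample Wilcoxon (Mann-Whitney) rank-sum test.

    Exact enumeration when the combined sample size is <= 20 and there are
    no ties (``auto``); otherwise the normal approximation with tie and
    continuity corrections.  The estimate is median(x) - median(y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ArgumentError("wilcoxon_rank_sum: both samples must be non-empty")
    if mode not in ("exact", "normal_approx", "auto"):
        raise ArgumentError(f"unknown mode {mode!r}")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    estimate = float(np.median(x) - np.median(y))

    if np.all(pooled == pooled[0]):
        logger.warning("wilcoxon_rank_sum: all values identical; p = 1")
        return StatResult(
            estimate, None, 1.0, (n1, n2), "wilcoxon_rank_sum", ["degenerate"]
        )

    ranks = sps.rankdata(pooled)
    has_ties = np.unique(pooled).size < n
    w = float(ranks[:n1].sum())

    use_exact = mode == "exact" or (mode == "auto" and n <= 20 and not has_ties)
    if use_exact:
        if has_ties:
            raise ArgumentError("exact mode requires tie-free data")
        counts = _rank_sum_exact_counts(n1, n2)
        total = counts.sum()
        wi = int(round(w))
        p_low = counts[: wi + 1].sum() / total
        p_high = counts[wi:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        method = "wilcoxon_rank_sum_exact"
    else:
        mean_w = n1 * (n + 1) / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var_w <= 0:
            return StatResult(
                estimate, w, 1.0, (n1, n2), "wilcoxon_rank_sum_normal", ["degenerate"]
            )
        diff = w - mean_w
        z = (diff - 0.5 * np.sign(diff)) / math.sqrt(var_w)
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        method = "wilcoxon_rank_sum_normal"
    return StatResult(estimate, w, p, (n1, n2), method)


# ---------------------------------------------------------------------------
# Fisher's exact test


def fisher_exact_2x2(table) -> StatResult:
    """Two-sided Fisher exact test for a 2x2 count table.

    p = sum of hypergeometric probabilities of all tables (with the observed
    margins) no more probable than the observed one; the estimate is the
    sample odds ratio (inf allowed).
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ArgumentError("fisher_exact_2x2 expects a 2x2 table")
    if np.any(arr < 0) or np.any(arr != np.round(arr)):
        raise ArgumentError("fisher_exact_2x2 expects non-negative integers")
    a, b, c, d = (int(v) for v in arr.ravel())
    n = a + b + c + d
    row1, col1 = a + b, a + c

    if (a + c) * (b + d) == 0 or (a + b) * (c + d) == 0:
        logger.warning("fisher_exact_2x2: zero margin; p = 1")
        odds = _odds_ratio(a, b, c, d)
        return StatResult(odds, float(a), 1.0, (n,), "fisher_exact", ["zero_margin"])

    rv = sps.hypergeom(n, row1, col1)
    support = np.arange(max(0, col1 - (c + d)), min(col1, row1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))
    return StatResult(
        _odds_ratio(a, b, c, d), float(a), p, (n,), "fisher_exact"
    )


def _odds_ratio(a, b, c, d) -> float:
    if b * c == 0:
        return math.inf if a * d > 0 else (0.0 if a * d == 0 and (b or c) else math.nan)
    return (a * d) / (b * c)


# ---------------------------------------------------------------------------
# Pearson correlation (reported as r^2)


def pearson_r2(pairs) -> StatResult:
    """Squared Pearson correlation with the usual t-based two-sided p."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ArgumentError("pearson_r2 expects an (n, 2) array of pairs")
    arr = arr[~np.isnan(arr).any(axis=1)]
    n = arr.shape[0]
    if n < 3:
        raise ArgumentError(f"pearson_r2 needs >= 3 complete pairs, got {n}")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return StatResult(
            None, None, None, (n,), "pearson_r2", ["zero_variance"]
        )
    r, p = sps.pearsonr(x, y)
    return StatResult(
        float(r * r), float(r), float(p), (n,), "pearson_r2", extra={"r": float(r)}
    )


# ---------------------------------------------------------------------------
# group comparisons


def group_feature_compare(
    features: pd.DataFrame,
    groups: tuple[str, str],
    feature: str,
    group_col: str = "group",
) -> tuple[tuple[GroupSummary, GroupSummary], StatResult]:
    """Compare one timing feature between two embryo groups.

    Returns per-group median/MAD/n summaries and a Wilcoxon rank-sum result
    whose estimate is median(first group) - median(second group).
    """
    if feature not in features.columns:
        raise ArgumentError(f"feature {feature!r} absent from the table")
    summaries = []
    samples = []
    for label in groups:
        vals = features.loc[features[group_col] == label, feature].dropna().to_numpy()
        if vals.size == 0:
            raise ArgumentError(
                f"feature {feature!r}: no non-missing values in group {label!r}"
            )
        summaries.append(
            GroupSummary(feature, label, float(np.median(vals)),
                         median_abs_deviation(vals), int(vals.size))
        )
        samples.append(vals)
    result = wilcoxon_rank_sum(samples[0], samples[1])
    return (summaries[0], summaries[1]), result


def mother_daughter_correlation(
    trees: list[LineageTree], round_k: int, per_embryo_mean: bool = False
) -> StatResult:
    """Correlation of cycle lengths between rounds k and k+1.

    Default pairing is per cell with both daughters contributing one pair
    each; ``per_embryo_mean`` instead correlates per-embryo round means.
    """
    pairs = []
    if per_embryo_mean:
        from .features import compute_features  # local import to avoid cycle

        for tree in trees:
            f = compute_features(tree)
            a = getattr(f, f"cc{round_k}", None)
            b = getattr(f, f"cc{round_k + 1}", None)
            if a is not None and b is not None:
                pairs.append((a, b))
    else:
        for tree in trees:
            for mother in tree.cells_of_round(round_k):
                lm = mother.cycle_length
                if lm is None:
                    continue
                for child in tree.nodes.values():
                    if child.parent_id == mother.cell_id:
                        ld = child.cycle_length
                        if ld is not None:
                            pairs.append((lm, ld))
    if len(pairs) < 3:
        raise ArgumentError(
            f"mother_daughter_correlation: only {len(pairs)} complete pairs"
        )
    return pearson_r2(pairs)


def sister_stats(
    trees: list[LineageTree], round_k: int
) -> tuple[StatResult, StatResult]:
    """Sister-cell cycle-length correlation and division-fate contingency.

    Correlation pairs are ordered by lineage label (".1" as x, ".2" as y);
    the contingency table counts, once per unordered sister pair, whether
    each of the two cells divided within the observation horizon.
    """
    length_pairs = []
    table = np.zeros((2, 2), dtype=int)
    for tree in trees:
        for left, right in tree.sister_pairs(round_k):
            ll, lr = left.cycle_length, right.cycle_length
            if ll is not None and lr is not None:
                length_pairs.append((ll, lr))
            i = 0 if left.fate == "divided" else 1
            j = 0 if right.fate == "divided" else 1
            table[i, j] += 1
    if len(length_pairs) < 3:
        raise ArgumentError(f"sister_stats: only {len(length_pairs)} complete pairs")
    return pearson_r2(length_pairs), fisher_exact_2x2(table)


# ---------------------------------------------------------------------------
# logistic association of M-phase aberrancy with cycle length


def aberrancy_logistic(
    events: list[tuple[float, bool]],
    max_iter: int = 50,
    tol: float = 1e-10,
) -> StatResult:
    """MLE of logit P(aberrant) = b0 + b1 * cycle_length, by IRLS.

    The estimate is the slope b1 with a two-sided Wald p.  Non-convergence
    or (quasi-)complete separation is reported via flags, not exceptions.
    """
    lengths = np.array([e[0] for e in events], dtype=float)
    outcome = np.array([bool(e[1]) for e in events], dtype=float)
    n = lengths.size
    n_pos = int(outcome.sum())
    if n_pos < 2 or n - n_pos < 2:
        raise ArgumentError(
            "aberrancy_logistic needs >= 2 events of each outcome class"
        )

    X = np.column_stack([np.ones(n), lengths])
    beta = np.zeros(2)
    flags: list[str] = []
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if np.min(w) < 1e-12 and np.max(np.abs(beta)) > 25:
            flags.append("separation")
            break
        WX = X * w[:, None]
        try:
            delta = np.linalg.solve(X.T @ WX, X.T @ (outcome - mu))
        except np.linalg.LinAlgError:
            flags.append("singular")
            break
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    if not converged and "separation" not in flags:
        # separation pushes |b1| out without the step ever shrinking
        if np.max(np.abs(beta)) > 25:
            flags.append("separation")
        else:
            flags.append("non_converged")

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
        se = math.sqrt(max(cov[1, 1], 0.0))
    except np.linalg.LinAlgError:
        se = math.nan
    if se > 0 and math.isfinite(se) and not flags:
        z = beta[1] / se
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        stat = float(z)
    else:
        p, stat = None, None
    return StatResult(
        float(beta[1]), stat, p, (n,), "logistic_irls", flags,
        extra={"intercept": float(beta[0]), "se": se},
    )


# ---------------------------------------------------------------------------
# tidy export


def results_table(named_results: list[tuple[str, StatResult]]) -> pd.DataFrame:
    """Tidy one-row-per-test table (method, target, estimate, statistic, p, n)."""
    rows = []
    for name, res in named_results:
        rows.append(
            {
                "target": name,
                "method": res.method,
                "estimate": res.estimate,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n": "/".join(str(v) for v in res.n),
                "significant_p<0.01": (
                    "*" if res.p_value is not None and res.p_value < 0.01 else ""
                ),
                "flags": ";".join(res.flags),
            }
        )
    return pd.DataFrame(rows)
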