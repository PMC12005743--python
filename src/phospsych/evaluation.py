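"""Accuracy scoring, aggregation and statistical comparisons.

Top-1 accuracy is the percentage of trials whose first choice (humans) or
highest-probability class (models) is correct; Top-2 additionally credits
the second choice / second-highest probability.  Accuracies aggregate into
tidy tables keyed by any of {PIQ level, class, condition, observer}, with
a single-pass 2-standard-deviation outlier exclusion at the observer level,
and are compared with the one-sided Wilcoxon rank-sum (Mann-Whitney U)
test and Pearson correlation.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy import stats

PIQ_KEYS = ["pixels", "grayscales"]


def score_model_records(records: pd.DataFrame) -> pd.DataFrame:
    """Add correct_top1 / correct_top2 columns to model prediction records.

    Top-1: the argmax class matches the true class.  Top-2: the true class
    is among the two highest probabilities.  Ties are broken toward the
    lowest class index (deterministic).
    """
    prob_cols = [c for c in records.columns if c.startswith("prob_")]
    if not prob_cols:
        raise ValueError("records carry no prob_* columns")
    probs = records[prob_cols].to_numpy()
    # stable ranking, ties toward lower class index: sort by (-p, index)
    order = np.lexsort((np.arange(probs.shape[1])[None, :].repeat(len(probs), 0), -probs))
    out = records.copy()
    true = records["class_id"].to_numpy()
    out["correct_top1"] = order[:, 0] == true
    out["correct_top2"] = (order[:, :2] == true[:, None]).any(axis=1)
    return out


def topk_accuracy(
    records: pd.DataFrame,
    k: int = 1,
    by: list[str] | None = None,
) -> pd.DataFrame:
    """Aggregate Top-k correctness into a tidy accuracy table.

    ``records`` are scored model predictions or human trial records (both
    carry boolean correct_top1/correct_top2).  ``by`` lists grouping keys
    (default: PIQ level).  Returns columns ``by + [k, mean, sd, n]`` with
    mean/sd in percent.
    """
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    col = f"correct_top{k}"
    if col not in records.columns:
        raise ValueError(f"records lack {col}; score them first")
    if len(records) == 0:
        raise ValueError("empty record set")
    by = by if by is not None else list(PIQ_KEYS)
    if by:
        g = records.groupby(by, observed=True)[col]
        out = g.agg(mean="mean", sd="std", n="count").reset_index()
    else:
        v = records[col]
        out = pd.DataFrame(
            {"mean": [v.mean()], "sd": [v.std()], "n": [len(v)]}
        )
    out["mean"] *= 100.0
    out["sd"] = (out["sd"] * 100.0).fillna(0.0)
    out.insert(len(by), "k", k)
    return out


def accuracy_by_observer(
    records: pd.DataFrame,
    observer_col: str,
    k: int = 1,
    by: list[str] | None = None,
) -> pd.DataFrame:
    """Per-observer accuracy table (one row per observer x cell)."""
    by = by if by is not None else list(PIQ_KEYS)
    return topk_accuracy(records, k=k, by=[observer_col, *by])


def exclude_outliers(values: np.ndarray | list[float]) -> np.ndarray:
    """Single-pass 2-SD exclusion.

    Removes values deviating from the mean by more than twice the
    (population) standard deviation, both computed from the full input.
    With fewer than two values the input is returned unchanged.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return values
    mean = values.mean()
    sd = values.std()  # population SD
    if sd == 0:
        return values
    return values[np.abs(values - mean) <= 2.0 * sd]


def mean_with_exclusion(
    per_observer: pd.DataFrame,
    by: list[str] | None = None,
    value_col: str = "mean",
) -> pd.DataFrame:
    """Average observer-level accuracies per cell after 2-SD exclusion.

    ``per_observer`` is the output of :func:`accuracy_by_observer`.
    Returns one row per cell with the across-observer mean, SD and count of
    the retained observers.
    """
    by = by if by is not None else list(PIQ_KEYS)
    rows = []
    for key, grp in per_observer.groupby(by, observed=True):
        kept = exclude_outliers(grp[value_col].to_numpy())
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            dict(zip(by, key))
            | {"mean": kept.mean(), "sd": kept.std(ddof=1) if kept.size > 1 else 0.0, "n": kept.size}
        )
    return pd.DataFrame(rows)


def _rank_sum_U(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of sample a (midranks for ties)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    ra = ranks[: len(a)].sum()
    return ra - len(a) * (len(a) + 1) / 2.0


def ranksum_test(
    a: np.ndarray | list[float],
    b: np.ndarray | list[float],
    side: str = "a<b",
    exact_limit: int = 200,
) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    ``side`` is "a<b" (alternative: a stochastically smaller) or "a>b".
    Returns (U statistic of sample a, one-sided p-value).  When
    ``len(a) * len(b) <= exact_limit`` the p-value is exact, by enumerating
    all C(n, n_a) assignments of the pooled midranks; otherwise the normal
    approximation with tie correction and continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if side not in ("a<b", "a>b"):
        raise ValueError("side must be 'a<b' or 'a>b'")
    na, nb = len(a), len(b)
    u_a = _rank_sum_U(a, b)
    u = u_a if side == "a>b" else na * nb - u_a  # large u favors the alternative

    if na * nb <= exact_limit:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        base = na * (na + 1) / 2.0
        count = 0
        total = comb(na + nb, na)
        for pick in combinations(range(na + nb), na):
            ua = ranks[list(pick)].sum() - base
            u_alt = ua if side == "a>b" else na * nb - ua
            if u_alt >= u - 1e-9:
                count += 1
        return u_a, count / total

    # normal approximation with tie and continuity corrections
    pooled = np.concatenate([a, b])
    n = na + nb
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    mu = na * nb / 2.0
    sigma = sqrt(na * nb / 12.0 * (n + 1 - tie_term))
    z = (u - mu - 0.5) / sigma
    return u_a, float(stats.norm.sf(z))


def pearson_correlation(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def discriminability_matrix(
    records: pd.DataFrame,
    class_col: str = "class_id",
) -> pd.DataFrame:
    """Per (class, condition) Top-1 accuracy matrix in percent.

    Rows are classes, columns (viewpoint, expression) conditions; cells are
    mean Top-1 accuracy on the 0-100 scale.  Cells absent from the records
    are NaN (flagged missing, never imputed as zero).
    """
    if "correct_top1" not in records.columns:
        raise ValueError("records lack correct_top1; score them first")
    table = records.pivot_table(
        index=class_col,
        columns=["viewpoint_deg", "expression"],
        values="correct_top1",
        aggfunc="mean",
    )
    return table * 100.0
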