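"""Statistical layer: above/below-break comparison and environmental regressions.

The survey's central question is whether coral abundance drops below a break
depth (the 270-280 m band; the default break of 275 m is the band centre).
Because only two deep stations exist in the design, the rank-sum comparison is
backed by a Monte-Carlo permutation test with 10,000 relabellings.

Two-sample Wilcoxon rank-sum
    Midranks for ties; the null distribution is enumerated exhaustively when
    the pooled sample is small (<= 12, no ties) and approximated by the
    tie-corrected normal otherwise. Two-sided p.

Permutation test
    Statistic: difference of group means, one-sided (above > below) by
    default, as the tested hypothesis is directional. p-value uses the
    add-one estimator (1 + #{permuted >= observed}) / (B + 1), which never
    returns zero.

Regressions
    Ordinary least squares of a coral parameter on one (or several)
    environmental parameters, reporting adjusted r^2
    = 1 - (1 - r^2)(n - 1)/(n - p - 1). Rows with missing values are dropped
    pairwise; the low-salinity surface layer (bin centre above the halocline,
    default 10 m) can be excluded.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import BreakSplitError, CollinearityError, DataError

__all__ = [
    "BreakTestResult",
    "RegressionResult",
    "split_by_break",
    "wilcoxon_two_sample",
    "permutation_test",
    "test_break",
    "regress",
]


@dataclass
class BreakTestResult:
    """Above/below-break comparison of a per-bin coral parameter."""

    break_depth_m: float
    statistic: float          # observed mean(above) - mean(below)
    wilcoxon_W: float         # rank sum of the above group (midranks)
    wilcoxon_p: float
    perm_p: float
    n_above: int
    n_below: int
    B: int
    seed: int | None
    wilcoxon_method: str = "exact"


@dataclass
class RegressionResult:
    response: str
    predictors: tuple[str, ...]
    adjusted_r2: float
    r2: float
    slopes: dict = field(default_factory=dict)
    n: int = 0
    surface_excluded: bool = False


def split_by_break(
    bins: pd.DataFrame,
    break_depth_m: float = 275.0,
    value: str = "abundance",
) -> tuple[np.ndarray, np.ndarray]:
    """Split per-bin values into above- and below-break groups.

    A bin whose interval contains the break depth counts as *above* (the break
    band is read as the lower edge of the deep regime). Raises if either side
    ends up empty.
    """
    sel = bins.dropna(subset=[value])
    contains = (sel["bin_lower_m"] <= break_depth_m) & (break_depth_m < sel["bin_upper_m"])
    above_mask = contains | (sel["bin_centre_m"] < break_depth_m)
    above = sel.loc[above_mask, value].to_numpy(dtype=float)
    below = sel.loc[~above_mask, value].to_numpy(dtype=float)
    if above.size == 0 or below.size == 0:
        raise BreakSplitError(
            f"break at {break_depth_m} m leaves an empty group "
            f"(n_above={above.size}, n_below={below.size}); choose another break depth"
        )
    return above, below


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def wilcoxon_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, str]:
    """Two-sample Wilcoxon rank-sum test; returns (W, two-sided p, method).

    W is the midrank sum of group ``a``. The exact null distribution is
    enumerated (all C(n, n_a) rank assignments) when n <= 12 and there are no
    ties; otherwise the normal approximation with tie correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both groups need at least one value")
    pooled = np.concatenate([a, b])
    n, n_a, n_b = pooled.size, a.size, b.size
    ranks = _midranks(pooled)
    W = float(ranks[:n_a].sum())

    if np.ptp(pooled) == 0:
        return W, 1.0, "degenerate"

    no_ties = np.unique(pooled).size == n
    if n <= 12 and no_ties:
        sums = np.fromiter(
            (sum(c) for c in itertools.combinations(range(1, n + 1), n_a)),
            dtype=float, count=math.comb(n, n_a),
        )
        p_le = float(np.mean(sums <= W + 1e-9))
        p_ge = float(np.mean(sums >= W - 1e-9))
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return W, p, "exact"

    # normal approximation with tie correction
    mean_W = n_a * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    var_W = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var_W <= 0:
        return W, 1.0, "degenerate"
    z = (W - mean_W) / math.sqrt(var_W)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return W, min(1.0, p), "normal"


def permutation_test(
    a: Sequence[float],
    b: Sequence[float],
    B: int = 10_000,
    seed: int | np.random.Generator | None = None,
    alternative: str = "greater",
) -> float:
    """Monte-Carlo permutation p-value for the difference of group means.

    Pools both groups, draws ``B`` random relabellings preserving the group
    sizes, and reports ``(1 + #{permuted stat as or more extreme}) / (B + 1)``.
    ``alternative``: "greater" (mean(a) > mean(b)), "less", or "two-sided".
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0 or B < 1:
        raise DataError("need non-empty groups and B >= 1")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise DataError("non-finite values in permutation test input")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    n, n_a = pooled.size, a.size
    observed = a.mean() - b.mean()

    total = pooled.sum()
    # B random relabellings at once: first n_a columns of row-wise random orders
    order = np.argsort(rng.random((B, n)), axis=1)[:, :n_a]
    sum_a = pooled[order].sum(axis=1)
    stat = sum_a / n_a - (total - sum_a) / (n - n_a)

    eps = 1e-12 * max(1.0, float(np.abs(pooled).max()))
    if alternative == "greater":
        extreme = stat >= observed - eps
    elif alternative == "less":
        extreme = stat <= observed + eps
    elif alternative == "two-sided":
        extreme = np.abs(stat) >= abs(observed) - eps
    else:
        raise DataError(f"unknown alternative '{alternative}'")
    return float((1 + int(extreme.sum())) / (B + 1))


def test_break(
    bins: pd.DataFrame,
    break_depth_m: float = 275.0,
    value: str = "abundance",
    B: int = 10_000,
    seed: int | None = None,
    alternative: str = "greater",
) -> BreakTestResult:
    """Full above/below-break analysis of one per-bin coral parameter."""
    above, below = split_by_break(bins, break_depth_m, value)
    W, wp, method = wilcoxon_two_sample(above, below)
    pp = permutation_test(above, below, B=B, seed=seed, alternative=alternative)
    return BreakTestResult(
        break_depth_m=break_depth_m,
        statistic=float(above.mean() - below.mean()),
        wilcoxon_W=W, wilcoxon_p=wp, perm_p=pp,
        n_above=int(above.size), n_below=int(below.size),
        B=B, seed=seed, wilcoxon_method=method,
    )


def regress(
    bins: pd.DataFrame,
    response: str,
    predictors: str | Sequence[str],
    exclude_surface: bool = False,
    halocline_depth_m: float = 10.0,
) -> RegressionResult:
    """OLS of a coral parameter on environmental parameter(s), adjusted r^2.

    ``predictors`` may be a single column name (the per-predictor layout of
    the study's regression table) or several for a joint multiple fit.
    """
    preds = (predictors,) if isinstance(predictors, str) else tuple(predictors)
    df = bins.copy()
    if exclude_surface:
        df = df[df["bin_centre_m"] >= halocline_depth_m]
    cols = [response, *preds]
    df = df.dropna(subset=cols)
    n = len(df)
    if n < len(preds) + 2:
        raise DataError(
            f"need at least {len(preds) + 2} complete rows to fit {preds}, have {n}"
        )
    X = df[list(preds)].to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < len(preds) + 1:
        raise CollinearityError(f"rank-deficient design: predictors {preds} are collinear")
    model = sm.OLS(df[response].to_numpy(dtype=float), sm.add_constant(X)).fit()
    slopes = {p: float(c) for p, c in zip(preds, model.params[1:])}
    return RegressionResult(
        response=response, predictors=preds,
        adjusted_r2=float(model.rsquared_adj), r2=float(model.rsquared),
        slopes=slopes, n=n, surface_excluded=exclude_surface,
    )
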