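"""Two-group statistics: Mann–Whitney U (exact and normal-approximate),
two-sided t tests, and mean ± SEM summaries.

The exact Mann–Whitney test enumerates the null distribution of
``U = Σᵢⱼ [xᵢ > yⱼ] + ½ Σᵢⱼ [xᵢ = yⱼ]`` over all C(m+n, m) assignments of
the pooled (mid-)ranks to the first group, so it remains exact under ties
conditional on the observed tie pattern. The two-sided p-value uses the
doubling rule ``min(1, 2·min(P(U ≤ u), P(U ≥ u)))``. ``auto`` mode runs the
exact test when min(m, n) ≤ 10 and the pooled sample is tie-free
(C(20,10) = 184,756 assignments enumerate in well under a second) and the
tie-corrected, continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError
from .types import GroupComparison

__all__ = [
    "mann_whitney_u",
    "t_test",
    "mean_sem",
    "significance_flag",
    "u_statistic",
]


def mean_sem(x: Sequence[float]) -> Tuple[float, float]:
    """Sample mean and standard error (ddof=1 standard deviation / sqrt(n))."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise InsufficientDataError("mean_sem needs n >= 2")
    return float(x.mean()), float(x.std(ddof=1) / np.sqrt(x.size))


def _safe_mean_sem(x: np.ndarray) -> Tuple[float, float]:
    if x.size >= 2:
        return mean_sem(x)
    return (float(x.mean()) if x.size else float("nan"), float("nan"))


def significance_flag(p: float) -> bool:
    """True iff p < 0.05, strictly (p = 0.05 is not significant)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value out of range: {p}")
    return p < 0.05


def u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of the first sample: pairs where x > y plus half the tied pairs."""
    x = np.asarray(x, dtype=np.float64)[:, None]
    y = np.asarray(y, dtype=np.float64)[None, :]
    return float(np.sum(x > y) + 0.5 * np.sum(x == y))


def _exact_u_p_value(pooled_ranks: np.ndarray, m: int, u_obs: float) -> float:
    """Two-sided exact p by full enumeration of rank assignments."""
    n_total = pooled_ranks.size
    const = m * (m + 1) / 2.0
    us = np.fromiter(
        (pooled_ranks[list(idx)].sum() - const for idx in combinations(range(n_total), m)),
        dtype=np.float64,
    )
    eps = 1e-9
    p_le = np.mean(us <= u_obs + eps)
    p_ge = np.mean(us >= u_obs - eps)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _approx_u_p_value(pooled: np.ndarray, m: int, n: int, u_obs: float) -> float:
    """Normal approximation with tie-corrected variance and continuity
    correction."""
    n_total = m + n
    mean_u = m * n / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_u = m * n / 12.0 * ((n_total + 1) - tie_term / (n_total * (n_total - 1)))
    if var_u <= 0:  # all values tied
        return 1.0
    z = (abs(u_obs - mean_u) - 0.5) / np.sqrt(var_u)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * sps.norm.sf(z)))


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
    group_labels: Tuple[str, str] = ("x", "y"),
) -> GroupComparison:
    """Two-sided Mann–Whitney U test.

    mode: ``exact`` enumerates all C(m+n, m) rank assignments; ``approx``
    uses the tie-corrected normal approximation with continuity correction;
    ``auto`` picks exact for tie-free samples with min(m, n) <= 10.
    """
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    m, n = x.size, y.size
    if m < 1 or n < 1:
        raise InsufficientDataError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    u_obs = u_statistic(x, y)
    if mode == "auto":
        mode = "exact" if (min(m, n) <= 10 and not has_ties) else "approx"
    if mode == "exact":
        ranks = sps.rankdata(pooled)  # mid-ranks under ties
        p = _exact_u_p_value(ranks, m, u_obs)
        variant = "exact"
    else:
        p = _approx_u_p_value(pooled, m, n, u_obs)
        variant = "normal_approx"
    mx, sx = _safe_mean_sem(x)
    my, sy = _safe_mean_sem(y)
    return GroupComparison(
        group_labels=group_labels,
        n_per_group=(m, n),
        statistic_name="U",
        statistic_value=u_obs,
        p_value=p,
        means=(mx, my),
        sems=(sx, sy),
        test_variant=variant,
    )


def t_test(
    x: Sequence[float],
    y: Sequence[float],
    variant: str = "welch",
    group_labels: Tuple[str, str] = ("x", "y"),
) -> GroupComparison:
    """Two-sided two-sample t test; Welch by default, Student available.

    Degenerate convention (documented): if both groups have zero variance,
    p = 1.0 when the means are equal and p = 0.0 otherwise, with t = 0/±inf.
    """
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown variant {variant!r}")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("t test needs n >= 2 per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        equal = x.mean() == y.mean()
        t_stat = 0.0 if equal else float(np.sign(x.mean() - y.mean()) * np.inf)
        p = 1.0 if equal else 0.0
    else:
        res = sps.ttest_ind(x, y, equal_var=(variant == "student"))
        t_stat, p = float(res.statistic), float(res.pvalue)
    mx, sx = mean_sem(x)
    my, sy = mean_sem(y)
    return GroupComparison(
        group_labels=group_labels,
        n_per_group=(int(x.size), int(y.size)),
        statistic_name="t",
        statistic_value=t_stat,
        p_value=p,
        means=(mx, my),
        sems=(sx, sy),
        test_variant=variant,
    )
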