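"""Cohort-level statistical comparison of margin methods.

The primary comparison is a one-way fixed-effects ANOVA F-test across the
per-patient margins of each method; a two-sample variance-ratio F-test is
exposed separately for pairwise use.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import InsufficientDataError, ZeroVarianceError

__all__ = ["MethodComparison", "compare_methods", "variance_ratio_test"]


@dataclass(frozen=True)
class MethodComparison:
    """Result of an F-test across margin methods for one site/direction."""

    methods: tuple[str, ...]
    f_statistic: float
    p_value: float
    significant: bool
    alpha: float
    n_per_group: tuple[int, ...]
    site: str | None = None
    direction: str | None = None


def compare_methods(
    per_method_margins: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    *,
    site: str | None = None,
    direction: str | None = None,
) -> MethodComparison:
    """One-way ANOVA across method groups of per-patient margins.

    Requires >= 2 methods with >= 2 values each.  All observations identical
    across all groups raise :class:`ZeroVarianceError` (F undefined).
    """
    methods = tuple(per_method_margins)
    if len(methods) < 2:
        raise InsufficientDataError(f"need >= 2 methods, got {len(methods)}")
    groups = [np.asarray(per_method_margins[m], dtype=float) for m in methods]
    if any(g.size < 2 for g in groups):
        raise InsufficientDataError("each method needs >= 2 values")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        raise ZeroVarianceError("all observations identical across all groups")
    f_stat, p = sps.f_oneway(*groups)
    f_stat, p = float(f_stat), float(p)
    return MethodComparison(
        methods=methods,
        f_statistic=f_stat,
        p_value=p,
        significant=bool(p <= alpha),
        alpha=alpha,
        n_per_group=tuple(g.size for g in groups),
        site=site,
        direction=direction,
    )


def variance_ratio_test(
    a: Sequence[float], b: Sequence[float], alpha: float = 0.05
) -> MethodComparison:
    """Two-sided two-sample F-test of equal variances (F = var_a / var_b)."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("each sample needs >= 2 values")
    va = x.var(ddof=1)
    vb = y.var(ddof=1)
    if va == 0 and vb == 0:
        raise ZeroVarianceError("both samples have zero variance")
    if vb == 0:
        f = float("inf")
        p = 0.0
    else:
        f = float(va / vb)
        dist = sps.f(x.size - 1, y.size - 1)
        p = float(2.0 * min(dist.sf(f), dist.cdf(f)))
        p = min(p, 1.0)
    return MethodComparison(
        methods=("a", "b"),
        f_statistic=f,
        p_value=p,
        significant=bool(p <= alpha),
        alpha=alpha,
        n_per_group=(x.size, y.size),
    )
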