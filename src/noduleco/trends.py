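"""Statistical assessment of ecological parameters along the cover gradient.

Two complementary tests per parameter, mirroring how class summaries are
evaluated against nodule cover:

* **class-1 distinctness** — a single joint criterion: the 95% CI upper
  bound of the minimal-cover class must clear the CI lower bounds of *all*
  other classes simultaneously (or the mirrored criterion for responses that
  are higher in class 1).  No pairwise testing.
* **Spearman rank correlation** between the k per-class summary centers and
  the k class mean covers, with a Student-t approximate p-value
  (t = r_s sqrt((k-2)/(1-r_s^2)) on k-2 df) and, for k <= 10, an exact
  permutation p-value Pr(|r_perm| >= |r_obs|) by full enumeration.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ClassSummary:
    """Per-class center and 95% CI for one ecological parameter."""

    parameter: str
    class_index: np.ndarray    # (k,)
    center: np.ndarray         # (k,)
    ci_low: np.ndarray         # (k,)
    ci_high: np.ndarray        # (k,)
    center_kind: str = "mean"  # mean | median

    def __post_init__(self) -> None:
        k = len(self.class_index)
        for a in (self.center, self.ci_low, self.ci_high):
            if len(a) != k:
                raise ValueError("class summary arrays must share length k")
        if (np.asarray(self.ci_low) > np.asarray(self.ci_high)).any():
            raise ValueError("ci_low must be <= ci_high in every class")

    @classmethod
    def from_replicates(cls, parameter: str, replicates_by_class: dict,
                        center: str = "mean",
                        level: float = 0.95) -> "ClassSummary":
        from .bootstrap import summarize_bootstrap
        idx = sorted(replicates_by_class)
        c, lo, hi = [], [], []
        for i in idx:
            ctr, l, h = summarize_bootstrap(replicates_by_class[i],
                                            center=center, level=level)
            c.append(ctr)
            lo.append(l)
            hi.append(h)
        return cls(parameter, np.array(idx), np.array(c), np.array(lo),
                   np.array(hi), center_kind=center)


@dataclass(frozen=True)
class TrendTestResult:
    """One row of the gradient trend table."""

    parameter: str
    distinct_class1: bool
    direction: str             # lower | higher (position of class 1)
    r_s: float
    p_t: float
    p_exact: float | None
    n: int


def class1_distinct(summary: ClassSummary, direction: str = "lower") -> bool:
    """Joint CI-separation of the minimal-cover class from all others.

    ``direction='lower'``: class 1's CI upper bound must be below the minimum
    CI lower bound of classes 2..k; ``'higher'`` is the mirror.  Overlap with
    any single class fails the criterion.
    """
    if len(summary.class_index) < 2:
        raise ValueError("need >= 2 classes")
    order = np.argsort(summary.class_index)
    lo = np.asarray(summary.ci_low)[order]
    hi = np.asarray(summary.ci_high)[order]
    if direction == "lower":
        return bool(hi[0] < lo[1:].min())
    if direction == "higher":
        return bool(lo[0] > hi[1:].max())
    raise ValueError("direction must be 'lower' or 'higher'")


def spearman_rs(values, covers) -> float:
    """Tie-corrected Spearman rank correlation of k class summaries vs cover."""
    values = np.asarray(values, dtype=float)
    covers = np.asarray(covers, dtype=float)
    if values.size != covers.size or values.size < 3:
        raise ValueError("need matched vectors of length k >= 3")
    if np.unique(values).size == 1 or np.unique(covers).size == 1:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rv = stats.rankdata(values)
    rc = stats.rankdata(covers)
    return float(np.corrcoef(rv, rc)[0, 1])


def spearman_p_t(r_s: float, k: int) -> float:
    """Two-sided p for a Spearman correlation via the Student-t transform.

    t = r_s sqrt((k-2)/(1-r_s^2)) referred to a t distribution on k-2 df.
    For |r_s| = 1 the transform degenerates; the exact enumeration minimum
    2/k! is reported instead.
    """
    if k < 3:
        raise ValueError("need k >= 3")
    if not -1.0 <= r_s <= 1.0:
        raise ValueError("r_s must lie in [-1, 1]")
    if abs(r_s) >= 1.0 - 1e-12:
        # degenerate t transform: report the exact-enumeration minimum
        return 2.0 / math.factorial(k)
    t = r_s * math.sqrt((k - 2) / (1.0 - r_s * r_s))
    return float(2.0 * stats.t.sf(abs(t), df=k - 2))


MAX_EXACT_K = 10


def spearman_p_exact(values, covers) -> float:
    """Exact two-sided permutation p: Pr(|r_perm| >= |r_obs|), full enumeration.

    Defined as the mass of the permutation distribution at least as extreme
    in absolute value (not a doubled one-tail).  Refuses k > 10 (k! grows too
    fast); use the t-approximation there.
    """
    values = np.asarray(values, dtype=float)
    covers = np.asarray(covers, dtype=float)
    k = values.size
    if k > MAX_EXACT_K:
        raise ValueError(
            f"exact enumeration limited to k <= {MAX_EXACT_K}; "
            "use spearman_p_t for larger k")
    r_obs = spearman_rs(values, covers)
    rv = stats.rankdata(values)
    rc = stats.rankdata(covers)
    rc_c = rc - rc.mean()
    sd_c = np.sqrt((rc_c ** 2).sum())
    sd_v = np.sqrt(((rv - rv.mean()) ** 2).sum())
    # r for a permuted assignment is affine in the dot product of centered
    # ranks, so only that scalar's permutation distribution is needed
    thresh = abs(r_obs) * sd_v * sd_c - 1e-12
    dots = _perm_dot_distribution(tuple(np.sort(rv)), tuple(rc_c))
    return float((dots >= thresh).mean())


_PERM_CACHE: dict = {}


def _perm_dot_distribution(rv_sorted: tuple, rc_c: tuple) -> np.ndarray:
    """|dot| over all permutations of the rank multiset (cached per ranks)."""
    key = (rv_sorted, rc_c)
    if key not in _PERM_CACHE:
        rc_arr = np.array(rc_c)
        rv_arr = np.array(rv_sorted) - np.mean(rv_sorted)
        out = []
        chunk: list = []
        for perm in itertools.permutations(rv_arr):
            chunk.append(perm)
            if len(chunk) == 200_000:
                out.append(np.abs(np.array(chunk) @ rc_arr))
                chunk = []
        if chunk:
            out.append(np.abs(np.array(chunk) @ rc_arr))
        if len(_PERM_CACHE) > 8:
            _PERM_CACHE.clear()
        _PERM_CACHE[key] = np.concatenate(out)
    return _PERM_CACHE[key]


def trend_table(summaries: list[ClassSummary], covers,
                exact: bool = True) -> pd.DataFrame:
    """Assemble the trend table: one row per ecological parameter.

    Columns: parameter, distinct_class1, direction, r_s, p_t, p_exact, n.
    ``covers`` are the k class mean covers shared by all parameters.
    """
    covers = np.asarray(covers, dtype=float)
    rows = []
    for s in summaries:
        rows.append(trend_test(s, covers, exact=exact))
    return pd.DataFrame([{
        "parameter": r.parameter,
        "distinct_class1": r.distinct_class1,
        "direction": r.direction,
        "r_s": r.r_s,
        "p_t": r.p_t,
        "p_exact": r.p_exact,
        "n": r.n,
    } for r in rows])


def trend_test(summary: ClassSummary, covers,
               exact: bool = True) -> TrendTestResult:
    covers = np.asarray(covers, dtype=float)
    k = len(summary.class_index)
    if covers.size != k:
        raise ValueError("covers must have one entry per class")
    order = np.argsort(summary.class_index)
    centers = np.asarray(summary.center)[order]
    direction = "lower" if centers[0] <= centers[1:].mean() else "higher"
    distinct = class1_distinct(summary, direction=direction)
    try:
        r_s = spearman_rs(centers, covers[order])
        p_t = spearman_p_t(r_s, k)
        p_exact = (spearman_p_exact(centers, covers[order])
                   if exact and k <= MAX_EXACT_K else None)
    except ValueError:
        r_s, p_t, p_exact = float("nan"), float("nan"), None
    return TrendTestResult(
        parameter=summary.parameter, distinct_class1=distinct,
        direction=direction, r_s=r_s, p_t=p_t, p_exact=p_exact, n=k)
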