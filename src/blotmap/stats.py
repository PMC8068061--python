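"""Cohort-level association statistics.

Spearman and Pearson correlations with the t approximation for two-sided
p-values (df = n - 2), first-order partial correlations (df = n - 3), the
in vitro VPA response metric from triplicate proliferation counts, and
the FAB ordinal encoding M0-M6 -> 0-6.

The t approximation mirrors standard statistical-package output; for
very small cohorts (n <= 9) an exact permutation p-value over all n!
pairings is available.  Missing values are removed listwise within each
analysis and the effective n is always reported on the result.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.stats import rankdata, t as t_dist

from .errors import DegenerateInputError, ParameterError

__all__ = [
    "TripletCounts",
    "AssociationResult",
    "vpa_response",
    "fab_ordinal",
    "spearman",
    "pearson",
    "partial_correlation",
    "p_from_r",
]

_MAX_EXACT_N = 9
_P_FLOOR = np.finfo(float).tiny


@dataclass(frozen=True)
class TripletCounts:
    """Triplicate 3H-thymidine incorporation counts (cpm) for one sample,
    untreated control arm vs VPA-treated arm."""

    control_cpm: tuple[float, float, float]
    treated_cpm: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name, arm in (("control", self.control_cpm), ("treated", self.treated_cpm)):
            if len(arm) != 3:
                raise ParameterError(f"{name} arm must have exactly 3 replicates")
            if any(c < 0 for c in arm):
                raise ParameterError(f"{name} arm has negative counts")


@dataclass(frozen=True)
class AssociationResult:
    """One correlation result: coefficient, t statistic, df, p, n."""

    method: str  # "spearman" | "pearson" | "partial"
    r: float
    t: float
    df: int
    p: float
    n: int
    controlled_for: str | None = None

    @property
    def significant(self) -> bool:
        """Raw two-sided p < 0.05, the study-wide reporting convention."""
        return bool(self.p < 0.05)


# ---------------------------------------------------------------------------
# Covariate construction
# ---------------------------------------------------------------------------


def vpa_response(counts: TripletCounts) -> float:
    """Percent VPA response: relative decrease in proliferation.

    response = (1 - mean(treated) / mean(control)) * 100.  Negative when
    treated cells proliferate more than the untreated control.
    """
    control = float(np.mean(counts.control_cpm))
    treated = float(np.mean(counts.treated_cpm))
    if control <= 0:
        raise DegenerateInputError("control arm mean cpm must be > 0")
    return (1.0 - treated / control) * 100.0


_FAB_RE = re.compile(r"^[Mm]([0-6])[a-zA-Z]?$")


def fab_ordinal(fab_label: str) -> int:
    """Encode a FAB class label M0-M6 as an ordinal 0-6.

    Subclass letters are ignored (M5a -> 5).  Labels outside M0-M6 are
    rejected.
    """
    m = _FAB_RE.match(fab_label.strip())
    if not m:
        raise ParameterError(f"unrecognized FAB label {fab_label!r} (expect M0-M6)")
    return int(m.group(1))


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------


def p_from_r(r: float, n: int, df_offset: int = 2) -> float:
    """Two-sided t-approximation p-value for a correlation coefficient.

    t = r * sqrt(df / (1 - r^2)) with df = n - df_offset (2 for simple,
    3 for first-order partial correlations).
    """
    df = n - df_offset
    if df < 1:
        raise ParameterError("not enough samples for a p-value")
    if not -1.0 <= r <= 1.0:
        raise ParameterError("|r| must be <= 1")
    if abs(r) == 1.0:
        return _P_FLOOR
    t = r * math.sqrt(df / (1.0 - r * r))
    return max(2.0 * float(t_dist.sf(abs(t), df=df)), _P_FLOOR)


def _listwise(*arrays: np.ndarray) -> tuple[np.ndarray, ...]:
    arrays = tuple(np.asarray(a, dtype=float) for a in arrays)
    if len({len(a) for a in arrays}) != 1:
        raise ParameterError("input vectors must share length")
    keep = np.logical_and.reduce([np.isfinite(a) for a in arrays])
    return tuple(a[keep] for a in arrays)


def _check_pair(x: np.ndarray, y: np.ndarray, min_n: int) -> None:
    if len(x) < min_n:
        raise DegenerateInputError(f"need >= {min_n} complete observations")
    for name, v in (("x", x), ("y", y)):
        if np.unique(v).size < 2:
            raise DegenerateInputError(f"{name} is constant")


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.dot(xc, yc) / math.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))


def _t_result(method: str, r: float, n: int, df_offset: int = 2, **kw) -> AssociationResult:
    df = n - df_offset
    r = min(1.0, max(-1.0, r))
    t = math.inf * np.sign(r) if abs(r) == 1.0 else r * math.sqrt(df / (1.0 - r * r))
    p = p_from_r(r, n, df_offset)
    return AssociationResult(method=method, r=r, t=t, df=df, p=p, n=n, **kw)


def _exact_p(x: np.ndarray, y: np.ndarray, r_func) -> float:
    """Exact two-sided permutation p over all n! orderings of y."""
    n = len(x)
    if n > _MAX_EXACT_N:
        raise ParameterError(
            f"exact mode enumerates n! permutations; n={n} exceeds {_MAX_EXACT_N}"
        )
    r_obs = abs(r_func(x, y))
    count = 0
    total = 0
    for perm in permutations(range(n)):
        total += 1
        if abs(r_func(x, y[list(perm)])) >= r_obs - 1e-12:
            count += 1
    return count / total


def spearman(x, y, p_mode: str = "t") -> AssociationResult:
    """Spearman rank-order correlation with midrank tie handling.

    r is the Pearson correlation of the two midrank vectors; p comes
    from the t approximation with df = n - 2 (``p_mode="exact"``
    enumerates all permutations for n <= 9).
    """
    x, y = _listwise(x, y)
    _check_pair(x, y, min_n=4)
    rx, ry = rankdata(x), rankdata(y)
    r = _pearson_r(rx, ry)
    res = _t_result("spearman", r, n=len(x))
    if p_mode == "exact":
        p = _exact_p(rx, ry, lambda a, b: _pearson_r(a, rankdata(b)))
        res = AssociationResult(
            method="spearman", r=res.r, t=res.t, df=res.df, p=p, n=res.n
        )
    elif p_mode != "t":
        raise ParameterError(f"unknown p_mode {p_mode!r}")
    return res


def pearson(x, y, p_mode: str = "t") -> AssociationResult:
    """Pearson product-moment correlation with the t-approximation p."""
    x, y = _listwise(x, y)
    _check_pair(x, y, min_n=4)
    r = _pearson_r(x, y)
    res = _t_result("pearson", r, n=len(x))
    if p_mode == "exact":
        p = _exact_p(x, y, _pearson_r)
        res = AssociationResult(
            method="pearson", r=res.r, t=res.t, df=res.df, p=p, n=res.n
        )
    elif p_mode != "t":
        raise ParameterError(f"unknown p_mode {p_mode!r}")
    return res


def partial_correlation(x, y, z, controlled_for: str | None = None) -> AssociationResult:
    """First-order partial correlation of x and y controlling for z.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)) on the
    Pearson scale, with t = r sqrt((n-3)/(1-r^2)) and df = n - 3.
    Equivalent to correlating the least-squares residuals of x on z and
    y on z.
    """
    x, y, z = _listwise(x, y, z)
    if len(x) < 5:
        raise DegenerateInputError("need >= 5 complete triples")
    for name, v in (("x", x), ("y", y), ("z", z)):
        if np.unique(v).size < 2:
            raise DegenerateInputError(f"{name} is constant")
    r_xy = _pearson_r(x, y)
    r_xz = _pearson_r(x, z)
    r_yz = _pearson_r(y, z)
    if abs(r_xz) >= 1.0 - 1e-12 or abs(r_yz) >= 1.0 - 1e-12:
        raise DegenerateInputError(
            "control variable is collinear with x or y (|r| = 1)"
        )
    r = (r_xy - r_xz * r_yz) / math.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    return _t_result(
        "partial", r, n=len(x), df_offset=3, controlled_for=controlled_for
    )
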