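"""Statistical kernels used by every pipeline stage.

The kernels are written from first principles because their exact
small-sample behaviour is what the surrounding analysis depends on:

* Mann-Whitney U with an *exact* null distribution, enumerated by dynamic
  programming, for the tiny two-group designs (9 vs 9) typical of pilot
  biomarker cohorts.  The reporting convention is the one used throughout
  this analysis style: one-tailed p is the smaller tail, two-tailed p is
  twice that, capped at 1.
* Pearson / Spearman correlation with the conventional Evans strength
  labels (very weak < 0.20 ... very strong >= 0.80 on |r|).
* Polynomial least-squares fits with the overall F-test (quadratic and
  cubic curve estimation).
* Box's M test of covariance homogeneity with the standard chi-square
  approximation, reported alongside quadratic discriminant fits.

scipy supplies only distribution functions (normal, t, F, chi-square);
the statistics themselves are computed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as _sps

from .exceptions import ConstantInputError, InsufficientDataError, SingularFitError

__all__ = [
    "MWTestResult",
    "CorrelationResult",
    "PolyFitResult",
    "BoxMResult",
    "exact_u_null",
    "mann_whitney",
    "pearson",
    "spearman",
    "evans_strength",
    "polyfit_f",
    "boxs_m",
]

_EXACT_N_LIMIT = 24

Alternative = Literal["two_sided", "greater", "less"]


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MWTestResult:
    u_statistic: float
    n1: int
    n2: int
    p_one_tailed: float
    p_two_tailed: float
    method: Literal["exact", "normal_approx"]
    tie_correction_applied: bool
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "u_statistic": self.u_statistic,
            "n1": self.n1,
            "n2": self.n2,
            "p_one_tailed": self.p_one_tailed,
            "p_two_tailed": self.p_two_tailed,
            "method": self.method,
            "tie_correction_applied": self.tie_correction_applied,
            "degenerate": self.degenerate,
        }


_null_cache: dict[tuple[int, int], np.ndarray] = {}


def exact_u_null(n1: int, n2: int) -> np.ndarray:
    """Exact null distribution of the Mann-Whitney U statistic.

    Returns an integer array ``counts`` of length ``n1*n2 + 1`` where
    ``counts[u]`` is the number of tie-free rank arrangements giving
    ``U = u``.  Total mass is C(n1+n2, n1).

    The distribution is built by the standard recursion on whether the
    largest remaining observation belongs to sample 1 (contributing n2
    to U) or to sample 2.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both sample sizes must be >= 1")
    if n1 + n2 > _EXACT_N_LIMIT:
        raise InsufficientDataError(
            f"exact null limited to n1+n2 <= {_EXACT_N_LIMIT} "
            f"(got {n1 + n2}); use the normal approximation"
        )
    key = (n1, n2)
    if key in _null_cache:
        return _null_cache[key]
    # Recursion on whether the largest of the remaining i+j observations
    # belongs to sample 1 (adding j to U) or sample 2:
    #   c_{i,j}(u) = c_{i-1,j}(u - j) + c_{i,j-1}(u)
    max_u = n1 * n2
    dp = np.zeros((n1 + 1, max_u + 1), dtype=np.int64)
    dp[:, 0] = 1  # j = 0: a single arrangement with U = 0 for any i
    for j in range(1, n2 + 1):
        ndp = np.zeros_like(dp)
        ndp[0, 0] = 1
        for i in range(1, n1 + 1):
            ndp[i] = dp[i]
            ndp[i, j:] += ndp[i - 1, : max_u + 1 - j]
        dp = ndp
    counts = dp[n1]
    assert int(counts.sum()) == math.comb(n1 + n2, n1)
    _null_cache[key] = counts
    return counts


def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled), dtype=float)
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Alternative = "two_sided",
) -> MWTestResult:
    """Two-sample Mann-Whitney U test.

    ``u_statistic`` is U of the first sample: the number of (x, y) pairs
    with x > y, counting ties as 1/2, so U(x, y) + U(y, x) = n1 * n2.

    The p-value is exact (null-distribution enumeration) when
    ``n1 + n2 <= 20`` and the pooled sample is tie-free; otherwise the
    normal approximation with tie correction (and no continuity
    correction) is used.  A constant pooled sample is flagged degenerate
    with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1

    if np.all(pooled == pooled[0]):
        return MWTestResult(
            u_statistic=u1,
            n1=n1,
            n2=n2,
            p_one_tailed=0.5,
            p_two_tailed=1.0,
            method="exact" if n1 + n2 <= 20 else "normal_approx",
            tie_correction_applied=False,
            degenerate=True,
        )

    has_ties = np.unique(pooled).size < pooled.size
    if n1 + n2 <= 20 and not has_ties:
        counts = exact_u_null(n1, n2)
        total = counts.sum()
        cdf = np.cumsum(counts) / total  # P(U <= u)
        u_int = int(round(u1))
        p_le = cdf[u_int]                      # P(U1 <= u1)
        p_ge = 1.0 - (cdf[u_int - 1] if u_int > 0 else 0.0)  # P(U1 >= u1)
        method = "exact"
        tie_corr = False
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, t_counts = np.unique(pooled, return_counts=True)
        tie_term = ((t_counts**3 - t_counts).sum()) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        sigma = math.sqrt(sigma2)
        z = (u1 - mu) / sigma
        p_ge = _sps.norm.sf(z)
        p_le = _sps.norm.cdf(z)
        method = "normal_approx"
        tie_corr = has_ties

    if alternative == "greater":
        p_one = p_ge
    elif alternative == "less":
        p_one = p_le
    else:
        p_one = min(p_le, p_ge)
    p_one = min(1.0, float(p_one))
    p_two = min(1.0, 2.0 * min(float(p_le), float(p_ge)))
    return MWTestResult(
        u_statistic=u1,
        n1=n1,
        n2=n2,
        p_one_tailed=p_one,
        p_two_tailed=p_two,
        method=method,
        tie_correction_applied=tie_corr,
    )


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

Strength = Literal["very_weak", "weak", "moderate", "strong", "very_strong"]

_EVANS_BINS = (
    (0.20, "very_weak"),
    (0.40, "weak"),
    (0.60, "moderate"),
    (0.80, "strong"),
    (float("inf"), "very_strong"),
)


def evans_strength(r: float) -> Strength:
    """Evans strength label for a correlation coefficient, on |r|.

    Bins are closed on the left: |r| = 0.80 is already "very strong".
    """
    a = abs(r)
    for edge, label in _EVANS_BINS:
        if a < edge:
            return label  # type: ignore[return-value]
    return "very_strong"


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    method: Literal["pearson", "spearman"]
    strength: Strength

    def as_dict(self) -> dict:
        return {
            "r": self.r,
            "p_value": self.p_value,
            "n": self.n,
            "method": self.method,
            "strength": self.strength,
        }


def _corr_p(r: float, n: int) -> float:
    # two-tailed p from t = r * sqrt((n-2)/(1-r^2))
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * _sps.t.sf(abs(t), df=n - 2))


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise InsufficientDataError("need n >= 3 for correlation")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantInputError("correlation undefined for constant input")
    xm = x - x.mean()
    ym = y - y.mean()
    r = float(xm @ ym / math.sqrt((xm @ xm) * (ym @ ym)))
    r = max(-1.0, min(1.0, r))
    return CorrelationResult(r, _corr_p(r, x.size), x.size, "pearson", evans_strength(r))


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise InsufficientDataError("need n >= 3 for correlation")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantInputError("correlation undefined for constant input")
    rx = _midranks(x)
    ry = _midranks(y)
    base = pearson(rx, ry)
    return CorrelationResult(base.r, base.p_value, x.size, "spearman", base.strength)


# ---------------------------------------------------------------------------
# Polynomial regression with overall F-test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PolyFitResult:
    degree: int
    coefficients: tuple[float, ...]  # b0 (intercept) .. b_degree
    r: float  # multiple correlation, sqrt(R^2)
    r_squared: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float

    def formula(self, xname: str = "X", yname: str = "Y") -> str:
        """Render the fitted curve the way curve-estimation reports print it."""
        parts = [f"{self.coefficients[0]:.3f}"]
        for k, b in enumerate(self.coefficients[1:], start=1):
            op = "+" if b >= 0 else "-"
            term = f"{abs(b):.3f}*{xname}" + (f"^{k}" if k > 1 else "")
            parts.append(f" {op} {term}")
        return f"{yname} = " + "".join(parts)

    def as_dict(self) -> dict:
        return {
            "degree": self.degree,
            "coefficients": list(self.coefficients),
            "r": self.r,
            "r_squared": self.r_squared,
            "f_statistic": self.f_statistic,
            "df": list(self.df),
            "p_value": self.p_value,
        }


def polyfit_f(x: Sequence[float], y: Sequence[float], degree: int) -> PolyFitResult:
    """Least-squares polynomial fit of y on x with the overall F-test.

    F = (R^2/k) / ((1-R^2)/(n-k-1)), df = (k, n-k-1).  A saturated fit
    (n == degree+1 distinct points) has R^2 = 1 and an undefined F,
    reported as inf with p = 0.
    """
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("x and y must have equal length")
    if n < degree + 1:
        raise InsufficientDataError(f"need n >= degree + 1 (= {degree + 1}), got {n}")
    if np.unique(x).size <= degree:
        raise SingularFitError(
            f"need more than {degree} distinct x values for a degree-{degree} fit"
        )
    design = np.vander(x, degree + 1, increasing=True)
    coefs, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < degree + 1:
        raise SingularFitError("rank-deficient polynomial design matrix")
    fitted = design @ coefs
    sst = float(((y - y.mean()) ** 2).sum())
    ssr = float(((y - fitted) ** 2).sum())
    if sst == 0.0:
        raise ConstantInputError("y is constant; fit statistics undefined")
    r2 = max(0.0, min(1.0, 1.0 - ssr / sst))
    k = degree
    df2 = n - k - 1
    if df2 <= 0 or r2 >= 1.0 or ssr <= 1e-300 * sst:
        # saturated or perfect fit: the F ratio degenerates
        f_stat, p = float("inf"), 0.0
        r2 = 1.0
    else:
        f_stat = (r2 / k) / ((1.0 - r2) / df2)
        p = float(_sps.f.sf(f_stat, k, df2))
    return PolyFitResult(
        degree=degree,
        coefficients=tuple(float(c) for c in coefs),
        r=math.sqrt(r2),
        r_squared=r2,
        f_statistic=f_stat,
        df=(k, df2),
        p_value=p,
    )


# ---------------------------------------------------------------------------
# Box's M
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoxMResult:
    m_statistic: float
    chi2_approx: float
    df: int
    p_value: float

    def as_dict(self) -> dict:
        return {
            "m_statistic": self.m_statistic,
            "chi2_approx": self.chi2_approx,
            "df": self.df,
            "p_value": self.p_value,
        }


def boxs_m(groups: Sequence[np.ndarray]) -> BoxMResult:
    """Box's M test for equality of group covariance matrices.

    M = (N-g) ln|S_pooled| - sum (n_i - 1) ln|S_i|, with the standard
    Box scale factor and chi-square approximation on
    df = p (p+1) (g-1) / 2.  Each group needs n_i > p observations and a
    nonsingular sample covariance.
    """
    mats = [np.asarray(g, dtype=float) for g in groups]
    g = len(mats)
    if g < 2:
        raise InsufficientDataError("need at least two groups")
    p = mats[0].shape[1]
    ns = []
    covs = []
    for idx, m in enumerate(mats):
        if m.ndim != 2 or m.shape[1] != p:
            raise ValueError("all groups must share the same number of variables")
        n_i = m.shape[0]
        if n_i <= p:
            raise InsufficientDataError(
                f"group {idx} has n={n_i} <= p={p} observations"
            )
        cov = np.cov(m, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        sign, _ = np.linalg.slogdet(cov)
        if sign <= 0:
            raise SingularFitError(f"singular covariance in group {idx}")
        ns.append(n_i)
        covs.append(cov)
    n_total = sum(ns)
    pooled = sum((n_i - 1) * c for n_i, c in zip(ns, covs)) / (n_total - g)
    sign, logdet_pooled = np.linalg.slogdet(pooled)
    if sign <= 0:
        raise SingularFitError("singular pooled covariance")
    m_stat = (n_total - g) * logdet_pooled - sum(
        (n_i - 1) * np.linalg.slogdet(c)[1] for n_i, c in zip(ns, covs)
    )
    m_stat = float(max(0.0, m_stat))
    c_factor = (
        (sum(1.0 / (n_i - 1) for n_i in ns) - 1.0 / (n_total - g))
        * (2 * p * p + 3 * p - 1)
        / (6.0 * (p + 1) * (g - 1))
    )
    chi2 = m_stat * (1.0 - c_factor)
    df = p * (p + 1) * (g - 1) // 2
    p_value = float(_sps.chi2.sf(chi2, df))
    return BoxMResult(m_statistic=m_stat, chi2_approx=float(chi2), df=df, p_value=p_value)
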