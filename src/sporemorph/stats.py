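"""Two-group comparisons and bivariate spore-size statistics.

``compare_groups`` follows the normality-gated protocol common in
morphometric papers: Shapiro–Wilk on each group at α = 0.05; if both pass,
an independent two-sample t-test (Welch by default), otherwise a two-sided
Mann–Whitney test.  Small-sample Mann–Whitney p-values come from full
enumeration of the permutation distribution of U (tie-safe); larger samples
use the normal approximation with tie correction.  Significance stars follow
the 0.05 / 0.01 / 0.001 thresholds.

Bivariate spore-size clouds are summarised by an isoprobability ellipse of
the fitted bivariate normal (covariance eigen-decomposition scaled by the
χ²₂ quantile at the chosen probability level) and by a 2-D Gaussian kernel
density estimate (Scott's bandwidth rule by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "EllipseParams",
    "DensityGrid",
    "compare_groups",
    "exact_mann_whitney",
    "assign_stars",
    "iso_ellipse",
    "kde2",
]

#: largest per-group size for which Mann-Whitney is solved by enumeration
EXACT_MW_MAX_N = 8


@dataclass(frozen=True)
class TestResult:
    method: str  # welch_t | student_t | mann_whitney | shapiro_wilk
    statistic_value: float
    p_value: float
    stars: str  # ns | * | ** | ***
    group_sizes: tuple

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if self.stars != assign_stars(self.p_value):
            raise ValueError("stars inconsistent with p-value thresholds")


@dataclass(frozen=True)
class EllipseParams:
    center: tuple
    semi_major: float
    semi_minor: float
    angle_deg: float
    prob_level: float

    def __post_init__(self):
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError("require semi_major >= semi_minor > 0")
        if not (0.0 < self.prob_level < 1.0):
            raise ValueError("prob_level must lie in (0, 1)")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the ellipse."""
        pts = np.atleast_2d(points) - np.asarray(self.center)
        th = np.radians(self.angle_deg)
        rot = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
        uv = pts @ rot.T
        return (uv[:, 0] / self.semi_major) ** 2 + (uv[:, 1] / self.semi_minor) ** 2 <= 1.0


@dataclass(frozen=True)
class DensityGrid:
    x: np.ndarray
    y: np.ndarray
    density: np.ndarray  # shape (len(y), len(x))
    bandwidths: tuple

    def integral(self) -> float:
        return float(np.trapezoid(np.trapezoid(self.density, self.x, axis=1), self.y))


def assign_stars(p: float) -> str:
    """Significance stars at the 0.05 / 0.01 / 0.001 thresholds."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _result(method, stat, p, sizes) -> TestResult:
    p = float(min(max(p, 0.0), 1.0))
    return TestResult(method, float(stat), p, assign_stars(p), sizes)


def exact_mann_whitney(a, b) -> tuple[float, float]:
    """Mann–Whitney U and its exact two-sided p by full enumeration.

    Enumerates all C(n+m, n) assignments of the pooled values to groups and
    counts arrangements whose U deviates from the null mean nm/2 at least as
    much as observed.  Handles ties naturally (U counts pairs with a half
    credit for equal values); identical constant groups give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)
    # G[i, j] = 1 if pooled[i] > pooled[j], 0.5 on ties
    G = (pooled[:, None] > pooled[None, :]) + 0.5 * (pooled[:, None] == pooled[None, :])
    np.fill_diagonal(G, 0.0)
    idx_all = frozenset(range(n + m))
    u_obs = float(G[:n, n:].sum())
    dev_obs = abs(u_obs - n * m / 2.0)
    hits = total = 0
    for subset in combinations(range(n + m), n):
        rest = list(idx_all - set(subset))
        u = float(G[np.ix_(list(subset), rest)].sum())
        total += 1
        if abs(u - n * m / 2.0) >= dev_obs - 1e-12:
            hits += 1
    return u_obs, hits / total


def compare_groups(a, b, method: str = "auto", t_variant: str = "welch") -> TestResult:
    """Two-sided comparison of two independent samples.

    method 'auto' runs Shapiro–Wilk on each group (α = 0.05) and picks the
    t-test when both pass, Mann–Whitney otherwise; 't' and 'mw' force the
    branch.  The t-test is Welch's by default (``t_variant='student'`` for
    the pooled-variance form).  Mann–Whitney uses exact enumeration when
    both groups have ≤ 8 observations, otherwise the normal approximation
    with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(len(a), len(b)) < 2:
        raise ValueError("each group needs at least 2 observations")
    sizes = (len(a), len(b))

    if method == "auto":
        if min(len(a), len(b)) < 3:
            raise ValueError("auto mode needs n >= 3 per group for normality testing")
        normal = all(
            np.ptp(g) > 0 and sps.shapiro(g).pvalue >= 0.05 for g in (a, b)
        )
        method = "t" if normal else "mw"

    if method == "t":
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            # degenerate: both groups constant
            stat, p = (0.0, 1.0) if a[0] == b[0] else (np.inf, 0.0)
            return _result("welch_t" if t_variant == "welch" else "student_t", stat, p, sizes)
        res = sps.ttest_ind(a, b, equal_var=(t_variant == "student"))
        name = "welch_t" if t_variant == "welch" else "student_t"
        return _result(name, res.statistic, res.pvalue, sizes)

    if method == "mw":
        if max(sizes) <= EXACT_MW_MAX_N:
            u, p = exact_mann_whitney(a, b)
            return _result("mann_whitney", u, p, sizes)
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return _result("mann_whitney", res.statistic, res.pvalue, sizes)

    raise ValueError(f"unknown method {method!r}")


def shapiro_normality(x) -> TestResult:
    """Shapiro–Wilk normality test wrapped in the common result type."""
    x = np.asarray(x, dtype=float)
    res = sps.shapiro(x)
    return _result("shapiro_wilk", res.statistic, res.pvalue, (len(x),))


def iso_ellipse(points, prob_level: float = 0.95) -> EllipseParams:
    """Isoprobability ellipse of a fitted bivariate normal.

    Sample mean and covariance (n − 1) define the ellipse whose boundary is
    the Mahalanobis contour at the χ² (2 df) quantile of ``prob_level``; for
    normal data the expected fraction of points inside approaches the level.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need at least 3 bivariate points")
    if not (0.0 < prob_level < 1.0):
        raise ValueError("prob_level must lie in (0, 1)")
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    if np.linalg.det(cov) <= np.finfo(float).tiny:
        raise ValueError("singular covariance (collinear points)")
    evals, evecs = np.linalg.eigh(cov)  # ascending
    r2 = sps.chi2.ppf(prob_level, df=2)
    semi_minor, semi_major = np.sqrt(evals * r2)
    major_vec = evecs[:, 1]
    angle = float(np.degrees(np.arctan2(major_vec[1], major_vec[0])) % 180.0)
    return EllipseParams(
        center=(float(mean[0]), float(mean[1])),
        semi_major=float(semi_major),
        semi_minor=float(semi_minor),
        angle_deg=angle,
        prob_level=prob_level,
    )


def kde2(points, bandwidth_rule: str | float = "scott", gridsize: int = 128) -> DensityGrid:
    """2-D Gaussian kernel density estimate on a regular grid.

    The grid covers the data ± 3 bandwidths per axis, so the returned
    density integrates to 1 (within quadrature error).  Bandwidth by
    Scott's rule unless a scalar factor or 'silverman' is given.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need at least 2 bivariate points")
    if np.ptp(pts[:, 0]) == 0 or np.ptp(pts[:, 1]) == 0:
        raise ValueError(
            "zero variance along one axis; jitter the data or use a 1-D KDE"
        )
    kde = sps.gaussian_kde(pts.T, bw_method=bandwidth_rule)
    bw = np.sqrt(np.diag(kde.covariance))
    x = np.linspace(pts[:, 0].min() - 3 * bw[0], pts[:, 0].max() + 3 * bw[0], gridsize)
    y = np.linspace(pts[:, 1].min() - 3 * bw[1], pts[:, 1].max() + 3 * bw[1], gridsize)
    X, Y = np.meshgrid(x, y)
    Z = kde(np.vstack([X.ravel(), Y.ravel()])).reshape(Y.shape)
    return DensityGrid(x, y, Z, (float(bw[0]), float(bw[1])))
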