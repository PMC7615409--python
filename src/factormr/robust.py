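"""Identification-robust tests with estimated factors as instruments.

F-AR, F-LM and F-CLR test H0: theta = theta0 with null distributions that
do not depend on instrument strength; F-CLR conditions on the strength
statistic Q_T.  Confidence sets come from grid inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import roots_legendre

from factormr.liml import MomentSystem, MomentSystemError, TestResult, fit_fliml


class DegenerateStatisticError(ValueError):
    """A required matrix or scalar is numerically degenerate."""


@dataclass
class STStatistics:
    """The S/T decomposition at a hypothesized theta0."""

    S_bar: np.ndarray
    T_bar: np.ndarray
    Q_S: float
    Q_ST: float
    Q_T: float
    delta_gg: np.ndarray
    delta_g: np.ndarray
    theta0: float


@dataclass
class ConfidenceSet:
    intervals: list[tuple[float, float]]
    alpha: float
    grid: str
    unbounded: bool = False

    def contains(self, theta: float) -> bool:
        return any(lo <= theta <= hi for lo, hi in self.intervals)


def _inv_sqrt_psd(matrix: np.ndarray, name: str) -> np.ndarray:
    """Symmetric inverse square root via eigendecomposition."""
    matrix = 0.5 * (matrix + matrix.T)
    w, v = np.linalg.eigh(matrix)
    if w[0] <= 0:
        raise DegenerateStatisticError(f"{name} is not positive definite")
    return (v / np.sqrt(w)) @ v.T


def st_statistics(theta0: float, ms: MomentSystem) -> STStatistics:
    """Compute S, T and their quadratic forms at theta0.

    S = Omega(theta0)^{-1/2} g(theta0) carries validity information;
    T = {D_GG - D_G Omega(theta0)^{-1} D_G}^{-1/2} {G - D_G Omega(theta0)^{-1} g(theta0)}
    carries strength information, with D_GG = Omega_0 sigma_V^2 / n_X and
    D_G = D_GG theta0.  The two are asymptotically independent under H0.
    """
    s_scalar = ms.omega_scalar(theta0)
    if s_scalar <= 0:
        raise MomentSystemError("Omega(theta0) multiplier is zero")
    omega_theta = ms.omega0 * s_scalar
    omega_inv_sqrt = _inv_sqrt_psd(omega_theta, "Omega(theta0)")

    g0 = ms.g(theta0)
    G = ms.g_slope
    delta_gg = ms.omega0 * (ms.sigma_v2 / ms.n_x)
    delta_g = delta_gg * theta0

    S_bar = omega_inv_sqrt @ g0

    omega_inv = omega_inv_sqrt @ omega_inv_sqrt
    bracket = delta_gg - delta_g @ omega_inv @ delta_g
    bracket_inv_sqrt = _inv_sqrt_psd(bracket, "T-bracket matrix")
    T_bar = bracket_inv_sqrt @ (G - delta_g @ omega_inv @ g0)

    return STStatistics(
        S_bar=S_bar,
        T_bar=T_bar,
        Q_S=float(S_bar @ S_bar),
        Q_ST=float(S_bar @ T_bar),
        Q_T=float(T_bar @ T_bar),
        delta_gg=delta_gg,
        delta_g=delta_g,
        theta0=theta0,
    )


def ar_test(theta0: float, ms: MomentSystem) -> TestResult:
    """Anderson-Rubin test with estimated factors: Q_S against chi^2_r."""
    st = st_statistics(theta0, ms)
    return TestResult(
        statistic=st.Q_S,
        p_value=float(stats.chi2.sf(st.Q_S, ms.r)),
        null_law=f"chi2_{ms.r}",
        theta0=theta0,
    )


def lm_test(theta0: float, ms: MomentSystem) -> TestResult:
    """Lagrange multiplier test: Q_ST^2 / Q_T against chi^2_1."""
    st = st_statistics(theta0, ms)
    if st.Q_T <= 0:
        raise DegenerateStatisticError("Q_T = 0: instruments entirely irrelevant")
    statistic = st.Q_ST**2 / st.Q_T
    return TestResult(
        statistic=statistic,
        p_value=float(stats.chi2.sf(statistic, 1)),
        null_law="chi2_1",
        theta0=theta0,
    )


def clr_statistic(Q_S: float, Q_ST: float, Q_T: float) -> float:
    """[Q_S - Q_T + sqrt{(Q_S+Q_T)^2 - 4(Q_S Q_T - Q_ST^2)}] / 2."""
    disc = (Q_S + Q_T) ** 2 - 4 * (Q_S * Q_T - Q_ST**2)
    if disc < -1e-10:
        raise DegenerateStatisticError("negative CLR discriminant")
    disc = max(disc, 0.0)
    return 0.5 * (Q_S - Q_T + np.sqrt(disc))


def clr_pvalue_numeric(m0: float, q_t: float, r: int, n_nodes: int = 256) -> float:
    """Conditional p-value P(CLR >= m0 | Q_T = q_t) by 1-D quadrature.

    Conditional on q_t, the null CLR statistic is a function of independent
    chi^2_1 (component of S along T) and chi^2_{r-1} draws.  For fixed
    chi^2_1 = x the statistic exceeds m0 iff the chi^2_{r-1} part exceeds
    (m0 + q_t) - x (1 + q_t / m0), a threshold that reaches zero at x = m0.
    The x-integral uses Gauss-Legendre after the substitution x = u^2,
    which removes the chi^2_1 density singularity at zero.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    if m0 <= 0:
        return 1.0
    if r == 1:
        return float(stats.chi2.sf(m0, 1))
    nodes, weights = roots_legendre(n_nodes)
    # map [-1, 1] -> u in [0, sqrt(m0)], x = u^2
    u = 0.5 * np.sqrt(m0) * (nodes + 1.0)
    half_width = 0.5 * np.sqrt(m0)
    x = u**2
    # chi^2_1 density transformed: f(x) dx = sqrt(2/pi) exp(-u^2/2) du
    dens = np.sqrt(2.0 / np.pi) * np.exp(-0.5 * u**2)
    thresh = (m0 + q_t) - x * (1.0 + q_t / m0)
    tail = stats.chi2.sf(np.clip(thresh, 0.0, None), r - 1)
    integral = float(np.sum(weights * dens * tail)) * half_width
    p = integral + float(stats.chi2.sf(m0, 1))
    return min(max(p, 0.0), 1.0)


def clr_pvalue_montecarlo(
    m0: float, q_t: float, r: int, n_draws: int = 200_000, seed: int | None = 0
) -> float:
    """Monte-Carlo cross-check of the conditional CLR p-value."""
    if m0 <= 0:
        return 1.0
    rng = np.random.default_rng(seed)
    chi1 = rng.chisquare(1, size=n_draws)
    chir = rng.chisquare(r - 1, size=n_draws) if r > 1 else np.zeros(n_draws)
    s = chi1 + chir
    stat = 0.5 * (s - q_t + np.sqrt((s - q_t) ** 2 + 4 * chi1 * q_t))
    return float(np.mean(stat >= m0))


def clr_test(
    theta0: float,
    ms: MomentSystem,
    pvalue_method: str = "numeric",
    mc_draws: int = 200_000,
    seed: int | None = 0,
) -> TestResult:
    """Conditional likelihood ratio test with estimated factors."""
    st = st_statistics(theta0, ms)
    statistic = clr_statistic(st.Q_S, st.Q_ST, st.Q_T)
    if pvalue_method == "numeric":
        p = clr_pvalue_numeric(statistic, st.Q_T, ms.r)
    elif pvalue_method == "montecarlo":
        p = clr_pvalue_montecarlo(statistic, st.Q_T, ms.r, mc_draws, seed)
    else:
        raise ValueError(f"unknown pvalue_method {pvalue_method!r}")
    return TestResult(
        statistic=statistic,
        p_value=p,
        null_law=f"clr_conditional(Q_T={st.Q_T:.6g})",
        theta0=theta0,
    )


_TESTS = {"ar": ar_test, "lm": lm_test, "clr": clr_test}


def invert_test(
    test: str,
    ms: MomentSystem,
    alpha: float = 0.05,
    bracket: tuple[float, float] | None = None,
    resolution: int = 2001,
) -> ConfidenceSet:
    """Confidence set {theta0 : p(theta0) >= alpha} by grid scan + bisection.

    The bracket defaults to theta_F +/- 20 sd when an F-LIML fit is
    available.  Disconnected regions are reported as separate intervals;
    a region touching the bracket edge sets the ``unbounded`` flag.
    """
    if test not in _TESTS:
        raise ValueError(f"test must be one of {sorted(_TESTS)}")
    test_fn = _TESTS[test]

    if bracket is None:
        fit = fit_fliml(ms)
        half = 20.0 * np.sqrt(fit.variance)
        if half <= 0 or not np.isfinite(half):
            raise ValueError("cannot auto-bracket: degenerate F-LIML variance")
        bracket = (fit.theta - half, fit.theta + half)
    lo, hi = bracket
    grid = np.linspace(lo, hi, resolution)

    def pval(theta0: float) -> float:
        return test_fn(theta0, ms).p_value

    pvals = np.array([pval(t) for t in grid])
    if not np.all(np.isfinite(pvals)):
        raise ValueError("non-finite p-value on inversion grid")
    accept = pvals >= alpha

    def _refine(inside: float, outside: float) -> float:
        # bisect the acceptance boundary between an accepted and rejected point
        for _ in range(100):
            mid = 0.5 * (inside + outside)
            if abs(outside - inside) < 1e-4:
                break
            if pval(mid) >= alpha:
                inside = mid
            else:
                outside = mid
        return 0.5 * (inside + outside)

    intervals: list[tuple[float, float]] = []
    unbounded = False
    i = 0
    while i < resolution:
        if not accept[i]:
            i += 1
            continue
        j = i
        while j + 1 < resolution and accept[j + 1]:
            j += 1
        left = grid[i] if i == 0 else _refine(grid[i], grid[i - 1])
        right = grid[j] if j == resolution - 1 else _refine(grid[j], grid[j + 1])
        if i == 0 or j == resolution - 1:
            unbounded = True
        intervals.append((float(left), float(right)))
        i = j + 1

    return ConfidenceSet(
        intervals=intervals,
        alpha=alpha,
        grid=f"[{lo:.6g}, {hi:.6g}] x {resolution}",
        unbounded=unbounded,
    )
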