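"""Moment construction, F-LIML estimation and the heterogeneity diagnostic.

The r estimating equations are g(theta) = L'(delta_Y - delta_X theta),
with variance Omega(theta) = Omega_0 * (sigma_e^2 / n_Y +
theta^2 sigma_V^2 / n_X) — a scalar multiple of Omega_0.  That structure
makes the LIML objective a ratio of quadratics in theta, so the minimizer
solves a quadratic equation in closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from factormr.factors import FactorMoments, LoadingsEstimate
from factormr.summary_data import SummaryDataset, VariantCovariance

SIGMA_FLOOR_SCALE = 1e-10


class MomentSystemError(ValueError):
    """Degenerate or singular moment system."""


@dataclass
class MomentSystem:
    """Everything the factor-level estimators need, on the moment scale."""

    m_x: np.ndarray            # L' delta_X (r-vector)
    m_y: np.ndarray            # L' delta_Y
    omega0: np.ndarray         # r x r
    sigma_v2: float
    sigma_e2: float
    n_x: int
    n_y: int
    var_x: float = 1.0
    var_y: float = 1.0
    sigma_clipped: bool = False

    def __post_init__(self) -> None:
        self.m_x = np.asarray(self.m_x, dtype=float)
        self.m_y = np.asarray(self.m_y, dtype=float)
        self.omega0 = np.asarray(self.omega0, dtype=float)
        if self.sigma_v2 < 0 or self.sigma_e2 < 0:
            raise MomentSystemError("variance components must be nonnegative")

    @property
    def r(self) -> int:
        return self.m_x.size

    @property
    def g_slope(self) -> np.ndarray:
        """G = -L' delta_X, the derivative of g(theta) in theta."""
        return -self.m_x

    def g(self, theta: float) -> np.ndarray:
        return self.m_y - self.m_x * theta

    def omega_scalar(self, theta: float) -> float:
        """Scalar s(theta) with Omega(theta) = Omega_0 * s(theta)."""
        return self.sigma_e2 / self.n_y + theta**2 * self.sigma_v2 / self.n_x

    def subset(self, indices: np.ndarray) -> "MomentSystem":
        """Restrict the moment system to a subset of factors (selection matrix)."""
        indices = np.asarray(indices, dtype=int)
        return MomentSystem(
            m_x=self.m_x[indices],
            m_y=self.m_y[indices],
            omega0=self.omega0[np.ix_(indices, indices)],
            sigma_v2=self.sigma_v2,
            sigma_e2=self.sigma_e2,
            n_x=self.n_x,
            n_y=self.n_y,
            var_x=self.var_x,
            var_y=self.var_y,
            sigma_clipped=self.sigma_clipped,
        )


@dataclass
class FLimlFit:
    theta: float
    variance: float
    ci_low: float
    ci_high: float
    objective_at_min: float


@dataclass
class TestResult:
    statistic: float
    p_value: float
    null_law: str
    theta0: float | None = None


def _solve_omega0(omega0: np.ndarray, vec: np.ndarray) -> np.ndarray:
    try:
        sol = np.linalg.solve(omega0, vec)
    except np.linalg.LinAlgError as exc:
        raise MomentSystemError(
            "Omega_0 is singular; try a smaller number of factors"
        ) from exc
    return sol


def build_moment_system(
    data: SummaryDataset,
    loadings: LoadingsEstimate,
    varz: VariantCovariance,
) -> MomentSystem:
    """Project summary data through the loadings and estimate variance components.

    sigma_V^2 = var(X) - (L'dX)' Omega_0^{-1} (L'dX), and analogously for
    sigma_eps^2 with the outcome.  Negative plug-in values are clipped at a
    small positive floor with a warning.
    """
    lam = loadings.loadings
    omega0 = lam.T @ varz.matrix @ lam
    omega0 = 0.5 * (omega0 + omega0.T)
    m_x = lam.T @ data.delta_x
    m_y = lam.T @ data.delta_y

    sigma_v2 = data.var_x - float(m_x @ _solve_omega0(omega0, m_x))
    sigma_e2 = data.var_y - float(m_y @ _solve_omega0(omega0, m_y))

    clipped = False
    floor_v = SIGMA_FLOOR_SCALE * data.var_x
    floor_e = SIGMA_FLOOR_SCALE * data.var_y
    if sigma_v2 < floor_v:
        warnings.warn(
            "sigma_V^2 plug-in estimate at or below zero; clipped to floor",
            RuntimeWarning,
            stacklevel=2,
        )
        sigma_v2 = floor_v
        clipped = True
    if sigma_e2 < floor_e:
        warnings.warn(
            "sigma_eps^2 plug-in estimate at or below zero; clipped to floor",
            RuntimeWarning,
            stacklevel=2,
        )
        sigma_e2 = floor_e
        clipped = True

    return MomentSystem(
        m_x=m_x,
        m_y=m_y,
        omega0=omega0,
        sigma_v2=sigma_v2,
        sigma_e2=sigma_e2,
        n_x=data.n_x,
        n_y=data.n_y,
        var_x=data.var_x,
        var_y=data.var_y,
        sigma_clipped=clipped,
    )


def moment_covariance(theta: float, ms: MomentSystem) -> np.ndarray:
    """Omega(theta) = Omega_0 * (sigma_e^2/n_Y + theta^2 sigma_V^2/n_X)."""
    s = ms.omega_scalar(theta)
    if s <= 0:
        raise MomentSystemError("moment covariance multiplier is zero")
    return ms.omega0 * s


def _objective_coefficients(ms: MomentSystem) -> tuple[float, float, float]:
    """(a, b, c) with g(t)' Omega_0^{-1} g(t) = a t^2 - 2 b t + c."""
    sol_x = _solve_omega0(ms.omega0, ms.m_x)
    sol_y = _solve_omega0(ms.omega0, ms.m_y)
    a = float(ms.m_x @ sol_x)
    b = float(ms.m_x @ sol_y)
    c = float(ms.m_y @ sol_y)
    return a, b, c


def objective(theta: float | np.ndarray, ms: MomentSystem) -> float | np.ndarray:
    """Q(theta) = g(theta)' Omega(theta)^{-1} g(theta)."""
    a, b, c = _objective_coefficients(ms)
    theta = np.asarray(theta, dtype=float)
    num = a * theta**2 - 2 * b * theta + c
    den = ms.sigma_e2 / ms.n_y + theta**2 * ms.sigma_v2 / ms.n_x
    out = num / den
    return float(out) if out.ndim == 0 else out


def fit_fliml(ms: MomentSystem, alpha: float = 0.05) -> FLimlFit:
    """Minimize the LIML objective in closed form and attach Wald inference.

    With alpha_d = sigma_e^2/n_Y, beta_d = sigma_V^2/n_X, the first-order
    condition reduces to b*beta_d*t^2 + (a*alpha_d - c*beta_d)*t - b*alpha_d = 0;
    among real roots the one with the smaller objective value is the global
    minimizer of the ratio of quadratics.
    """
    a, b, c = _objective_coefficients(ms)
    alpha_d = ms.sigma_e2 / ms.n_y
    beta_d = ms.sigma_v2 / ms.n_x

    candidates: list[float] = []
    qa = b * beta_d
    qb = a * alpha_d - c * beta_d
    qc = -b * alpha_d
    if abs(qa) > 1e-300:
        disc = qb**2 - 4 * qa * qc
        if disc < 0:
            raise MomentSystemError("no real minimizer of the LIML objective")
        sq = np.sqrt(disc)
        candidates += [(-qb + sq) / (2 * qa), (-qb - sq) / (2 * qa)]
    elif abs(qb) > 1e-300:
        candidates.append(-qc / qb)
    else:
        # flat first-order condition; fall back to a coarse grid
        if a <= 0:
            raise MomentSystemError("degenerate LIML objective (a = 0)")
        grid = np.linspace(-100.0, 100.0, 20001)
        vals = objective(grid, ms)
        candidates.append(float(grid[np.argmin(vals)]))

    vals = [float(objective(t, ms)) for t in candidates]
    theta_hat = float(candidates[int(np.argmin(vals))])
    q_min = float(min(vals))

    if a <= 0:
        raise MomentSystemError("G' Omega_0^{-1} G is not positive; cannot form V")
    variance = ms.omega_scalar(theta_hat) / a
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(variance)
    return FLimlFit(
        theta=theta_hat,
        variance=variance,
        ci_low=theta_hat - half,
        ci_high=theta_hat + half,
        objective_at_min=max(q_min, 0.0),
    )


def sargan_hansen(
    theta_eval: float,
    ms: MomentSystem,
    df: int | None = None,
    *,
    at_minimizer: bool = True,
) -> TestResult:
    """Overidentification test of mutual consistency of the factor instruments.

    The statistic is the LIML objective evaluated at ``theta_eval``.  When
    ``theta_eval`` is the LIML minimizer one parameter was estimated, so the
    reference distribution is chi^2_{r-1}; for a substituted value (e.g. a
    confidence-interval midpoint) no parameter is estimated and chi^2_r is
    used.  ``df`` overrides either convention.
    """
    if df is None:
        df = ms.r - 1 if at_minimizer else ms.r
    if df < 1:
        raise ValueError("Sargan-Hansen test needs df >= 1 (r >= 2 at the minimizer)")
    statistic = float(objective(theta_eval, ms))
    p_value = float(stats.chi2.sf(statistic, df))
    return TestResult(
        statistic=statistic,
        p_value=p_value,
        null_law=f"chi2_{df}",
        theta0=theta_eval,
    )


def factor_f_statistic(ms: MomentSystem, r: int | None = None) -> float:
    """Aggregate instrument-strength measure for the estimated factors.

    Defined as F = 1 + n_X (L'dX)' Omega_0^{-1} (L'dX) / (r sigma_V^2),
    the expected first-stage F of a regression of the exposure on the r
    factor scores.  Unreliable (warning) when sigma_V^2 sat at its clip floor.
    """
    if r is None:
        r = ms.r
    if ms.sigma_v2 <= 0:
        raise MomentSystemError("sigma_V^2 must be positive for the F-statistic")
    if ms.sigma_clipped:
        warnings.warn(
            "sigma_V^2 was clipped; F-statistic may be unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    quad = float(ms.m_x @ _solve_omega0(ms.omega0, ms.m_x))
    return 1.0 + ms.n_x * quad / (r * ms.sigma_v2)
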