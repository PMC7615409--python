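"""Selective inference after pre-testing factor relevance (S-LIML).

Factors are screened with two-sided t-tests of their exposure association;
LIML is refit on the survivors.  Testing H0: theta = theta0 then has to
account for the screening: the conditional test draws from the null law of
the selected-factor estimate, keeps only draws consistent with the
observed selection event, and compares the estimate to the conditional
quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from factormr.liml import MomentSystem, fit_fliml
from factormr.robust import ConfidenceSet


class SelectionError(ValueError):
    """Pre-testing left no usable factors or the selection event is too rare."""


@dataclass
class Selection:
    """Result of the factor-relevance pre-test."""

    t_stats: np.ndarray        # r-vector of pre-test t-statistics
    threshold: float           # c_nu = Phi^{-1}(1 - nu/2)
    nu: float
    selected: np.ndarray       # ordered indices of selected factors
    selection_matrix: np.ndarray  # r x r* 0/1 matrix
    r_star: int


@dataclass
class SLimlFit:
    theta_s: float
    v_s: float
    c_g: np.ndarray            # r-vector coupling selection stats to the estimate
    d_diag: np.ndarray         # diag of Delta_GG
    u: np.ndarray              # observed conditioning statistic
    selection: Selection
    ci_low: float = np.nan     # Wald interval on the selected subsystem
    ci_high: float = np.nan


@dataclass
class ConditionalTestResult:
    theta0: float
    lower_q: float
    upper_q: float
    reject: bool
    acceptance_prob: float
    n_draws: int
    n_kept: int
    seed: int | None


def pretest_factors(ms: MomentSystem, nu: float = 0.01) -> Selection:
    """Two-sided t pre-test of each factor's exposure association.

    t_j = G_j / sqrt((Delta_GG)_jj) with Delta_GG = Omega_0 sigma_V^2/n_X;
    factor j is selected iff |t_j| strictly exceeds c_nu = Phi^{-1}(1 - nu/2).
    """
    if not 0 < nu < 1:
        raise ValueError("nu must lie strictly in (0, 1)")
    d_diag = np.diag(ms.omega0) * (ms.sigma_v2 / ms.n_x)
    if np.any(d_diag <= 0):
        raise SelectionError("Delta_GG has nonpositive diagonal entries")
    t_stats = ms.g_slope / np.sqrt(d_diag)
    threshold = float(stats.norm.ppf(1 - nu / 2))
    selected = np.flatnonzero(np.abs(t_stats) > threshold)
    r_star = selected.size
    gamma = np.zeros((ms.r, r_star))
    gamma[selected, np.arange(r_star)] = 1.0
    if r_star == 0:
        raise SelectionError(
            f"no relevant factors at level nu = {nu}; "
            "consider identification-robust tests instead"
        )
    return Selection(
        t_stats=t_stats,
        threshold=threshold,
        nu=nu,
        selected=selected,
        selection_matrix=gamma,
        r_star=r_star,
    )


def fit_sliml(ms: MomentSystem, selection: Selection, alpha: float = 0.05) -> SLimlFit:
    """LIML on the selected factor subset, plus the conditioning quantities.

    theta_S is the F-LIML minimizer of the projected moment system; the
    coupling vector C_G = -D^{-1/2} Delta_GG Gamma_S Omega_S^{-1} G_S V_S theta_S
    and the sufficient statistic U = T - C_G V_S^{-1} theta_S feed the
    conditional test.
    """
    if selection.r_star < 1:
        raise SelectionError("selection contains no factors")
    sub = ms.subset(selection.selected)
    fit = fit_fliml(sub, alpha=alpha)
    theta_s, v_s = fit.theta, fit.variance

    delta_gg = ms.omega0 * (ms.sigma_v2 / ms.n_x)
    d_diag = np.diag(delta_gg)
    s_scalar = ms.omega_scalar(theta_s)
    omega_s = sub.omega0 * s_scalar
    g_s = sub.g_slope
    sol = np.linalg.solve(omega_s, g_s)
    c_g = -(delta_gg[:, selection.selected] @ sol) * v_s * theta_s / np.sqrt(d_diag)
    u = selection.t_stats - c_g * theta_s / v_s
    return SLimlFit(
        theta_s=theta_s,
        v_s=v_s,
        c_g=c_g,
        d_diag=d_diag,
        u=u,
        selection=selection,
        ci_low=fit.ci_low,
        ci_high=fit.ci_high,
    )


def _selection_event_mask(
    u_bar_abs: np.ndarray, selection: Selection
) -> np.ndarray:
    """Boolean mask of draws consistent with the observed selection event."""
    c = selection.threshold
    in_sel = np.zeros(u_bar_abs.shape[1], dtype=bool)
    in_sel[selection.selected] = True
    ok_selected = np.all(u_bar_abs[:, in_sel] > c, axis=1)
    ok_dropped = np.all(u_bar_abs[:, ~in_sel] <= c, axis=1)
    return ok_selected & ok_dropped


def conditional_test(
    theta0: float,
    fit: SLimlFit,
    ms: MomentSystem,
    alpha: float = 0.05,
    n_draws: int = 200_000,
    seed: int | None = 0,
    *,
    u_bar_form: str = "consistent",
    k_draws: np.ndarray | None = None,
    min_kept: int = 100,
) -> ConditionalTestResult:
    """Monte-Carlo conditional test of H0: theta = theta0 given selection.

    Draws K ~ N(0,1), forms candidate estimates theta(K) = theta0 +
    sqrt(V_S) K, reconstructs the pre-test vector u_bar(K), keeps draws
    where the observed selection event recurs, and compares theta_S to the
    (alpha/2, 1 - alpha/2) empirical quantiles of the kept draws.

    ``u_bar_form="consistent"`` uses u_bar = u + C_G V_S^{-1} theta(K),
    which reduces to the observed pre-test vector at theta(K) = theta_S and
    supports inversion at theta0 != 0; ``"displayed"`` uses
    u_bar = u + C_G V_S^{-1/2} K (the two agree at theta0 = 0).
    """
    if k_draws is not None:
        k = np.asarray(k_draws, dtype=float)
        n_draws = k.size
    else:
        if n_draws < 10_000:
            raise ValueError("n_draws must be at least 10^4")
        k = np.random.default_rng(seed).standard_normal(n_draws)

    theta_vec = theta0 + np.sqrt(fit.v_s) * k
    if u_bar_form == "consistent":
        shift = np.outer(theta_vec / fit.v_s, fit.c_g)
    elif u_bar_form == "displayed":
        shift = np.outer(k / np.sqrt(fit.v_s), fit.c_g)
    else:
        raise ValueError(f"unknown u_bar_form {u_bar_form!r}")
    u_bar_abs = np.abs(fit.u[None, :] + shift)
    mask = _selection_event_mask(u_bar_abs, fit.selection)
    n_kept = int(mask.sum())
    if n_kept < min_kept:
        raise SelectionError(
            f"selection event too rare under H0 ({n_kept}/{n_draws} draws kept); "
            "increase draws or report an identification-robust interval"
        )
    kept = theta_vec[mask]
    lower_q = float(np.quantile(kept, alpha / 2))
    upper_q = float(np.quantile(kept, 1 - alpha / 2))
    return ConditionalTestResult(
        theta0=theta0,
        lower_q=lower_q,
        upper_q=upper_q,
        reject=not (lower_q <= fit.theta_s <= upper_q),
        acceptance_prob=n_kept / n_draws,
        n_draws=n_draws,
        n_kept=n_kept,
        seed=seed,
    )


def selective_ci(
    fit: SLimlFit,
    ms: MomentSystem,
    alpha: float = 0.05,
    bracket: tuple[float, float] | None = None,
    resolution: int = 201,
    n_draws: int = 200_000,
    seed: int | None = 0,
    u_bar_form: str = "consistent",
) -> ConfidenceSet:
    """Selective confidence set by inverting the conditional test.

    One K-stream is drawn up front and reused across all grid points
    (common random numbers), which keeps the acceptance boundary smooth in
    theta0 and makes the endpoints reproducible for a fixed seed.
    """
    if bracket is None:
        z = stats.norm.ppf(1 - alpha / 2)
        half = 5.0 * z * np.sqrt(fit.v_s)
        bracket = (fit.theta_s - half, fit.theta_s + half)
    k = np.random.default_rng(seed).standard_normal(n_draws)

    def accepts(theta0: float) -> bool:
        try:
            res = conditional_test(
                theta0, fit, ms, alpha=alpha,
                u_bar_form=u_bar_form, k_draws=k, seed=seed,
            )
        except SelectionError:
            return False
        return not res.reject

    lo, hi = bracket
    grid = np.linspace(lo, hi, resolution)
    flags = np.array([accepts(t) for t in grid])

    def _refine(inside: float, outside: float) -> float:
        for _ in range(60):
            if abs(outside - inside) < 1e-4:
                break
            mid = 0.5 * (inside + outside)
            if accepts(mid):
                inside = mid
            else:
                outside = mid
        return 0.5 * (inside + outside)

    intervals: list[tuple[float, float]] = []
    unbounded = False
    i = 0
    while i < resolution:
        if not flags[i]:
            i += 1
            continue
        j = i
        while j + 1 < resolution and flags[j + 1]:
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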