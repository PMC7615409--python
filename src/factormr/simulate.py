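"""Synthetic cis regions and Monte-Carlo studies.

A region truth is a block-structured factor model for the variants plus
covariance-scale trait associations.  Two-sample summary statistics are
drawn at the factor level — the Gaussian law of L'delta_hat with
covariances Omega_0 sigma_V^2/n_X and Omega_0 sigma_e^2/n_Y — and lifted
back to variant space through the loadings pseudoinverse, which preserves
the distribution of every downstream statistic (all depend on delta_hat
only through factor projections).

Model catalogue: 1 = correct specification, varying instrument strength;
2/3 = local pleiotropy delta_Y = delta_X theta0 + tau/sqrt(n) with
constant (2) or U(-1,1) (3) direct effects; 4 = additive correlation
mismeasurement rho - kappa0; 5 = power-transformed correlations
sign(rho) |rho|^kappa2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from factormr import liml, robust, selective
from factormr.factors import estimate_loadings
from factormr.summary_data import (
    LDMatrix,
    SummaryDataset,
    VariantCovariance,
    nearest_psd,
)

logger = logging.getLogger(__name__)


@dataclass
class RegionTruth:
    """Ground truth for a synthetic cis region."""

    loadings: np.ndarray          # p x r true loadings
    factor_cov: np.ndarray        # r x r Sigma_F
    idio_sd: np.ndarray           # p-vector
    variant_variances: np.ndarray # diag of implied var(Z)
    delta_x: np.ndarray
    delta_y: np.ndarray
    theta0: float
    var_x: float = 1.0
    var_y: float = 1.0
    tau: np.ndarray | None = None

    @property
    def p(self) -> int:
        return self.loadings.shape[0]

    @property
    def r(self) -> int:
        return self.loadings.shape[1]

    def var_z(self) -> np.ndarray:
        vz = self.loadings @ self.factor_cov @ self.loadings.T + np.diag(self.idio_sd**2)
        return 0.5 * (vz + vz.T)

    def correlation(self) -> np.ndarray:
        vz = self.var_z()
        sd = np.sqrt(np.diag(vz))
        rho = vz / np.outer(sd, sd)
        np.fill_diagonal(rho, 1.0)
        return rho

    def omega0(self) -> np.ndarray:
        om = self.loadings.T @ self.var_z() @ self.loadings
        return 0.5 * (om + om.T)

    def factor_assoc_x(self) -> np.ndarray:
        return self.loadings.T @ self.delta_x

    def factor_assoc_y(self) -> np.ndarray:
        return self.loadings.T @ self.delta_y

    def sigma_v2(self) -> float:
        m = self.factor_assoc_x()
        return self.var_x - float(m @ np.linalg.solve(self.omega0(), m))

    def sigma_e2(self) -> float:
        m = self.factor_assoc_y()
        return self.var_y - float(m @ np.linalg.solve(self.omega0(), m))


def synth_region(
    p: int,
    r: int,
    seed: int | None = 0,
    block_structure: Mapping[str, float] | None = None,
    theta0: float = 0.0,
) -> RegionTruth:
    """Generate a block-structured region truth.

    Variants are split into r contiguous blocks; each block loads with a
    coherent sign on its own factor, with small cross-loadings elsewhere.
    Idiosyncratic variances are set so the implied var(Z) has unit
    diagonal.  ``block_structure`` keys (all optional): ``signal_share``
    (systematic variance share per variant, default 0.9),
    ``cross_loading`` (relative magnitude of off-block loadings, 0.1),
    ``exposure_quad`` (the quadratic form (L'dX)' Omega_0^{-1} (L'dX),
    i.e. var_x - sigma_V^2, default 0.002 — weak per-variant associations,
    so calibrated sample sizes land in a realistic range).
    """
    if r >= p:
        raise ValueError("need r < p")
    cfg = {"signal_share": 0.9, "cross_loading": 0.1, "exposure_quad": 0.002}
    cfg.update(block_structure or {})
    if not 0 < cfg["signal_share"] < 1:
        raise ValueError("signal_share must lie in (0, 1): idiosyncratic variance "
                         "would be nonpositive after rescaling")
    rng = np.random.default_rng(seed)

    blocks = np.array_split(np.arange(p), r)
    lam = rng.uniform(0.2, 1.0, size=(p, r)) * cfg["cross_loading"]
    lam *= rng.choice([-1.0, 1.0], size=(p, r))
    for k, idx in enumerate(blocks):
        lam[idx, k] = rng.uniform(0.7, 1.0, size=idx.size)
    factor_cov = np.eye(r)

    # rescale rows so systematic variance is signal_share, idio the rest
    sys_var = np.einsum("ij,jk,ik->i", lam, factor_cov, lam)
    lam *= np.sqrt(cfg["signal_share"] / sys_var)[:, None]
    idio_sd = np.sqrt(1.0 - cfg["signal_share"]) * np.ones(p)

    # exposure associations through the factors, scaled to a fixed quadratic form
    gamma = rng.uniform(0.5, 1.5, size=r) * rng.choice([-1.0, 1.0], size=r)
    delta_x = lam @ gamma
    truth = RegionTruth(
        loadings=lam,
        factor_cov=factor_cov,
        idio_sd=idio_sd,
        variant_variances=np.ones(p),
        delta_x=delta_x,
        delta_y=delta_x * theta0,
        theta0=theta0,
    )
    m = truth.factor_assoc_x()
    quad = float(m @ np.linalg.solve(truth.omega0(), m))
    scale = np.sqrt(cfg["exposure_quad"] / quad)
    truth.delta_x = delta_x * scale
    truth.delta_y = truth.delta_x * theta0
    return truth


def calibrate_n(truth: RegionTruth, f_target: float) -> int:
    """Sample size giving a target factor-level F-statistic.

    Inverts F = 1 + n (L'dX)' Omega_0^{-1} (L'dX) / (r sigma_V^2), rounding up.
    """
    if f_target <= 1:
        raise ValueError("f_target must exceed 1")
    m = truth.factor_assoc_x()
    quad = float(m @ np.linalg.solve(truth.omega0(), m))
    if quad <= 0:
        raise ValueError("delta_x has no factor-level association; cannot calibrate")
    n = (f_target - 1.0) * truth.r * truth.sigma_v2() / quad
    return int(np.ceil(n))


def draw_summary_stats(
    truth: RegionTruth,
    n_x: int,
    n_y: int,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> SummaryDataset:
    """Draw two-sample covariance-scale summary statistics.

    Factor-level associations are drawn from their Gaussian law and lifted
    to variant space via delta_hat = delta + L (L'L)^{-1} (m - L'delta),
    so that L' delta_hat equals the drawn factor-level vector exactly and
    the off-span component stays at truth.
    """
    if n_x < 2 or n_y < 2:
        raise ValueError("sample sizes must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    sigma_v2 = truth.sigma_v2()
    sigma_e2 = truth.sigma_e2()
    if sigma_v2 <= 0:
        raise ValueError("truth implies sigma_V^2 <= 0")
    if sigma_e2 <= 0:
        raise ValueError("truth implies sigma_e^2 <= 0")
    omega0 = truth.omega0()
    chol = np.linalg.cholesky(omega0)
    m_x = truth.factor_assoc_x() + np.sqrt(sigma_v2 / n_x) * (chol @ rng.standard_normal(truth.r))
    m_y = truth.factor_assoc_y() + np.sqrt(sigma_e2 / n_y) * (chol @ rng.standard_normal(truth.r))

    lam = truth.loadings
    lift = lam @ np.linalg.solve(lam.T @ lam, np.eye(truth.r))
    delta_x_hat = truth.delta_x + lift @ (m_x - truth.factor_assoc_x())
    delta_y_hat = truth.delta_y + lift @ (m_y - truth.factor_assoc_y())
    ids = [f"v{j+1}" for j in range(truth.p)]
    return SummaryDataset(
        variant_ids=ids,
        delta_x=delta_x_hat,
        delta_y=delta_y_hat,
        n_x=n_x,
        n_y=n_y,
        var_x=truth.var_x,
        var_y=truth.var_y,
        variant_variances=truth.variant_variances.copy(),
    )


def noisy_variant_variances(
    truth: RegionTruth,
    n: int,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Truncated-normal measurement noise on per-variant variances.

    Each draw has mean var(Z_j), variance 1/n, and is bounded by the
    minimum and maximum variance over all variants in the region.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    means = np.diag(truth.var_z())
    lo, hi = float(means.min()), float(means.max())
    if hi - lo < 1e-14:
        return means.copy()
    sd = 1.0 / np.sqrt(n)
    a = (lo - means) / sd
    b = (hi - means) / sd
    return stats.truncnorm.rvs(a, b, loc=means, scale=sd, random_state=rng)


def perturb_correlations(
    rho: np.ndarray,
    model: int,
    kappa0: float | None = None,
    kappa2: float | None = None,
) -> np.ndarray:
    """Model 4/5 correlation mismeasurement, then PSD repair.

    Model 4 subtracts kappa0 from every off-diagonal correlation; Model 5
    maps rho_jk to sign(rho_jk) |rho_jk|^kappa2.
    """
    rho = np.asarray(rho, dtype=float)
    off = ~np.eye(rho.shape[0], dtype=bool)
    if model == 4:
        if kappa0 is None:
            raise ValueError("Model 4 requires kappa0")
        if np.any(rho[off] - kappa0 < -1 - 1e-12):
            raise ValueError(
                "kappa0 pushes correlations below -1; infeasible for this region"
            )
        out = rho.copy()
        out[off] = rho[off] - kappa0
    elif model == 5:
        if kappa2 is None:
            raise ValueError("Model 5 requires kappa2")
        out = np.sign(rho) * np.abs(rho) ** kappa2
    else:
        raise ValueError("perturb_correlations applies to models 4 and 5 only")
    np.fill_diagonal(out, 1.0)
    return nearest_psd(0.5 * (out + out.T))


def apply_pleiotropy(
    truth: RegionTruth,
    model: int,
    tau_spec: float,
    n: int,
    seed: int | None = 0,
) -> RegionTruth:
    """Local misspecification delta_Y = delta_X theta0 + tau/sqrt(n).

    Model 2 uses a constant direct-effect vector tau * 1; Model 3 draws
    each element from U(-tau_spec, tau_spec) once (fixed across reps).
    """
    if model == 2:
        tau = np.full(truth.p, float(tau_spec))
    elif model == 3:
        rng = np.random.default_rng(seed)
        tau = rng.uniform(-float(tau_spec), float(tau_spec), size=truth.p)
    else:
        raise ValueError("apply_pleiotropy applies to models 2 and 3 only")
    delta_y = truth.delta_x * truth.theta0 + tau / np.sqrt(n)
    return RegionTruth(
        loadings=truth.loadings,
        factor_cov=truth.factor_cov,
        idio_sd=truth.idio_sd,
        variant_variances=truth.variant_variances,
        delta_x=truth.delta_x,
        delta_y=delta_y,
        theta0=truth.theta0,
        var_x=truth.var_x,
        var_y=truth.var_y,
        tau=tau,
    )


def default_nu_rule(f: float) -> float:
    """Pre-test level as a function of instrument strength."""
    if f >= 10:
        return 0.01
    if f >= 5:
        return 0.05
    return 0.1


VALID_METHODS = ("fliml", "far", "flm", "fclr", "sliml")


@dataclass
class SimulationDesign:
    """Configuration of one Monte-Carlo study."""

    model: int = 1
    p: int = 60
    r_true: int = 5
    r_assumed: int | None = None
    f_target: Sequence[float] = (20.0,)
    n: int | None = None
    theta_grid: Sequence[float] = (0.0,)
    theta0_test: float = 0.0
    tau: Sequence[float] = (0.0,)
    kappa0: Sequence[float] = (0.0,)
    kappa2: Sequence[float] = (1.0,)
    reps: int = 500
    seed: int = 0
    methods: Sequence[str] = VALID_METHODS
    alpha: float = 0.05
    nu_rule: Callable[[float], float] = default_nu_rule
    sliml_draws: int = 20_000
    block_structure: Mapping[str, float] | None = None
    failure_ceiling: float = 0.05

    def __post_init__(self) -> None:
        if self.model not in (1, 2, 3, 4, 5):
            raise ValueError(f"unknown model {self.model}")
        bad = set(self.methods) - set(VALID_METHODS)
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}")
        if self.r_assumed is None:
            self.r_assumed = self.r_true

    def cells(self) -> list[dict]:
        """Enumerate the (F, theta, tau/kappa) cells this design spans."""
        out = []
        taus = self.tau if self.model in (2, 3) else (0.0,)
        k0s = self.kappa0 if self.model == 4 else (0.0,)
        k2s = self.kappa2 if self.model == 5 else (1.0,)
        for f in self.f_target:
            for theta in self.theta_grid:
                for tau in taus:
                    for k0 in k0s:
                        for k2 in k2s:
                            out.append(
                                {"f": float(f), "theta": float(theta),
                                 "tau": float(tau), "kappa0": float(k0),
                                 "kappa2": float(k2)}
                            )
        return out


@dataclass
class SimulationResult:
    """Per-cell, per-method Monte-Carlo summaries."""

    table: pd.DataFrame
    design_seed: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, design_seed: int = -1) -> "SimulationResult":
        return cls(pd.read_csv(path, sep="\t"), design_seed)


def _run_rep(
    truth: RegionTruth,
    rho_obs: np.ndarray,
    n: int,
    design: SimulationDesign,
    nu: float,
    rng: np.random.Generator,
) -> dict:
    """One replication: draw data, estimate, test H0: theta = theta0_test.

    Per-method problems (e.g. an empty pre-test selection for S-LIML,
    whose error rate is defined conditional on selecting something) are
    recorded as that method skipping the rep, not as a rep failure.
    """
    data = draw_summary_stats(truth, n, n, rng=rng)
    noisy_vars = noisy_variant_variances(truth, n, rng=rng)
    varz_hat = VariantCovariance(
        nearest_psd(rho_obs * np.outer(np.sqrt(noisy_vars), np.sqrt(noisy_vars)))
    )
    loadings = estimate_loadings(varz_hat, design.r_assumed)
    ms = liml.build_moment_system(data, loadings, varz_hat)
    theta0 = design.theta0_test
    out: dict = {}
    for method in design.methods:
        try:
            if method == "fliml":
                fit = liml.fit_fliml(ms, alpha=design.alpha)
                out[method] = {
                    "reject": not (fit.ci_low <= theta0 <= fit.ci_high),
                    "estimate": fit.theta,
                }
            elif method == "far":
                out[method] = {"reject": robust.ar_test(theta0, ms).p_value < design.alpha}
            elif method == "flm":
                out[method] = {"reject": robust.lm_test(theta0, ms).p_value < design.alpha}
            elif method == "fclr":
                out[method] = {"reject": robust.clr_test(theta0, ms).p_value < design.alpha}
            elif method == "sliml":
                sel = selective.pretest_factors(ms, nu=nu)
                fit_s = selective.fit_sliml(ms, sel, alpha=design.alpha)
                k = rng.standard_normal(design.sliml_draws)
                res = selective.conditional_test(
                    theta0, fit_s, ms, alpha=design.alpha, k_draws=k,
                )
                out[method] = {
                    "reject": res.reject,
                    "estimate": fit_s.theta_s,
                    "r_star": sel.r_star,
                }
        except (ValueError, np.linalg.LinAlgError) as exc:
            out[method] = {"skipped": str(exc)}
    return out


def run_design(design: SimulationDesign) -> SimulationResult:
    """Run the Monte-Carlo study described by ``design``.

    Per-rep randomness is derived from (master seed, cell index, rep
    index) through ``numpy`` seed sequences, so results do not depend on
    execution order.  Per-rep failures (e.g. an empty pre-test selection)
    are counted and tolerated up to ``failure_ceiling``.
    """
    base_truth = synth_region(
        design.p, design.r_true, seed=design.seed,
        block_structure=design.block_structure,
    )
    rho_true = base_truth.correlation()
    rows = []
    for cell_idx, cell in enumerate(design.cells()):
        truth = RegionTruth(
            loadings=base_truth.loadings,
            factor_cov=base_truth.factor_cov,
            idio_sd=base_truth.idio_sd,
            variant_variances=base_truth.variant_variances,
            delta_x=base_truth.delta_x,
            delta_y=base_truth.delta_x * cell["theta"],
            theta0=cell["theta"],
            var_x=base_truth.var_x,
            var_y=base_truth.var_y,
        )
        n = design.n if design.n is not None else calibrate_n(truth, cell["f"])
        if design.model in (2, 3):
            truth = apply_pleiotropy(
                truth, design.model, cell["tau"], n,
                seed=design.seed + 7919 * cell_idx,
            )
        if design.model == 4:
            rho_obs = perturb_correlations(rho_true, 4, kappa0=cell["kappa0"])
        elif design.model == 5:
            rho_obs = perturb_correlations(rho_true, 5, kappa2=cell["kappa2"])
        else:
            rho_obs = rho_true
        nu = design.nu_rule(cell["f"])

        per_method: dict[str, dict[str, list]] = {
            m: {"reject": [], "estimate": [], "r_star": [], "skipped": 0}
            for m in design.methods
        }
        n_failures = 0
        for rep in range(design.reps):
            rng = np.random.default_rng([design.seed, cell_idx, rep])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                try:
                    rep_out = _run_rep(truth, rho_obs, n, design, nu, rng)
                except (ValueError, np.linalg.LinAlgError) as exc:
                    n_failures += 1
                    logger.debug("rep %d failed: %s", rep, exc)
                    continue
            for m, vals in rep_out.items():
                if "skipped" in vals:
                    per_method[m]["skipped"] += 1
                    continue
                per_method[m]["reject"].append(bool(vals["reject"]))
                if "estimate" in vals:
                    per_method[m]["estimate"].append(vals["estimate"])
                if "r_star" in vals:
                    per_method[m]["r_star"].append(vals["r_star"])
        if n_failures > design.failure_ceiling * design.reps:
            raise RuntimeError(
                f"{n_failures}/{design.reps} replications failed in cell {cell}"
            )
        for m in design.methods:
            rejects = np.asarray(per_method[m]["reject"], dtype=float)
            n_ok = rejects.size
            rate = float(np.mean(rejects)) if n_ok else np.nan
            mc_se = float(np.sqrt(rate * (1 - rate) / n_ok)) if n_ok else np.nan
            estimates = np.asarray(per_method[m]["estimate"], dtype=float)
            if estimates.size:
                bias = float(np.mean(estimates) - cell["theta"])
                rmse = float(np.sqrt(np.mean((estimates - cell["theta"]) ** 2)))
            else:
                bias = rmse = np.nan
            r_stars = per_method[m]["r_star"]
            med_r = float(np.median(r_stars)) if r_stars else np.nan
            rows.append(
                {
                    "model": design.model,
                    "f": cell["f"],
                    "theta": cell["theta"],
                    "tau": cell["tau"],
                    "kappa0": cell["kappa0"],
                    "kappa2": cell["kappa2"],
                    "n": n,
                    "method": m,
                    "rejection_rate": rate,
                    "bias": bias,
                    "rmse": rmse,
                    "median_r_star": med_r,
                    "reps": n_ok,
                    "mc_se": mc_se,
                    "n_failures": n_failures,
                    "n_skipped": per_method[m]["skipped"],
                }
            )
    return SimulationResult(table=pd.DataFrame(rows), design_seed=design.seed)
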