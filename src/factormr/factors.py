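"""Factor-loading estimation from the variant covariance matrix.

Loadings are the top-r eigenvectors of var(Z), rescaled so that
p^{-1} L'L = I_r; downstream statistics are invariant to the r x r
rotation left unidentified by the factor model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from factormr.summary_data import VariantCovariance


class FactorSelectionError(ValueError):
    """Raised when a factor-count heuristic cannot produce an answer."""


@dataclass
class LoadingsEstimate:
    """Rescaled factor loadings and the eigen-spectrum they came from."""

    loadings: np.ndarray       # p x r, satisfies p^{-1} L'L = I_r
    eigenvalues: np.ndarray    # all p eigenvalues, descending
    r: int
    explained_share: float

    @property
    def p(self) -> int:
        return self.loadings.shape[0]


@dataclass
class FactorMoments:
    """Factor-level covariance Omega_0 = L' var(Z) L."""

    omega0: np.ndarray


def estimate_loadings(varz: VariantCovariance, r: int) -> LoadingsEstimate:
    """Estimate p x r rescaled loadings from the variant covariance.

    The top-r unit eigenvectors of ``varz`` are scaled by sqrt(p) and then
    renormalized so that p^{-1} L'L = I_r exactly.  Column signs are fixed
    so the largest-magnitude entry of each column is positive, making the
    output deterministic across eigen-solvers.
    """
    p = varz.p
    if not 1 <= r < p:
        raise ValueError(f"need 1 <= r < p, got r = {r}, p = {p}")
    eigvals, eigvecs = np.linalg.eigh(varz.matrix)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    rank = int(np.sum(eigvals > eigvals[0] * 1e-12))
    if r > rank:
        warnings.warn(
            f"requested r = {r} exceeds numerical rank {rank} of var(Z)",
            RuntimeWarning,
            stacklevel=2,
        )

    lam_bar = eigvecs[:, :r] * np.sqrt(p)
    # renormalize: L = Lbar (p^{-1} Lbar' Lbar)^{-1/2}
    gram = lam_bar.T @ lam_bar / p
    w, v = np.linalg.eigh(gram)
    gram_inv_sqrt = (v / np.sqrt(w)) @ v.T
    loadings = lam_bar @ gram_inv_sqrt

    signs = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(r)])
    signs[signs == 0] = 1.0
    loadings = loadings * signs

    total = float(np.sum(np.clip(eigvals, 0, None)))
    explained = float(np.sum(np.clip(eigvals[:r], 0, None)) / total) if total > 0 else 0.0
    return LoadingsEstimate(
        loadings=loadings,
        eigenvalues=eigvals,
        r=r,
        explained_share=explained,
    )


def select_num_factors(
    eigenvalues: np.ndarray,
    method: str = "gap",
    threshold: float = 0.99,
    r_max: int | None = None,
) -> int:
    """Heuristic factor-count choice from a descending eigen-spectrum.

    ``gap`` returns the r in [1, r_max] maximizing the ratio
    lambda_r / lambda_{r+1}; ``variance_threshold`` the smallest r whose
    cumulative share reaches ``threshold``.  These helpers are advisory —
    inference treats r as user-supplied.
    """
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    p = eigenvalues.size
    if p < 2:
        raise ValueError("need at least 2 eigenvalues")
    if np.any(np.diff(eigenvalues) > 1e-10):
        raise ValueError("eigenvalues must be in descending order")
    if np.any(eigenvalues < -1e-10):
        raise ValueError("eigenvalues must be nonnegative")
    if r_max is None:
        r_max = min(p - 1, 30)
    r_max = min(r_max, p - 1)

    if method == "gap":
        if np.allclose(eigenvalues, eigenvalues[0]):
            raise FactorSelectionError(
                "no-gap: all eigenvalues equal; supply r explicitly"
            )
        head = eigenvalues[:r_max]
        tail = eigenvalues[1 : r_max + 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(tail > 0, head / tail, np.inf)
        return int(np.argmax(ratios)) + 1
    if method == "variance_threshold":
        shares = np.cumsum(eigenvalues) / np.sum(eigenvalues)
        return int(np.searchsorted(shares, threshold - 1e-12)) + 1
    raise ValueError(f"unknown method {method!r}")


def factor_moments(loadings: LoadingsEstimate, varz: VariantCovariance) -> FactorMoments:
    """Omega_0 = L' var(Z) L, symmetrized."""
    if varz.p != loadings.p:
        raise ValueError("loadings and covariance dimensions disagree")
    omega0 = loadings.loadings.T @ varz.matrix @ loadings.loadings
    return FactorMoments(omega0=0.5 * (omega0 + omega0.T))


def eigenvalue_table(eigenvalues: np.ndarray) -> "np.ndarray":
    """Gap ratios and cumulative shares for scree inspection (returns a recarray)."""
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    p = eigenvalues.size
    ratios = np.full(p, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios[:-1] = np.where(
            eigenvalues[1:] > 0, eigenvalues[:-1] / eigenvalues[1:], np.inf
        )
    shares = np.cumsum(eigenvalues) / np.sum(eigenvalues)
    out = np.recarray(p, dtype=[("eigenvalue", float), ("gap_ratio", float), ("cum_share", float)])
    out.eigenvalue = eigenvalues
    out.gap_ratio = ratios
    out.cum_share = shares
    return out
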