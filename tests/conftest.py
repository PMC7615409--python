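import numpy as np
import pytest

from factormr.factors import estimate_loadings
from factormr.liml import build_moment_system
from factormr.simulate import (
    calibrate_n,
    draw_summary_stats,
    noisy_variant_variances,
    synth_region,
)
from factormr.summary_data import VariantCovariance, nearest_psd


def random_correlation(p: int, rng: np.random.Generator) -> np.ndarray:
    """A valid random correlation matrix (factor structure + noise)."""
    raw = rng.standard_normal((p, max(2, p // 3)))
    cov = raw @ raw.T + np.diag(rng.uniform(0.5, 1.5, p))
    sd = np.sqrt(np.diag(cov))
    rho = cov / np.outer(sd, sd)
    np.fill_diagonal(rho, 1.0)
    return rho


def make_moment_system(
    seed: int = 0,
    p: int = 60,
    r: int = 3,
    f_target: float = 20.0,
    theta0: float = 0.3,
):
    """Synthetic region -> drawn summary stats -> moment system (plus truth)."""
    truth = synth_region(p, r, seed=seed, theta0=theta0)
    n = calibrate_n(truth, f_target)
    rng = np.random.default_rng(seed + 1)
    data = draw_summary_stats(truth, n, n, rng=rng)
    noisy = noisy_variant_variances(truth, n, rng=rng)
    varz = VariantCovariance(
        nearest_psd(truth.correlation() * np.outer(np.sqrt(noisy), np.sqrt(noisy)))
    )
    loadings = estimate_loadings(varz, r)
    ms = build_moment_system(data, loadings, varz)
    return ms, truth, data, varz, loadings


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def moment_system():
    ms, *_ = make_moment_system(seed=5)
    return ms
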