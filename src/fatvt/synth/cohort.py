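"""Cohort-level synthetic data: correlated tissue masses and VT counts.

Per-heart (inFAT mass, scar mass) pairs are drawn from a bivariate
lognormal through a Gaussian copula.  The latent normal correlation is
solved in closed form so that the *observed* Pearson correlation of the
lognormal masses matches the configured value:

    r_X = (exp(rho s1 s2) - 1) / sqrt((exp(s1^2)-1)(exp(s2^2)-1))

VT counts follow a log-linear Poisson model,
count ~ Poisson(exp(a + b fat_g + c scar_g)) with
b = ln(rate ratio per 5.55 g)/5.55 and c = ln(scar rate ratio); the
intercept anchors the expected count of an average heart.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SynthConfig, stream

__all__ = ["lognormal_params", "latent_corr", "draw_masses", "gen_cohort_counts"]


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and SD."""
    cv2 = (sd / mean) ** 2
    sigma2 = np.log1p(cv2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def latent_corr(target_r: float, s1: float, s2: float) -> float:
    """Latent normal correlation giving Pearson ``target_r`` after exp."""
    denom = np.sqrt(np.expm1(s1**2) * np.expm1(s2**2))
    rho = np.log1p(target_r * denom) / (s1 * s2)
    if not -1.0 < rho < 1.0:
        raise ValueError("target correlation unattainable for these margins")
    return float(rho)


def draw_masses(
    config: SynthConfig, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated (fat_g, scar_g) pairs for ``n`` hearts."""
    mu1, s1 = lognormal_params(config.fat_mass_mean, config.fat_mass_sd)
    mu2, s2 = lognormal_params(config.scar_mass_mean, config.scar_mass_sd)
    rho = latent_corr(config.mass_corr, s1, s2)
    z = rng.multivariate_normal(
        [0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n
    )
    fat = np.exp(mu1 + s1 * z[:, 0])
    scar = np.exp(mu2 + s2 * z[:, 1])
    return fat, scar


def gen_cohort_counts(
    config: SynthConfig, n: int, seed=None
) -> pd.DataFrame:
    """Table of per-heart masses and induced-VT counts.

    Columns: heart, fat_g, scar_g, vt_count.  ``seed`` overrides the
    config seed stream key (any hashable); the default uses the config's
    own seed with the "cohort" stage key.
    """
    if n < 2:
        raise ValueError("need a cohort of at least 2 hearts")
    rng = stream(config, "cohort") if seed is None else stream(config, "cohort", seed)
    fat, scar = draw_masses(config, n, rng)
    b = np.log(config.vt_rate_ratio_per_5p55g) / 5.55
    c = np.log(config.scar_rate_ratio)
    a = (
        np.log(config.vt_mean_at_mean_mass)
        - b * config.fat_mass_mean
        - c * config.scar_mass_mean
    )
    lam = np.exp(a + b * fat + c * scar)
    counts = rng.poisson(lam)
    return pd.DataFrame(
        {"heart": np.arange(n), "fat_g": fat, "scar_g": scar, "vt_count": counts}
    )
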