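"""Beta-binomial conjugate inference for per-observation allele frequencies.

Read counts are modelled as y ~ Binomial(n, p) with a conjugate Beta(α, β)
prior on the population allele frequency p, so the posterior is
Beta(α + y, β + n − y). Its mean and variance summarize what a finite
sequencing depth tells us about p: shallow sites get wide posteriors, and a
site with no coverage simply returns the prior. These moments feed the GP
stage as a per-observation heteroscedastic noise floor.
"""

from __future__ import annotations

import numpy as np

from .types import BetaPrior, DataError, FreqPosterior, SnpSeries

__all__ = ["posterior_update", "posterior_moments", "series_posterior"]


def posterior_update(y, n, prior: BetaPrior = BetaPrior()):
    """Conjugate update: Beta(α, β) prior + Binomial(n, p) data.

    Parameters
    ----------
    y, n : int or array of int
        Focal-allele read count and total depth, elementwise 0 <= y <= n.
    prior : BetaPrior

    Returns
    -------
    (alpha_star, beta_star)
        Posterior beta parameters α + y and β + n − y.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(y < 0) or np.any(n < 0) or np.any(y > n):
        raise DataError(f"invalid counts: need 0 <= y <= n, got y={y}, n={n}")
    return prior.alpha + y, prior.beta + n - y


def posterior_moments(alpha_star, beta_star):
    """Mean and variance of a Beta(a, b) distribution.

    m = a/(a+b) and s2 = ab / ((a+b)^2 (a+b+1)). Plain arithmetic is well
    conditioned for depths up to ~1e6; no log-space care is needed.
    """
    a = np.asarray(alpha_star, dtype=float)
    b = np.asarray(beta_star, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("beta parameters must be positive")
    tot = a + b
    m = a / tot
    s2 = a * b / (tot * tot * (tot + 1.0))
    return m, s2


def series_posterior(
    series: SnpSeries,
    prior: BetaPrior = BetaPrior(),
    drop_zero_depth: bool = False,
) -> tuple[FreqPosterior, np.ndarray]:
    """Posterior moments for every observation of a SNP series.

    Zero-depth observations are kept by default and return the prior moments
    (for Beta(1,1): m = 0.5, s2 = 1/12); their large variance makes them
    nearly uninformative downstream. With ``drop_zero_depth`` they are
    removed instead.

    Returns
    -------
    (FreqPosterior, keep)
        Moments for the kept observations and the boolean keep mask into the
        original series.
    """
    keep = np.ones(series.n_obs, dtype=bool)
    if drop_zero_depth:
        keep = series.n > 0
    try:
        a, b = posterior_update(series.y[keep], series.n[keep], prior)
    except DataError as err:
        raise DataError(f"SNP {series.snp_id}: {err}") from err
    m, s2 = posterior_moments(a, b)
    return FreqPosterior(m=m, s2=s2), keep
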