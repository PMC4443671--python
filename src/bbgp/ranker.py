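"""Bayes-factor ranking of SNPs with the beta-binomial Gaussian process test.

For each SNP the posterior allele-frequency means are centered and fitted
with two models sharing the fixed beta-binomial (FBB) variances as known
observation noise:

* time-dependent: SE-kernel GP + white noise + FBB;
* time-independent: constant mean + white noise + FBB (diagonal covariance).

The natural-log Bayes factor ln BF = LML(dep) - LML(indep) measures temporal
structure; SNPs are ranked by descending ln BF. Because the time-independent
model is nested in the time-dependent one (signal variance -> 0), ln BF is
non-negative up to optimizer tolerance, and by the symmetry of the uniform
beta prior the ranking does not depend on which allele is called "rising".

All replicates feed a single shared latent trajectory: observations at the
same generation from different replicates are repeated observations of one
GP. Per-replicate latent functions are deliberately out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import gp_engine
from .freq_posterior import series_posterior
from .types import BetaPrior, BfRecord, CenteredSnpData, GPFit, SnpSeries

__all__ = [
    "prepare_snp",
    "fit_time_dependent",
    "fit_time_independent",
    "log_bayes_factor",
    "score_snp",
    "rank_snps",
    "BetaBinomialGPTest",
    "bbgp_test",
]

logger = logging.getLogger(__name__)


def prepare_snp(
    series: SnpSeries,
    prior: BetaPrior = BetaPrior(),
    drop_zero_depth: bool = False,
) -> CenteredSnpData:
    """Posterior moments for every observation, jointly mean-centered.

    Raises ``ValueError`` if fewer than two distinct generations remain;
    the time-dependent model is not identifiable from a single time point.
    """
    post, keep = series_posterior(series, prior, drop_zero_depth=drop_zero_depth)
    t = series.t[keep]
    if np.unique(t).size < 2:
        raise ValueError(
            f"SNP {series.snp_id}: fewer than 2 distinct time points"
        )
    center = float(np.mean(post.m))
    return CenteredSnpData(
        t=t,
        y_centered=post.m - center,
        fbb=post.s2,
        center=center,
        rep=series.rep[keep],
    )


def fit_time_dependent(
    data: CenteredSnpData, indep_fit: GPFit | None = None
) -> GPFit:
    """Maximize the LML of the SE + white + FBB model over (l, sf2, sn2).

    When the time-independent fit is supplied, its optimum (with signal
    variance at the floor) joins the initialization set, which pins the
    nested-model bound ln BF >= 0 down to numerical tolerance.
    """
    extra = None
    if indep_fit is not None and np.isfinite(indep_fit.log_ml):
        l_lo, _ = gp_engine.length_scale_bounds(data.t)
        extra = [(l_lo, gp_engine.VAR_FLOOR, indep_fit.noise_variance)]
    return gp_engine.fit_se_model(
        data.t, data.y_centered, data.fbb, extra_inits=extra
    )


def fit_time_independent(data: CenteredSnpData) -> GPFit:
    """Maximize the diagonal-covariance LML over the noise variance."""
    return gp_engine.fit_noise_model(data.y_centered, data.fbb)


def log_bayes_factor(fit_dep: GPFit, fit_indep: GPFit) -> float:
    """Natural-log Bayes factor of time-dependent vs time-independent."""
    return fit_dep.log_ml - fit_indep.log_ml


def score_snp(
    series: SnpSeries,
    prior: BetaPrior = BetaPrior(),
    drop_zero_depth: bool = False,
) -> BfRecord:
    """Full per-SNP test: moments, both fits, ln BF. Failures are recorded
    in the ``status`` field rather than raised."""
    meta = dict(
        chrom=series.chrom, pos=series.pos,
        allele1=series.allele1, allele2=series.allele2,
    )
    try:
        data = prepare_snp(series, prior, drop_zero_depth=drop_zero_depth)
        fit_indep = fit_time_independent(data)
        fit_dep = fit_time_dependent(data, indep_fit=fit_indep)
        if not (np.isfinite(fit_dep.log_ml) and np.isfinite(fit_indep.log_ml)):
            raise gp_engine.GPNumericalError("non-finite marginal likelihood")
    except (ValueError, gp_engine.GPNumericalError) as err:
        logger.warning("SNP %s: fit failed (%s)", series.snp_id, err)
        return BfRecord(
            snp_id=series.snp_id, ln_bf=np.nan,
            fit_dep=None, fit_indep=None, status="failed", **meta,
        )
    return BfRecord(
        snp_id=series.snp_id,
        ln_bf=log_bayes_factor(fit_dep, fit_indep),
        fit_dep=fit_dep,
        fit_indep=fit_indep,
        status="ok",
        **meta,
    )


def rank_snps(records: list[BfRecord]) -> list[BfRecord]:
    """Descending ln BF; ties broken by (chrom, pos) ascending; failed
    records last. Deterministic for identical inputs."""
    ok = [r for r in records if r.status == "ok"]
    failed = [r for r in records if r.status != "ok"]
    ok.sort(key=lambda r: (-r.ln_bf, r.chrom, r.pos))
    failed.sort(key=lambda r: (r.chrom, r.pos))
    return ok + failed


def _records_frame(records: list[BfRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            dict(
                chrom=r.chrom,
                pos=r.pos,
                allele1=r.allele1,
                allele2=r.allele2,
                snp_id=r.snp_id,
                ln_bf=r.ln_bf,
                l_hat=r.fit_dep.length_scale if r.fit_dep else np.nan,
                sf2_hat=r.fit_dep.signal_variance if r.fit_dep else np.nan,
                sn2_hat_dep=r.fit_dep.noise_variance if r.fit_dep else np.nan,
                sn2_hat_indep=(
                    r.fit_indep.noise_variance if r.fit_indep else np.nan
                ),
                status=r.status,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "allele1", "allele2", "snp_id", "ln_bf",
            "l_hat", "sf2_hat", "sn2_hat_dep", "sn2_hat_indep", "status",
        ],
    )


class BetaBinomialGPTest(BaseEstimator):
    """Beta-binomial Gaussian process test, scikit-learn estimator style.

    Parameters
    ----------
    prior_alpha, prior_beta : float, default 1.0
        Beta prior on per-observation allele frequencies. The uniform
        default makes the test invariant to the choice of focal allele.
    drop_zero_depth : bool, default False
        Drop observations with zero coverage instead of letting them fall
        back to the prior moments.

    Attributes
    ----------
    records_ : list of BfRecord
        Per-SNP fits, in input order.
    results_ : pandas.DataFrame
        One row per SNP with ln_bf and fitted hyperparameters.
    log_bf_ : ndarray of shape (n_snps,)
        Natural-log Bayes factors (NaN where the fit failed).
    ranking_ : list of BfRecord
        Records sorted best-first by ln BF.

    Examples
    --------
    >>> test = BetaBinomialGPTest().fit(snp_series_list)
    >>> test.results_.sort_values("ln_bf", ascending=False).head()
    """

    def __init__(
        self,
        prior_alpha: float = 1.0,
        prior_beta: float = 1.0,
        drop_zero_depth: bool = False,
    ):
        self.prior_alpha = prior_alpha
        self.prior_beta = prior_beta
        self.drop_zero_depth = drop_zero_depth

    def fit(self, X, y=None):
        """Fit both models for every SNP in X (a sequence of SnpSeries)."""
        prior = BetaPrior(self.prior_alpha, self.prior_beta)
        self.records_ = [
            score_snp(s, prior, drop_zero_depth=self.drop_zero_depth)
            for s in X
        ]
        self.results_ = _records_frame(self.records_)
        self.log_bf_ = self.results_["ln_bf"].to_numpy()
        self.ranking_ = rank_snps(self.records_)
        n_failed = sum(r.status != "ok" for r in self.records_)
        if n_failed:
            logger.warning("%d of %d SNP fits failed", n_failed, len(self.records_))
        return self

    def score_samples(self, X):
        """ln BF per SNP without storing state (stateless convenience)."""
        prior = BetaPrior(self.prior_alpha, self.prior_beta)
        return np.array(
            [
                score_snp(s, prior, drop_zero_depth=self.drop_zero_depth).ln_bf
                for s in X
            ]
        )


def bbgp_test(series_list, prior: BetaPrior = BetaPrior()) -> pd.DataFrame:
    """Functional wrapper: run the BBGP test, return the results table."""
    est = BetaBinomialGPTest(prior.alpha, prior.beta).fit(series_list)
    return est.results_
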