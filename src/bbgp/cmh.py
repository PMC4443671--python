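"""Cochran-Mantel-Haenszel test on replicate-stratified allele counts.

The classical comparator for evolve-and-resequence data: for each SNP, each
replicate contributes a 2x2 table of allele counts (rows: allele 1/2,
columns: base/end generation), and the CMH statistic tests for a common
odds ratio different from one across the R strata:

    chi2 = (|sum_r (a_r - E[a_r])| - cc)^2 / sum_r Var(a_r),

with a_r the allele-1/base cell, E[a_r] = row1*col1/N_r and
Var(a_r) = row1*row2*col1*col2 / (N_r^2 (N_r - 1)) under the null of
independence given the margins; chi2 ~ chi-square(1). Intermediate time
points are ignored: the CMH can only use two time points.

The continuity correction cc = 0.5 is off by default so the statistic stays
a smooth ranking score; a flag turns it on.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from sklearn.base import BaseEstimator

from .types import SnpSeries

__all__ = [
    "counts_to_tables",
    "cmh_statistic",
    "rank_by_cmh",
    "CMHTest",
    "cmh_test",
]

logger = logging.getLogger(__name__)

_TINY_P = np.nextafter(0.0, 1.0)  # underflowed p-values are clamped here


def counts_to_tables(
    series: SnpSeries, base_gen: float, end_gen: float
) -> np.ndarray:
    """Per-replicate 2x2 tables ((y_B, y_E), (n_B - y_B, n_E - y_E)).

    A replicate missing either time point, or with a zero-depth sample at
    one of them, is dropped with a warning; if no replicate survives a
    ``ValueError`` is raised.
    """
    tables = []
    for rep in pd.unique(series.rep):
        sel = series.rep == rep
        at_b = sel & (series.t == base_gen)
        at_e = sel & (series.t == end_gen)
        if at_b.sum() != 1 or at_e.sum() != 1:
            logger.warning(
                "SNP %s: replicate %r lacks a unique base/end observation; dropped",
                series.snp_id, rep,
            )
            continue
        yb, nb = int(series.y[at_b][0]), int(series.n[at_b][0])
        ye, ne = int(series.y[at_e][0]), int(series.n[at_e][0])
        if nb == 0 or ne == 0:
            logger.warning(
                "SNP %s: replicate %r has zero depth at base or end; dropped",
                series.snp_id, rep,
            )
            continue
        tables.append([[yb, ye], [nb - yb, ne - ye]])
    if not tables:
        raise ValueError(f"SNP {series.snp_id}: no replicate with both time points")
    return np.asarray(tables, dtype=float)


def cmh_statistic(
    tables: np.ndarray, continuity_correction: bool = False
) -> tuple[float, float]:
    """CMH chi-square statistic and upper-tail p-value (df = 1).

    Strata with a zero margin contribute nothing; if every stratum is
    degenerate the statistic is undefined and a ``ValueError`` is raised.
    """
    tables = np.asarray(tables, dtype=float)
    if tables.ndim == 2:
        tables = tables[None]
    a = tables[:, 0, 0]
    row1 = tables[:, 0, 0] + tables[:, 0, 1]
    row2 = tables[:, 1, 0] + tables[:, 1, 1]
    col1 = tables[:, 0, 0] + tables[:, 1, 0]
    col2 = tables[:, 0, 1] + tables[:, 1, 1]
    n = row1 + row2
    ok = (n > 1) & (row1 > 0) & (row2 > 0) & (col1 > 0) & (col2 > 0)
    if not np.any(ok):
        raise ValueError("all strata degenerate: CMH statistic undefined")
    expect = row1[ok] * col1[ok] / n[ok]
    var = (
        row1[ok] * row2[ok] * col1[ok] * col2[ok]
        / (n[ok] ** 2 * (n[ok] - 1.0))
    )
    dev = float(np.sum(a[ok] - expect))
    denom = float(np.sum(var))
    cc = 0.5 if continuity_correction else 0.0
    num = max(abs(dev) - cc, 0.0)
    chi2 = num * num / denom
    p = float(chi2_dist.sf(chi2, df=1))
    if p <= 0.0:
        p = _TINY_P
    return float(chi2), p


def rank_by_cmh(results: pd.DataFrame) -> pd.DataFrame:
    """Ascending p-value; ties by statistic descending, then (chrom, pos)."""
    ok = results[results["status"] == "ok"]
    failed = results[results["status"] != "ok"]
    ok = ok.sort_values(
        ["p_value", "chi2", "chrom", "pos"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    failed = failed.sort_values(["chrom", "pos"], kind="mergesort")
    return pd.concat([ok, failed]).reset_index(drop=True)


class CMHTest(BaseEstimator):
    """CMH test across replicates, scikit-learn estimator style.

    Parameters
    ----------
    base_gen, end_gen : float
        Generations to compare. ``end_gen=None`` uses each SNP's last
        observed generation (and ``base_gen=None`` its first).
    continuity_correction : bool, default False
        Apply the 0.5 continuity correction.

    Attributes
    ----------
    results_ : pandas.DataFrame with chi2, p_value and status per SNP.
    statistic_, pvalue_ : ndarrays in input order (NaN where failed).
    ranking_ : results_ sorted best-first.
    """

    def __init__(
        self,
        base_gen: float | None = None,
        end_gen: float | None = None,
        continuity_correction: bool = False,
    ):
        self.base_gen = base_gen
        self.end_gen = end_gen
        self.continuity_correction = continuity_correction

    def fit(self, X, y=None):
        rows = []
        for s in X:
            base = self.base_gen if self.base_gen is not None else float(np.min(s.t))
            end = self.end_gen if self.end_gen is not None else float(np.max(s.t))
            row = dict(
                chrom=s.chrom, pos=s.pos, allele1=s.allele1,
                allele2=s.allele2, snp_id=s.snp_id,
            )
            try:
                tables = counts_to_tables(s, base, end)
                chi2, p = cmh_statistic(tables, self.continuity_correction)
                row.update(chi2=chi2, p_value=p, n_strata=len(tables), status="ok")
            except ValueError as err:
                logger.warning("SNP %s: CMH failed (%s)", s.snp_id, err)
                row.update(chi2=np.nan, p_value=np.nan, n_strata=0, status="failed")
            rows.append(row)
        self.results_ = pd.DataFrame(
            rows,
            columns=[
                "chrom", "pos", "allele1", "allele2", "snp_id",
                "chi2", "p_value", "n_strata", "status",
            ],
        )
        self.statistic_ = self.results_["chi2"].to_numpy()
        self.pvalue_ = self.results_["p_value"].to_numpy()
        self.ranking_ = rank_by_cmh(self.results_)
        return self


def cmh_test(
    series_list,
    base_gen: float | None = None,
    end_gen: float | None = None,
    continuity_correction: bool = False,
) -> pd.DataFrame:
    """Functional wrapper: run the CMH test, return the results table."""
    est = CMHTest(base_gen, end_gen, continuity_correction).fit(series_list)
    return est.results_
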