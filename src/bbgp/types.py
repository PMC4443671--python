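"""Core in-memory containers shared across the package.

A SNP's data is a short, possibly irregular time series of allele read
counts: at each observation j we know the generation t_j, the replicate
label r_j, the number of reads y_j carrying the focal ("rising") allele and
the total sequencing depth n_j at the site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DataError(ValueError):
    """Invalid observation data (e.g. counts exceeding depth)."""


@dataclass(frozen=True)
class BetaPrior:
    """Beta prior on a per-observation allele frequency.

    The default Beta(1, 1) (uniform) prior makes the analysis symmetric in
    the choice of focal allele.
    """

    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(
                f"beta prior parameters must be positive, got "
                f"({self.alpha}, {self.beta})"
            )


@dataclass
class SnpSeries:
    """One SNP's allele-count time series across replicates.

    Parameters
    ----------
    snp_id : str
        Opaque identifier, conventionally ``"chrom:pos"``.
    t : array of float, shape (J,)
        Generation of each observation.
    rep : array, shape (J,)
        Replicate label of each observation.
    y : array of int, shape (J,)
        Reads carrying the focal allele.
    n : array of int, shape (J,)
        Total depth at the site. ``n = 0`` (missing coverage) is legal.
    chrom, pos, allele1, allele2 : optional site annotation.
    """

    snp_id: str
    t: np.ndarray
    rep: np.ndarray
    y: np.ndarray
    n: np.ndarray
    chrom: str = ""
    pos: int = 0
    allele1: str = ""
    allele2: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.rep = np.asarray(self.rep)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.n = np.asarray(self.n, dtype=np.int64)
        if not (self.t.shape == self.rep.shape == self.y.shape == self.n.shape):
            raise DataError(f"SNP {self.snp_id}: observation arrays differ in length")
        bad = np.flatnonzero((self.y < 0) | (self.n < 0) | (self.y > self.n))
        if bad.size:
            j = int(bad[0])
            raise DataError(
                f"SNP {self.snp_id}, observation {j}: invalid counts "
                f"y={self.y[j]}, n={self.n[j]} (need 0 <= y <= n)"
            )

    @property
    def n_obs(self) -> int:
        return self.t.size

    def swapped(self) -> "SnpSeries":
        """The same series with the focal allele swapped (y -> n - y)."""
        return SnpSeries(
            snp_id=self.snp_id,
            t=self.t.copy(),
            rep=self.rep.copy(),
            y=self.n - self.y,
            n=self.n.copy(),
            chrom=self.chrom,
            pos=self.pos,
            allele1=self.allele2,
            allele2=self.allele1,
        )


@dataclass
class FreqPosterior:
    """Per-observation posterior mean and variance of the allele frequency."""

    m: np.ndarray
    s2: np.ndarray


@dataclass
class GPFit:
    """Hyperparameters and maximized log marginal likelihood of one model.

    ``length_scale`` and ``signal_variance`` are ``None`` for the
    time-independent (noise-only) model.
    """

    log_ml: float
    noise_variance: float
    length_scale: float | None = None
    signal_variance: float | None = None
    converged: bool = True
    n_restarts_used: int = 0


@dataclass
class BfRecord:
    """Per-SNP Bayes factor record: the unit of ranking."""

    snp_id: str
    ln_bf: float
    fit_dep: GPFit | None
    fit_indep: GPFit | None
    status: str = "ok"  # "ok" | "failed"
    chrom: str = ""
    pos: int = 0
    allele1: str = ""
    allele2: str = ""


@dataclass
class CenteredSnpData:
    """Centered posterior means plus their fixed beta-binomial variances.

    All replicates are stacked into one vector: observations at the same
    generation from different replicates are treated as repeated
    observations of a single shared latent trajectory.
    """

    t: np.ndarray
    y_centered: np.ndarray
    fbb: np.ndarray
    center: float
    rep: np.ndarray = field(default_factory=lambda: np.empty(0))
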