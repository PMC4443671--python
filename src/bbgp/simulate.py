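"""Desk-scale synthetic evolve-and-resequence (E&R) experiment generator.

Replicated diploid Wright-Fisher populations evolve independently per locus
(free recombination; no linkage, so hitchhiking is deliberately absent).
Each replicate is founded by drawing 2N haplotypes with replacement from a
pool of H founder haplotypes carrying the focal allele at frequency p0.
Selection acts through genotype fitnesses

    w_AA = 1 + s,   w_Aa = 1 + h*s,   w_aa = 1,

so the deterministic update of the focal-allele frequency p (q = 1 - p) is

    p' = (p^2 (1+s) + p q (1+h s)) / (p^2 (1+s) + 2 p q (1+h s) + q^2),

followed by binomial drift: the next generation's allele count is
Binomial(2N, p') under random union of gametes. Pool sequencing is emulated
by Poisson(lambda) depth and binomial read counts at the population
frequency (optionally via an intermediate finite DNA pool).

Defaults mirror a typical Drosophila E&R design: N = 1000 diploids, H = 200
founder haplotypes, 5 replicates, 60 generations sampled at
{0, 14, 28, 44, 60}, selected loci with s = 0.1 and semi-dominance h = 0.5
starting in [0.12, 0.8], and mean depth lambda = 45.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "ErSimResult",
    "found_replicate",
    "wf_step",
    "selection_update",
    "sequence_sample",
    "simulate_experiment",
]


@dataclass
class SimConfig:
    """Parameters of one simulated E&R experiment."""

    N: int = 1000                 # census size (diploid individuals)
    H: int = 200                  # founder haplotypes
    R: int = 5                    # replicates
    G: int = 60                   # total generations
    sample_gens: tuple = (0, 14, 28, 44, 60)
    s: float = 0.1                # selection coefficient at selected loci
    h: float = 0.5                # dominance (0.5 = additive)
    lambda_depth: float = 45.0    # mean sequencing depth
    L_neutral: int = 500
    L_selected: int = 25
    p0_range_selected: tuple = (0.12, 0.8)
    p0_range_neutral: tuple = (0.05, 0.95)
    pool_females: int | None = None  # finite DNA pool stage (e.g. 500); None = off
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.N, self.H, self.R, self.G) <= 0 or self.lambda_depth <= 0:
            raise ValueError("N, H, R, G and lambda_depth must be positive")
        gens = sorted(set(int(g) for g in self.sample_gens))
        if gens[0] < 0 or gens[-1] > self.G:
            raise ValueError("sample_gens must lie within [0, G]")
        self.sample_gens = tuple(gens)
        lo, hi = self.p0_range_selected
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("p0_range_selected must be inside (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ErSimResult:
    """Simulated experiment: truth labels, trajectories, sequencing counts.

    ``truth`` has one row per locus (chrom, pos, label, p0, s, h);
    ``freqs``, ``y`` and ``n`` have shape (L, R, T) over loci, replicates
    and sampled generations.
    """

    config: SimConfig
    truth: pd.DataFrame
    freqs: np.ndarray
    y: np.ndarray
    n: np.ndarray
    sample_gens: tuple = field(default_factory=tuple)


def selection_update(p, s: float, h: float):
    """Deterministic one-generation frequency change under selection."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    num = p * p * (1.0 + s) + p * q * (1.0 + h * s)
    wbar = p * p * (1.0 + s) + 2.0 * p * q * (1.0 + h * s) + q * q
    out = np.where(wbar > 0, num / np.where(wbar > 0, wbar, 1.0), p)
    return out if out.ndim else float(out)


def found_replicate(H: int, N: int, p0: float, rng: np.random.Generator):
    """Found one population: 2N haplotypes drawn with replacement from a
    pool of H founders carrying round(H*p0) copies of the focal allele.

    Returns the focal-allele copy count among the 2N founding haplotypes.
    Vectorized: ``p0`` may be an array of per-locus frequencies.
    """
    p0 = np.asarray(p0, dtype=float)
    if np.any((p0 < 0) | (p0 > 1)):
        raise ValueError("p0 must lie in [0, 1]")
    pool_freq = np.round(H * p0) / H
    out = rng.binomial(2 * N, pool_freq)
    return out if np.ndim(out) else int(out)


def wf_step(copy_count, N: int, s: float, h: float, rng: np.random.Generator):
    """One Wright-Fisher generation: selection then binomial drift.

    Absorbing at 0 and 2N. Vectorized over loci; ``s`` and ``h`` may be
    arrays matching ``copy_count``.
    """
    c = np.asarray(copy_count)
    p = c / (2.0 * N)
    p_sel = selection_update(p, s, h) if np.ndim(s) == 0 else selection_update(p, np.asarray(s), np.asarray(h))
    out = rng.binomial(2 * N, p_sel)
    return out if np.ndim(copy_count) else int(out)


def sequence_sample(
    freq,
    lambda_depth: float,
    rng: np.random.Generator,
    N: int | None = None,
    copies=None,
    pool_females: int | None = None,
):
    """Pool-seq emulation: depth n ~ Poisson(lambda), reads y ~ Binomial(n, f).

    With ``pool_females`` set, a finite DNA pool of that many diploid
    individuals is first drawn without replacement from the population
    (hypergeometric on allele copies), and reads are binomial at the pool
    frequency. ``n = 0`` is a legal outcome.
    """
    freq = np.asarray(freq, dtype=float)
    n = rng.poisson(lambda_depth, size=freq.shape)
    f = freq
    if pool_females is not None:
        if N is None or copies is None:
            raise ValueError("pool sampling needs N and allele copy counts")
        k = min(2 * pool_females, 2 * N)
        pool = rng.hypergeometric(copies, 2 * N - np.asarray(copies), k)
        f = pool / k
    y = rng.binomial(n, f)
    if freq.ndim == 0:
        return int(y), int(n)
    return y, n


def simulate_experiment(config: SimConfig, rng=None) -> ErSimResult:
    """Run the full replicated experiment for all loci.

    Loci are unlinked and evolve independently; selected loci use
    (config.s, config.h), neutral loci s = 0. Selected starting frequencies
    are uniform on ``p0_range_selected`` (redrawn if rounding to the
    founder pool would lose either allele); neutral ones uniform on
    ``p0_range_neutral``. Fully reproducible from ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.L_neutral + config.L_selected
    labels = np.array(
        ["neutral"] * config.L_neutral + ["selected"] * config.L_selected
    )
    s_vec = np.where(labels == "selected", config.s, 0.0)
    h_vec = np.full(L, config.h)

    lo, hi = config.p0_range_neutral
    p0 = rng.uniform(lo, hi, size=L)
    slo, shi = config.p0_range_selected
    sel = labels == "selected"
    p0[sel] = rng.uniform(slo, shi, size=sel.sum())
    # a selected locus must not round to a monomorphic founder pool
    for _ in range(100):
        bad = sel & (
            (np.round(config.H * p0) <= 0) | (np.round(config.H * p0) >= config.H)
        )
        if not bad.any():
            break
        p0[bad] = rng.uniform(slo, shi, size=bad.sum())

    gens = np.asarray(config.sample_gens)
    T = gens.size
    freqs = np.zeros((L, config.R, T))
    y = np.zeros((L, config.R, T), dtype=np.int64)
    n = np.zeros((L, config.R, T), dtype=np.int64)

    for r in range(config.R):
        copies = found_replicate(config.H, config.N, p0, rng)
        ti = 0
        for g in range(config.G + 1):
            if ti < T and g == gens[ti]:
                f = copies / (2.0 * config.N)
                freqs[:, r, ti] = f
                y[:, r, ti], n[:, r, ti] = sequence_sample(
                    f, config.lambda_depth, rng,
                    N=config.N, copies=copies, pool_females=config.pool_females,
                )
                ti += 1
            if g < config.G:
                copies = wf_step(copies, config.N, s_vec, h_vec, rng)

    truth = pd.DataFrame(
        dict(
            chrom="sim",
            pos=np.arange(1, L + 1),
            label=labels,
            p0=p0,
            s=s_vec,
            h=h_vec,
        )
    )
    return ErSimResult(
        config=config, truth=truth, freqs=freqs, y=y, n=n,
        sample_gens=tuple(int(g) for g in gens),
    )
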