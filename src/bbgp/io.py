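"""Sync-format I/O, bi-allelification and results tables.

The PoPoolation2 "sync" format is tab-separated with three leading columns
(chromosome, 1-based position, reference base) followed by one column per
sample holding colon-separated counts ``A:T:C:G:N:del``. A sample map
assigns each sample column a (generation, replicate) pair; the CLI encodes
it as ``"0:1,0:2,...,60:5"`` in column order.

Multi-allelic sites are reduced to the two alleles with the highest total
count over all samples; remaining counts are either dropped from the depth
(default; rare third alleles are usually sequencing errors) or collapsed
into the minor allele. The "rising" allele is the one whose pooled
frequency increases from the first to the last sampled generation — by the
symmetry of the uniform prior the tests do not depend on this choice.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ErSimResult
from .types import SnpSeries

__all__ = [
    "SyncRecord",
    "SyncParseError",
    "parse_sample_map",
    "read_sync",
    "extract_biallelic",
    "sync_to_series",
    "write_sync",
    "write_results",
    "read_results",
]

logger = logging.getLogger(__name__)

_BASES = ("A", "T", "C", "G", "N", "del")
_ACGT_IDX = {"A": 0, "T": 1, "C": 2, "G": 3}


class SyncParseError(ValueError):
    """Malformed sync input, with the offending line number."""


@dataclass
class SyncRecord:
    chrom: str
    pos: int
    ref: str
    counts: np.ndarray  # shape (n_samples, 6): A, T, C, G, N, del


def parse_sample_map(spec) -> list[tuple[float, str]]:
    """Sample map from ``"gen:rep,gen:rep,..."`` or a list of pairs."""
    if isinstance(spec, str):
        pairs = []
        for i, tok in enumerate(spec.split(",")):
            parts = tok.strip().split(":")
            if len(parts) != 2:
                raise ValueError(f"sample map entry {i}: expected 'gen:rep', got {tok!r}")
            pairs.append((float(parts[0]), parts[1]))
    else:
        pairs = [(float(g), str(r)) for g, r in spec]
    if len(set(pairs)) != len(pairs):
        raise ValueError("sample map has duplicate (generation, replicate) pairs")
    return pairs


def _open_text(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sync(path, n_samples: int | None = None):
    """Yield validated ``SyncRecord`` objects from a (possibly gzipped) file.

    Malformed lines raise ``SyncParseError`` naming the line number; an
    inconsistent sample-column count across records is also an error.
    """
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise SyncParseError(
                    f"{path}:{lineno}: expected at least 4 tab-separated fields"
                )
            samples = fields[3:]
            if n_samples is None:
                n_samples = len(samples)
            elif len(samples) != n_samples:
                raise SyncParseError(
                    f"{path}:{lineno}: expected {n_samples} sample columns, "
                    f"got {len(samples)}"
                )
            counts = np.empty((len(samples), 6), dtype=np.int64)
            for si, col in enumerate(samples):
                parts = col.split(":")
                if len(parts) != 6:
                    raise SyncParseError(
                        f"{path}:{lineno}: sample column {si + 1} has "
                        f"{len(parts)} fields, expected 6 (A:T:C:G:N:del)"
                    )
                try:
                    counts[si] = [int(p) for p in parts]
                except ValueError as err:
                    raise SyncParseError(
                        f"{path}:{lineno}: non-integer count in sample "
                        f"column {si + 1}"
                    ) from err
            if (counts < 0).any():
                raise SyncParseError(f"{path}:{lineno}: negative count")
            try:
                pos = int(fields[1])
            except ValueError as err:
                raise SyncParseError(f"{path}:{lineno}: non-integer position") from err
            yield SyncRecord(chrom=fields[0], pos=pos, ref=fields[2], counts=counts)


def extract_biallelic(
    record: SyncRecord,
    sample_map: list[tuple[float, str]],
    policy: str = "drop",
) -> SnpSeries | None:
    """Reduce a sync record to a bi-allelic SNP series, or ``None``.

    The two alleles with the highest total count over all samples (among
    A, T, C, G; N and deletions never count) become alleles 1 and 2; total
    ties are broken by the fixed base order A < C < G < T. Policy ``drop``
    excludes residual third-allele counts from the depth; ``collapse`` adds
    them to the minor allele. Sites where fewer than two alleles are ever
    observed are monomorphic and skipped.
    """
    if policy not in ("drop", "collapse"):
        raise ValueError(f"unknown bi-allelification policy {policy!r}")
    if record.counts.shape[0] != len(sample_map):
        raise ValueError(
            f"{record.chrom}:{record.pos}: {record.counts.shape[0]} sample "
            f"columns but sample map has {len(sample_map)} entries"
        )
    acgt = record.counts[:, [0, 1, 2, 3]]  # A, T, C, G per sample
    totals = acgt.sum(axis=0)
    # rank alleles by total count, ties by A < C < G < T
    order = {"A": 0, "C": 1, "G": 2, "T": 3}
    bases = ["A", "T", "C", "G"]
    observed = [b for b in bases if totals[_ACGT_IDX[b]] > 0]
    if len(observed) < 2:
        logger.info("%s:%d: monomorphic site skipped", record.chrom, record.pos)
        return None
    ranked = sorted(observed, key=lambda b: (-totals[_ACGT_IDX[b]], order[b]))
    a1, a2 = ranked[0], ranked[1]
    y1 = acgt[:, _ACGT_IDX[a1]]
    y2 = acgt[:, _ACGT_IDX[a2]]
    if policy == "collapse":
        rest = acgt.sum(axis=1) - y1 - y2
        y2 = y2 + rest
    n = y1 + y2

    t = np.array([g for g, _ in sample_map], dtype=float)
    rep = np.array([r for _, r in sample_map])
    # focal allele = the one rising from first to last sampled generation
    first, last = t.min(), t.max()
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n > 0, y1 / np.maximum(n, 1), np.nan)
    f_first = np.nanmean(f[t == first]) if np.any(t == first) else np.nan
    f_last = np.nanmean(f[t == last]) if np.any(t == last) else np.nan
    y = y1
    if np.isfinite(f_first) and np.isfinite(f_last) and f_last < f_first:
        y = n - y1
        a1, a2 = a2, a1
    return SnpSeries(
        snp_id=f"{record.chrom}:{record.pos}",
        t=t,
        rep=rep,
        y=y,
        n=n,
        chrom=record.chrom,
        pos=record.pos,
        allele1=a1,
        allele2=a2,
    )


def sync_to_series(path, sample_map, policy: str = "drop"):
    """Parse a sync file straight into SnpSeries, skipping monomorphic sites."""
    sample_map = parse_sample_map(sample_map)
    n_skipped = 0
    for rec in read_sync(path, n_samples=len(sample_map)):
        series = extract_biallelic(rec, sample_map, policy=policy)
        if series is None:
            n_skipped += 1
            continue
        yield series
    if n_skipped:
        logger.info("skipped %d monomorphic sites", n_skipped)


def write_sync(result: ErSimResult, path) -> list[tuple[float, str]]:
    """Write a simulated experiment as a sync file.

    The focal allele is written as A and the other allele as T; sample
    columns are ordered replicate-major then generation. Returns the sample
    map matching the column order.
    """
    L, R, T = result.y.shape
    sample_map = [
        (float(result.sample_gens[ti]), str(r + 1))
        for r in range(R)
        for ti in range(T)
    ]
    with open(path, "w") as fh:
        for i in range(L):
            cols = []
            for r in range(R):
                for ti in range(T):
                    yy = result.y[i, r, ti]
                    nn = result.n[i, r, ti]
                    cols.append(f"{yy}:{nn - yy}:0:0:0:0")
            fh.write(f"sim\t{i + 1}\tA\t" + "\t".join(cols) + "\n")
    return sample_map


def write_results(df: pd.DataFrame, path) -> None:
    """Write a results table as TSV with 12-significant-digit floats."""
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
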