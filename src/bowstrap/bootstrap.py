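"""The bootstrap-style expression estimator.

A read that aligns to more than one location cannot be attributed to a
single gene model deterministically.  Instead of discarding such reads or
committing to one arbitrary placement, each bootstrap iteration assigns
every ambiguous read uniformly at random to one of its candidate
alignment *locations* (records, not distinct genes: a gene hit at two
positions by one read carries weight 2/|locations|).  Each iteration
yields one complete per-gene RPKM vector; across iterations the per-gene
sample mean and sample standard deviation summarize the expression
distribution induced by alignment ambiguity.

RPKM = count / (length_bp/1000) / (total_aligned_reads/1e6).  The
denominator is the number of aligned reads (reads with >=1 alignment),
identical in every iteration and in the unique-read column, so all
columns are on one comparable scale.  Unaligned reads never enter the
program.

Determinism: each iteration's random stream is derived from
(seed, iteration index), and iterations are aggregated in fixed chunks
merged in index order, so the output is bit-identical for any worker
count.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .formats import GeneTable, ReadAlignments

logger = logging.getLogger(__name__)

# Iterations per aggregation chunk.  Fixed (never a function of the worker
# count) so that the chunk boundaries, and hence the merged floating-point
# result, do not depend on parallelism.
_CHUNK = 32


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling parameters.

    iterations
        Number of bootstrap iterations (>= 2; the SD is undefined below
        that).  Default 100.
    seed
        Non-negative integer seeding every random stream.
    workers
        Threads used to compute iteration chunks; the result is
        independent of this value.
    """

    iterations: int = 100
    seed: int = 0
    workers: int = 1

    def __post_init__(self) -> None:
        if self.iterations < 2:
            raise ValueError(
                f"iterations must be >= 2 (SD undefined), got {self.iterations}"
            )
        if self.seed < 0:
            raise ValueError(f"seed must be non-negative, got {self.seed}")
        if self.workers < 1:
            raise ValueError(f"workers must be >= 1, got {self.workers}")


@dataclass
class ExpressionEstimate:
    """Per-gene result: unique-read accounting, bootstrap moments, p-values.

    ``unique_reads`` counts reads whose candidate locations all lie on this
    one gene — a lower bound on the gene's count in every iteration.
    ``cnd_pvalue``/``bh_pvalue`` are filled by the significance step.
    """

    gene: str
    unique_reads: int
    unique_rpkm: float
    mean_rpkm: float
    sd_rpkm: float
    cnd_pvalue: float | None = None
    bh_pvalue: float | None = None


def compute_rpkm(count: float, length_bp: int, total_aligned_reads: int) -> float:
    """Reads per kilobase of gene sequence per million aligned reads."""
    if length_bp < 1:
        raise ValueError(f"length_bp must be >= 1, got {length_bp}")
    if total_aligned_reads < 1:
        raise ValueError(
            "total_aligned_reads must be >= 1 (no aligned reads: RPKM undefined)"
        )
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    return count / (length_bp / 1000.0) / (total_aligned_reads / 1.0e6)


class _CompiledReads:
    """Index-space view of a read set, built once per estimation run.

    Reads whose locations all lie on one gene contribute a fixed count
    vector; the rest are kept as a CSR-style array of candidate gene
    indices for vectorized per-iteration sampling.
    """

    def __init__(self, reads: Sequence[ReadAlignments], genes: GeneTable):
        n_genes = len(genes)
        fixed = np.zeros(n_genes, dtype=np.int64)
        flat: list[int] = []
        starts: list[int] = []
        for ra in reads:
            if not ra.locations:
                raise ValueError(f"read {ra.read_id!r} has no alignment locations")
            idx = [genes.index(loc.gene) for loc in ra.locations]
            first = idx[0]
            if all(i == first for i in idx):
                fixed[first] += 1
            else:
                starts.append(len(flat))
                flat.extend(idx)
        self.n_reads = len(reads)
        self.fixed_counts = fixed
        self.flat = np.array(flat, dtype=np.int64)
        starts_arr = np.array(starts + [len(flat)], dtype=np.int64)
        self.offsets = starts_arr[:-1]
        self.lens = np.diff(starts_arr)
        self.n_genes = n_genes

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        """One iteration: per-gene counts after random assignment."""
        counts = self.fixed_counts.copy()
        if len(self.offsets):
            pick = rng.integers(0, self.lens)
            chosen = self.flat[self.offsets + pick]
            counts += np.bincount(chosen, minlength=self.n_genes)
        return counts


def _iteration_rng(seed: int, iteration: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, iteration]))


def resample_iteration(
    reads: Sequence[ReadAlignments], genes: GeneTable, rng: np.random.Generator
) -> np.ndarray:
    """One random assignment of every read; counts aligned to ``genes``.

    Each read contributes exactly 1 to the gene owning its selected
    location; selection is uniform over the read's alignment records.
    """
    return _CompiledReads(reads, genes).draw(rng)


def _chunk_moments(
    compiled: _CompiledReads,
    scale: np.ndarray,
    seed: int,
    start: int,
    stop: int,
) -> tuple[int, np.ndarray, np.ndarray]:
    """Welford (count, mean, M2) of per-iteration RPKM over [start, stop)."""
    n = 0
    mean = np.zeros(compiled.n_genes)
    m2 = np.zeros(compiled.n_genes)
    for i in range(start, stop):
        x = compiled.draw(_iteration_rng(seed, i)) * scale
        n += 1
        delta = x - mean
        mean += delta / n
        m2 += delta * (x - mean)
    return n, mean, m2


def _merge_moments(a, b):
    na, mean_a, m2_a = a
    nb, mean_b, m2_b = b
    n = na + nb
    delta = mean_b - mean_a
    mean = mean_a + delta * (nb / n)
    m2 = m2_a + m2_b + delta * delta * (na * nb / n)
    return n, mean, m2


def run_bootstrap(
    reads: Sequence[ReadAlignments],
    genes: GeneTable,
    config: BootstrapConfig,
) -> list[ExpressionEstimate]:
    """Bootstrap mean/SD RPKM per gene; p-value fields left unfilled.

    Every gene in ``genes`` gets an estimate, including genes with zero
    alignments (all-zero row).  With zero reads all estimates are zero and
    the downstream degenerate rule forces their p-values to 1.
    """
    compiled = _CompiledReads(reads, genes)
    total = compiled.n_reads
    if total == 0:
        logger.warning("no aligned reads: all estimates are zero")
        return [
            ExpressionEstimate(g.name, 0, 0.0, 0.0, 0.0) for g in genes
        ]
    # RPKM = count * 1e9 / (length * total)
    scale = 1.0e9 / (genes.lengths.astype(float) * float(total))

    bounds = list(range(0, config.iterations, _CHUNK)) + [config.iterations]
    ranges = list(zip(bounds[:-1], bounds[1:]))
    if config.workers > 1 and len(ranges) > 1:
        with ThreadPoolExecutor(max_workers=config.workers) as pool:
            chunk_results = list(
                pool.map(
                    lambda r: _chunk_moments(compiled, scale, config.seed, *r),
                    ranges,
                )
            )
    else:
        chunk_results = [
            _chunk_moments(compiled, scale, config.seed, lo, hi)
            for lo, hi in ranges
        ]
    agg = chunk_results[0]
    for part in chunk_results[1:]:
        agg = _merge_moments(agg, part)
    n, mean, m2 = agg
    sd = np.sqrt(m2 / (n - 1))

    unique = compiled.fixed_counts
    unique_rpkm = unique * scale
    n_multi = len(compiled.offsets)
    logger.info(
        "bootstrap: %d reads (%d multiply-aligned, %.1f%%), %d iterations",
        total,
        n_multi,
        100.0 * n_multi / total,
        config.iterations,
    )
    return [
        ExpressionEstimate(
            gene=g.name,
            unique_reads=int(unique[i]),
            unique_rpkm=float(unique_rpkm[i]),
            mean_rpkm=float(mean[i]),
            sd_rpkm=float(sd[i]),
        )
        for i, g in enumerate(genes)
    ]


def estimate_expression(
    reads: Sequence[ReadAlignments],
    genes: GeneTable,
    config: BootstrapConfig,
) -> list[ExpressionEstimate]:
    """Full estimator: bootstrap moments plus CND and BH-adjusted p-values."""
    from .significance import annotate_significance

    estimates = run_bootstrap(reads, genes, config)
    annotate_significance(estimates)
    return estimates
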