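"""The two non-bootstrap comparison methods.

*Random assignment* mirrors the aligner's default behavior: every
ambiguous read is committed once, uniformly at random, to one of its
candidate locations — statistically one bootstrap iteration.  Its RPKM
denominator is the total number of aligned reads.

*Unique-only* discards every read with more than one alignment record
and models a separate aligner run that reports only unique alignments;
its RPKM denominator is therefore its own aligned total, the number of
uniquely aligning reads.

Neither baseline yields a significance measure, so expression is called
as any RPKM strictly greater than zero.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .bootstrap import _CompiledReads, resample_iteration
from .formats import GeneTable, ReadAlignments

logger = logging.getLogger(__name__)


def random_assignment_expression(
    reads: Sequence[ReadAlignments], genes: GeneTable, seed: int
) -> np.ndarray:
    """Per-gene RPKM from a single random allocation of ambiguous reads."""
    total = len(reads)
    if total == 0:
        logger.warning("no aligned reads: random-assignment RPKM is all zero")
        return np.zeros(len(genes))
    rng = np.random.default_rng(seed)
    counts = resample_iteration(reads, genes, rng)
    return counts * 1.0e9 / (genes.lengths.astype(float) * float(total))


def unique_only_expression(
    reads: Sequence[ReadAlignments], genes: GeneTable
) -> np.ndarray:
    """Per-gene RPKM counting only reads with exactly one alignment record."""
    counts = np.zeros(len(genes), dtype=np.int64)
    n_unique = 0
    for ra in reads:
        if len(ra.locations) == 1:
            counts[genes.index(ra.locations[0].gene)] += 1
            n_unique += 1
    if n_unique == 0:
        logger.warning("no uniquely aligning reads: unique-only RPKM is all zero")
        return np.zeros(len(genes))
    return counts * 1.0e9 / (genes.lengths.astype(float) * float(n_unique))


def call_expressed_baseline(rpkm: np.ndarray) -> np.ndarray:
    """Expressed <=> RPKM strictly greater than zero."""
    return np.asarray(rpkm) > 0
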