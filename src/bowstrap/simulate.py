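"""Synthetic validation harness.

Emulates a metatranscriptome whose difficulty comes from families of
highly similar gene models (duplicate genes, cross-species homologs): a
random transcriptome containing ``n_families`` families of near-identical
sequences, a sparse known-expression truth with log-normal expression
weights, error-free fixed-length reads sampled in proportion to
expression, and an internal exact-match k-mer aligner that emits
Bowtie-v1-format lines — so the full estimation pipeline runs with no
external aligner binary.  Real-data users align with Bowtie
(``bowtie --all``) instead.

Truth convention: expression weights act as transcript molarity, so the
expected number of reads originating from gene *g* is proportional to
``weight_g * (length_g − read_length + 1)`` and the published
``true_rpkm`` is the RPKM of that *expected* origin count — a target
independent of sampling noise.  Realized origin counts are retained for
diagnostics.  Reads are sampled and aligned on the forward strand only.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bootstrap import compute_rpkm
from .formats import Alignment, GeneModel, GeneTable, ReadAlignments

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Generation parameters for one synthetic dataset.

    Defaults are the harness's standard study conditions: a 2000-gene
    transcriptome with 10 duplicate-gene families of size 2 at 98%
    within-family identity, half the genes expressed with log-normal
    weights spanning roughly three orders of magnitude, and error-free
    46-mer reads.
    """

    n_genes: int = 2000
    length_range: tuple[int, int] = (500, 2500)
    n_families: int = 10
    family_size: int = 2
    within_family_identity: float = 0.98
    frac_expressed: float = 0.5
    mu_log: float = 0.0
    sigma_log: float = 1.5
    n_reads: int = 300_000
    read_length_bp: int = 46
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid length_range {self.length_range}")
        if self.read_length_bp > lo:
            raise ValueError(
                f"read_length_bp {self.read_length_bp} exceeds minimum gene "
                f"length {lo}"
            )
        if self.n_families * self.family_size > self.n_genes:
            raise ValueError("n_families * family_size exceeds n_genes")
        if self.n_families and self.family_size < 2:
            raise ValueError("family_size must be >= 2")
        if not 0 < self.within_family_identity <= 1:
            raise ValueError("within_family_identity must be in (0, 1]")
        if not 0 <= self.frac_expressed <= 1:
            raise ValueError("frac_expressed must be in [0, 1]")
        if self.n_genes < 1 or self.n_reads < 1:
            raise ValueError("n_genes and n_reads must be positive")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


@dataclass
class Transcriptome:
    """Gene table plus the gene sequences, index-aligned."""

    genes: GeneTable
    sequences: list[str]

    def write_fasta(self, path: str | os.PathLike) -> None:
        records = [
            SeqRecord(Seq(seq), id=g.name, description="")
            for g, seq in zip(self.genes, self.sequences)
        ]
        SeqIO.write(records, str(path), "fasta")


@dataclass
class TruthTable:
    """Ground truth: per-gene expression weight, target RPKM, origin tally."""

    genes: list[str]
    expression_weight: np.ndarray
    true_rpkm: np.ndarray = field(default_factory=lambda: np.array([]))
    origin_read_count: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        n = len(self.genes)
        if self.true_rpkm.size == 0:
            self.true_rpkm = np.zeros(n)
        if self.origin_read_count.size == 0:
            self.origin_read_count = np.zeros(n, dtype=np.int64)

    @property
    def expressed(self) -> np.ndarray:
        """Truth-positive status: strictly positive expression weight."""
        return self.expression_weight > 0

    def to_tsv(self, path: str | os.PathLike) -> None:
        pd.DataFrame(
            {
                "gene": self.genes,
                "weight": self.expression_weight,
                "true_rpkm": self.true_rpkm,
                "origin_reads": self.origin_read_count,
            }
        ).to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "TruthTable":
        frame = pd.read_csv(path, sep="\t")
        return cls(
            genes=list(frame["gene"]),
            expression_weight=frame["weight"].to_numpy(dtype=float),
            true_rpkm=frame["true_rpkm"].to_numpy(dtype=float),
            origin_read_count=frame["origin_reads"].to_numpy(dtype=np.int64),
        )


class SimRead(NamedTuple):
    """One simulated read; the name encodes ``read<i>|<origin gene>|<offset>``."""

    name: str
    sequence: str


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length).astype(np.uint8)


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _stage_rngs(seed: int) -> tuple[np.random.Generator, ...]:
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def simulate_transcriptome(config: SimConfig) -> Transcriptome:
    """Random transcriptome with families of near-identical gene models.

    The first ``n_families * family_size`` genes form the families: each
    family copies one seed sequence and substitutes each position
    independently with probability ``1 − within_family_identity`` (always
    to a different base, so the identity parameter is the expected
    pairwise identity to the seed).  Remaining genes are independent
    random sequences.
    """
    rng, _, _ = _stage_rngs(config.seed)
    lo, hi = config.length_range
    names = [f"gene{i:05d}" for i in range(config.n_genes)]
    seqs: list[np.ndarray] = []
    for fam in range(config.n_families):
        length = int(rng.integers(lo, hi + 1))
        seed_seq = _random_sequence(rng, length)
        seqs.append(seed_seq)
        for _ in range(config.family_size - 1):
            member = seed_seq.copy()
            mutate = rng.random(length) < (1.0 - config.within_family_identity)
            n_mut = int(mutate.sum())
            if n_mut:
                member[mutate] = (
                    member[mutate] + rng.integers(1, 4, size=n_mut).astype(np.uint8)
                ) % 4
            seqs.append(member)
    while len(seqs) < config.n_genes:
        length = int(rng.integers(lo, hi + 1))
        seqs.append(_random_sequence(rng, length))
    genes = GeneTable(
        GeneModel(name, len(seq)) for name, seq in zip(names, seqs)
    )
    return Transcriptome(genes=genes, sequences=[_to_str(s) for s in seqs])


def assign_expression(genes: GeneTable, config: SimConfig) -> TruthTable:
    """Sparse known-expression truth: log-normal weights for a fixed fraction.

    Exactly ``round(frac_expressed * n_genes)`` genes, chosen without
    replacement, receive i.i.d. log-normal weights; all others get
    exactly 0.
    """
    _, rng, _ = _stage_rngs(config.seed)
    n = len(genes)
    n_expressed = int(round(config.frac_expressed * n))
    chosen = rng.choice(n, size=n_expressed, replace=False)
    weights = np.zeros(n)
    weights[chosen] = rng.lognormal(config.mu_log, config.sigma_log, size=n_expressed)
    return TruthTable(genes=genes.names, expression_weight=weights)


def simulate_reads(
    transcriptome: Transcriptome, truth: TruthTable, config: SimConfig
) -> tuple[list[SimRead], TruthTable]:
    """Error-free forward-strand reads sampled in proportion to expression.

    Each read picks a gene with probability proportional to
    ``weight * (length − read_length + 1)`` and a start uniform over the
    valid positions, then copies the exact substring.  Returns the reads
    and the truth updated with realized origin counts and ``true_rpkm``.
    """
    _, _, rng = _stage_rngs(config.seed)
    rl = config.read_length_bp
    weights = truth.expression_weight
    if not np.any(weights > 0):
        raise ValueError("all expression weights are zero: nothing to sample")
    lengths = transcriptome.genes.lengths
    if np.any(lengths[weights > 0] < rl):
        raise ValueError("an expressed gene is shorter than the read length")
    n_starts = (lengths - rl + 1).astype(float)
    probs = weights * n_starts
    probs = probs / probs.sum()
    origin = rng.multinomial(config.n_reads, probs)

    reads: list[SimRead] = []
    i = 0
    for g_idx in np.nonzero(origin)[0]:
        seq = transcriptome.sequences[g_idx]
        gene = truth.genes[g_idx]
        starts = rng.integers(0, lengths[g_idx] - rl + 1, size=origin[g_idx])
        for start in starts:
            reads.append(
                SimRead(f"read{i}|{gene}|{int(start)}", seq[start : start + rl])
            )
            i += 1
    expected_origin = config.n_reads * probs
    true_rpkm = np.array(
        [
            compute_rpkm(expected_origin[j], int(lengths[j]), config.n_reads)
            for j in range(len(lengths))
        ]
    )
    updated = TruthTable(
        genes=truth.genes,
        expression_weight=weights,
        true_rpkm=true_rpkm,
        origin_read_count=origin.astype(np.int64),
    )
    logger.info("simulated %d reads from %d genes", len(reads), int((origin > 0).sum()))
    return reads, updated


def align_exact(
    reads: Sequence[SimRead], transcriptome: Transcriptome
) -> list[ReadAlignments]:
    """Every exact forward-strand occurrence of every read in every gene.

    Hashes the distinct read sequences, then scans every gene k-mer
    window (k = read length) once, recording each window that matches a
    read.  Error-free reads always hit their origin, so every read has
    at least one alignment.
    """
    if not reads:
        return []
    k = len(reads[0].sequence)
    if any(len(r.sequence) != k for r in reads):
        raise ValueError("all reads must have the same length")
    index: dict[str, list[tuple[str, int]]] = {r.sequence: [] for r in reads}
    for gene, seq in zip(transcriptome.genes.names, transcriptome.sequences):
        for off in range(len(seq) - k + 1):
            locs = index.get(seq[off : off + k])
            if locs is not None:
                locs.append((gene, off))
    out: list[ReadAlignments] = []
    for read in reads:
        hits = index[read.sequence]
        if not hits:
            raise ValueError(
                f"read {read.name!r} has no exact match in the transcriptome "
                f"(reads must be error-free substrings of the gene sequences)"
            )
        out.append(
            ReadAlignments(
                read.name,
                tuple(Alignment(read.name, gene, off, "+") for gene, off in hits),
            )
        )
    return out


def write_bowtie_output(
    reads: Sequence[SimRead],
    aligned: Sequence[ReadAlignments],
    path: str | os.PathLike,
) -> None:
    """Emit alignments as Bowtie-v1 default text lines.

    Fields: read name, strand, reference, 0-based offset, sequence,
    qualities (constant 'I'), and the reserved same-alignment-count
    field (number of other alignments of the read).
    """
    seq_by_name = {r.name: r.sequence for r in reads}
    with open(path, "w") as fh:
        for ra in aligned:
            seq = seq_by_name[ra.read_id]
            qual = "I" * len(seq)
            others = len(ra.locations) - 1
            for loc in ra.locations:
                fh.write(
                    f"{ra.read_id}\t{loc.strand}\t{loc.gene}\t{loc.offset}"
                    f"\t{seq}\t{qual}\t{others}\n"
                )


def write_reads_fastq(reads: Sequence[SimRead], path: str | os.PathLike) -> None:
    """Write simulated reads as FASTQ with constant quality 'I'."""
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.name, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(r.sequence)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


@dataclass
class SimulatedDataset:
    """One end-to-end dataset: transcriptome, truth, reads, alignments."""

    transcriptome: Transcriptome
    truth: TruthTable
    reads: list[SimRead]
    aligned: list[ReadAlignments]


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Convenience: transcriptome → truth → reads → exact alignments."""
    tx = simulate_transcriptome(config)
    truth = assign_expression(tx.genes, config)
    reads, truth = simulate_reads(tx, truth, config)
    aligned = align_exact(reads, tx)
    return SimulatedDataset(tx, truth, reads, aligned)
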