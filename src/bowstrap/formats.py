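"""External file formats and the core in-memory containers.

Three plain-text formats are handled here:

* the **gene-size file** — ``name<TAB>length_bp``, one gene model per line,
  no header.  Gene models are transcript-level reference sequences; their
  lengths are the denominator of RPKM.
* the **alignment file** — legacy Bowtie (v1) default text output, one
  alignment per line: ``read_name  strand  reference  0-based-offset
  sequence  qualities  [extra fields]``.  Only the first four fields are
  consumed; offsets follow Bowtie's 0-based convention.  SAM input is out
  of scope — the contract is the plain ``bowtie --all`` output.
* the **expression table** — the TSV results written after estimation.

Unknown reference names are a hard error rather than a warning: a silent
mismatch between the aligner index and the gene-size file would corrupt
the RPKM denominator invisibly.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .bootstrap import ExpressionEstimate

logger = logging.getLogger(__name__)

#: Column order of the expression-table TSV.
EXPRESSION_COLUMNS = (
    "gene",
    "length_bp",
    "unique_reads",
    "unique_rpkm",
    "mean_rpkm",
    "sd_rpkm",
    "cnd_pvalue",
    "bh_pvalue",
)

#: Column order of a baseline (single-RPKM-vector) TSV.
BASELINE_COLUMNS = ("gene", "rpkm", "expressed")


@dataclass(frozen=True)
class GeneModel:
    """One gene model: a named reference sequence of known length."""

    name: str
    length_bp: int

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene model name must be non-empty")
        if int(self.length_bp) < 1:
            raise ValueError(
                f"gene model {self.name!r}: length must be a positive "
                f"integer, got {self.length_bp}"
            )


class GeneTable(Sequence[GeneModel]):
    """Ordered collection of gene models; the universe over which RPKM is defined.

    Iteration order is the input order and is deterministic.  Names are
    unique; lookup by name is O(1).
    """

    def __init__(self, genes: Iterable[GeneModel]):
        self._genes: list[GeneModel] = list(genes)
        self._index: dict[str, int] = {}
        for i, g in enumerate(self._genes):
            if g.name in self._index:
                raise ValueError(f"duplicate gene model name {g.name!r}")
            self._index[g.name] = i
        self.lengths: np.ndarray = np.array(
            [g.length_bp for g in self._genes], dtype=np.int64
        )

    @property
    def names(self) -> list[str]:
        return [g.name for g in self._genes]

    def index(self, name: str) -> int:  # type: ignore[override]
        """Position of ``name`` in the table; KeyError if absent."""
        return self._index[name]

    def __contains__(self, name: object) -> bool:
        return name in self._index

    def __len__(self) -> int:
        return len(self._genes)

    def __getitem__(self, i):  # type: ignore[override]
        return self._genes[i]

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._genes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneTable):
            return NotImplemented
        return self._genes == other._genes

    def __repr__(self) -> str:
        return f"GeneTable({len(self)} gene models)"


class Alignment(NamedTuple):
    """One candidate alignment location of one read (0-based offset)."""

    read_id: str
    gene: str
    offset: int
    strand: str


class ReadAlignments(NamedTuple):
    """A read together with its full set of candidate alignment locations."""

    read_id: str
    locations: tuple[Alignment, ...]


def parse_gene_size_file(path: str | os.PathLike) -> GeneTable:
    """Read a tab-separated ``name<TAB>length_bp`` file into a GeneTable.

    Blank lines are ignored.  Duplicate names, non-integer or non-positive
    lengths, and an effectively empty file are all errors naming the
    offending line.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'name<TAB>length', got {line!r}"
                )
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: length is not an integer: {fields[1]!r}"
                ) from None
            if length < 1:
                raise ValueError(
                    f"{path}:{lineno}: gene {name!r} has non-positive length {length}"
                )
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene name {name!r}")
            seen.add(name)
            genes.append(GeneModel(name, length))
    if not genes:
        raise ValueError(f"{path}: no gene models found (empty file?)")
    return GeneTable(genes)


def write_gene_size_file(genes: GeneTable, path: str | os.PathLike) -> None:
    """Write a GeneTable back to the tab-separated gene-size format."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.name}\t{g.length_bp}\n")


def group_alignments(alignments: Iterable[Alignment]) -> list[ReadAlignments]:
    """Group alignment records by read name (first-seen order preserved)."""
    by_read: dict[str, list[Alignment]] = {}
    for aln in alignments:
        by_read.setdefault(aln.read_id, []).append(aln)
    return [ReadAlignments(rid, tuple(locs)) for rid, locs in by_read.items()]


def parse_bowtie_output(
    path: str | os.PathLike, genes: GeneTable
) -> list[ReadAlignments]:
    """Parse Bowtie-v1 default text output and group lines by read.

    Each line must carry at least the four leading fields
    ``read  strand  reference  offset``; trailing fields (sequence,
    qualities, reserved) are ignored.  Every reference name must exist in
    ``genes``.
    """
    path = Path(path)
    alignments: list[Alignment] = []
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected >=4 tab-separated fields, "
                    f"got {len(fields)}"
                )
            read_id, strand, ref, offset_s = fields[0], fields[1], fields[2], fields[3]
            if ref not in genes:
                raise ValueError(
                    f"{path}:{lineno}: reference {ref!r} not present in the "
                    f"gene-size file — aligner index and gene table disagree"
                )
            alignments.append(Alignment(read_id, ref, int(offset_s), strand))
            n_lines += 1
    reads = group_alignments(alignments)
    logger.info(
        "%s: %d alignment lines for %d distinct reads", path, n_lines, len(reads)
    )
    return reads


def write_expression_table(
    estimates: Sequence["ExpressionEstimate"],
    genes: GeneTable,
    path: str | os.PathLike,
) -> None:
    """Write per-gene expression estimates as a TSV in GeneTable order.

    There must be exactly one estimate per gene in ``genes``.  Floating
    values are printed with 6 significant digits.
    """
    by_gene = {e.gene: e for e in estimates}
    if len(by_gene) != len(estimates):
        raise ValueError("duplicate gene in estimates")
    missing = [g.name for g in genes if g.name not in by_gene]
    if missing:
        raise ValueError(f"missing estimates for {len(missing)} genes, e.g. {missing[:3]}")
    extra = set(by_gene) - set(genes.names)
    if extra:
        raise ValueError(f"estimates for genes not in table: {sorted(extra)[:3]}")
    rows = []
    for g in genes:
        e = by_gene[g.name]
        rows.append(
            (
                g.name,
                g.length_bp,
                e.unique_reads,
                e.unique_rpkm,
                e.mean_rpkm,
                e.sd_rpkm,
                e.cnd_pvalue,
                e.bh_pvalue,
            )
        )
    frame = pd.DataFrame(rows, columns=list(EXPRESSION_COLUMNS))
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_expression_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read back an expression TSV written by :func:`write_expression_table`."""
    frame = pd.read_csv(path, sep="\t")
    missing = set(EXPRESSION_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: not an expression table, missing {sorted(missing)}")
    return frame


def write_baseline_table(
    genes: GeneTable,
    rpkm: np.ndarray,
    expressed: np.ndarray,
    path: str | os.PathLike,
) -> None:
    """Write a baseline method's per-gene RPKM vector and expressed calls."""
    if len(rpkm) != len(genes) or len(expressed) != len(genes):
        raise ValueError("rpkm/expressed vectors must align with the gene table")
    frame = pd.DataFrame(
        {
            "gene": genes.names,
            "rpkm": np.asarray(rpkm, dtype=float),
            "expressed": np.asarray(expressed, dtype=bool),
        }
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_baseline_table(path: str | os.PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = set(BASELINE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: not a baseline table, missing {sorted(missing)}")
    return frame
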