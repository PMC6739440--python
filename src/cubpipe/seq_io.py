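"""Reading and writing the flat-file formats the pipeline touches.

FASTA for sequences and protein alignments, 12-column tab-separated hit
tables (the classic tabular alignment-search dialect: qseqid sseqid pident
length mismatch gapopen qstart qend sstart send evalue bitscore), and
two-column TSV expression tables (gene id, RPKM).

Identifiers are matched across CDS / protein / alignment files by exact
string equality after first-whitespace-token truncation; there is no fuzzy
matching, because a silent mismatch would corrupt the orthologous-position
bookkeeping downstream.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .genetic_code import STOP, GeneticCode

#: Column names of the 12-column tabular hit format.
HIT_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)
_HIT_TYPES = (str, str, float, int, int, int, int, int, int, int, float, float)


class FastaError(ValueError):
    pass


class HitTableError(ValueError):
    pass


class ExpressionError(ValueError):
    pass


class CdsValidationError(ValueError):
    """Structured rejection of a coding sequence.

    Attributes: ``seq_id``, ``reason`` (machine-friendly tag) and ``position``
    (1-based codon or nucleotide index where applicable, else None).
    """

    def __init__(self, seq_id: str, reason: str, position: int | None = None,
                 detail: str = ""):
        self.seq_id = seq_id
        self.reason = reason
        self.position = position
        msg = f"CDS {seq_id!r} rejected: {reason}"
        if position is not None:
            msg += f" at position {position}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


@dataclass(frozen=True)
class CodingSequence:
    """A validated protein-coding nucleotide sequence (no terminal stop)."""

    id: str
    species: str
    nucleotides: str
    terminal_stop: str | None = None

    @property
    def n_codons(self) -> int:
        return len(self.nucleotides) // 3

    def codons(self) -> list[str]:
        n = self.nucleotides
        return [n[i : i + 3] for i in range(0, len(n), 3)]


@dataclass
class ExpressionTable:
    """Per-gene expression levels (RPKM) for one species.

    Genes absent from ``values`` are treated as missing downstream (real
    expression studies rarely cover every orthologue).
    """

    species: str
    values: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse a FASTA file into ordered (id, sequence) pairs.

    Ids are the first whitespace token of the header; sequences are
    upper-cased. Gap characters are allowed (alignment files). Empty files
    and duplicate ids are rejected.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            rid = header.split()[0] if header.split() else ""
            if not rid:
                raise FastaError(f"{path}: record with empty id")
            if rid in seen:
                raise FastaError(f"{path}: duplicate record id {rid!r}")
            seen.add(rid)
            records.append((rid, seq.upper()))
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]],
                width: int = 60) -> None:
    """Write (id, sequence) pairs wrapped at ``width`` columns.

    Round-trips byte-stably with :func:`read_fasta` for upper-case,
    60-column-wrapped input.
    """
    with open(path, "w") as out:
        for rid, seq in records:
            out.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def validate_cds(seq: CodingSequence, code: GeneticCode | None = None) -> CodingSequence:
    """Validate a coding sequence against a genetic code.

    Accepts iff the length is a multiple of 3, the alphabet is clean
    (U normalised to T; ambiguity codes rejected whole, never masked) and no
    internal stop codon occurs. A terminal stop codon is trimmed and recorded
    on the returned record — the only repair ever performed.
    """
    code = code or GeneticCode.standard()
    nt = seq.nucleotides.upper().replace("U", "T")
    bad = next((i for i, b in enumerate(nt) if b not in "ACGT"), None)
    if bad is not None:
        raise CdsValidationError(seq.id, "invalid character", bad + 1,
                                 detail=f"char {nt[bad]!r}")
    if len(nt) % 3:
        raise CdsValidationError(seq.id, "length not a multiple of 3",
                                 detail=f"length {len(nt)}")
    if len(nt) < 3:
        raise CdsValidationError(seq.id, "too short", detail="length < 3")
    codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    terminal = None
    if code.translate(codons[-1]) == STOP:
        terminal = codons[-1]
        codons = codons[:-1]
    if not codons:
        raise CdsValidationError(seq.id, "empty after terminal-stop trimming")
    for i, codon in enumerate(codons):
        if code.translate(codon) == STOP:
            raise CdsValidationError(seq.id, "internal stop codon", i + 1,
                                     detail=codon)
    return CodingSequence(id=seq.id, species=seq.species,
                          nucleotides="".join(codons), terminal_stop=terminal)


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read a 12-column tabular hit file, preserving row order.

    Scientific-notation e-values are parsed as floats. Blank lines and
    ``#`` comments are skipped; any other row with the wrong column count is
    rejected with its line number.
    """
    rows: list[tuple] = []
    with open(path, newline="") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("#"):
                continue
            if len(row) != len(HIT_COLUMNS):
                raise HitTableError(
                    f"{path}: line {lineno}: expected {len(HIT_COLUMNS)} "
                    f"columns, found {len(row)}"
                )
            try:
                rows.append(tuple(t(v) for t, v in zip(_HIT_TYPES, row)))
            except ValueError as exc:
                raise HitTableError(f"{path}: line {lineno}: {exc}") from exc
    frame = pd.DataFrame(rows, columns=list(HIT_COLUMNS))
    return frame


def write_hit_table(path: str | Path, hits: pd.DataFrame) -> None:
    hits.to_csv(path, sep="\t", header=False, index=False,
                float_format="%.6g")


def read_expression_table(path: str | Path, species: str | None = None) -> ExpressionTable:
    """Read a two-column (gene id, RPKM) TSV into an :class:`ExpressionTable`.

    A single header row is skipped when its second field is non-numeric.
    Negative, non-finite or non-numeric values and duplicate ids are rejected.
    """
    species = species or Path(path).stem
    values: dict[str, float] = {}
    with open(path, newline="") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise ExpressionError(
                    f"{path}: line {lineno}: expected 2 columns, found {len(row)}")
            gene, raw = row[0].strip(), row[1].strip()
            try:
                value = float(raw)
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ExpressionError(
                    f"{path}: line {lineno}: non-numeric value {raw!r}")
            if not math.isfinite(value) or value < 0:
                raise ExpressionError(
                    f"{path}: line {lineno}: invalid expression value {value}")
            if gene in values:
                raise ExpressionError(f"{path}: line {lineno}: duplicate id {gene!r}")
            values[gene] = value
    return ExpressionTable(species=species, values=values)


def write_expression_table(path: str | Path, table: ExpressionTable) -> None:
    with open(path, "w") as out:
        out.write("gene\trpkm\n")
        for gene, value in table.values.items():
            out.write(f"{gene}\t{value:.6g}\n")


def read_cds_fasta(path: str | Path, species: str,
                   code: GeneticCode | None = None) -> list[CodingSequence]:
    """Read and validate every CDS in a FASTA file for one species."""
    return [
        validate_cds(CodingSequence(id=rid, species=species, nucleotides=seq), code)
        for rid, seq in read_fasta(path)
    ]
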