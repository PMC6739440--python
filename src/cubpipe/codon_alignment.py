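"""Back-translation of protein alignments into codon alignments.

Protein multiple alignments (one per orthologue group) are combined with the
validated coding sequences to produce codon alignments; columns with a gap in
any species are removed; short groups are filtered; and the retained groups
are concatenated into one gap-free "super-sequence" per species (peptide and
codon resolution, with per-group coordinate bookkeeping).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genetic_code import GeneticCode, translate_cds
from .seq_io import CodingSequence, write_fasta

GAP_CODON = "---"
GAP_AA = "-"

#: Default minimum degapped length (amino acids) for a group to be retained.
DEFAULT_MIN_LENGTH = 35


class BackTranslationError(ValueError):
    def __init__(self, cog_id: str, species: str, position: int, detail: str):
        self.cog_id = cog_id
        self.species = species
        self.position = position
        super().__init__(
            f"COG {cog_id}, species {species}: back-translation mismatch at "
            f"alignment position {position}: {detail}")


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class CodonAlignment:
    """Species x column matrix of codons (``---`` marks gaps).

    ``source_columns`` retains, per codon column, the 1-based index of the
    originating protein-alignment column, so positions survive degapping with
    their provenance intact.
    """

    cog_id: str
    species_order: tuple[str, ...]
    columns: np.ndarray  # shape (n_species, n_columns), dtype <U3
    source_columns: tuple[int, ...]

    @property
    def n_columns(self) -> int:
        return self.columns.shape[1]

    @property
    def has_gaps(self) -> bool:
        return bool((self.columns == GAP_CODON).any())

    def row(self, species: str) -> list[str]:
        return list(self.columns[self.species_order.index(species)])


@dataclass(frozen=True)
class SuperSequence:
    """Gap-free concatenation of retained group alignments for one species."""

    species: str
    peptide: str
    codons: str
    cog_boundaries: Mapping[str, tuple[int, int]]  # 1-based inclusive, aa units

    @property
    def n_codons(self) -> int:
        return len(self.codons) // 3

    def codon_list(self) -> list[str]:
        return [self.codons[i : i + 3] for i in range(0, len(self.codons), 3)]


def back_translate_alignment(
    cog_id: str,
    protein_alignment: Sequence[tuple[str, str]],
    cds_by_species: Mapping[str, CodingSequence],
    code: GeneticCode | None = None,
) -> CodonAlignment:
    """Map each aligned amino acid back onto its CDS codon.

    Requires the ungapped protein row to equal the translation of the species
    CDS exactly; codons are consumed left to right with no skips. The first
    mismatching position is reported on failure.
    """
    code = code or GeneticCode.standard()
    if not protein_alignment:
        raise AlignmentError(f"COG {cog_id}: empty protein alignment")
    lengths = {len(row) for _, row in protein_alignment}
    if len(lengths) != 1:
        raise AlignmentError(f"COG {cog_id}: ragged alignment rows {lengths}")
    n_cols = lengths.pop()
    species_order = tuple(sp for sp, _ in protein_alignment)
    matrix = np.full((len(species_order), n_cols), GAP_CODON, dtype="<U3")
    for r, (species, row) in enumerate(protein_alignment):
        if species not in cds_by_species:
            raise AlignmentError(f"COG {cog_id}: no CDS for species {species!r}")
        cds = cds_by_species[species]
        codons = cds.codons()
        k = 0
        for c, aa in enumerate(row.upper()):
            if aa == GAP_AA:
                continue
            if k >= len(codons):
                raise BackTranslationError(
                    cog_id, species, c + 1,
                    f"alignment longer than CDS ({len(codons)} codons)")
            trans = code.translate(codons[k])
            if trans != aa:
                raise BackTranslationError(
                    cog_id, species, c + 1,
                    f"protein says {aa}, codon {codons[k]} translates to {trans}")
            matrix[r, c] = codons[k]
            k += 1
        if k != len(codons):
            raise BackTranslationError(
                cog_id, species, n_cols,
                f"CDS has {len(codons) - k} unconsumed codons")
    return CodonAlignment(cog_id=cog_id, species_order=species_order,
                          columns=matrix,
                          source_columns=tuple(range(1, n_cols + 1)))


def remove_gapped_columns(aln: CodonAlignment) -> CodonAlignment:
    """Drop every column gapped in one or more species; order preserved.

    Idempotent; original protein-alignment column indices are retained.
    """
    keep = ~(aln.columns == GAP_CODON).any(axis=0)
    return CodonAlignment(
        cog_id=aln.cog_id,
        species_order=aln.species_order,
        columns=aln.columns[:, keep],
        source_columns=tuple(np.asarray(aln.source_columns)[keep]),
    )


def filter_short_cogs(
    alns: Iterable[CodonAlignment], min_len: int = DEFAULT_MIN_LENGTH
) -> tuple[list[CodonAlignment], list[tuple[str, int]]]:
    """Keep degapped alignments of length >= ``min_len`` amino acids.

    "Less than ``min_len``" is strict: length 35 survives the default filter,
    34 does not. Returns the retained list and a drop log of
    (cog_id, degapped_length) pairs.
    """
    retained: list[CodonAlignment] = []
    dropped: list[tuple[str, int]] = []
    for aln in alns:
        if aln.n_columns >= min_len:
            retained.append(aln)
        else:
            dropped.append((aln.cog_id, aln.n_columns))
    return retained, dropped


def concatenate_superseqs(
    alns: Sequence[CodonAlignment], code: GeneticCode | None = None
) -> dict[str, SuperSequence]:
    """Concatenate degapped group alignments into per-species super-sequences.

    Groups are concatenated in ascending ``cog_id`` order regardless of input
    order, so the result is deterministic. Every group must cover the same
    species set and be gap-free.
    """
    code = code or GeneticCode.standard()
    if not alns:
        raise AlignmentError("no alignments to concatenate")
    ordered = sorted(alns, key=lambda a: a.cog_id)
    species_set = set(ordered[0].species_order)
    parts: dict[str, list[str]] = {sp: [] for sp in sorted(species_set)}
    boundaries: dict[str, tuple[int, int]] = {}
    offset = 0
    for aln in ordered:
        if set(aln.species_order) != species_set:
            raise AlignmentError(
                f"COG {aln.cog_id}: species set {sorted(aln.species_order)} "
                f"differs from {sorted(species_set)}")
        if aln.has_gaps:
            raise AlignmentError(f"COG {aln.cog_id}: gaps present; degap first")
        for sp in parts:
            parts[sp].append("".join(aln.row(sp)))
        boundaries[aln.cog_id] = (offset + 1, offset + aln.n_columns)
        offset += aln.n_columns
    result: dict[str, SuperSequence] = {}
    for sp, chunks in parts.items():
        codons = "".join(chunks)
        result[sp] = SuperSequence(
            species=sp,
            peptide=translate_cds(codons, code),
            codons=codons,
            cog_boundaries=dict(boundaries),
        )
    return result


def write_codon_alignment(aln: CodonAlignment, path: str | Path) -> None:
    write_fasta(path, [(sp, "".join(aln.row(sp))) for sp in aln.species_order])


def write_superseqs(superseqs: Mapping[str, SuperSequence], path: str | Path) -> None:
    write_fasta(path, [(sp, ss.codons) for sp, ss in sorted(superseqs.items())])
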