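"""Genetic code tables, synonymous codon families, and codon arithmetic.

The standard nuclear code ships as the default table. Alternate codes can be
loaded from a plain-text two-column file (codon, amino-acid one-letter symbol,
``*`` for stop) via :meth:`GeneticCode.from_file`; every downstream statistic
takes the code as a parameter, so nothing in the pipeline hard-wires the
standard table beyond its being the default.

Amino acids are one-letter symbols throughout; ``STOP`` (``"*"``) is a
distinct symbol and is never silently dropped by :func:`translate_codon`.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Mapping

STOP = "*"
BASES = ("A", "C", "G", "T")
_BASE_SET = frozenset(BASES)

#: The 20 amino acids, one-letter, alphabetical.
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

_STANDARD_TABLE = """
TTT F  TTC F  TTA L  TTG L
CTT L  CTC L  CTA L  CTG L
ATT I  ATC I  ATA I  ATG M
GTT V  GTC V  GTA V  GTG V
TCT S  TCC S  TCA S  TCG S
CCT P  CCC P  CCA P  CCG P
ACT T  ACC T  ACA T  ACG T
GCT A  GCC A  GCA A  GCG A
TAT Y  TAC Y  TAA *  TAG *
CAT H  CAC H  CAA Q  CAG Q
AAT N  AAC N  AAA K  AAG K
GAT D  GAC D  GAA E  GAG E
TGT C  TGC C  TGA *  TGG W
CGT R  CGC R  CGA R  CGG R
AGT S  AGC S  AGA R  AGG R
GGT G  GGC G  GGA G  GGG G
"""


class InvalidCodonError(ValueError):
    """A codon is not three unambiguous nucleotides; reports the offender."""

    def __init__(self, codon: str, reason: str = "not a valid codon"):
        self.codon = codon
        super().__init__(f"{reason}: {codon!r}")


def normalize_codon(codon: str) -> str:
    """Upper-case a codon and map U to T; reject anything ambiguous.

    RNA alphabets (transcriptomic sources) are accepted by normalising U to T.
    Gaps, Ns and any other IUPAC ambiguity codes are rejected.
    """
    c = codon.upper().replace("U", "T")
    if len(c) != 3 or not _BASE_SET.issuperset(c):
        raise InvalidCodonError(codon)
    return c


class GeneticCode:
    """A codon -> amino-acid map with synonymous families and degeneracy classes.

    Attributes
    ----------
    table_id : str
        Identifier of the table (``"standard"`` for the default).
    codon_to_aa : dict
        Map over all 64 codons to amino-acid symbols or ``STOP``.
    families : dict
        Amino acid -> tuple of its synonymous codons, alphabetically ordered.
    degeneracy_classes : dict
        Fold (1, 2, 3, 4, 6 under the standard code) -> tuple of amino acids.
    """

    def __init__(self, codon_to_aa: Mapping[str, str], table_id: str = "custom"):
        table = {normalize_codon(c): aa.upper() for c, aa in codon_to_aa.items()}
        if len(table) != 64:
            raise ValueError(
                f"genetic code table must map all 64 codons, got {len(table)}"
            )
        self.table_id = table_id
        self.codon_to_aa: dict[str, str] = table
        self.stop_codons: tuple[str, ...] = tuple(
            sorted(c for c, aa in table.items() if aa == STOP)
        )
        self.sense_codons: tuple[str, ...] = tuple(
            sorted(c for c, aa in table.items() if aa != STOP)
        )
        fams: dict[str, list[str]] = {}
        for codon in self.sense_codons:
            fams.setdefault(table[codon], []).append(codon)
        self.families: dict[str, tuple[str, ...]] = {
            aa: tuple(sorted(cs)) for aa, cs in sorted(fams.items())
        }
        degs: dict[int, list[str]] = {}
        for aa, cs in self.families.items():
            degs.setdefault(len(cs), []).append(aa)
        self.degeneracy_classes: dict[int, tuple[str, ...]] = {
            k: tuple(sorted(v)) for k, v in sorted(degs.items())
        }
        # invariant: families partition the sense codons
        assert sum(len(v) for v in self.families.values()) == len(self.sense_codons)

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(self.families)

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[normalize_codon(codon)]

    @classmethod
    def standard(cls) -> "GeneticCode":
        return _standard_code()

    @classmethod
    def from_file(cls, path: str | Path, table_id: str | None = None) -> "GeneticCode":
        """Load a code from a two-column whitespace-separated codon/aa file."""
        pairs = Path(path).read_text().split()
        if len(pairs) % 2:
            raise ValueError(f"odd number of fields in code table {path}")
        mapping = dict(zip(pairs[::2], pairs[1::2]))
        return cls(mapping, table_id=table_id or Path(path).stem)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneticCode({self.table_id!r})"


@lru_cache(maxsize=1)
def _standard_code() -> GeneticCode:
    fields = _STANDARD_TABLE.split()
    return GeneticCode(dict(zip(fields[::2], fields[1::2])), table_id="standard")


def translate_codon(codon: str, code: GeneticCode | None = None) -> str:
    """Translate one codon; returns an amino-acid symbol or ``STOP``."""
    return (code or GeneticCode.standard()).translate(codon)


def translate_cds(nucleotides: str, code: GeneticCode | None = None) -> str:
    """Translate an in-frame nucleotide string codon by codon."""
    code = code or GeneticCode.standard()
    if len(nucleotides) % 3:
        raise ValueError(f"length {len(nucleotides)} is not a multiple of 3")
    return "".join(
        code.translate(nucleotides[i : i + 3]) for i in range(0, len(nucleotides), 3)
    )


def nucleotide_diff(codon_a: str, codon_b: str) -> int:
    """Number of positions (0-3) at which two codons differ. Symmetric."""
    a, b = normalize_codon(codon_a), normalize_codon(codon_b)
    return sum(x != y for x, y in zip(a, b))


def codon_gc_fraction(codon: str) -> float:
    """G+C count of a codon divided by 3."""
    c = normalize_codon(codon)
    return sum(b in "GC" for b in c) / 3.0


@dataclass(frozen=True)
class AminoAcidGCGroup:
    """Tertile grouping of amino acids by the mean GC fraction of their codons.

    ``groups`` maps each amino acid to ``"low"``, ``"medium"`` or ``"high"``;
    ``scores`` holds the underlying mean GC fractions. Ranking ties are broken
    by one-letter alphabetical order, and tertile sizes for 20 amino acids are
    7 / 7 / 6 (low gets the remainder first).
    """

    groups: Mapping[str, str]
    scores: Mapping[str, float]


def classify_aa_by_codon_gc(code: GeneticCode | None = None) -> AminoAcidGCGroup:
    """Split amino acids into low / medium / high GC tertiles.

    The score of an amino acid is the mean, over its synonymous codons, of the
    codon GC fraction. Under the standard code Lys (AAR) scores 1/6 and lands
    in the low tertile while Ala (GCN) and Arg (CGN/AGR) land in the high one.
    """
    code = code or GeneticCode.standard()
    scores = {
        aa: sum(codon_gc_fraction(c) for c in codons) / len(codons)
        for aa, codons in code.families.items()
    }
    ranked = sorted(scores, key=lambda aa: (scores[aa], aa))
    n = len(ranked)
    n_low = (n + 2) // 3
    n_med = (n + 1) // 3
    groups: dict[str, str] = {}
    for i, aa in enumerate(ranked):
        groups[aa] = "low" if i < n_low else ("medium" if i < n_low + n_med else "high")
    return AminoAcidGCGroup(groups=groups, scores=scores)
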