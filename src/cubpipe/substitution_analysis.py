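"""Asymmetric substitution matrices and two-hit analysis on paired super-sequences.

For an ordered species pair (rows = first species, columns = second), the
amino-acid matrix A counts, per ordered symbol pair (Z, X), the aligned
positions where species 1 shows Z while species 2 shows X; the codon matrix
is the same construction over the 61 sense codons. Both are asymmetric by
construction; aggregating the codon matrix by the amino acids its codons
encode reproduces the amino-acid matrix exactly, and each matrix's cells sum
to the ungapped alignment length.

Two chi-square tests (df = 1, no continuity correction, expected value = the
average of the two observed counts) probe the matrices:

* usage deviation — per amino acid, total count in species 1 (row sum)
  versus species 2 (column sum);
* reciprocal asymmetry — per unordered amino-acid pair {Z, X}, the cell
  A[Z][X] versus its mirror A[X][Z].

Cells with expected count < 5 are flagged low-count and not tested (a
standard chi-square validity guard). Benjamini-Hochberg adjustment is applied
across the tested set; raw p values are always reported alongside.

The two-hit summary quantifies, per amino-acid change and source codon, how
often the observed target codon differs by two or more nucleotides, against
a single-step-favouring baseline in which the target would be the
minimal-nucleotide-difference codon of the new amino acid (ties split
equally). The positive excess of multi-step targets is the operational
signature of a non-synonymous substitution followed by a synonymous
GC-restoring change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .codon_alignment import SuperSequence
from .genetic_code import GeneticCode, nucleotide_diff


class SubstitutionError(ValueError):
    pass


@dataclass(frozen=True)
class SubstitutionTables:
    """Amino-acid (20x20) and codon (61x61) count matrices for one ordered pair."""

    species_pair: tuple[str, str]
    aa_matrix: pd.DataFrame
    codon_matrix: pd.DataFrame
    n_positions: int


def _paired_codons(super_a: SuperSequence, super_b: SuperSequence
                   ) -> list[tuple[str, str]]:
    if len(super_a.codons) != len(super_b.codons):
        raise SubstitutionError(
            f"super-sequence length mismatch: {super_a.species} has "
            f"{super_a.n_codons} codons, {super_b.species} has {super_b.n_codons}")
    return list(zip(super_a.codon_list(), super_b.codon_list()))


def build_substitution_tables(super_a: SuperSequence, super_b: SuperSequence,
                              code: GeneticCode | None = None
                              ) -> SubstitutionTables:
    """Count both matrices in one pass over the aligned positions."""
    code = code or GeneticCode.standard()
    aas = list(code.amino_acids)
    codons = list(code.sense_codons)
    aa_idx = {a: i for i, a in enumerate(aas)}
    cd_idx = {c: i for i, c in enumerate(codons)}
    aa_m = np.zeros((len(aas), len(aas)), dtype=int)
    cd_m = np.zeros((len(codons), len(codons)), dtype=int)
    for ca, cb in _paired_codons(super_a, super_b):
        if ca not in cd_idx or cb not in cd_idx:
            raise SubstitutionError(f"stop or invalid codon in pair ({ca}, {cb})")
        cd_m[cd_idx[ca], cd_idx[cb]] += 1
        aa_m[aa_idx[code.translate(ca)], aa_idx[code.translate(cb)]] += 1
    return SubstitutionTables(
        species_pair=(super_a.species, super_b.species),
        aa_matrix=pd.DataFrame(aa_m, index=aas, columns=aas),
        codon_matrix=pd.DataFrame(cd_m, index=codons, columns=codons),
        n_positions=super_a.n_codons,
    )


def aa_substitution_matrix(super_a: SuperSequence, super_b: SuperSequence,
                           code: GeneticCode | None = None) -> pd.DataFrame:
    """20x20 count matrix; rows are the first-named species."""
    return build_substitution_tables(super_a, super_b, code).aa_matrix


def codon_substitution_matrix(super_a: SuperSequence, super_b: SuperSequence,
                              code: GeneticCode | None = None) -> pd.DataFrame:
    """61x61 count matrix over sense codons; rows are the first-named species."""
    return build_substitution_tables(super_a, super_b, code).codon_matrix


def aggregate_codon_matrix(codon_matrix: pd.DataFrame,
                           code: GeneticCode | None = None) -> pd.DataFrame:
    """Collapse a codon matrix to amino-acid resolution (consistency check)."""
    code = code or GeneticCode.standard()
    aas = list(code.amino_acids)
    idx = {a: i for i, a in enumerate(aas)}
    row_aa = np.array([idx[code.translate(c)] for c in codon_matrix.index])
    col_aa = np.array([idx[code.translate(c)] for c in codon_matrix.columns])
    M = codon_matrix.to_numpy()
    out = np.zeros((len(aas), len(aas)), dtype=M.dtype)
    for i, r in enumerate(row_aa):
        np.add.at(out[r], col_aa, M[i])
    return pd.DataFrame(out, index=aas, columns=aas)


def _chi2_two_cell(c1: float, c2: float) -> tuple[float, float, float]:
    """Chi-square of two observed counts against their common average."""
    e = (c1 + c2) / 2.0
    if e == 0:
        return 0.0, math.nan, e
    chi2 = (c1 - e) ** 2 / e + (c2 - e) ** 2 / e
    return chi2, float(stats.chi2.sf(chi2, df=1)), e


def _bh_adjust(frame: pd.DataFrame) -> pd.DataFrame:
    tested = frame["pvalue"].notna()
    frame["p_adj"] = math.nan
    if tested.any():
        frame.loc[tested, "p_adj"] = multipletests(
            frame.loc[tested, "pvalue"], method="fdr_bh")[1]
    return frame


def usage_deviation_test(tables: SubstitutionTables,
                         min_expected: float = 5.0) -> pd.DataFrame:
    """Per-amino-acid chi-square of species-1 vs species-2 usage totals.

    Totals are row sums (species 1) and column sums (species 2) of the
    amino-acid matrix. Amino acids with zero combined count are skipped;
    expected counts below ``min_expected`` are flagged and left untested.
    """
    rows = []
    m = tables.aa_matrix
    for aa in m.index:
        c1, c2 = int(m.loc[aa].sum()), int(m[aa].sum())
        if c1 + c2 == 0:
            continue
        chi2, p, e = _chi2_two_cell(c1, c2)
        low = e < min_expected
        rows.append({"aa": aa, "count_1": c1, "count_2": c2, "expected": e,
                     "chi2": chi2, "low_count": low,
                     "pvalue": math.nan if low else p})
    frame = pd.DataFrame(rows).set_index("aa")
    return _bh_adjust(frame)


def reciprocal_asymmetry_test(tables: SubstitutionTables,
                              min_expected: float = 5.0) -> pd.DataFrame:
    """Chi-square of each off-diagonal cell against its mirror cell.

    For each unordered amino-acid pair {Z, X} with at least one observed
    change, tests A[Z][X] versus A[X][Z] with the average as expected value.
    """
    m = tables.aa_matrix
    rows = []
    aas = list(m.index)
    for i, z in enumerate(aas):
        for x in aas[i + 1 :]:
            n_zx, n_xz = int(m.loc[z, x]), int(m.loc[x, z])
            if n_zx + n_xz == 0:
                continue
            chi2, p, e = _chi2_two_cell(n_zx, n_xz)
            low = e < min_expected
            rows.append({"aa_1": z, "aa_2": x, "count_12": n_zx,
                         "count_21": n_xz, "expected": e, "chi2": chi2,
                         "low_count": low, "pvalue": math.nan if low else p})
    frame = pd.DataFrame(rows)
    return _bh_adjust(frame)


def classify_codon_pairs(super_a: SuperSequence, super_b: SuperSequence,
                         code: GeneticCode | None = None) -> pd.DataFrame:
    """Per source codon: conserved / synonymous / non-synonymous counts.

    Also reports the nucleotide-difference histogram (columns nt0..nt3).
    This is the stacked-bar data behind per-codon substitution-state plots.
    """
    code = code or GeneticCode.standard()
    frame = pd.DataFrame(
        0, index=list(code.sense_codons),
        columns=["conserved", "synonymous", "nonsynonymous",
                 "nt0", "nt1", "nt2", "nt3"], dtype=int)
    for ca, cb in _paired_codons(super_a, super_b):
        d = nucleotide_diff(ca, cb)
        if d == 0:
            status = "conserved"
        elif code.translate(ca) == code.translate(cb):
            status = "synonymous"
        else:
            status = "nonsynonymous"
        frame.loc[ca, status] += 1
        frame.loc[ca, f"nt{d}"] += 1
    return frame


@lru_cache(maxsize=4096)
def _min_diff_to_family(codon: str, family: tuple[str, ...]) -> int:
    return min(nucleotide_diff(codon, t) for t in family)


def two_hit_summary(tables: SubstitutionTables,
                    code: GeneticCode | None = None) -> pd.DataFrame:
    """Single- vs multi-step target partition per amino-acid change and source codon.

    For every ordered change Z -> X observed in the codon matrix and every
    source codon c of Z, partitions the observed target codons of X into
    single-step (1 nucleotide from c) and multi-step (>= 2). The baseline is
    the minimal-path expectation: had the target been the
    minimal-nucleotide-difference codon of X from c (ties split equally), the
    multi-step fraction would be 0 when that minimum is 1 and 1 otherwise.
    ``excess`` = observed multi-step fraction - baseline multi-step fraction.
    """
    code = code or GeneticCode.standard()
    m = tables.codon_matrix
    codon_aa = {c: code.translate(c) for c in m.index}
    rows = []
    for src in m.index:
        row = m.loc[src]
        observed = row[row > 0]
        by_target_aa: dict[str, list[tuple[str, int]]] = {}
        for tgt, n in observed.items():
            aa = codon_aa[tgt]
            if aa == codon_aa[src]:
                continue  # conserved or synonymous
            by_target_aa.setdefault(aa, []).append((tgt, int(n)))
        for aa, targets in sorted(by_target_aa.items()):
            n_single = sum(n for t, n in targets if nucleotide_diff(src, t) == 1)
            n_total = sum(n for _, n in targets)
            n_multi = n_total - n_single
            min_d = _min_diff_to_family(src, code.families[aa])
            baseline = 0.0 if min_d == 1 else 1.0
            obs = n_multi / n_total
            rows.append({
                "aa_from": codon_aa[src], "aa_to": aa, "source_codon": src,
                "n_total": n_total, "n_single": n_single, "n_multi": n_multi,
                "obs_multi_frac": obs, "min_nt_diff": min_d,
                "baseline_multi_frac": baseline, "excess": obs - baseline,
            })
    return pd.DataFrame(
        rows, columns=["aa_from", "aa_to", "source_codon", "n_total",
                       "n_single", "n_multi", "obs_multi_frac", "min_nt_diff",
                       "baseline_multi_frac", "excess"])


def two_hit_excess(summary: pd.DataFrame) -> float:
    """Count-weighted mean excess over all change cells (NaN if no changes)."""
    if summary.empty or summary["n_total"].sum() == 0:
        return math.nan
    w = summary["n_total"].to_numpy(float)
    return float(np.average(summary["excess"].to_numpy(float), weights=w))
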