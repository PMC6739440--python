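"""Compositional statistics of coding sequences.

Per-unit (gene or concatenated species super-gene) codon counts, GC content
by codon position, relative synonymous codon usage (RSCU), Wright's effective
number of codons (ENC), the mutation-pressure ENC expectation curve, the
GC12-on-GC3 neutrality regression, and per-codon usage-vs-GC3 correlations.

Definitions
-----------
RSCU of codon j in amino-acid family i of size k:
    RSCU_ij = x_ij / ((1/k) * sum_j' x_ij')
so uniform within-family usage gives 1 everywhere; families with zero total
are missing (NaN), never zero. Met and Trp (single-codon families) are
excluded from RSCU vectors, leaving 59 entries under the standard code.

ENC follows Wright's estimator. Per amino acid with n >= 2 observations the
codon homozygosity is F = (n * sum p_i^2 - 1) / (n - 1); F values are
averaged within degeneracy classes and the class contributions summed:
ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 under the standard code (the leading 2
counts the single-codon amino acids). If no 3-fold amino acid is observed,
F3 is imputed as (F2 + F4)/2. The result is capped into [20, 61]; missing
class means (other than the imputed F3) make the statistic missing.

The mutation-only expectation used in ENC-vs-GC3 plots is
    ENC_exp(s) = 2 + s + 29 / (s^2 + (1 - s)^2)
for third-position GC fraction s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import GeneticCode
from .seq_io import CodingSequence

_SINGLE_CODON_EXCLUDED = True  # RSCU drops 1-fold families (Met, Trp)


class GCByPosition(NamedTuple):
    gc1: float
    gc2: float
    gc3: float
    gc12: float


@dataclass(frozen=True)
class CompositionProfile:
    """All compositional statistics for one sequence unit."""

    unit_id: str
    codon_counts: pd.Series  # indexed by the sense codons
    gc: GCByPosition
    rscu: pd.Series  # 59 entries under the standard code, NaN = missing
    enc: float  # NaN = missing


@dataclass(frozen=True)
class NeutralityResult:
    """OLS fit of GC12 on GC3; ``note`` flags degenerate inputs."""

    slope: float
    intercept: float
    r: float
    pvalue: float
    n: int
    note: str | None = None


def codon_counts(sequence: str | CodingSequence,
                 code: GeneticCode | None = None) -> pd.Series:
    """Counts over the sense codons of a validated in-frame sequence."""
    code = code or GeneticCode.standard()
    nt = sequence.nucleotides if isinstance(sequence, CodingSequence) else sequence
    if len(nt) % 3 or not nt:
        raise ValueError("sequence must be non-empty and in frame")
    counts = pd.Series(0, index=list(code.sense_codons), dtype=int)
    for i in range(0, len(nt), 3):
        codon = nt[i : i + 3]
        if codon not in counts.index:
            raise ValueError(f"stop or invalid codon {codon!r} at codon {i // 3 + 1}")
        counts[codon] += 1
    return counts


def gc_by_position(counts: pd.Series, code: GeneticCode | None = None,
                   synonymous_only: bool = False) -> GCByPosition:
    """GC fraction at each codon position, computed from codon counts.

    By default all sense codons enter every position, Met and Trp included.
    With ``synonymous_only`` the third-position fraction (GC3s variant) is
    computed over codons of degenerate families only; positions 1-2 are
    unaffected.
    """
    code = code or GeneticCode.standard()
    total = int(counts.sum())
    if total == 0:
        raise ValueError("zero codons: GC content undefined")
    gc = []
    for pos in range(3):
        if pos == 2 and synonymous_only:
            keep = [c for c in counts.index if len(code.families[code.translate(c)]) > 1]
            sub = counts[keep]
            denom = int(sub.sum())
            hits = sum(n for c, n in sub.items() if c[2] in "GC")
            gc.append(hits / denom if denom else math.nan)
        else:
            hits = sum(n for c, n in counts.items() if c[pos] in "GC")
            gc.append(hits / total)
    return GCByPosition(gc1=gc[0], gc2=gc[1], gc3=gc[2], gc12=(gc[0] + gc[1]) / 2)


def rscu(counts: pd.Series, code: GeneticCode | None = None) -> pd.Series:
    """Relative synonymous codon usage; NaN for unobserved families."""
    code = code or GeneticCode.standard()
    out: dict[str, float] = {}
    for aa, family in code.families.items():
        if len(family) == 1 and _SINGLE_CODON_EXCLUDED:
            continue
        total = sum(int(counts.get(c, 0)) for c in family)
        for c in family:
            out[c] = (len(family) * counts.get(c, 0) / total) if total else math.nan
    return pd.Series(out).sort_index()


def enc(counts: pd.Series, code: GeneticCode | None = None) -> float:
    """Wright's effective number of codons; NaN when not estimable."""
    code = code or GeneticCode.standard()
    fold_f: dict[int, list[float]] = {}
    for aa, family in code.families.items():
        k = len(family)
        if k == 1:
            continue
        n = sum(int(counts.get(c, 0)) for c in family)
        if n < 2:
            continue
        sum_p2 = sum((counts.get(c, 0) / n) ** 2 for c in family)
        f = (n * sum_p2 - 1) / (n - 1)
        fold_f.setdefault(k, []).append(f)
    fold_sizes = {k: len(aas) for k, aas in code.degeneracy_classes.items()}
    n_single = fold_sizes.get(1, 0)
    fbar = {k: float(np.mean(v)) for k, v in fold_f.items()}
    if 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2  # Wright's convention for Ile
    value = float(n_single)
    for k, n_aa in fold_sizes.items():
        if k == 1:
            continue
        f = fbar.get(k)
        if f is None or f <= 0:
            return math.nan
        value += n_aa / f
    return float(min(61.0, max(20.0, value)))


def enc_expected_curve(s: float | np.ndarray) -> float | np.ndarray:
    """Mutation-pressure ENC expectation at third-position GC fraction ``s``."""
    s = np.asarray(s, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("GC3 fraction must lie in [0, 1]")
    out = 2.0 + s + 29.0 / (s**2 + (1.0 - s) ** 2)
    return float(out) if out.ndim == 0 else out


def profile(unit_id: str, sequence: str | CodingSequence,
            code: GeneticCode | None = None,
            gc3_synonymous: bool = False) -> CompositionProfile:
    """Full compositional profile of one sequence unit."""
    code = code or GeneticCode.standard()
    counts = codon_counts(sequence, code)
    return CompositionProfile(
        unit_id=unit_id,
        codon_counts=counts,
        gc=gc_by_position(counts, code, synonymous_only=gc3_synonymous),
        rscu=rscu(counts, code),
        enc=enc(counts, code),
    )


def composition_table(units: Iterable[tuple[str, str] | CodingSequence],
                      code: GeneticCode | None = None,
                      gc3_synonymous: bool = False) -> pd.DataFrame:
    """Per-unit composition table: GC metrics, ENC and all RSCU values.

    One row per unit; RSCU columns are named ``rscu_<codon>``. This is the
    frame consumed by the correlation, ordination and preferred-codon stages.
    """
    code = code or GeneticCode.standard()
    rows = []
    for unit in units:
        if isinstance(unit, CodingSequence):
            uid, seq = unit.id, unit
        else:
            uid, seq = unit
        p = profile(uid, seq, code, gc3_synonymous=gc3_synonymous)
        row: dict[str, float] = {
            "unit_id": uid,
            "n_codons": int(p.codon_counts.sum()),
            "gc1": p.gc.gc1, "gc2": p.gc.gc2, "gc3": p.gc.gc3, "gc12": p.gc.gc12,
            "enc": p.enc,
        }
        row.update({f"rscu_{c}": v for c, v in p.rscu.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("unit_id")


def counts_table(units: Iterable[tuple[str, str] | CodingSequence],
                 code: GeneticCode | None = None) -> pd.DataFrame:
    """Per-unit raw codon counts (one column per sense codon)."""
    code = code or GeneticCode.standard()
    rows = {}
    for unit in units:
        if isinstance(unit, CodingSequence):
            uid, seq = unit.id, unit
        else:
            uid, seq = unit
        rows[uid] = codon_counts(seq, code)
    frame = pd.DataFrame(rows).T
    frame.index.name = "unit_id"
    return frame


def neutrality_regression(gc3: Sequence[float], gc12: Sequence[float]
                          ) -> NeutralityResult:
    """Ordinary least squares of GC12 on GC3 across units.

    A slope near 1 is the mutation-driven (neutral) limit; a slope near 0
    indicates selective constraint on codon positions 1-2. Also serves the
    species-level plot over concatenated super-genes (one point per species).
    """
    x = np.asarray(gc3, dtype=float)
    y = np.asarray(gc12, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 (gc3, gc12) points")
    if np.ptp(x) == 0:
        return NeutralityResult(math.nan, math.nan, math.nan, math.nan,
                                n=int(x.size), note="zero GC3 variance")
    fit = stats.linregress(x, y)
    return NeutralityResult(slope=float(fit.slope), intercept=float(fit.intercept),
                            r=float(fit.rvalue), pvalue=float(fit.pvalue),
                            n=int(x.size))


def codon_gc3_correlations(table: pd.DataFrame,
                           code: GeneticCode | None = None,
                           method: str = "pearson",
                           min_units: int = 3) -> pd.Series:
    """Per-codon correlation between RSCU and GC3 across genes.

    ``table`` is a :func:`composition_table` frame. Genes missing a codon's
    RSCU (unobserved family) are dropped pairwise; codons with fewer than
    ``min_units`` informative genes, or with zero variance on either side,
    are missing. Single-codon families never appear.
    """
    code = code or GeneticCode.standard()
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unsupported correlation method {method!r}")
    gc3 = table["gc3"].astype(float)
    out: dict[str, float] = {}
    rscu_cols = [c for c in table.columns if c.startswith("rscu_")]
    for col in sorted(rscu_cols):
        codon = col[len("rscu_"):]
        usage = table[col].astype(float)
        mask = usage.notna() & gc3.notna()
        x, y = gc3[mask], usage[mask]
        if mask.sum() < min_units or np.ptp(x) == 0 or np.ptp(y) == 0:
            out[codon] = math.nan
            continue
        if method == "pearson":
            out[codon] = float(stats.pearsonr(x, y).statistic)
        else:
            out[codon] = float(stats.spearmanr(x, y).statistic)
    return pd.Series(out).sort_index()
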