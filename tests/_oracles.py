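"""Independent brute-force reference implementations used only by tests.

Deliberately naive and structured differently from the package code: plain
dict/loop arithmetic straight from the formula definitions, so agreement is
meaningful.
"""

from __future__ import annotations

import math


def oracle_rscu(counts: dict[str, int], families: dict[str, tuple[str, ...]]
                ) -> dict[str, float]:
    out = {}
    for aa, fam in families.items():
        if len(fam) == 1:
            continue
        total = sum(counts.get(c, 0) for c in fam)
        for c in fam:
            if total == 0:
                out[c] = math.nan
            else:
                expected = total / len(fam)
                out[c] = counts.get(c, 0) / expected
    return out


def oracle_enc(counts: dict[str, int], families: dict[str, tuple[str, ...]]
               ) -> float:
    by_fold: dict[int, list[float]] = {}
    n_single = sum(1 for fam in families.values() if len(fam) == 1)
    for fam in families.values():
        k = len(fam)
        if k == 1:
            continue
        n = sum(counts.get(c, 0) for c in fam)
        if n < 2:
            continue
        s = sum((counts.get(c, 0) / n) ** 2 for c in fam)
        by_fold.setdefault(k, []).append((n * s - 1) / (n - 1))
    fbar = {k: sum(v) / len(v) for k, v in by_fold.items()}
    folds = sorted({len(f) for f in families.values()} - {1})
    if 3 in folds and 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2
    total = float(n_single)
    for k in folds:
        n_aa = sum(1 for f in families.values() if len(f) == k)
        if k not in fbar or fbar[k] <= 0:
            return math.nan
        total += n_aa / fbar[k]
    return min(61.0, max(20.0, total))


def oracle_gc_by_position(codon_list: list[str]) -> tuple[float, float, float, float]:
    n = len(codon_list)
    gc = [sum(1 for c in codon_list if c[p] in "GC") / n for p in range(3)]
    return gc[0], gc[1], gc[2], (gc[0] + gc[1]) / 2


def oracle_two_cell_chi2(c1: float, c2: float) -> tuple[float, float]:
    """Textbook chi-square of two observations vs their average, df=1."""
    from scipy.stats import chi2 as chi2_dist

    e = (c1 + c2) / 2
    stat = (c1 - e) ** 2 / e + (c2 - e) ** 2 / e
    return stat, float(chi2_dist.sf(stat, 1))
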