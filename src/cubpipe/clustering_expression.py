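"""Species clustering on RSCU, gene ordination, and preferred-codon calling.

The species clustering runs hierarchical agglomeration under a grid of
(distance, linkage) settings and keeps the groupings that a majority of
settings agree on: every dendrogram is reduced to its set of clades (leaf
subsets under internal nodes), clade frequencies are counted across the
grid, and clades appearing in more than half of the settings form the
consensus tree (strict majority guarantees mutual compatibility). Support
values are the clade frequencies.

Gene-level ordination projects the genes x codon-frequency matrix by PCA
(default) or correspondence analysis, and labels each gene high / low / mid
by expression percentile. Preferred codons are those whose per-gene RSCU is
significantly higher in the high-expression stratum than in the low one
(two-sided rank-sum test, Benjamini-Hochberg adjusted across codons, with a
direction requirement); a pooled-count chi-square mode is available as an
alternative.

Percentile boundaries are exclusive (strictly above the high percentile,
strictly below the low one) and are taken at observed data values, so the
stratification is invariant under monotone transformations of expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .genetic_code import GeneticCode
from .seq_io import ExpressionTable

#: Default settings grid: Euclidean distance under three linkage rules.
DEFAULT_GRID: tuple[tuple[str, str], ...] = (
    ("euclidean", "complete"),
    ("euclidean", "average"),
    ("euclidean", "ward"),
)


class ClusteringError(ValueError):
    pass


class StratificationError(ValueError):
    pass


@dataclass
class ConsensusCluster:
    settings_grid: tuple[tuple[str, str], ...]
    newicks: dict[tuple[str, str], str]  # one dendrogram per setting
    consensus_newick: str
    support: dict[frozenset, float]  # retained clade -> frequency

    def has_clade(self, leaves: Sequence[str]) -> bool:
        return frozenset(leaves) in self.support


@dataclass
class OrdinationResult:
    mode: str
    coords: pd.DataFrame  # index gene, columns axis1, axis2, expression, label
    explained: tuple[float, float]  # variance (PCA) / inertia (COA) fractions


def _linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        inner = ",".join(sorted([left, right]))
        return f"({inner}):{length:.6g}"

    return render(tree, tree.dist).rsplit(":", 1)[0] + ";"


def _linkage_clades(Z: np.ndarray, labels: Sequence[str]) -> set[frozenset]:
    """All clades (leaf subsets under internal nodes), root included."""
    n = len(labels)
    clades: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    out: set[frozenset] = set()
    for i, (a, b, _dist, _size) in enumerate(Z):
        merged = clades[int(a)] | clades[int(b)]
        clades[n + i] = merged
        out.add(merged)
    return out


def _consensus_newick(retained: dict[frozenset, float], leaves: Sequence[str]) -> str:
    root = frozenset(leaves)
    inner = sorted((c for c in retained if c != root), key=lambda c: (-len(c), sorted(c)))
    children: dict[frozenset, list[frozenset]] = {root: []}
    for clade in inner:
        parent = root
        # smallest already-placed clade strictly containing this one
        for cand in inner:
            if cand is clade:
                continue
            if clade < cand and (parent == root or cand < parent):
                parent = cand
        children.setdefault(parent, [])
        children[parent].append(clade)
        children.setdefault(clade, [])

    def render(clade: frozenset) -> str:
        kids = children.get(clade, [])
        covered = frozenset().union(*kids) if kids else frozenset()
        parts = [render(k) for k in sorted(kids, key=lambda c: sorted(c))]
        parts += sorted(clade - covered)
        if len(parts) == 1:
            return parts[0]
        return f"({','.join(parts)}){retained[clade]:.2f}"

    return render(root) + ";"


def rscu_cluster_consensus(species_rscu: pd.DataFrame,
                           grid: Sequence[tuple[str, str]] = DEFAULT_GRID
                           ) -> ConsensusCluster:
    """Majority-rule consensus over hierarchical clusterings of species RSCU.

    ``species_rscu`` is a dense species x codon RSCU frame (species-level
    vectors from concatenated super-genes have no missing families). Missing
    entries are rejected — impute or pool upstream. The consensus retains
    clades appearing in strictly more than half of the grid settings, which
    makes the result independent of grid order.
    """
    if species_rscu.isna().any().any():
        raise ClusteringError(
            "missing RSCU entries; species-level vectors must be dense "
            "(compute them from concatenated super-genes or impute upstream)")
    if len(species_rscu) < 3:
        raise ClusteringError("need at least 3 species to cluster")
    labels = list(species_rscu.index)
    X = species_rscu.to_numpy(float)
    newicks: dict[tuple[str, str], str] = {}
    counts: dict[frozenset, int] = {}
    grid = tuple((d, l) for d, l in grid)
    for distance, linkage_method in grid:
        Z = hierarchy.linkage(X, method=linkage_method, metric=distance)
        newicks[(distance, linkage_method)] = _linkage_to_newick(Z, labels)
        for clade in _linkage_clades(Z, labels):
            counts[clade] = counts.get(clade, 0) + 1
    n_settings = len(grid)
    retained = {c: k / n_settings for c, k in counts.items() if k / n_settings > 0.5}
    retained[frozenset(labels)] = counts.get(frozenset(labels), n_settings) / n_settings
    return ConsensusCluster(
        settings_grid=grid,
        newicks=newicks,
        consensus_newick=_consensus_newick(retained, labels),
        support=retained,
    )


def _stratify(expression: pd.Series, hi_pct: float, lo_pct: float) -> pd.Series:
    """Label genes high / low / mid by exclusive percentile boundaries."""
    values = expression.to_numpy(float)
    if np.ptp(values) == 0:
        raise StratificationError(
            "all expression values equal; percentile strata undefined")
    hi_thr = np.quantile(values, hi_pct / 100.0, method="higher")
    lo_thr = np.quantile(values, lo_pct / 100.0, method="lower")
    labels = pd.Series("mid", index=expression.index)
    labels[expression > hi_thr] = "high"
    labels[expression < lo_thr] = "low"
    return labels


def _correspondence_analysis(freq: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Row coordinates of a correspondence analysis (chi-square metric SVD)."""
    P = freq / freq.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    keep = c > 0
    P, c = P[:, keep], c[keep]
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sing, _ = np.linalg.svd(S, full_matrices=False)
    coords = (U[:, :2] * sing[:2]) / np.sqrt(r)[:, None]
    inertia = sing**2
    total = inertia.sum()
    expl = (float(inertia[0] / total), float(inertia[1] / total)) if total > 0 else (0.0, 0.0)
    return coords, expl


def codon_usage_pca(gene_counts: pd.DataFrame, expression: ExpressionTable,
                    hi_pct: float = 90.0, lo_pct: float = 10.0,
                    mode: str = "pca",
                    code: GeneticCode | None = None) -> OrdinationResult:
    """Ordination of genes by codon frequency, labelled by expression stratum.

    ``gene_counts`` is a genes x sense-codon count frame (see
    ``composition.counts_table``); rows are converted to frequencies. Genes
    without an expression value are excluded (missing expression is
    tolerated, not fabricated). ``mode`` is ``"pca"`` or ``"coa"``.
    """
    if mode not in ("pca", "coa"):
        raise ValueError(f"unknown ordination mode {mode!r}")
    genes = [g for g in gene_counts.index if g in expression.values]
    if len(genes) < 10:
        raise StratificationError(
            f"need >= 10 genes with expression values, found {len(genes)}")
    counts = gene_counts.loc[genes].to_numpy(float)
    expr = pd.Series({g: expression.values[g] for g in genes})
    labels = _stratify(expr, hi_pct, lo_pct)
    freq = counts / counts.sum(axis=1, keepdims=True)
    if mode == "pca":
        model = PCA(n_components=2, svd_solver="full")
        xy = model.fit_transform(freq)
        explained = (float(model.explained_variance_ratio_[0]),
                     float(model.explained_variance_ratio_[1]))
    else:
        xy, explained = _correspondence_analysis(counts)
    coords = pd.DataFrame({"axis1": xy[:, 0], "axis2": xy[:, 1],
                           "expression": expr, "label": labels}, index=genes)
    coords.index.name = "gene"
    return OrdinationResult(mode=mode, coords=coords, explained=explained)


def preferred_codons(gene_rscu: pd.DataFrame, expression: ExpressionTable,
                     hi_pct: float = 90.0, lo_pct: float = 10.0,
                     alpha: float = 0.05, method: str = "ranksum",
                     gene_counts: pd.DataFrame | None = None,
                     code: GeneticCode | None = None) -> pd.DataFrame:
    """Codons whose RSCU rises significantly in highly expressed genes.

    ``gene_rscu`` is a genes x codon frame of per-gene RSCU (columns may use
    the ``rscu_<codon>`` naming of ``composition.composition_table``). The
    default test is a two-sided Mann-Whitney rank-sum between the strata per
    codon, BH-adjusted across codons; ``method="chisq"`` instead pools codon
    counts per stratum (requires ``gene_counts``) and tests codon-vs-family
    usage in a 2x2 table. A codon is ``preferred`` iff its adjusted p is
    below ``alpha`` and the high-stratum mean exceeds the low-stratum mean.
    """
    code = code or GeneticCode.standard()
    if method not in ("ranksum", "chisq"):
        raise ValueError(f"unknown test method {method!r}")
    rscu = gene_rscu.rename(columns=lambda c: c.removeprefix("rscu_"))
    genes = [g for g in rscu.index if g in expression.values]
    expr = pd.Series({g: expression.values[g] for g in genes})
    labels = _stratify(expr, hi_pct, lo_pct)
    hi_genes = labels[labels == "high"].index
    lo_genes = labels[labels == "low"].index
    if len(hi_genes) == 0 or len(lo_genes) == 0:
        raise StratificationError("empty expression stratum")
    rows = []
    for codon in sorted(rscu.columns):
        hi_vals = rscu.loc[hi_genes, codon].dropna()
        lo_vals = rscu.loc[lo_genes, codon].dropna()
        record = {
            "codon": codon, "aa": code.translate(codon),
            "n_high": len(hi_vals), "n_low": len(lo_vals),
            "mean_high": float(hi_vals.mean()) if len(hi_vals) else math.nan,
            "mean_low": float(lo_vals.mean()) if len(lo_vals) else math.nan,
            "statistic": math.nan, "pvalue": math.nan,
        }
        if len(hi_vals) and len(lo_vals):
            if method == "ranksum":
                if np.ptp(np.concatenate([hi_vals, lo_vals])) == 0:
                    record["statistic"], record["pvalue"] = math.nan, 1.0
                else:
                    res = stats.mannwhitneyu(hi_vals, lo_vals,
                                             alternative="two-sided")
                    record["statistic"] = float(res.statistic)
                    record["pvalue"] = float(res.pvalue)
            else:
                family = code.families[code.translate(codon)]
                pooled = {}
                for name, idx in (("hi", hi_genes), ("lo", lo_genes)):
                    sub = gene_counts.loc[idx]
                    pooled[name] = (int(sub[codon].sum()),
                                    int(sub[list(family)].sum().sum()))
                table = np.array([
                    [pooled["hi"][0], pooled["hi"][1] - pooled["hi"][0]],
                    [pooled["lo"][0], pooled["lo"][1] - pooled["lo"][0]],
                ])
                if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
                    record["pvalue"] = 1.0
                else:
                    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
                    record["statistic"], record["pvalue"] = float(chi2), float(p)
        rows.append(record)
    frame = pd.DataFrame(rows).set_index("codon")
    tested = frame["pvalue"].notna()
    frame["p_adj"] = math.nan
    if tested.any():
        frame.loc[tested, "p_adj"] = multipletests(
            frame.loc[tested, "pvalue"], method="fdr_bh")[1]
    frame["preferred"] = (
        (frame["p_adj"] < alpha) & (frame["mean_high"] > frame["mean_low"])
    ).fillna(False)
    return frame
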