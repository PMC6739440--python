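"""Core orthologue groups from pairwise hit tables by best reciprocal hits.

A best reciprocal hit (RBH) pair is two genes, one per species, that are each
other's best hit after an e-value cutoff (default 1e-5; hits at exactly the
cutoff are kept). The core set keeps only groups with exactly one member in
every species, mirroring restrictive one-orthologue-per-species selection.

Two strategies build multi-species groups from pairwise RBH lists:

``anchor``
    Groups are seeded from the genes of one anchor species (default: first
    species alphabetically) and extended with that gene's RBH partner in
    every other species; a group survives only if every species has one.
    O(k) hit tables needed for k species.
``clique``
    As ``anchor``, plus every within-group pair must itself be an RBH pair
    in the corresponding species-pair table, i.e. the group is a full
    reciprocal clique. Requires all k(k-1)/2 unordered pair tables.

Neither strategy is asserted to be "the" published procedure; the strategy
used is recorded in the result and in the output table header.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

DEFAULT_EVALUE_CUTOFF = 1e-5


class OrthologyError(ValueError):
    pass


@dataclass(frozen=True)
class OrthologGroup:
    """One gene per species for one gene family."""

    cog_id: str
    members: Mapping[str, str]  # species -> gene id


@dataclass
class OrthologResult:
    groups: list[OrthologGroup]
    strategy: str
    anchor: str
    species: tuple[str, ...]


def best_hits(hits: pd.DataFrame, evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
              ) -> dict[str, str]:
    """Best subject per query for one directed species pair.

    Hits with e-value strictly above the cutoff are discarded. Per query the
    best hit is the lowest e-value; ties break by highest bitscore, then by
    lexicographically smallest subject id. Self hits (query == subject) are
    ignored. Empty input yields an empty map.
    """
    if hits.empty:
        return {}
    kept = hits[(hits["evalue"] <= evalue_cutoff) & (hits["qseqid"] != hits["sseqid"])]
    if kept.empty:
        return {}
    ordered = kept.sort_values(
        ["qseqid", "evalue", "bitscore", "sseqid"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    firsts = ordered.drop_duplicates("qseqid", keep="first")
    return dict(zip(firsts["qseqid"], firsts["sseqid"]))


def reciprocal_best_hits(hits_ab: pd.DataFrame, hits_ba: pd.DataFrame,
                         evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
                         ) -> list[tuple[str, str]]:
    """RBH pairs (gene_a, gene_b) for one species pair, sorted by gene_a."""
    fwd = best_hits(hits_ab, evalue_cutoff)
    rev = best_hits(hits_ba, evalue_cutoff)
    return sorted((a, b) for a, b in fwd.items() if rev.get(b) == a)


def _directed_maps(rbh_pairs: Mapping[tuple[str, str], Sequence[tuple[str, str]]]
                   ) -> dict[tuple[str, str], dict[str, str]]:
    maps: dict[tuple[str, str], dict[str, str]] = {}
    for (sp_a, sp_b), pairs in rbh_pairs.items():
        maps[(sp_a, sp_b)] = {a: b for a, b in pairs}
        maps[(sp_b, sp_a)] = {b: a for a, b in pairs}
    return maps


def core_ortholog_groups(
    rbh_pairs: Mapping[tuple[str, str], Sequence[tuple[str, str]]],
    species: Sequence[str],
    strategy: str = "anchor",
    anchor: str | None = None,
) -> OrthologResult:
    """One-per-species core groups from RBH lists.

    Parameters
    ----------
    rbh_pairs
        Map from a species pair (order as produced) to its RBH gene pairs.
    species
        All species that must be represented in every group.
    strategy
        ``"anchor"`` or ``"clique"`` (see module docstring).
    anchor
        Anchor species; defaults to the alphabetically first.

    Groups get deterministic ``cog#####`` identifiers assigned in sorted
    anchor-gene order.
    """
    if strategy not in ("anchor", "clique"):
        raise OrthologyError(f"unknown strategy {strategy!r}")
    species = tuple(sorted(species))
    anchor = anchor or species[0]
    if anchor not in species:
        raise OrthologyError(f"anchor species {anchor!r} not in species list")
    maps = _directed_maps(rbh_pairs)
    others = [s for s in species if s != anchor]

    for sp in others:
        if (anchor, sp) not in maps:
            raise OrthologyError(f"missing RBH table for pair ({anchor}, {sp})")
    if strategy == "clique":
        for i, sp_i in enumerate(species):
            for sp_j in species[i + 1 :]:
                if (sp_i, sp_j) not in maps:
                    raise OrthologyError(
                        f"clique strategy requires RBH table for pair "
                        f"({sp_i}, {sp_j})")

    groups: list[OrthologGroup] = []
    anchor_genes = sorted(maps[(anchor, others[0])]) if others else []
    if not others:
        anchor_genes = []
    n = 0
    for gene in anchor_genes:
        members = {anchor: gene}
        for sp in others:
            partner = maps[(anchor, sp)].get(gene)
            if partner is None:
                members = None
                break
            members[sp] = partner
        if members is None:
            continue
        if strategy == "clique":
            consistent = all(
                maps[(sp_i, sp_j)].get(members[sp_i]) == members[sp_j]
                for i, sp_i in enumerate(species)
                for sp_j in species[i + 1 :]
            )
            if not consistent:
                continue
        groups.append(OrthologGroup(cog_id=f"cog{n:05d}", members=members))
        n += 1
    return OrthologResult(groups=groups, strategy=strategy, anchor=anchor,
                          species=species)


def write_cog_table(result: OrthologResult, path: str | Path) -> None:
    """COG membership TSV: cog_id, species, gene_id; strategy in the header."""
    with open(path, "w") as out:
        out.write(f"# strategy={result.strategy} anchor={result.anchor}\n")
        out.write("cog_id\tspecies\tgene_id\n")
        for group in result.groups:
            for sp in sorted(group.members):
                out.write(f"{group.cog_id}\t{sp}\t{group.members[sp]}\n")


def read_cog_table(path: str | Path) -> list[OrthologGroup]:
    rows = pd.read_csv(path, sep="\t", comment="#")
    groups = []
    for cog_id, sub in rows.groupby("cog_id", sort=True):
        groups.append(OrthologGroup(
            cog_id=str(cog_id),
            members=dict(zip(sub["species"], sub["gene_id"]))))
    return groups
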