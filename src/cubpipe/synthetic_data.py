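"""Synthetic ortholog families with controllable codon-usage structure.

The generator emulates the data regime the analysis assumes: a set of
orthologue families shared by k species whose genomes differ in
third-position GC (the real phylum spans roughly 0.30-0.59 transcript GC,
with a wider GC3 spread), with conservative amino-acid substitutions, a
tunable two-hit coupling, gap columns, and expression-coupled codon
preference.

Mechanism, per family: an ancestral protein is drawn i.i.d. from a fixed
amino-acid frequency vector and assigned codons at an ancestral GC3 tilt.
Each species independently attempts an amino-acid substitution at each site
with probability ``aa_sub_rate``; a substitution replaces the ancestral
codon by one of its single-nucleotide neighbours that encodes a different
amino acid of the same conservative substitution class (sites whose codon
has no such neighbour stay put). The derived codon is either that neighbour
itself (single hit, probability ``1 - two_hit_theta``) or a fresh draw from
the species' GC3-tilted distribution over the new amino acid's family (two
hit). Synonymous variation is injected at fully conserved columns by
re-drawing codons from the tilted distribution; at columns where any species
substituted, conserved species keep the ancestral codon. Together these
choices make every theta = 0 non-synonymous codon pair sit exactly at the
minimal nucleotide distance in both viewing directions (verified
exhaustively over the code table in the test suite), so the theta = 0 null
of the two-hit excess is calibrated at zero by construction.

Species GC3 targets are honoured by calibration: the deterministic sites
(frozen + minimal-path) are counted first and the third-position G/C
probability of the re-drawn sites is solved so the expected overall GC3
equals the target; infeasible targets are rejected with the achievable
range. Substitution classes are restricted to amino-acid sets whose codon
families have symmetric minimal paths (see ``SIMILARITY_GROUPS``); Pro, Met,
Cys and Arg only ever vary synonymously here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genetic_code import GeneticCode, nucleotide_diff
from .seq_io import (CodingSequence, ExpressionTable, HIT_COLUMNS, write_fasta)

#: Conservative substitution classes used by the generator. Within each class
#: every ordered amino-acid pair has a symmetric minimal codon path (the
#: minimal nucleotide distance from any codon of one family to the other
#: family is the same in both directions), which keeps the single-hit null of
#: the two-hit analysis exactly calibrated. Amino acids absent from every
#: class (P, M, C, R) undergo only synonymous changes in simulation.
SIMILARITY_GROUPS: tuple[frozenset, ...] = (
    frozenset("GAVLI"),   # small aliphatic
    frozenset("ST"),      # hydroxyl
    frozenset("NQH"),     # amide / imidazole polar
    frozenset("DEK"),     # ionizable
    frozenset("FYW"),     # aromatic
)
_GROUP_OF: dict[str, frozenset] = {
    aa: group for group in SIMILARITY_GROUPS for aa in group
}

#: Ancestral amino-acid frequencies (typical eukaryotic proteome composition).
BASE_AA_FREQS: dict[str, float] = {
    "A": 0.074, "R": 0.042, "N": 0.044, "D": 0.059, "C": 0.033,
    "E": 0.058, "Q": 0.037, "G": 0.074, "H": 0.029, "I": 0.038,
    "L": 0.076, "K": 0.072, "M": 0.018, "F": 0.040, "P": 0.050,
    "S": 0.081, "T": 0.062, "W": 0.013, "Y": 0.033, "V": 0.067,
}


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """All knobs of the generator; identical configs give identical output."""

    seed: int = 0
    n_species: int = 6
    n_cogs: int = 100
    protein_length_mean: int = 300
    protein_length_min: int = 40
    gc3_targets: tuple[float, ...] | None = None  # default: linspace 0.30-0.70
    ancestral_gc3: float = 0.5
    aa_sub_rate: float = 0.05
    two_hit_theta: float = 0.7
    gap_rate: float = 0.03
    ragged_cog_rate: float = 0.05  # families with heavy gapping (70-95% columns)
    expression_log_mean: float = 2.0
    expression_log_sd: float = 1.5
    expression_coupling: float = 0.27
    preferred_set: tuple[str, ...] = ("GCC",)
    hi_pct: float = 90.0

    def __post_init__(self) -> None:
        for name in ("ancestral_gc3", "aa_sub_rate", "two_hit_theta", "gap_rate",
                     "ragged_cog_rate", "expression_coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        if self.n_species < 1 or self.n_cogs < 1:
            raise SimulationError("need at least one species and one family")
        if self.gc3_targets is not None:
            self.gc3_targets = tuple(float(t) for t in self.gc3_targets)
            if len(self.gc3_targets) != self.n_species:
                raise SimulationError("gc3_targets length must equal n_species")
            if any(not 0.0 <= t <= 1.0 for t in self.gc3_targets):
                raise SimulationError("gc3_targets must lie in [0, 1]")
        self.preferred_set = tuple(str(c).upper() for c in self.preferred_set)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(f"sp{i + 1:02d}" for i in range(self.n_species))

    @property
    def resolved_gc3_targets(self) -> dict[str, float]:
        if self.gc3_targets is not None:
            targets = self.gc3_targets
        elif self.n_species == 1:
            targets = (0.5,)
        else:
            targets = tuple(np.linspace(0.30, 0.70, self.n_species))
        return dict(zip(self.species, targets))


@dataclass
class ChangeEvent:
    """Provenance of one amino-acid substitution at one aligned position."""

    cog_id: str
    column: int  # 1-based alignment column
    species: str
    mechanism: str  # "single_hit" | "two_hit"
    ancestral_aa: str
    derived_aa: str
    ancestral_codon: str
    derived_codon: str
    nt_diff: int
    min_diff: int  # minimal possible distance from the ancestral codon


@dataclass
class TruthSet:
    orthology: dict[str, dict[str, str]]  # cog -> species -> gene id
    gene_gc3_target: dict[str, float]
    preferred_codons: dict[str, tuple[str, ...]] = field(default_factory=dict)
    provenance: list[ChangeEvent] = field(default_factory=list)
    realized_gc3: dict[str, float] = field(default_factory=dict)


@dataclass
class SimulatedData:
    config: SimulationConfig
    species: tuple[str, ...]
    cds: dict[str, dict[str, CodingSequence]]  # species -> gene -> CDS
    alignments: dict[str, list[tuple[str, str, str]]]  # cog -> (species, gene, row)
    truth: TruthSet
    expression: dict[str, ExpressionTable] = field(default_factory=dict)


def _family_gc_split(code: GeneticCode) -> dict[str, tuple[tuple[str, ...], tuple[str, ...]]]:
    split = {}
    for aa, family in code.families.items():
        gc = tuple(c for c in family if c[2] in "GC")
        at = tuple(c for c in family if c[2] not in "GC")
        split[aa] = (gc, at)
    return split


def _min_diff_targets(codon: str, family: Sequence[str]) -> tuple[int, tuple[str, ...]]:
    dists = [(nucleotide_diff(codon, t), t) for t in family]
    d = min(x for x, _ in dists)
    return d, tuple(sorted(t for x, t in dists if x == d))


def single_step_neighbors(codon: str, code: GeneticCode | None = None
                          ) -> tuple[tuple[str, str], ...]:
    """In-class amino-acid-changing single-nucleotide neighbours of a codon.

    Returns (neighbour codon, its amino acid) pairs, in deterministic
    (position, base) order. These are the substitutions the generator can
    realise as single hits; stops and out-of-class amino acids are excluded.
    """
    code = code or GeneticCode.standard()
    aa = code.translate(codon)
    group = _GROUP_OF.get(aa, frozenset())
    out = []
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            neighbour = codon[:pos] + base + codon[pos + 1 :]
            n_aa = code.translate(neighbour)
            if n_aa != aa and n_aa in group:
                out.append((neighbour, n_aa))
    return tuple(out)


def _sample_tilted(aa: str, g: float, split, rng) -> str:
    gc, at = split[aa]
    if not at:
        return gc[0] if len(gc) == 1 else gc[int(rng.integers(len(gc)))]
    if not gc:
        return at[int(rng.integers(len(at)))]
    if rng.random() < g:
        return gc[int(rng.integers(len(gc)))]
    return at[int(rng.integers(len(at)))]


def simulate_ortholog_set(config: SimulationConfig,
                          code: GeneticCode | None = None) -> SimulatedData:
    """Generate CDS, protein alignments and a truth set for every species.

    Deterministic in ``config`` (including the seed). No internal stop codon
    is ever emitted, and every aligned amino acid back-translates to its CDS
    codon exactly.
    """
    code = code or GeneticCode.standard()
    rng = np.random.default_rng(config.seed)
    species = config.species
    targets = config.resolved_gc3_targets
    split = _family_gc_split(code)
    aas = sorted(BASE_AA_FREQS)
    freqs = np.array([BASE_AA_FREQS[a] for a in aas])
    freqs = freqs / freqs.sum()

    # per-cog working state
    cogs: list[dict] = []
    # deferred tilt-sampled cells: per species, list of (cog_idx, site, aa, kind)
    deferred: dict[str, list[tuple[int, int, str, str | None]]] = {
        sp: [] for sp in species}
    pending_two_hit: dict[str, list[dict]] = {sp: [] for sp in species}

    for ci in range(config.n_cogs):
        cog_id = f"cog{ci:04d}"
        length = int(max(config.protein_length_min,
                         round(rng.normal(config.protein_length_mean,
                                          config.protein_length_mean / 4))))
        anc_aa = [aas[i] for i in rng.choice(len(aas), size=length, p=freqs)]
        anc_codon = [_sample_tilted(a, config.ancestral_gc3, split, rng)
                     for a in anc_aa]

        sp_aa = {sp: list(anc_aa) for sp in species}
        sp_codon: dict[str, list[str | None]] = {sp: [None] * length for sp in species}
        events: dict[str, list[ChangeEvent]] = {sp: [] for sp in species}
        mutated_col = np.zeros(length, dtype=bool)

        # amino-acid substitutions: single-nucleotide in-class neighbours
        targets_by_sp: dict[str, dict[int, tuple[str, str]]] = {}
        for sp in species:
            mask = rng.random(length) < config.aa_sub_rate
            chosen: dict[int, tuple[str, str]] = {}
            for site in np.flatnonzero(mask):
                neighbours = single_step_neighbors(anc_codon[site], code)
                if not neighbours:
                    continue
                pick = neighbours[int(rng.integers(len(neighbours)))]
                chosen[int(site)] = pick  # (single-hit codon, new aa)
                mutated_col[site] = True
            targets_by_sp[sp] = chosen

        # codon decisions
        for sp in species:
            chosen = targets_by_sp[sp]
            for site in range(length):
                if site in chosen:
                    hit_codon, new_aa = chosen[site]
                    sp_aa[sp][site] = new_aa
                    if rng.random() < config.two_hit_theta:
                        deferred[sp].append((ci, site, new_aa, "two_hit"))
                        pending_two_hit[sp].append({
                            "cog": ci, "site": site, "min_diff": 1,
                            "anc_aa": anc_aa[site], "new_aa": new_aa,
                            "anc_codon": anc_codon[site]})
                    else:
                        sp_codon[sp][site] = hit_codon
                        events[sp].append(ChangeEvent(
                            cog_id=cog_id, column=site + 1, species=sp,
                            mechanism="single_hit", ancestral_aa=anc_aa[site],
                            derived_aa=new_aa, ancestral_codon=anc_codon[site],
                            derived_codon=hit_codon, nt_diff=1, min_diff=1))
                elif mutated_col[site]:
                    sp_codon[sp][site] = anc_codon[site]  # frozen
                else:
                    deferred[sp].append((ci, site, anc_aa[site], None))

        # gap columns: per-family gap intensity, shared-or-private placement.
        # A small fraction of families is heavily gapped ("poorly aligned")
        # so the short-family filter downstream sees real work.
        if rng.random() < config.ragged_cog_rate:
            gap_q = float(rng.uniform(0.70, 0.95))
        else:
            gap_q = min(float(rng.exponential(config.gap_rate)), 0.5)
        gapped: dict[str, set[int]] = {sp: set() for sp in species}
        if gap_q > 0:
            for site in np.flatnonzero(rng.random(length) < gap_q):
                if rng.random() < 0.6 or config.n_species == 1:  # private gap
                    hit = [species[int(rng.integers(config.n_species))]]
                else:  # shared gap in a random subset
                    mask = rng.random(config.n_species) < 0.5
                    if not mask.any():
                        mask[int(rng.integers(config.n_species))] = True
                    hit = [sp for sp, m in zip(species, mask) if m]
                for sp in hit:
                    gapped[sp].add(int(site))
        for sp in species:  # a species never loses a family outright
            if len(gapped[sp]) == length:
                gapped[sp].discard(0)

        cogs.append({
            "cog_id": cog_id, "length": length, "anc_aa": anc_aa,
            "anc_codon": anc_codon, "sp_aa": sp_aa, "sp_codon": sp_codon,
            "events": events, "gapped": gapped})

    # --- GC3 calibration per species ------------------------------------
    tilt: dict[str, float] = {}
    for sp in species:
        det_gc = det_n = 0
        for cog in cogs:
            gapset = cog["gapped"][sp]
            for site, codon in enumerate(cog["sp_codon"][sp]):
                if codon is not None and site not in gapset:
                    det_n += 1
                    det_gc += codon[2] in "GC"
        n_def_forced = n_def_deg = 0
        for ci, site, aa, _kind in deferred[sp]:
            if site in cogs[ci]["gapped"][sp]:
                continue
            gc_set, at_set = split[aa]
            if not at_set:      # Met / Trp: always G-ended
                n_def_forced += 1
            elif not gc_set:    # no GC-ended synonym (impossible, standard code)
                pass
            else:
                n_def_deg += 1
        n_total = det_n + n_def_forced + n_def_deg
        lo = (det_gc + n_def_forced) / n_total
        hi = (det_gc + n_def_forced + n_def_deg) / n_total
        target = targets[sp]
        if n_def_deg == 0 or not lo <= target <= hi:
            raise SimulationError(
                f"species {sp}: gc3_target {target:.3f} infeasible; achievable "
                f"range is [{lo:.3f}, {hi:.3f}] under this configuration")
        tilt[sp] = (target * n_total - det_gc - n_def_forced) / n_def_deg

    # --- sample deferred codons -----------------------------------------
    for sp in species:
        g = tilt[sp]
        for ci, site, aa, _kind in deferred[sp]:
            cogs[ci]["sp_codon"][sp][site] = _sample_tilted(aa, g, split, rng)
        for item in pending_two_hit[sp]:
            cog = cogs[item["cog"]]
            derived = cog["sp_codon"][sp][item["site"]]
            if item["site"] in cog["gapped"][sp]:
                continue
            cog["events"][sp].append(ChangeEvent(
                cog_id=cog["cog_id"], column=item["site"] + 1, species=sp,
                mechanism="two_hit", ancestral_aa=item["anc_aa"],
                derived_aa=item["new_aa"], ancestral_codon=item["anc_codon"],
                derived_codon=derived,
                nt_diff=nucleotide_diff(item["anc_codon"], derived),
                min_diff=item["min_diff"]))

    # --- assemble outputs ------------------------------------------------
    orthology: dict[str, dict[str, str]] = {}
    gene_targets: dict[str, float] = {}
    cds: dict[str, dict[str, CodingSequence]] = {sp: {} for sp in species}
    alignments: dict[str, list[tuple[str, str, str]]] = {}
    provenance: list[ChangeEvent] = []
    gc3_num = {sp: 0 for sp in species}
    gc3_den = {sp: 0 for sp in species}
    for ci, cog in enumerate(cogs):
        cog_id = cog["cog_id"]
        orthology[cog_id] = {}
        rows = []
        for sp in species:
            gene = f"{sp}_g{ci:04d}"
            orthology[cog_id][sp] = gene
            gene_targets[gene] = targets[sp]
            gapset = cog["gapped"][sp]
            row = "".join("-" if s in gapset else cog["sp_aa"][sp][s]
                          for s in range(cog["length"]))
            codons = [cog["sp_codon"][sp][s] for s in range(cog["length"])
                      if s not in gapset]
            nt = "".join(codons)
            cds[sp][gene] = CodingSequence(id=gene, species=sp, nucleotides=nt)
            rows.append((sp, gene, row))
            gc3_num[sp] += sum(c[2] in "GC" for c in codons)
            gc3_den[sp] += len(codons)
            provenance.extend(e for e in cog["events"][sp]
                              if (e.column - 1) not in gapset)
        alignments[cog_id] = rows

    truth = TruthSet(
        orthology=orthology,
        gene_gc3_target=gene_targets,
        provenance=provenance,
        realized_gc3={sp: gc3_num[sp] / gc3_den[sp] for sp in species},
    )
    return SimulatedData(config=config, species=species, cds=cds,
                         alignments=alignments, truth=truth)


def simulate_hit_tables(truth: TruthSet, decoy_rate: float = 0.1,
                        seed: int = 0) -> dict[tuple[str, str], pd.DataFrame]:
    """Directed 12-column hit tables consistent with the true orthology.

    True orthologues receive mutual best hits with e-values drawn as
    10^-U(20, 80); decoy hits (non-orthologous subjects) appear at rate
    ``decoy_rate`` per query and are always at least 100-fold weaker than the
    true hit, so recall of reciprocal-best-hit screening is 100% whenever
    decoys exist at all.
    """
    rng = np.random.default_rng(seed)
    cog_ids = sorted(truth.orthology)
    if not cog_ids:
        return {}
    species = sorted(truth.orthology[cog_ids[0]])
    genes = {sp: [truth.orthology[c][sp] for c in cog_ids] for sp in species}
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    for sp_a in species:
        for sp_b in species:
            if sp_a == sp_b:
                continue
            rows = []
            for k, cog in enumerate(cog_ids):
                qseq, sseq = genes[sp_a][k], genes[sp_b][k]
                length = int(rng.integers(100, 500))
                pident = round(float(rng.uniform(60, 95)), 1)
                evalue = float(10.0 ** -rng.uniform(20, 80))
                bitscore = round(float(rng.uniform(150, 400)), 1)
                rows.append((qseq, sseq, pident, length,
                             int(length * (1 - pident / 100)), 0, 1, length,
                             1, length, evalue, bitscore))
                if rng.random() < decoy_rate and len(cog_ids) > 1:
                    other = int(rng.integers(len(cog_ids) - 1))
                    if other >= k:
                        other += 1
                    rows.append((qseq, genes[sp_b][other],
                                 round(pident * 0.8, 1), length,
                                 int(length * 0.4), 1, 1, length, 1, length,
                                 float(evalue * 10.0 ** rng.uniform(2, 10)),
                                 round(bitscore * 0.5, 1)))
            tables[(sp_a, sp_b)] = pd.DataFrame(rows, columns=list(HIT_COLUMNS))
    return tables


def simulate_expression(data: SimulatedData,
                        config: SimulationConfig | None = None,
                        seed: int | None = None) -> dict[str, ExpressionTable]:
    """Log-normal expression with codon preference coupled to the high stratum.

    Genes above the ``hi_pct`` percentile have their codons re-tilted toward
    ``preferred_set`` with probability ``expression_coupling`` per eligible
    site (synonymous swaps only, so alignments remain valid). The modified
    CDS replace the originals on ``data``; the planted preference is recorded
    in the truth set. Coupling 0 leaves every sequence untouched.
    """
    config = config or data.config
    code = GeneticCode.standard()
    rng = np.random.default_rng(config.seed + 20011 if seed is None else seed)
    pref_by_family: dict[str, str] = {}
    for codon in config.preferred_set:
        if codon not in code.sense_codons:
            raise SimulationError(f"preferred codon {codon!r} is not a sense codon")
        aa = code.translate(codon)
        pref_by_family.setdefault(aa, codon)
    out: dict[str, ExpressionTable] = {}
    for sp in data.species:
        gene_ids = sorted(data.cds[sp])
        values = rng.lognormal(config.expression_log_mean,
                               config.expression_log_sd, len(gene_ids))
        table = ExpressionTable(species=sp,
                                values=dict(zip(gene_ids, map(float, values))))
        out[sp] = table
        if config.expression_coupling > 0 and pref_by_family:
            thr = np.quantile(values, config.hi_pct / 100.0, method="higher")
            for gene, value in table.values.items():
                if value <= thr:
                    continue
                old = data.cds[sp][gene]
                codons = old.codons()
                for i, codon in enumerate(codons):
                    pref = pref_by_family.get(code.translate(codon))
                    if pref is not None and rng.random() < config.expression_coupling:
                        codons[i] = pref
                data.cds[sp][gene] = CodingSequence(
                    id=old.id, species=old.species, nucleotides="".join(codons))
        data.truth.preferred_codons[sp] = config.preferred_set
    data.expression = out
    return out


# --- file emission ------------------------------------------------------


def write_ortholog_set(data: SimulatedData, outdir: str | Path) -> None:
    """Emit the exact layout the pipeline consumes, plus a truth JSON."""
    outdir = Path(outdir)
    (outdir / "cds").mkdir(parents=True, exist_ok=True)
    (outdir / "alignments").mkdir(exist_ok=True)
    for sp in data.species:
        records = [(gene, cds.nucleotides + "TAA")
                   for gene, cds in sorted(data.cds[sp].items())]
        write_fasta(outdir / "cds" / f"{sp}.fasta", records)
    for cog_id, rows in sorted(data.alignments.items()):
        write_fasta(outdir / "alignments" / f"{cog_id}.faa",
                    [(gene, row) for _sp, gene, row in rows])
    truth = {
        "orthology": data.truth.orthology,
        "gene_gc3_target": data.truth.gene_gc3_target,
        "preferred_codons": {k: list(v)
                             for k, v in data.truth.preferred_codons.items()},
        "realized_gc3": data.truth.realized_gc3,
        "provenance": [vars(e) for e in data.truth.provenance],
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def write_hit_tables(tables: Mapping[tuple[str, str], pd.DataFrame],
                     outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (sp_a, sp_b), frame in sorted(tables.items()):
        frame.to_csv(outdir / f"{sp_a}__{sp_b}.tsv", sep="\t", header=False,
                     index=False, float_format="%.6g")


def write_expression_tables(tables: Mapping[str, ExpressionTable],
                            outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sp, table in sorted(tables.items()):
        with open(outdir / f"{sp}.tsv", "w") as fh:
            fh.write("gene\trpkm\n")
            for gene, value in sorted(table.values.items()):
                fh.write(f"{gene}\t{value:.6g}\n")
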