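"""End-to-end orchestration: stage graph, config, manifest and report.

Stages run in dependency order (simulate -> orthology -> align-prep ->
composition -> cluster / expression -> substitution -> report) and exchange
data only through declared files under the run directory:

```
<outdir>/
  inputs/            cds/, alignments/, hits/, expression/, truth.json
  orthology/         cogs.tsv
  align_prep/        codon_alignments/, superseqs.fasta, drop_log.tsv
  composition/       per_gene_composition.tsv, species_composition.tsv,
                     neutrality.tsv, gc3_correlations.tsv
  cluster/           setting_*.nwk, consensus.nwk, support.tsv
  expression/        preferred_codons_<sp>.tsv, ordination_<sp>.tsv
  substitution/      {aa,codon}_matrix_<A>__<B>.tsv, usage_tests_*.tsv,
                     reciprocal_tests_*.tsv, classification_*.tsv,
                     two_hit_*.tsv
  manifest.json, report.md
```

Re-running with an identical config reproduces identical outputs; the
manifest records the config hash, seed and per-stage record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import (clustering_expression as ce, codon_alignment as ca,
               composition as comp, orthology as orth,
               substitution_analysis as subs, synthetic_data as synth)
from .genetic_code import GeneticCode
from .seq_io import read_cds_fasta, read_expression_table, read_fasta, read_hit_table

STAGES = ("simulate", "orthology", "align_prep", "composition", "cluster",
          "expression", "substitution", "report")

logger = logging.getLogger("cubpipe")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException | str):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Run configuration; exactly one of ``simulate`` / ``input_dirs`` is set."""

    seed: int = 0
    outdir: str = "cubpipe_run"
    simulate: synth.SimulationConfig | None = None
    input_dirs: dict[str, str] | None = None
    evalue_cutoff: float = 1e-5
    min_len: int = 35
    hi_pct: float = 90.0
    lo_pct: float = 10.0
    alpha: float = 0.05
    decoy_rate: float = 0.1
    orthology_strategy: str = "anchor"
    ordination_mode: str = "pca"
    gc3_synonymous: bool = False
    clustering_grid: tuple[tuple[str, str], ...] = ce.DEFAULT_GRID
    substitution_pairs: tuple[tuple[str, str], ...] | None = None
    stages: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.input_dirs is None):
            raise ValueError("exactly one of 'simulate' / 'input_dirs' required")
        if isinstance(self.simulate, dict):
            self.simulate = synth.SimulationConfig(**self.simulate)
        if self.simulate is not None:
            self.simulate.seed = self.seed  # one top-level seed drives everything
        if not 0 < self.evalue_cutoff:
            raise ValueError("evalue_cutoff must be positive")
        if not (0 <= self.lo_pct < self.hi_pct <= 100):
            raise ValueError("need 0 <= lo_pct < hi_pct <= 100")
        self.clustering_grid = tuple((str(d), str(l)) for d, l in self.clustering_grid)
        if self.substitution_pairs is not None:
            self.substitution_pairs = tuple(
                (str(a), str(b)) for a, b in self.substitution_pairs)
        self.stages = {s: bool(self.stages.get(s, True)) for s in STAGES}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.simulate is not None:
            d["simulate"] = asdict(self.simulate)
        return d

    def config_hash(self) -> str:
        payload = self.to_dict()
        payload.pop("outdir", None)  # where a run lands is not what it computes
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _species_of_cogs(groups: list[orth.OrthologGroup]) -> list[str]:
    return sorted({sp for g in groups for sp in g.members})


def _input_dirs(config: PipelineConfig, outdir: Path) -> dict[str, Path]:
    if config.input_dirs is not None:
        return {k: Path(v) for k, v in config.input_dirs.items()}
    base = outdir / "inputs"
    dirs = {"cds": base / "cds", "alignments": base / "alignments",
            "hits": base / "hits"}
    if (base / "expression").exists():
        dirs["expression"] = base / "expression"
    return dirs


# --- stages -------------------------------------------------------------


def stage_simulate(config: PipelineConfig, outdir: Path) -> dict[str, int]:
    data = synth.simulate_ortholog_set(config.simulate)
    synth.simulate_expression(data, config.simulate)
    base = outdir / "inputs"
    synth.write_ortholog_set(data, base)
    synth.write_hit_tables(
        synth.simulate_hit_tables(data.truth, config.decoy_rate,
                                  seed=config.seed + 1),
        base / "hits")
    synth.write_expression_tables(data.expression, base / "expression")
    return {"species": len(data.species),
            "families": len(data.alignments),
            "provenance_events": len(data.truth.provenance)}


def stage_orthology(config: PipelineConfig, outdir: Path) -> dict[str, int]:
    hits_dir = _input_dirs(config, outdir)["hits"]
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    for path in sorted(hits_dir.glob("*.tsv")):
        sp_a, _, sp_b = path.stem.partition("__")
        tables[(sp_a, sp_b)] = read_hit_table(path)
    species = sorted({sp for pair in tables for sp in pair})
    rbh: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for i, sp_a in enumerate(species):
        for sp_b in species[i + 1 :]:
            if (sp_a, sp_b) in tables and (sp_b, sp_a) in tables:
                rbh[(sp_a, sp_b)] = orth.reciprocal_best_hits(
                    tables[(sp_a, sp_b)], tables[(sp_b, sp_a)],
                    config.evalue_cutoff)
    result = orth.core_ortholog_groups(rbh, species,
                                       strategy=config.orthology_strategy)
    stage_dir = outdir / "orthology"
    stage_dir.mkdir(parents=True, exist_ok=True)
    orth.write_cog_table(result, stage_dir / "cogs.tsv")
    return {"species": len(species), "groups": len(result.groups)}


def _load_cds(config: PipelineConfig, outdir: Path,
              code: GeneticCode) -> dict[str, dict[str, object]]:
    cds_dir = _input_dirs(config, outdir)["cds"]
    by_species: dict[str, dict[str, object]] = {}
    for path in sorted(cds_dir.glob("*.fasta")):
        sp = path.stem
        by_species[sp] = {c.id: c for c in read_cds_fasta(path, sp, code)}
    return by_species


def stage_align_prep(config: PipelineConfig, outdir: Path) -> dict[str, int]:
    code = GeneticCode.standard()
    groups = orth.read_cog_table(outdir / "orthology" / "cogs.tsv")
    cds = _load_cds(config, outdir, code)
    gene_species = {gid: sp for g in groups for sp, gid in g.members.items()}
    by_geneset = {frozenset(g.members.values()): g for g in groups}
    aln_dir = _input_dirs(config, outdir)["alignments"]
    degapped: list[ca.CodonAlignment] = []
    unmatched = 0
    for path in sorted(aln_dir.glob("*.faa")):
        records = read_fasta(path)
        group = by_geneset.get(frozenset(r[0] for r in records))
        if group is None:
            unmatched += 1
            continue
        rows = []
        cds_by_sp = {}
        for gene, row in records:
            sp = gene_species[gene]
            rows.append((sp, row))
            cds_by_sp[sp] = cds[sp][gene]
        rows.sort(key=lambda r: r[0])
        aln = ca.back_translate_alignment(group.cog_id, rows, cds_by_sp, code)
        degapped.append(ca.remove_gapped_columns(aln))
    retained, dropped = ca.filter_short_cogs(degapped, config.min_len)
    stage_dir = outdir / "align_prep"
    (stage_dir / "codon_alignments").mkdir(parents=True, exist_ok=True)
    for aln in retained:
        ca.write_codon_alignment(aln, stage_dir / "codon_alignments" /
                                 f"{aln.cog_id}.fasta")
    with open(stage_dir / "drop_log.tsv", "w") as fh:
        fh.write("cog_id\tdegapped_length\n")
        for cog_id, length in dropped:
            fh.write(f"{cog_id}\t{length}\n")
    superseqs = ca.concatenate_superseqs(retained, code)
    ca.write_superseqs(superseqs, stage_dir / "superseqs.fasta")
    return {"alignments": len(degapped), "retained": len(retained),
            "dropped": len(dropped), "unmatched_files": unmatched,
            "super_length_aa": next(iter(superseqs.values())).n_codons}


def _read_superseqs(outdir: Path, code: GeneticCode) -> dict[str, ca.SuperSequence]:
    from .genetic_code import translate_cds
    out = {}
    for sp, codons in read_fasta(outdir / "align_prep" / "superseqs.fasta"):
        out[sp] = ca.SuperSequence(species=sp, peptide=translate_cds(codons, code),
                                  codons=codons, cog_boundaries={})
    return out


def stage_composition(config: PipelineConfig, outdir: Path) -> dict[str, int]:
    code = GeneticCode.standard()
    groups = orth.read_cog_table(outdir / "orthology" / "cogs.tsv")
    cds = _load_cds(config, outdir, code)
    stage_dir = outdir / "composition"
    stage_dir.mkdir(parents=True, exist_ok=True)

    per_gene_frames = []
    neutrality_rows = []
    corr_cols = {}
    for sp in _species_of_cogs(groups):
        members = [cds[sp][g.members[sp]] for g in groups if sp in g.members]
        table = comp.composition_table(members, code,
                                       gc3_synonymous=config.gc3_synonymous)
        table.insert(0, "species", sp)
        per_gene_frames.append(table)
        fit = comp.neutrality_regression(table["gc3"], table["gc12"])
        neutrality_rows.append({"unit": sp, "level": "per_gene", **vars(fit)})
        corr_cols[sp] = comp.codon_gc3_correlations(table, code)
    per_gene = pd.concat(per_gene_frames)
    per_gene.to_csv(stage_dir / "per_gene_composition.tsv", sep="\t",
                    float_format="%.6g")

    superseqs = _read_superseqs(outdir, code)
    species_table = comp.composition_table(
        [(sp, ss.codons) for sp, ss in sorted(superseqs.items())], code,
        gc3_synonymous=config.gc3_synonymous)
    species_table.to_csv(stage_dir / "species_composition.tsv", sep="\t",
                         float_format="%.6g")
    pseudo = comp.neutrality_regression(species_table["gc3"],
                                        species_table["gc12"])
    neutrality_rows.append({"unit": "all_species", "level": "super_gene",
                            **vars(pseudo)})
    pd.DataFrame(neutrality_rows).to_csv(stage_dir / "neutrality.tsv",
                                         sep="\t", index=False,
                                         float_format="%.6g")
    pd.DataFrame(corr_cols).to_csv(stage_dir / "gc3_correlations.tsv",
                                   sep="\t", float_format="%.6g")
    return {"genes": len(per_gene), "species": len(species_table)}


def stage_cluster(config: PipelineConfig, outdir: Path) -> dict[str, int]:
    stage_dir = outdir / "cluster"
    stage_dir.mkdir(parents=True, exist_ok=True)
    species_table = pd.read_csv(outdir / "composition" / "species_composition.tsv",
                                sep="\t", index_col=0)
    rscu_cols = [c for c in species_table.columns if c.startswith("rscu_")]
    consensus = ce.rscu_cluster_consensus(species_table[rscu_cols],
                                          grid=config.clustering_grid)
    for (dist, link), newick in consensus.newicks.items():
        (stage_dir / f"setting_{dist}_{link}.nwk").write_text(newick + "\n")
    (stage_dir / "consensus.nwk").write_text(consensus.consensus_newick + "\n")
    with open(stage_dir / "support.tsv", "w") as fh:
        fh.write("clade\tsupport\n")
        for clade, freq in sorted(consensus.support.items(),
                                  key=lambda kv: (-len(kv[0]), sorted(kv[0]))):
            fh.write(",".join(sorted(clade)) + f"\t{freq:.3f}\n")
    return {"settings": len(consensus.newicks),
            "consensus_clades": len(consensus.support)}


def stage_expression(config: PipelineConfig, outdir: Path) -> dict[str, int]:
    code = GeneticCode.standard()
    dirs = _input_dirs(config, outdir)
    stage_dir = outdir / "expression"
    stage_dir.mkdir(parents=True, exist_ok=True)
    expr_dir = dirs.get("expression")
    if expr_dir is None or not Path(expr_dir).exists():
        (stage_dir / "UNAVAILABLE").write_text("no expression input\n")
        return {"species": 0}
    groups = orth.read_cog_table(outdir / "orthology" / "cogs.tsv")
    cds = _load_cds(config, outdir, code)
    n_done = 0
    for path in sorted(Path(expr_dir).glob("*.tsv")):
        sp = path.stem
        if sp not in cds:
            continue
        expression = read_expression_table(path, sp)
        members = [cds[sp][g.members[sp]] for g in groups if sp in g.members]
        counts = comp.counts_table(members, code)
        rscu = comp.composition_table(members, code)
        rscu = rscu[[c for c in rscu.columns if c.startswith("rscu_")]]
        calls = ce.preferred_codons(rscu, expression, config.hi_pct,
                                    config.lo_pct, config.alpha, code=code)
        calls.to_csv(stage_dir / f"preferred_codons_{sp}.tsv", sep="\t",
                     float_format="%.6g")
        ordination = ce.codon_usage_pca(counts, expression, config.hi_pct,
                                        config.lo_pct,
                                        mode=config.ordination_mode, code=code)
        ordination.coords.to_csv(stage_dir / f"ordination_{sp}.tsv", sep="\t",
                                 float_format="%.6g")
        n_done += 1
    return {"species": n_done}


def stage_substitution(config: PipelineConfig, outdir: Path) -> dict[str, object]:
    code = GeneticCode.standard()
    superseqs = _read_superseqs(outdir, code)
    stage_dir = outdir / "substitution"
    stage_dir.mkdir(parents=True, exist_ok=True)
    pairs = config.substitution_pairs
    if pairs is None:
        # default: the most GC3-divergent species pair
        species_table = pd.read_csv(
            outdir / "composition" / "species_composition.tsv", sep="\t",
            index_col=0)
        gc3 = species_table["gc3"].sort_values(kind="mergesort")
        pairs = ((gc3.index[0], gc3.index[-1]),)
    info: dict[str, object] = {"pairs": len(pairs)}
    for sp_a, sp_b in pairs:
        tag = f"{sp_a}__{sp_b}"
        tables = subs.build_substitution_tables(superseqs[sp_a],
                                                superseqs[sp_b], code)
        tables.aa_matrix.to_csv(stage_dir / f"aa_matrix_{tag}.tsv", sep="\t")
        tables.codon_matrix.to_csv(stage_dir / f"codon_matrix_{tag}.tsv",
                                   sep="\t")
        subs.usage_deviation_test(tables).to_csv(
            stage_dir / f"usage_tests_{tag}.tsv", sep="\t",
            float_format="%.6g")
        subs.reciprocal_asymmetry_test(tables).to_csv(
            stage_dir / f"reciprocal_tests_{tag}.tsv", sep="\t", index=False,
            float_format="%.6g")
        subs.classify_codon_pairs(superseqs[sp_a], superseqs[sp_b], code).to_csv(
            stage_dir / f"classification_{tag}.tsv", sep="\t")
        summary = subs.two_hit_summary(tables, code)
        summary.to_csv(stage_dir / f"two_hit_{tag}.tsv", sep="\t", index=False,
                       float_format="%.6g")
        info[f"two_hit_excess_{tag}"] = subs.two_hit_excess(summary)
    return info


def _report_section(title: str, path: Path, max_rows: int = 12) -> str:
    if not path.exists():
        return f"## {title}\n\n_unavailable_\n"
    frame = pd.read_csv(path, sep="\t")
    body = frame.head(max_rows).to_string(index=False)
    more = f"\n... ({len(frame)} rows total)" if len(frame) > max_rows else ""
    return f"## {title}\n\n```\n{body}{more}\n```\n"


def report(outdir: str | Path) -> str:
    """Assemble a deterministic markdown summary of a completed run."""
    outdir = Path(outdir)
    parts = ["# cubpipe run report\n"]
    parts.append(_report_section("Species composition (GC by position, ENC)",
                                 outdir / "composition" / "species_composition.tsv"))
    parts.append(_report_section("Neutrality regressions",
                                 outdir / "composition" / "neutrality.tsv"))
    consensus = outdir / "cluster" / "consensus.nwk"
    if consensus.exists():
        parts.append("## RSCU consensus clustering\n\n```\n"
                     + consensus.read_text().strip() + "\n```\n")
    else:
        parts.append("## RSCU consensus clustering\n\n_unavailable_\n")
    expr_dir = outdir / "expression"
    pref = sorted(expr_dir.glob("preferred_codons_*.tsv"))
    if pref:
        for path in pref:
            frame = pd.read_csv(path, sep="\t")
            called = frame[frame.get("preferred", False) == True]  # noqa: E712
            sp = path.stem.replace("preferred_codons_", "")
            parts.append(f"## Preferred codons ({sp})\n\n```\n"
                         + (called.to_string(index=False) if len(called)
                            else "none called") + "\n```\n")
    else:
        parts.append("## Preferred codons\n\n_unavailable_\n")
    for path in sorted((outdir / "substitution").glob("reciprocal_tests_*.tsv")) \
            if (outdir / "substitution").exists() else []:
        tag = path.stem.replace("reciprocal_tests_", "")
        frame = pd.read_csv(path, sep="\t")
        sig = frame[(frame["p_adj"] < 0.05) & (~frame["low_count"])]
        parts.append(f"## Significant asymmetric substitutions ({tag})\n\n```\n"
                     + (sig.to_string(index=False) if len(sig) else "none")
                     + "\n```\n")
    for path in sorted((outdir / "substitution").glob("two_hit_*.tsv")) \
            if (outdir / "substitution").exists() else []:
        tag = path.stem.replace("two_hit_", "")
        parts.append(_report_section(f"Two-hit summary ({tag})", path))
    text = "\n".join(parts)
    (outdir / "report.md").write_text(text)
    return text


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "orthology": stage_orthology,
    "align_prep": stage_align_prep,
    "composition": stage_composition,
    "cluster": stage_cluster,
    "expression": stage_expression,
    "substitution": stage_substitution,
}


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run every enabled stage and write a manifest; halts on first failure."""
    outdir = Path(outdir or config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    for stage in STAGES:
        if stage == "report":
            continue
        if stage == "simulate" and config.simulate is None:
            continue
        if not config.stages.get(stage, True):
            continue
        t0 = time.perf_counter()
        try:
            counts = _STAGE_FUNCS[stage](config, outdir)
        except Exception as exc:
            (outdir / "FAILED").write_text(f"{stage}: {exc}\n")
            logger.error("stage=%s status=FAILED error=%r", stage, str(exc))
            raise PipelineError(stage, exc) from exc
        # wall time goes to the log, not the manifest, so identical configs
        # produce byte-identical manifests
        logger.info("stage=%s wall_s=%.3f records=%s", stage,
                    time.perf_counter() - t0, counts)
        manifest["stages"][stage] = {"records": counts}
    if config.stages.get("report", True):
        report(outdir)
        manifest["stages"]["report"] = {"records": {"sections": 1}}
    (outdir / "FAILED").unlink(missing_ok=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
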