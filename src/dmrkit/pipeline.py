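"""End-to-end orchestration: simulate or load inputs, gate, call DmCs and
DMRs, annotate onto genes, run differential expression, integrate, and
write every stage's table plus a summary report and a run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, diffmeth, expression, integrate, methylome, simulate
from .annotate import GeneModel, read_genes_bed
from .genome import Genome
from .methylome import MethylomeSample, read_sample_tsv


@dataclass
class PipelineConfig:
    """Inputs, thresholds and the seed for one organ's analysis run."""

    outdir: str = "dmrkit_out"
    genome_fasta: str = ""
    chloroplast_name: str = simulate.CHLOROPLAST
    genes_bed: str = ""
    sample_sheet: str = ""  # TSV: sample, condition, organ, replicate, counts_path
    count_matrix: str = ""
    gene_lengths: str = ""
    gene_sets: dict = field(default_factory=dict)  # name -> path
    organ: str = "root"
    seed: int = 0
    min_cov: int = 10
    min_reps: int = 2
    dmc_fdr: float = 0.01
    dmr_window: int = 100
    dmr_min_dmcs: int = 4
    dmr_min_diff: float = 0.2
    dmr_alpha: float = 0.01
    flank: int = 2000
    track_window: int = 50_000
    deg_fdr: float = 0.05
    deg_min_fold: float = 2.0
    min_cpm: float = 5.0
    min_cpm_samples: int = 3

    def validate(self) -> None:
        for name in ("min_cov", "min_reps", "dmr_window", "dmr_min_dmcs", "flank",
                     "track_window", "min_cpm_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("dmc_fdr", "dmr_alpha", "deg_fdr"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if isinstance(v, dict):
                    v = ",".join(f"{k}:{x}" for k, x in v.items())
                fh.write(f"{f.name} = {v}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs: dict = {}
        defaults = cls()
        names = {f.name for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                key, val = (x.strip() for x in line.split("=", 1))
                if key not in names:
                    raise ValueError(f"unknown config key {key!r}")
                cur = getattr(defaults, key)
                if isinstance(cur, dict):
                    kwargs[key] = (
                        {k: x for k, x in (kv.split(":", 1) for kv in val.split(","))}
                        if val else {}
                    )
                elif isinstance(cur, int):
                    kwargs[key] = int(val)
                elif isinstance(cur, float):
                    kwargs[key] = float(val)
                else:
                    kwargs[key] = val
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _log(msg: str) -> None:
    print(f"[dmrkit] {msg}", file=sys.stderr)


def load_inputs(config: PipelineConfig):
    """Read and cross-validate all pipeline inputs."""
    genome = Genome.from_fasta(config.genome_fasta, config.chloroplast_name)
    genes = read_genes_bed(config.genes_bed)
    chroms = set(genome.chrom_names)
    for g in genes:
        if g.chrom not in chroms:
            raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom!r}")
    sheet = pd.read_csv(config.sample_sheet, sep="\t")
    required = {"sample", "condition", "organ", "replicate", "counts_path"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing fields: {sorted(missing)}")
    sheet = sheet[sheet["organ"] == config.organ]
    base = Path(config.sample_sheet).parent
    samples = []
    for _, row in sheet.iterrows():
        path = Path(row["counts_path"])
        if not path.is_absolute():
            path = base / path
        s = read_sample_tsv(
            path, row["sample"], row["condition"], row["organ"], int(row["replicate"])
        )
        bad = set(s.counts["chrom"].unique()) - chroms
        if bad:
            raise ValueError(f"sample {row['sample']}: unknown chromosomes {sorted(bad)}")
        samples.append(s)
    matrix = expression.read_count_matrix(
        config.count_matrix, config.sample_sheet, config.gene_lengths
    )
    gene_ids = {g.gene_id for g in genes}
    unknown = set(matrix.counts.index) - gene_ids
    if unknown:
        raise ValueError(f"count matrix contains unknown gene ids, e.g. {sorted(unknown)[:3]}")
    gene_sets = {name: integrate.read_gene_set(path) for name, path in config.gene_sets.items()}
    return genome, genes, samples, matrix, gene_sets


def run_pipeline(
    config: PipelineConfig,
    genome: Genome | None = None,
    genes: list[GeneModel] | None = None,
    samples: list[MethylomeSample] | None = None,
    matrix: expression.ExpressionMatrix | None = None,
    gene_sets: dict | None = None,
) -> dict:
    """Run every stage for one organ and write the report bundle.

    Inputs may be passed in-memory (as the demo does) or read from the
    paths in ``config``.
    """
    config.validate()
    if genome is None:
        genome, genes, samples, matrix, gene_sets = load_inputs(config)
    gene_sets = gene_sets or {}
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _log(f"run {config.digest()} seed={config.seed} organ={config.organ}")

    flight = [s for s in samples if s.condition == "flight"]
    ground = [s for s in samples if s.condition == "ground"]

    # conversion efficiency from the chloroplast control
    conv = methylome.conversion_report(samples, genome)
    conv.to_csv(outdir / "conversion_efficiency.tsv", sep="\t", index=False)

    # coverage gate + condition-pooled levels
    gate = methylome.coverage_gate(flight, ground, config.min_cov, config.min_reps)
    levels_f = methylome.condition_levels(flight, gate)
    levels_g = methylome.condition_levels(ground, gate)
    glob = {
        "flight": methylome.global_levels(levels_f),
        "ground": methylome.global_levels(levels_g),
    }
    for cond, lv in (("flight", levels_f), ("ground", levels_g)):
        methylome.level_distribution(lv).to_csv(
            outdir / f"level_distribution_{cond}.tsv", sep="\t", index=False
        )
        track = methylome.genome_tracks(lv, config.track_window)
        for ctx, sub in track.groupby("context", observed=True):
            methylome.write_bedgraph(sub, outdir / f"track_{cond}_{ctx}.bedGraph")

    # DmCs and DMRs
    tested = diffmeth.test_sites(flight, ground, gate)
    dmcs = diffmeth.call_dmcs(tested, fdr=config.dmc_fdr)
    dmrs = diffmeth.call_dmrs(
        dmcs,
        window=config.dmr_window,
        min_dmcs=config.dmr_min_dmcs,
        min_diff=config.dmr_min_diff,
        alpha=config.dmr_alpha,
    )
    diffmeth.write_dmc_tsv(dmcs, outdir / "dmcs.tsv")
    diffmeth.write_dmr_bed(dmrs, outdir / "dmrs.bed")
    summary = diffmeth.summarize_differential(dmcs, dmrs)

    # gene annotation of DmCs; metagene profiles per condition
    called = dmcs[dmcs["is_dmc"]]
    assignments = annotate.assign_regions(called, genes, flank=config.flank)
    if not assignments.empty:
        out_asn = assignments.copy()
        out_asn["pos"] = out_asn["pos"] + 1
        out_asn[
            ["chrom", "pos", "strand", "context", "direction", "diff", "gene_id", "region"]
        ].to_csv(outdir / "dmc_gene_assignments.tsv", sep="\t", index=False)
    affected = annotate.genes_affected(assignments)
    affected.to_csv(outdir / "genes_affected.tsv", sep="\t", index=False)
    for cond, lv in (("flight", levels_f), ("ground", levels_g)):
        prof = annotate.metagene_profile(lv, genes, flank=config.flank)
        prof.insert(0, "condition", cond)
        prof.to_csv(outdir / f"metagene_{cond}.tsv", sep="\t", index=False)

    # differential expression
    degs = expression.call_degs(
        matrix,
        organ=config.organ,
        fdr=config.deg_fdr,
        min_fold=config.deg_min_fold,
        min_cpm=config.min_cpm,
        min_cpm_samples=config.min_cpm_samples,
    )
    degs.to_csv(outdir / "degs.tsv", sep="\t")

    # integration
    records = integrate.join_dmc_deg(degs, assignments)
    records.to_csv(outdir / "integration.tsv", sep="\t")
    trends = integrate.trend_counts(records)
    corr = integrate.expression_methylation_correlation(records)
    corr.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
    deg_ids = set(degs.index[degs["is_deg"]])
    dmc_deg_ids = set(records.index)
    overlaps = []
    for name, ref in gene_sets.items():
        overlaps.append(integrate.gene_set_overlap(deg_ids, dmc_deg_ids, ref, name))
    if overlaps:
        pd.DataFrame(overlaps).to_csv(outdir / "gene_set_overlaps.tsv", sep="\t", index=False)

    report = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "organ": config.organ,
        "n_sites_gated": int(gate.sum()),
        "conversion_efficiency": {
            s: float(conv.loc[(conv["sample"] == s) & (conv["context"] == "overall"),
                              "converted_ratio"].iloc[0])
            for s in conv["sample"].unique()
        },
        "global_levels": glob,
        "n_dmcs": summary["n_dmcs"],
        "n_dmrs": summary["n_dmrs"],
        "n_dmcs_in_dmrs": summary["n_dmcs_in_dmrs"],
        "dmc_counts": summary["dmc_counts"].to_dict(orient="records"),
        "dmr_counts": summary["dmr_counts"].to_dict(orient="records"),
        "n_degs": int(degs["is_deg"].sum()),
        "n_dmc_degs": int(len(records)),
        "trend_counts": trends,
        "gene_set_overlaps": overlaps,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    with open(outdir / "run_manifest.txt", "w") as fh:
        fh.write(f"config_digest = {config.digest()}\nseed = {config.seed}\n")
        config.to_file(outdir / "config_used.txt")
    _log(
        f"done: {summary['n_dmcs']} DmCs, {summary['n_dmrs']} DMRs, "
        f"{report['n_degs']} DEGs, {report['n_dmc_degs']} DmC-DEGs"
    )
    report["_tables"] = {
        "dmcs": dmcs, "dmrs": dmrs, "degs": degs, "records": records,
        "assignments": assignments, "correlations": corr,
    }
    return report


def write_simulated_inputs(config: simulate.SimulationConfig, outdir: str | Path,
                           organ: str = "root") -> PipelineConfig:
    """Simulate a dataset, write it in the pipeline's input formats, and
    return a PipelineConfig pointing at the files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, samples, matrix, truth = simulate.simulate_dataset(config, organ=organ)
    genome.to_fasta(outdir / "genome.fa")
    annotate.write_genes_bed(genes, outdir / "genes.bed")
    rows = []
    for sid, s in samples.items():
        path = outdir / f"{sid}.meth.tsv"
        methylome.write_sample_tsv(s, path)
        rows.append(
            {"sample": sid, "condition": s.condition, "organ": s.organ,
             "replicate": s.replicate, "counts_path": path.name}
        )
    pd.DataFrame(rows).to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
    expression.write_count_matrix(
        matrix, outdir / "counts.tsv", outdir / "expr_samples.tsv", outdir / "gene_lengths.tsv"
    )
    # expression sample sheet must match the shared sheet; merge counts_path in
    simulate.write_truth_tables(truth, outdir)
    config.to_file(outdir / "sim_config.txt")
    return PipelineConfig(
        outdir=str(outdir / "results"),
        genome_fasta=str(outdir / "genome.fa"),
        chloroplast_name=genome.chloroplast_name,
        genes_bed=str(outdir / "genes.bed"),
        sample_sheet=str(outdir / "sample_sheet.tsv"),
        count_matrix=str(outdir / "counts.tsv"),
        gene_lengths=str(outdir / "gene_lengths.tsv"),
        organ=organ,
        seed=config.seed,
    )


def demo(outdir: str | Path, seed: int = 0) -> dict:
    """One-command synthetic end-to-end run with planted-truth recovery."""
    sim = simulate.SimulationConfig(
        seed=seed,
        n_chroms=2,
        chrom_length=100_000,
        n_genes=60,
        depth_mean=50.0,
        n_true_dmcs=150,
        dmc_effect=0.4,
        n_true_dmrs=8,
        n_true_degs=40,
    )
    pcfg = write_simulated_inputs(sim, outdir)
    report = run_pipeline(pcfg)
    return report
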