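"""Synthetic WGBS + RNA-seq data with planted ground truth.

Emulates the study design the pipeline targets: two conditions (flight vs
ground) x 3 biological replicates per organ, context-dependent baseline
methylation (bimodal CG around a 0.24 mean, unimodal low CHG ~0.10 and
CHH ~0.05 — conventional Arabidopsis values), a fully unmethylated
chloroplast whose apparent methylation is purely bisulfite-conversion
failure, planted DmCs and DMRs that shift the flight-condition level, and
NB-distributed expression counts with planted DEGs, a fraction of which
carry a coupled (opposite-sign) gene-body methylation change.

All randomness flows from the single config seed through named
``numpy.random.Generator`` streams; identical config -> identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import GeneModel
from .expression import ExpressionMatrix
from .genome import Genome, enumerate_sites
from .methylome import MethylomeSample

CHLOROPLAST = "ChrC"


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 100_000
    chloroplast_length: int = 10_000
    n_genes: int = 100
    gene_length_mean: int = 2_000
    n_replicates: int = 3
    depth_mean: float = 30.0
    conversion_efficiency: float = 0.99
    baseline_levels: dict = field(
        default_factory=lambda: {"CG": 0.24, "CHG": 0.10, "CHH": 0.05}
    )
    cg_bimodal_high_frac: float = 0.25  # fraction of CG sites in the ~0.85 mode
    n_true_dmcs: int = 300
    dmc_effect: float = 0.3
    n_true_dmrs: int = 10
    dmr_width: int = 300
    n_true_degs: int = 100
    deg_log2fc: float = 2.0
    expr_mean: float = 200.0
    nb_dispersion: float = 0.1
    coupling_fraction: float = 0.3
    gc_content: float = 0.36

    def validate(self) -> None:
        for name in (
            "n_chroms", "chrom_length", "chloroplast_length", "n_genes",
            "gene_length_mean", "n_replicates", "n_true_dmcs", "n_true_dmrs",
            "dmr_width", "n_true_degs",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.conversion_efficiency <= 1.0:
            raise ValueError("conversion_efficiency must be in [0, 1]")
        if not -1.0 <= self.dmc_effect <= 1.0:
            raise ValueError("dmc_effect must be in [-1, 1]")
        for ctx, lvl in self.baseline_levels.items():
            if not 0.0 <= lvl <= 1.0:
                raise ValueError(f"baseline level for {ctx} outside [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if isinstance(v, dict):
                    v = ",".join(f"{k}:{x}" for k, x in v.items())
                fh.write(f"{f.name} = {v}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        kwargs: dict = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                key, val = (x.strip() for x in line.split("=", 1))
                if key not in types:
                    raise ValueError(f"unknown config key {key!r}")
                cur = getattr(defaults, key)
                if isinstance(cur, dict):
                    kwargs[key] = {
                        k: float(x) for k, x in (kv.split(":") for kv in val.split(","))
                    }
                elif isinstance(cur, bool):
                    kwargs[key] = val.lower() in ("1", "true", "yes")
                elif isinstance(cur, int):
                    kwargs[key] = int(val)
                elif isinstance(cur, float):
                    kwargs[key] = float(val)
                else:
                    kwargs[key] = val
        if "seed" not in kwargs:
            raise ValueError("config file must set a seed")
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


@dataclass
class GroundTruth:
    """Planted signal: what a perfect analysis should recover."""

    true_dmc_sites: set = field(default_factory=set)  # (chrom, pos, strand)
    true_dmr_intervals: list = field(default_factory=list)  # (chrom, start, end, direction)
    true_deg_log2fc: dict = field(default_factory=dict)  # gene_id -> planted log2fc
    coupled_gene_ids: set = field(default_factory=set)


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_genome(config: SimulationConfig) -> tuple[Genome, list[GeneModel]]:
    """Random nuclear chromosomes with non-overlapping genes, plus a
    chloroplast chromosome carrying no genes."""
    config.validate()
    rng = _rng_streams(config.seed, 8)[0]
    bases = np.array(list("ACGT"))
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    sequences: dict[str, str] = {}
    for i in range(config.n_chroms):
        seq = rng.choice(bases, size=config.chrom_length, p=probs)
        sequences[f"Chr{i + 1}"] = "".join(seq)
    sequences[CHLOROPLAST] = "".join(
        rng.choice(bases, size=config.chloroplast_length, p=probs)
    )
    genome = Genome(sequences=sequences, chloroplast_name=CHLOROPLAST)

    genes: list[GeneModel] = []
    if config.n_genes:
        nuclear = genome.nuclear_names
        occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in nuclear}
        placed = 0
        attempts = 0
        max_attempts = config.n_genes * 200
        while placed < config.n_genes:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    f"could not place {config.n_genes} non-overlapping genes "
                    f"on {config.n_chroms} x {config.chrom_length} bp"
                )
            chrom = nuclear[int(rng.integers(len(nuclear)))]
            length = max(
                300, int(rng.normal(config.gene_length_mean, 0.25 * config.gene_length_mean))
            )
            if length >= config.chrom_length:
                continue
            start = int(rng.integers(0, config.chrom_length - length))
            end = start + length
            if any(start < e and s < end for s, e in occupied[chrom]):
                continue
            occupied[chrom].append((start, end))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"gene{placed + 1:05d}",
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                )
            )
            placed += 1
        genes.sort(key=lambda g: (g.chrom, g.start))
    return genome, genes


def _baseline_levels(contexts: np.ndarray, config: SimulationConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Per-site true methylation level drawn from context-typical
    distributions: CG a low/high bimodal mixture, CHG/CHH unimodal low."""
    n = contexts.size
    levels = np.empty(n)
    cg = contexts == "CG"
    high = rng.random(n) < config.cg_bimodal_high_frac
    levels[cg & high] = rng.beta(8.5, 1.5, size=int((cg & high).sum()))
    levels[cg & ~high] = rng.beta(0.5, 15.0, size=int((cg & ~high).sum()))
    chg = contexts == "CHG"
    levels[chg] = rng.beta(2.0, 18.0, size=int(chg.sum()))
    rest = ~cg & ~chg
    levels[rest] = rng.beta(1.5, 28.5, size=int(rest.sum()))
    return levels


def simulate_methylomes(
    genome: Genome,
    config: SimulationConfig,
    organ: str = "root",
    genes: list[GeneModel] | None = None,
    coupled: dict[str, int] | None = None,
    sites: pd.DataFrame | None = None,
) -> tuple[dict[str, MethylomeSample], GroundTruth]:
    """Per-sample cytosine count tables with planted differential signal.

    Per site and sample: total ~ Poisson(depth_mean); methylated ~
    Binomial(total, effective level) where the effective level is the true
    level for nuclear sites and (1 - conversion_efficiency) for every
    chloroplast cytosine.  Planted DmCs and DMR intervals shift the
    flight-condition true level by +-dmc_effect.  ``coupled`` optionally
    maps gene_id -> direction (+1/-1) to plant a gene-body methylation
    interval for coupled DEGs (direction is the methylation sign).
    """
    config.validate()
    rngs = _rng_streams(config.seed, 8)
    rng_level, rng_plant = rngs[1], rngs[2]
    if sites is None:
        sites = enumerate_sites(genome)
    n = len(sites)
    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    ctx = sites["context"].to_numpy()
    is_chl = chrom == genome.chloroplast_name
    base = _baseline_levels(ctx, config, rng_level)

    truth = GroundTruth()
    flight_level = base.copy()
    effect = abs(config.dmc_effect)
    plantable = ~is_chl & (ctx != "UNKNOWN")

    # planted single-site DmCs
    if config.n_true_dmcs and effect > 0:
        cand = np.flatnonzero(plantable)
        chosen = rng_plant.choice(cand, size=min(config.n_true_dmcs, cand.size), replace=False)
        dirs = rng_plant.choice([1, -1], size=chosen.size)
        # re-draw the baseline inside the feasible band so the shifted level
        # stays in [0, 1]
        margin = 0.02
        for idx, d in zip(chosen, dirs):
            if d > 0:
                base[idx] = rng_plant.uniform(margin, 1.0 - effect - margin)
                flight_level[idx] = base[idx] + effect
            else:
                base[idx] = rng_plant.uniform(effect + margin, 1.0 - margin)
                flight_level[idx] = base[idx] - effect
            truth.true_dmc_sites.add((chrom[idx], int(pos[idx]), sites["strand"].iloc[idx]))

    # planted DMR intervals (plus coupled gene-body intervals)
    intervals: list[tuple[str, int, int, int]] = []
    if config.n_true_dmrs and effect > 0:
        nuclear = genome.nuclear_names
        sizes = genome.chrom_sizes()
        taken: dict[str, list[tuple[int, int]]] = {c: [] for c in nuclear}
        tries = 0
        while len(intervals) < config.n_true_dmrs and tries < config.n_true_dmrs * 100:
            tries += 1
            c = nuclear[int(rng_plant.integers(len(nuclear)))]
            start = int(rng_plant.integers(0, max(1, sizes[c] - config.dmr_width)))
            end = start + config.dmr_width
            if any(start < e and s < end for s, e in taken[c]):
                continue
            taken[c].append((start, end))
            d = int(rng_plant.choice([1, -1]))
            intervals.append((c, start, end, d))
    if coupled and effect > 0:
        by_id = {g.gene_id: g for g in (genes or [])}
        for gid, d in coupled.items():
            g = by_id.get(gid)
            if g is None:
                raise KeyError(f"coupled gene {gid!r} not among gene models")
            width = min(config.dmr_width, g.length)
            mid = (g.start + g.end) // 2
            start = max(g.start, mid - width // 2)
            intervals.append((g.chrom, start, start + width, int(np.sign(d))))

    for c, start, end, d in intervals:
        in_iv = (chrom == c) & (pos >= start) & (pos < end) & plantable
        idxs = np.flatnonzero(in_iv)
        margin = 0.02
        for idx in idxs:
            if d > 0:
                base[idx] = min(base[idx], 1.0 - effect - margin)
                base[idx] = max(base[idx], margin)
                flight_level[idx] = base[idx] + effect
            else:
                base[idx] = max(base[idx], effect + margin)
                base[idx] = min(base[idx], 1.0 - margin)
                flight_level[idx] = base[idx] - effect
            truth.true_dmc_sites.add((c, int(pos[idx]), sites["strand"].iloc[idx]))
        truth.true_dmr_intervals.append((c, start, end, "hyper" if d > 0 else "hypo"))

    fail = 1.0 - config.conversion_efficiency
    eff_ground = np.where(is_chl, fail, base)
    eff_flight = np.where(is_chl, fail, flight_level)

    samples: dict[str, MethylomeSample] = {}
    sample_streams = np.random.SeedSequence(config.seed).spawn(8)[3].spawn(
        2 * config.n_replicates
    )
    k = 0
    for condition, eff in (("flight", eff_flight), ("ground", eff_ground)):
        for rep in range(1, config.n_replicates + 1):
            srng = np.random.default_rng(sample_streams[k]); k += 1
            total = srng.poisson(config.depth_mean, size=n)
            meth = srng.binomial(total, eff)
            counts = sites.copy()
            counts["methylated"] = meth
            counts["total"] = total
            sid = f"{organ}_{condition}_{rep}"
            samples[sid] = MethylomeSample(
                sample_id=sid, condition=condition, organ=organ,
                replicate=rep, counts=counts,
            )
    return samples, truth


def simulate_expression(
    genes: list[GeneModel],
    config: SimulationConfig,
    organ: str = "root",
    planted: dict[str, float] | None = None,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """NB-distributed gene counts with planted log2 fold changes.

    ``planted`` maps gene_id -> log2fc in the flight condition; if omitted,
    ``n_true_degs`` genes get +-``deg_log2fc`` at random.  Per-sample
    library factors are drawn uniformly in [0.75, 1.25].
    """
    config.validate()
    rngs = _rng_streams(config.seed, 8)
    rng = rngs[4]
    gene_ids = [g.gene_id for g in genes]
    n_genes = len(gene_ids)
    base_mean = np.exp(rng.normal(np.log(config.expr_mean), 1.0, size=n_genes))
    base_mean = np.maximum(base_mean, 1.0)

    truth = GroundTruth()
    if planted is None:
        n_deg = min(config.n_true_degs, n_genes)
        chosen = rng.choice(n_genes, size=n_deg, replace=False)
        signs = rng.choice([1.0, -1.0], size=n_deg)
        planted = {
            gene_ids[i]: float(s * config.deg_log2fc) for i, s in zip(chosen, signs)
        }
    truth.true_deg_log2fc = dict(planted)
    lfc = np.array([planted.get(g, 0.0) for g in gene_ids])

    n_rep = config.n_replicates
    cols, data = [], []
    cond_rows = []
    sample_streams = np.random.SeedSequence(config.seed).spawn(8)[5].spawn(2 * n_rep)
    k = 0
    for condition in ("flight", "ground"):
        for rep in range(1, n_rep + 1):
            srng = np.random.default_rng(sample_streams[k]); k += 1
            factor = srng.uniform(0.75, 1.25)
            mu = base_mean * factor * (2.0 ** lfc if condition == "flight" else 1.0)
            alpha = config.nb_dispersion
            if alpha < 1e-12:
                y = srng.poisson(mu)
            else:
                r = 1.0 / alpha
                y = srng.negative_binomial(r, r / (r + mu))
            sid = f"{organ}_{condition}_{rep}"
            cols.append(sid)
            data.append(y)
            cond_rows.append(
                {"sample": sid, "condition": condition, "organ": organ, "replicate": rep}
            )
    counts = pd.DataFrame(np.column_stack(data), index=gene_ids, columns=cols)
    sheet = pd.DataFrame(cond_rows).set_index("sample")
    lengths = pd.Series([g.length for g in genes], index=gene_ids, name="length")
    matrix = ExpressionMatrix(counts=counts, samples=sheet, gene_lengths=lengths)
    return matrix, truth


def simulate_dataset(config: SimulationConfig, organ: str = "root"):
    """Full coupled dataset: genome, genes, methylomes, expression, truth.

    A ``coupling_fraction`` of the planted DEGs also receive a planted
    gene-body methylation interval whose sign opposes their expression
    change (negative methylation-expression coupling).
    """
    config.validate()
    genome, genes = simulate_genome(config)
    rng = _rng_streams(config.seed, 8)[6]
    gene_ids = [g.gene_id for g in genes]
    n_deg = min(config.n_true_degs, len(gene_ids))
    chosen = list(rng.choice(len(gene_ids), size=n_deg, replace=False))
    signs = rng.choice([1.0, -1.0], size=n_deg)
    planted = {gene_ids[i]: float(s * config.deg_log2fc) for i, s in zip(chosen, signs)}
    n_coupled = int(round(config.coupling_fraction * n_deg))
    coupled_ids = [gene_ids[i] for i in chosen[:n_coupled]]
    coupled = {gid: -int(np.sign(planted[gid])) for gid in coupled_ids}

    samples, meth_truth = simulate_methylomes(
        genome, config, organ=organ, genes=genes, coupled=coupled
    )
    matrix, expr_truth = simulate_expression(genes, config, organ=organ, planted=planted)
    truth = GroundTruth(
        true_dmc_sites=meth_truth.true_dmc_sites,
        true_dmr_intervals=meth_truth.true_dmr_intervals,
        true_deg_log2fc=expr_truth.true_deg_log2fc,
        coupled_gene_ids=set(coupled_ids),
    )
    return genome, genes, samples, matrix, truth


def simulate_dmc_benchmark(
    n_sites: int,
    frac_planted: float,
    effect: float,
    depth: float,
    n_reps: int,
    rng: np.random.Generator,
) -> tuple[list[tuple[np.ndarray, np.ndarray]], list[tuple[np.ndarray, np.ndarray]], np.ndarray]:
    """Site-level benchmark: per-replicate (meth, total) for flight and
    ground over ``n_sites`` coverage-ready sites, the first
    ``frac_planted`` fraction carrying a planted level shift of ``effect``
    in flight.  Returns (flight_reps, ground_reps, is_null mask)."""
    n_planted = int(round(frac_planted * n_sites))
    base = rng.uniform(0.05, 0.95 - effect, size=n_sites)
    flight_level = base.copy()
    flight_level[:n_planted] += effect
    is_null = np.ones(n_sites, dtype=bool)
    is_null[:n_planted] = False
    flight, ground = [], []
    for _ in range(n_reps):
        t = rng.poisson(depth, size=n_sites)
        flight.append((rng.binomial(t, flight_level), t))
        t = rng.poisson(depth, size=n_sites)
        ground.append((rng.binomial(t, base), t))
    return flight, ground, is_null


def write_truth_tables(truth: GroundTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    pd.DataFrame(
        sorted(truth.true_dmc_sites), columns=["chrom", "pos", "strand"]
    ).assign(pos=lambda d: d["pos"] + 1).to_csv(
        outdir / "truth_dmcs.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        truth.true_dmr_intervals, columns=["chrom", "start", "end", "direction"]
    ).to_csv(outdir / "truth_dmrs.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"gene_id": g, "log2fc": v, "coupled": g in truth.coupled_gene_ids}
            for g, v in sorted(truth.true_deg_log2fc.items())
        ]
    ).to_csv(outdir / "truth_degs.tsv", sep="\t", index=False)
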