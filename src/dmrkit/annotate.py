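"""Gene-structure annotation of methylation features and metagene profiles.

Features (DmCs, DMRs) are mapped onto gene bodies and their 2 kb flanks:
"upstream" is the 2 kb 5' of the transcription start site and "downstream"
the 2 kb 3' of the transcription termination site, strand-aware.  Metagene
profiles average site methylation levels over genes rescaled to a common
body axis with fixed-width flank bins, read 5'->3'.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

REGIONS = ("upstream", "body", "downstream")


@dataclass(frozen=True)
class GeneModel:
    """A gene as an oriented genomic interval.

    ``start``/``end`` are 0-based half-open genomic coordinates with
    start < end; the strand determines which end is the TSS.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: empty body [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Genomic coordinate of the transcription start (first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    def region_intervals(self, flank: int = 2000) -> dict[str, tuple[int, int]]:
        """Half-open genomic intervals of upstream / body / downstream."""
        if self.strand == "+":
            return {
                "upstream": (max(0, self.start - flank), self.start),
                "body": (self.start, self.end),
                "downstream": (self.end, self.end + flank),
            }
        return {
            "upstream": (self.end, self.end + flank),
            "body": (self.start, self.end),
            "downstream": (max(0, self.start - flank), self.start),
        }


def read_genes_bed(path: str | Path) -> list[GeneModel]:
    """BED6 gene models (chrom, start, end, name, score, strand)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            genes.append(
                GeneModel(gene_id=f[3], chrom=f[0], strand=f[5], start=int(f[1]), end=int(f[2]))
            )
    return genes


def read_genes_gff3(path: str | Path) -> list[GeneModel]:
    """Gene features (type ``gene``) from a GFF3 file; ID attribute required."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].strip().split(";") if "=" in kv
            )
            if "ID" not in attrs:
                raise ValueError(f"gene feature without ID attribute: {line.rstrip()}")
            genes.append(
                GeneModel(
                    gene_id=attrs["ID"],
                    chrom=f[0],
                    strand=f[6],
                    start=int(f[3]) - 1,  # GFF3 is 1-based closed
                    end=int(f[4]),
                )
            )
    return genes


def write_genes_bed(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def assign_regions(
    features: pd.DataFrame, genes: list[GeneModel], flank: int = 2000
) -> pd.DataFrame:
    """Assign each feature position to every gene region containing it.

    ``features`` needs columns chrom and pos (a point position; for DMRs
    pass e.g. the midpoint, or call once per DmC).  Each (feature, gene)
    pair is classified independently, so a feature inside one gene's body
    and another gene's flank yields two assignments.  Features falling in
    no gene region are absent from the output.

    Returns the feature rows (original index preserved in ``feature_idx``)
    plus gene_id and region columns.
    """
    out = []
    pos = features["pos"].to_numpy()
    chrom = features["chrom"].to_numpy()
    for gene in genes:
        on_chrom = chrom == gene.chrom
        if not on_chrom.any():
            continue
        for region, (lo, hi) in gene.region_intervals(flank).items():
            hit = on_chrom & (pos >= lo) & (pos < hi)
            if hit.any():
                sub = features.loc[hit].copy()
                sub["feature_idx"] = sub.index
                sub["gene_id"] = gene.gene_id
                sub["region"] = region
                out.append(sub)
    if not out:
        cols = list(features.columns) + ["feature_idx", "gene_id", "region"]
        return pd.DataFrame(columns=cols)
    return pd.concat(out, ignore_index=True)


def genes_affected(assignments: pd.DataFrame) -> pd.DataFrame:
    """Distinct gene counts per (region, context, direction).

    A gene is counted once per cell regardless of how many features hit it;
    a gene with both hyper and hypo features in one region appears in both
    direction cells.
    """
    if assignments.empty:
        return pd.DataFrame(columns=["region", "context", "direction", "n_genes"])
    return (
        assignments.groupby(["region", "context", "direction"], observed=True)["gene_id"]
        .nunique()
        .rename("n_genes")
        .reset_index()
    )


def metagene_profile(
    levels: pd.DataFrame,
    genes: list[GeneModel],
    flank: int = 2000,
    body_bins: int = 100,
    flank_bins: int = 20,
) -> pd.DataFrame:
    """Mean methylation level along a normalized gene axis, per context.

    The profile axis has ``flank_bins`` upstream bins (fixed width
    flank/flank_bins bp), ``body_bins`` body bins (each gene's body rescaled),
    and ``flank_bins`` downstream bins, oriented 5'->3' for every gene.
    Genes with a body shorter than ``body_bins`` bases are skipped (their
    sites would be double-counted by upsampling).  The mean pools site
    levels over all contributing genes.

    ``levels`` needs columns chrom, pos, context, level (typically the
    pooled condition levels of gated sites).

    Returns columns bin (0-based along the axis), region, context,
    mean_level, n_sites.
    """
    bin_w = flank / flank_bins
    total_bins = body_bins + 2 * flank_bins
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    by_chrom = {c: g.sort_values("pos") for c, g in levels.groupby("chrom", observed=True)}
    for gene in genes:
        if gene.length < body_bins:
            continue
        sub = by_chrom.get(gene.chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lo, hi = gene.start - flank, gene.end + flank
        i0, i1 = np.searchsorted(pos, [lo, hi])
        if i1 <= i0:
            continue
        p = pos[i0:i1]
        lvl = sub["level"].to_numpy()[i0:i1]
        ctx = sub["context"].to_numpy()[i0:i1]
        # distance along the 5'->3' gene axis
        if gene.strand == "+":
            before = p < gene.start
            after = p >= gene.end
            body_frac = (p - gene.start) / gene.length
            up_off = p - (gene.start - flank)
            down_off = p - gene.end
        else:
            before = p >= gene.end  # genomic right is 5' of a - strand gene
            after = p < gene.start
            body_frac = (gene.end - 1 - p) / gene.length
            up_off = (gene.end + flank - 1) - p
            down_off = (gene.start - 1) - p
        bins = np.empty(p.size, dtype=np.int64)
        bins[before] = np.minimum((up_off[before] // bin_w).astype(np.int64), flank_bins - 1)
        inside = ~before & ~after
        bins[inside] = flank_bins + np.minimum(
            (body_frac[inside] * body_bins).astype(np.int64), body_bins - 1
        )
        bins[after] = (
            flank_bins
            + body_bins
            + np.minimum((down_off[after] // bin_w).astype(np.int64), flank_bins - 1)
        )
        for context in np.unique(ctx):
            sel = ctx == context
            if context not in sums:
                sums[context] = np.zeros(total_bins)
                counts[context] = np.zeros(total_bins, dtype=np.int64)
            np.add.at(sums[context], bins[sel], lvl[sel])
            np.add.at(counts[context], bins[sel], 1)
    rows = []
    for context in sorted(sums):
        with np.errstate(invalid="ignore"):
            mean = np.where(counts[context] > 0, sums[context] / np.maximum(counts[context], 1), np.nan)
        for b in range(total_bins):
            region = (
                "upstream"
                if b < flank_bins
                else "body"
                if b < flank_bins + body_bins
                else "downstream"
            )
            rows.append(
                {
                    "bin": b,
                    "region": region,
                    "context": context,
                    "mean_level": mean[b],
                    "n_sites": int(counts[context][b]),
                }
            )
    return pd.DataFrame(rows)
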