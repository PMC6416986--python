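"""Per-sample and per-condition methylome summaries.

A methylome sample is a table of (methylated, total) read counts per
strand-resolved cytosine.  This module implements methylation levels, the
replicate coverage inclusion rule, chloroplast-based bisulfite conversion
efficiency, genome-wide level summaries (ten-bin distributions) and
fixed-width chromosome tracks exported as bedGraph.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import CONTEXTS, UNKNOWN, Genome

SITE_COLS = ["chrom", "pos", "strand", "context"]


@dataclass
class MethylomeSample:
    """Methylated/total read counts for one biological sample.

    ``counts`` has columns chrom, pos (0-based), strand, context,
    methylated, total — one row per cytosine site, in a fixed genome-wide
    site order shared by all samples of a study.
    """

    sample_id: str
    condition: str  # "flight" or "ground"
    organ: str
    replicate: int
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        missing = [col for col in SITE_COLS + ["methylated", "total"] if col not in c.columns]
        if missing:
            raise ValueError(f"sample {self.sample_id}: missing columns {missing}")
        if np.any(c["methylated"].to_numpy() > c["total"].to_numpy()):
            raise ValueError(f"sample {self.sample_id}: methylated > total at some sites")
        if np.any(c["methylated"].to_numpy() < 0):
            raise ValueError(f"sample {self.sample_id}: negative counts")


def check_aligned(samples: list[MethylomeSample]) -> None:
    """All samples must share one site order (same chrom/pos/strand rows)."""
    ref = samples[0].counts
    for s in samples[1:]:
        if len(s.counts) != len(ref) or not (
            np.array_equal(s.counts["pos"].to_numpy(), ref["pos"].to_numpy())
            and (s.counts["chrom"].to_numpy() == ref["chrom"].to_numpy()).all()
            and (s.counts["strand"].to_numpy() == ref["strand"].to_numpy()).all()
        ):
            raise ValueError(
                f"sample {s.sample_id} site table is not aligned with {samples[0].sample_id}"
            )


def site_level(methylated: float, total: float) -> float:
    """Methylation level = methylated / total; undefined at zero coverage."""
    if total <= 0:
        raise ValueError("site level undefined at zero coverage (exclude the site)")
    return methylated / total


def coverage_gate(
    flight: list[MethylomeSample],
    ground: list[MethylomeSample],
    min_cov: int = 10,
    min_reps: int = 2,
) -> np.ndarray:
    """Boolean mask of sites retained by the replicate coverage rule.

    A site is retained iff, in *each* condition, at least ``min_reps``
    replicates have total coverage >= ``min_cov`` there.
    """
    if len(flight) < min_reps or len(ground) < min_reps:
        raise ValueError(f"need at least {min_reps} replicates per condition")
    check_aligned(flight + ground)
    keep = np.ones(len(flight[0].counts), dtype=bool)
    for group in (flight, ground):
        cov = np.stack([s.counts["total"].to_numpy() for s in group])
        keep &= (cov >= min_cov).sum(axis=0) >= min_reps
    return keep


def pool_counts(samples: list[MethylomeSample]) -> tuple[np.ndarray, np.ndarray]:
    """Replicate-pooled (sum methylated, sum total) arrays across samples."""
    meth = np.sum([s.counts["methylated"].to_numpy() for s in samples], axis=0)
    total = np.sum([s.counts["total"].to_numpy() for s in samples], axis=0)
    return meth, total


def conversion_efficiency(sample: MethylomeSample, genome: Genome) -> dict[str, float]:
    """Bisulfite conversion efficiency from the (unmethylated) chloroplast.

    Every chloroplast cytosine is assumed truly unmethylated, so any
    methylated read there is a conversion failure.  Returns the pooled
    efficiency under key "overall" plus one entry per context:
    1 - sum(methylated)/sum(total) over the sample's chloroplast sites.
    """
    c = sample.counts
    mask = (c["chrom"] == genome.chloroplast_name).to_numpy()
    if mask.sum() == 0 or c.loc[mask, "total"].sum() == 0:
        raise ValueError("no chloroplast coverage; cannot estimate conversion efficiency")
    out: dict[str, float] = {}
    sub = c.loc[mask]
    out["overall"] = 1.0 - sub["methylated"].sum() / sub["total"].sum()
    for ctx in CONTEXTS:
        csub = sub[sub["context"] == ctx]
        tot = csub["total"].sum()
        out[ctx] = 1.0 - csub["methylated"].sum() / tot if tot > 0 else float("nan")
    return out


def conversion_report(
    samples: list[MethylomeSample], genome: Genome
) -> pd.DataFrame:
    """Per sample x context conversion-efficiency table."""
    rows = []
    for s in samples:
        eff = conversion_efficiency(s, genome)
        for ctx in ["overall", *CONTEXTS]:
            rows.append(
                {"sample": s.sample_id, "context": ctx, "converted_ratio": eff[ctx]}
            )
    return pd.DataFrame(rows)


def condition_levels(
    samples: list[MethylomeSample], mask: np.ndarray | None = None
) -> pd.DataFrame:
    """Pooled per-site levels for one condition (sum meth / sum total).

    Returns site columns plus methylated, total, level; rows with zero
    pooled coverage (or excluded by ``mask``) are dropped, as are UNKNOWN
    contexts.
    """
    check_aligned(samples)
    meth, total = pool_counts(samples)
    df = samples[0].counts[SITE_COLS].copy()
    df["methylated"] = meth
    df["total"] = total
    keep = (total > 0) & (df["context"] != UNKNOWN).to_numpy()
    if mask is not None:
        keep &= mask
    df = df.loc[keep].copy()
    df["level"] = df["methylated"] / df["total"]
    return df


def global_levels(levels: pd.DataFrame) -> dict[str, float]:
    """Genome-wide pooled methylation level per context (coverage-weighted)."""
    out = {}
    for ctx, grp in levels.groupby("context", observed=True):
        tot = grp["total"].sum()
        out[str(ctx)] = grp["methylated"].sum() / tot if tot else float("nan")
    return out


def level_distribution(levels: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Proportion of sites per methylation-level bin, per context.

    Bins are [0,0.1), [0.1,0.2), ..., [0.9,1.0] — half-open except the last,
    so every defined level maps to exactly one bin and each context's
    proportions sum to 1.
    """
    if levels.empty:
        raise ValueError("no defined levels to bin (empty input)")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    rows = []
    for ctx, grp in levels.groupby("context", observed=True):
        idx = np.minimum(np.digitize(grp["level"].to_numpy(), edges[1:-1], right=False), n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins)
        props = counts / counts.sum()
        for b in range(n_bins):
            rows.append(
                {
                    "context": ctx,
                    "bin": b,
                    "bin_low": edges[b],
                    "bin_high": edges[b + 1],
                    "proportion": props[b],
                }
            )
    return pd.DataFrame(rows)


def genome_tracks(levels: pd.DataFrame, window: int = 50_000) -> pd.DataFrame:
    """Mean site level in fixed non-overlapping windows, per context.

    Windows tile each chromosome from position 0; windows containing no
    gated site are omitted.  Output columns: chrom, start, end, context,
    mean_level (bedGraph-ready).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    df = levels.copy()
    df["win"] = df["pos"] // window
    agg = (
        df.groupby(["chrom", "context", "win"], observed=True)["level"]
        .mean()
        .reset_index()
    )
    agg["start"] = agg["win"] * window
    agg["end"] = agg["start"] + window
    agg = agg.rename(columns={"level": "mean_level"})
    return agg[["chrom", "start", "end", "context", "mean_level"]].sort_values(
        ["context", "chrom", "start"], ignore_index=True
    )


def write_bedgraph(track: pd.DataFrame, path: str | Path) -> None:
    track[["chrom", "start", "end", "mean_level"]].to_csv(
        path, sep="\t", index=False, header=False, float_format="%.6g"
    )


def write_sample_tsv(sample: MethylomeSample, path: str | Path) -> None:
    """Write the per-site count table, positions 1-based."""
    out = sample.counts.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_sample_tsv(
    path: str | Path, sample_id: str, condition: str, organ: str, replicate: int
) -> MethylomeSample:
    counts = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    counts["pos"] = counts["pos"].astype(np.int64) - 1
    return MethylomeSample(
        sample_id=sample_id,
        condition=condition,
        organ=organ,
        replicate=replicate,
        counts=counts,
    )
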