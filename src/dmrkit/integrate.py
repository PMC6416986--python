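"""Methylation-expression integration: join DmCs with DEGs per gene,
classify opposite/consistent/mixed trends, correlate differential
methylation with expression fold change, and overlap with reference gene
sets (e.g. ROS signaling, housekeeping catalogs).

"Opposite" means every mapped methylation change has the sign opposite to
the gene's expression change (hypomethylation with upregulation or
hypermethylation with downregulation); "consistent" the converse;
disagreement across regions/contexts is "mixed".
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

TRENDS = ("opposite", "consistent", "mixed")


def join_dmc_deg(degs: pd.DataFrame, assignments: pd.DataFrame) -> pd.DataFrame:
    """One record per DEG with >= 1 mapped DmC.

    ``degs``: output of ``expression.call_degs`` (indexed by gene_id, with
    is_deg and log2fc).  ``assignments``: DmC region assignments with
    columns gene_id, region, context, diff (output of
    ``annotate.assign_regions`` on the DmC table).

    Returns a wide table: gene_id, log2fc, mean_diff__<region>__<context>
    columns (NaN where no DmC mapped), n_dmcs, trend.
    """
    deg_ids = set(degs.index[degs["is_deg"]])
    hits = assignments[assignments["gene_id"].isin(deg_ids)]
    if hits.empty:
        return pd.DataFrame(
            columns=["gene_id", "log2fc", "n_dmcs", "trend"]
        ).set_index("gene_id")
    mean_diff = (
        hits.groupby(["gene_id", "region", "context"], observed=True)["diff"]
        .mean()
        .unstack(["region", "context"])
    )
    mean_diff.columns = [f"mean_diff__{r}__{c}" for r, c in mean_diff.columns]
    n_dmcs = hits.groupby("gene_id")["feature_idx"].nunique().rename("n_dmcs")
    out = mean_diff.join(n_dmcs)
    out.insert(0, "log2fc", degs.loc[out.index, "log2fc"])
    out["trend"] = [
        classify_trend(row["log2fc"], row.filter(like="mean_diff__").dropna())
        for _, row in out.iterrows()
    ]
    out.index.name = "gene_id"
    return out.sort_index()


def classify_trend(log2fc: float, mean_diffs) -> str:
    """Trend of one gene from its expression change and mapped DmC means.

    Zero mean diffs carry no sign and are ignored; if every remaining diff
    opposes the sign of log2fc the trend is "opposite", if all agree it is
    "consistent", otherwise "mixed".  Raises if no signed diff remains.
    """
    diffs = np.asarray(mean_diffs, dtype=float)
    diffs = diffs[~np.isnan(diffs)]
    signs = set(np.sign(diffs[diffs != 0]).astype(int))
    if not signs:
        raise ValueError("trend unclassifiable: all mapped methylation diffs are zero")
    e = int(np.sign(log2fc))
    if signs == {-e}:
        return "opposite"
    if signs == {e}:
        return "consistent"
    return "mixed"


def trend_counts(records: pd.DataFrame) -> dict[str, int]:
    counts = {t: 0 for t in TRENDS}
    for t, n in records["trend"].value_counts().items():
        counts[str(t)] = int(n)
    counts["total"] = int(len(records))
    return counts


def expression_methylation_correlation(
    records: pd.DataFrame, min_points: int = 3
) -> pd.DataFrame:
    """Pearson and Spearman per (region, context) cell over the records.

    Cells with fewer than ``min_points`` genes are reported with NaN
    coefficients.  Returns region, context, n, pearson_r, pearson_p,
    spearman_r, spearman_p.
    """
    rows = []
    for col in [c for c in records.columns if c.startswith("mean_diff__")]:
        _, region, context = col.split("__")
        sub = records[["log2fc", col]].dropna()
        if len(sub) < min_points:
            rows.append(
                {"region": region, "context": context, "n": len(sub),
                 "pearson_r": np.nan, "pearson_p": np.nan,
                 "spearman_r": np.nan, "spearman_p": np.nan}
            )
            continue
        pr = pearsonr(sub[col], sub["log2fc"])
        sr = spearmanr(sub[col], sub["log2fc"])
        rows.append(
            {"region": region, "context": context, "n": len(sub),
             "pearson_r": pr.statistic, "pearson_p": pr.pvalue,
             "spearman_r": sr.statistic, "spearman_p": sr.pvalue}
        )
    return pd.DataFrame(rows)


def scatter_table(records: pd.DataFrame, region: str, context: str) -> pd.DataFrame:
    col = f"mean_diff__{region}__{context}"
    if col not in records.columns:
        return pd.DataFrame(columns=["gene_id", "log2fc", "mean_diff"])
    sub = records[["log2fc", col]].dropna().rename(columns={col: "mean_diff"})
    return sub.reset_index()


def gene_set_overlap(
    deg_set: set, dmc_deg_set: set, reference_set: set, set_name: str = "reference"
) -> dict:
    """Pairwise and triple overlaps of DEGs, DmC-DEGs and a reference set.

    DmC-DEGs must be a subset of DEGs (they are DEGs that additionally carry
    mapped DmCs); a violation indicates inconsistent upstream inputs.
    """
    if not dmc_deg_set <= deg_set:
        raise ValueError("DmC-DEG set is not a subset of the DEG set")
    inter_deg = deg_set & reference_set
    inter_dmc = dmc_deg_set & reference_set
    return {
        "set_name": set_name,
        "n_deg": len(deg_set),
        "n_dmc_deg": len(dmc_deg_set),
        "n_reference": len(reference_set),
        "deg_and_reference": len(inter_deg),
        "dmc_deg_and_reference": len(inter_dmc),
        "triple": len(dmc_deg_set & reference_set),  # dmc_deg subset of deg
        "fraction_deg_in_reference": len(inter_deg) / len(deg_set) if deg_set else np.nan,
        "fraction_dmc_deg_in_reference": (
            len(inter_dmc) / len(dmc_deg_set) if dmc_deg_set else np.nan
        ),
    }


def read_gene_set(path: str | Path) -> set[str]:
    """One gene id per line (or first TSV column); '#' comments allowed."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line.split("\t")[0])
    return out
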