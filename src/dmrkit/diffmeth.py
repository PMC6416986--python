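"""Differential methylation: site-level DmC calling and windowed DMR calling.

Replicate counts are pooled within condition and each site is tested with a
two-sided Fisher's exact test on the 2x2 methylated/unmethylated table;
Benjamini-Hochberg adjustment is applied across all tested sites of one
organ (all contexts jointly) and sites with q below the FDR threshold
(default 0.01) are DmCs.

DMRs are fixed 100 bp tiles (anchored at position 0, per chromosome and
context) that contain at least 4 DmCs, have an absolute pooled-level
difference of at least 0.2, and are significant at the window level
(Fisher on window-pooled counts, BH across windows of the context,
q < 0.01).  Qualifying same-direction windows separated by at most one
window are merged into one larger DMR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .methylome import SITE_COLS, MethylomeSample, check_aligned, coverage_gate, pool_counts
from .stats import bh_adjust, fisher_exact_2x2, fisher_exact_single

# |mean_diff| >= min_diff is evaluated with this absolute slack: pooled level
# differences like 0.6 - 0.4 are not exactly representable in binary floats,
# and the threshold is inclusive ("at least").
_DIFF_TOL = 1e-12


def dmc_test(
    flight: list[tuple[int, int]], ground: list[tuple[int, int]]
) -> tuple[float, float]:
    """Pooled level difference (flight - ground) and two-sided Fisher p.

    Each argument is a per-replicate list of (methylated, total) counts for
    one site.
    """
    mf = sum(m for m, _ in flight)
    tf = sum(t for _, t in flight)
    mg = sum(m for m, _ in ground)
    tg = sum(t for _, t in ground)
    if tf == 0 or tg == 0:
        raise ValueError("zero pooled coverage in a condition")
    diff = mf / tf - mg / tg
    p = fisher_exact_single(mf, tf - mf, mg, tg - mg)
    return diff, p


def pooled_site_table(
    chrom, pos, context, meth_f, tot_f, meth_g, tot_g, strand=None
) -> pd.DataFrame:
    """Build a tested-site table directly from pooled per-condition counts.

    Convenience constructor for synthetic benchmarks: computes levels, diff
    and Fisher p, producing the same layout as ``test_sites``.
    """
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(pos, dtype=np.int64),
            "strand": "+" if strand is None else strand,
            "context": context,
            "meth_f": np.asarray(meth_f, dtype=np.int64),
            "tot_f": np.asarray(tot_f, dtype=np.int64),
            "meth_g": np.asarray(meth_g, dtype=np.int64),
            "tot_g": np.asarray(tot_g, dtype=np.int64),
        }
    )
    df["level_f"] = df["meth_f"] / df["tot_f"]
    df["level_g"] = df["meth_g"] / df["tot_g"]
    df["diff"] = df["level_f"] - df["level_g"]
    df["p"] = fisher_exact_2x2(
        df["meth_f"].to_numpy(),
        (df["tot_f"] - df["meth_f"]).to_numpy(),
        df["meth_g"].to_numpy(),
        (df["tot_g"] - df["meth_g"]).to_numpy(),
    )
    return df


def test_sites(
    flight: list[MethylomeSample],
    ground: list[MethylomeSample],
    gate: np.ndarray | None = None,
    min_cov: int = 10,
    min_reps: int = 2,
) -> pd.DataFrame:
    """Pool replicates and Fisher-test every gated, known-context site.

    Returns one row per tested site: site columns, pooled counts and levels
    per condition, diff (flight - ground) and p.
    """
    check_aligned(flight + ground)
    if gate is None:
        gate = coverage_gate(flight, ground, min_cov=min_cov, min_reps=min_reps)
    meth_f, tot_f = pool_counts(flight)
    meth_g, tot_g = pool_counts(ground)
    df = flight[0].counts[SITE_COLS].copy()
    df["meth_f"] = meth_f
    df["tot_f"] = tot_f
    df["meth_g"] = meth_g
    df["tot_g"] = tot_g
    keep = gate & (df["context"] != "UNKNOWN").to_numpy() & (tot_f > 0) & (tot_g > 0)
    df = df.loc[keep].reset_index(drop=True)
    df["level_f"] = df["meth_f"] / df["tot_f"]
    df["level_g"] = df["meth_g"] / df["tot_g"]
    df["diff"] = df["level_f"] - df["level_g"]
    df["p"] = fisher_exact_2x2(
        df["meth_f"].to_numpy(),
        (df["tot_f"] - df["meth_f"]).to_numpy(),
        df["meth_g"].to_numpy(),
        (df["tot_g"] - df["meth_g"]).to_numpy(),
    )
    return df


def call_dmcs(tested: pd.DataFrame, fdr: float = 0.01) -> pd.DataFrame:
    """BH-adjust site p-values (all contexts jointly) and flag DmCs.

    Adds columns q, is_dmc (q < fdr) and direction (hyper = higher in
    flight, hypo = lower).
    """
    out = tested.copy()
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.array([])
    out["is_dmc"] = out["q"] < fdr
    out["direction"] = np.where(out["diff"] > 0, "hyper", "hypo")
    return out


def _merge_windows(qual: pd.DataFrame, window: int) -> list[dict]:
    """Merge qualifying same-direction windows separated by <= 1 window."""
    merged: list[dict] = []
    for (chrom, context, direction), grp in qual.groupby(
        ["chrom", "context", "direction"], observed=True
    ):
        grp = grp.sort_values("win")
        run: list[pd.Series] = []
        for _, row in grp.iterrows():
            if run and row["win"] - run[-1]["win"] <= 2:
                run.append(row)
            else:
                if run:
                    merged.append(_finish_run(run, chrom, context, direction, window))
                run = [row]
        if run:
            merged.append(_finish_run(run, chrom, context, direction, window))
    return merged


def _finish_run(run, chrom, context, direction, window) -> dict:
    return {
        "chrom": chrom,
        "context": context,
        "direction": direction,
        "start": int(run[0]["win"]) * window,
        "end": (int(run[-1]["win"]) + 1) * window,
        "q": float(min(r["q"] for r in run)),
        "n_windows_merged": len(run),
    }


def call_dmrs(
    dmcs: pd.DataFrame,
    window: int = 100,
    min_dmcs: int = 4,
    min_diff: float = 0.2,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Call DMRs from DmC-annotated site results (output of ``call_dmcs``).

    ``dmcs`` must carry all tested sites (not only DmCs): window level
    differences pool every gated site in the window.  Returns one row per
    (possibly merged) DMR: chrom, start, end, context, direction, n_dmcs,
    mean_diff, q, n_windows_merged.
    """
    if min_dmcs < 1:
        raise ValueError("min_dmcs must be >= 1")
    if window < 1:
        raise ValueError("window must be >= 1")
    if dmcs.empty:
        return _empty_dmrs()
    sites = dmcs.copy()
    sites["win"] = sites["pos"] // window
    rows = []
    for context, csub in sites.groupby("context", observed=True):
        agg = csub.groupby(["chrom", "win"], observed=True).agg(
            meth_f=("meth_f", "sum"),
            tot_f=("tot_f", "sum"),
            meth_g=("meth_g", "sum"),
            tot_g=("tot_g", "sum"),
            n_dmcs=("is_dmc", "sum"),
        )
        agg = agg[(agg["tot_f"] > 0) & (agg["tot_g"] > 0)].reset_index()
        if agg.empty:
            continue
        agg["mean_diff"] = agg["meth_f"] / agg["tot_f"] - agg["meth_g"] / agg["tot_g"]
        agg["p"] = fisher_exact_2x2(
            agg["meth_f"].to_numpy(),
            (agg["tot_f"] - agg["meth_f"]).to_numpy(),
            agg["meth_g"].to_numpy(),
            (agg["tot_g"] - agg["meth_g"]).to_numpy(),
        )
        agg["q"] = bh_adjust(agg["p"].to_numpy())
        agg["context"] = context
        rows.append(agg)
    if not rows:
        return _empty_dmrs()
    windows = pd.concat(rows, ignore_index=True)
    qual = windows[
        (windows["n_dmcs"] >= min_dmcs)
        & (windows["mean_diff"].abs() >= min_diff - _DIFF_TOL)
        & (windows["q"] < alpha)
    ].copy()
    if qual.empty:
        return _empty_dmrs()
    qual["direction"] = np.where(qual["mean_diff"] > 0, "hyper", "hypo")
    merged = _merge_windows(qual, window)
    # recompute n_dmcs and pooled mean_diff over each merged span
    out_rows = []
    for rec in merged:
        span = sites[
            (sites["chrom"] == rec["chrom"])
            & (sites["context"] == rec["context"])
            & (sites["pos"] >= rec["start"])
            & (sites["pos"] < rec["end"])
        ]
        mf, tf = span["meth_f"].sum(), span["tot_f"].sum()
        mg, tg = span["meth_g"].sum(), span["tot_g"].sum()
        mean_diff = mf / tf - mg / tg
        rec = dict(rec)
        rec["n_dmcs"] = int(span["is_dmc"].sum())
        rec["mean_diff"] = mean_diff
        rec["direction"] = "hyper" if mean_diff > 0 else "hypo"
        out_rows.append(rec)
    out = pd.DataFrame(out_rows)
    cols = [
        "chrom", "start", "end", "context", "direction",
        "n_dmcs", "mean_diff", "q", "n_windows_merged",
    ]
    return out[cols].sort_values(["context", "chrom", "start"], ignore_index=True)


def _empty_dmrs() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "chrom", "start", "end", "context", "direction",
            "n_dmcs", "mean_diff", "q", "n_windows_merged",
        ]
    )


def summarize_differential(dmcs: pd.DataFrame, dmrs: pd.DataFrame) -> dict:
    """Per context x direction DmC/DMR counts and the DmC-within-DMR count."""
    called = dmcs[dmcs["is_dmc"]] if "is_dmc" in dmcs.columns else dmcs
    dmc_counts = (
        called.groupby(["context", "direction"], observed=True).size().rename("n").reset_index()
    )
    dmr_counts = (
        dmrs.groupby(["context", "direction"], observed=True).size().rename("n").reset_index()
        if len(dmrs)
        else pd.DataFrame(columns=["context", "direction", "n"])
    )
    n_in_dmr = 0
    for _, dmr in dmrs.iterrows():
        n_in_dmr += int(
            (
                (called["chrom"] == dmr["chrom"])
                & (called["context"] == dmr["context"])
                & (called["pos"] >= dmr["start"])
                & (called["pos"] < dmr["end"])
            ).sum()
        )
    return {
        "dmc_counts": dmc_counts,
        "dmr_counts": dmr_counts,
        "n_dmcs": int(len(called)),
        "n_dmrs": int(len(dmrs)),
        "n_dmcs_in_dmrs": n_in_dmr,
    }


def write_dmc_tsv(dmcs: pd.DataFrame, path) -> None:
    out = dmcs[dmcs["is_dmc"]].copy()
    out["pos"] = out["pos"] + 1
    cols = ["chrom", "pos", "strand", "context", "level_f", "level_g", "diff", "p", "q", "direction"]
    out[cols].to_csv(path, sep="\t", index=False)


def write_dmr_bed(dmrs: pd.DataFrame, path) -> None:
    """BED6+3: name=context, score=-10*log10(q) capped at 1000, strand '.'."""
    with open(path, "w") as fh:
        for _, r in dmrs.iterrows():
            q = max(float(r["q"]), 1e-100)
            score = min(int(round(-10 * np.log10(q))), 1000)
            fh.write(
                f"{r['chrom']}\t{int(r['start'])}\t{int(r['end'])}\t{r['context']}\t"
                f"{score}\t.\t{int(r['n_dmcs'])}\t{r['mean_diff']:.4f}\t{r['direction']}\n"
            )
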