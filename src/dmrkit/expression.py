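"""Differential gene expression: CPM/FPKM, expression gating, TMM
normalization, a negative-binomial likelihood-ratio test, and DEG calling.

The two-group NB test pools information across genes: per-gene
method-of-moments dispersions are squeezed toward the common value
(empirical-Bayes style, prior df 10), group means are fitted by Newton
iterations on the NB log-likelihood with effective-library offsets, and
the condition effect is assessed with a 1-df likelihood-ratio chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .stats import bh_adjust

_MIN_DISP = 1e-8
_PRIOR_DF = 10.0


@dataclass
class ExpressionMatrix:
    """Gene x sample integer read counts with sample metadata and gene lengths."""

    counts: pd.DataFrame  # genes x samples
    samples: pd.DataFrame  # index: sample ids; columns: condition, organ, replicate
    gene_lengths: pd.Series  # bases, indexed by gene id

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("counts columns and sample sheet rows disagree")
        if not self.counts.index.equals(self.gene_lengths.index):
            self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
            if self.gene_lengths.isna().any():
                raise ValueError("gene_lengths missing for some genes")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError("a sample has zero library size")

    def condition_samples(self, condition: str) -> list[str]:
        return list(self.samples.index[self.samples["condition"] == condition])


def cpm(counts: pd.DataFrame, lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million mapped reads: count / library size * 1e6."""
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    if (lib_sizes <= 0).any():
        raise ValueError("zero library size")
    return counts / lib_sizes * 1e6


def fpkm(counts: pd.DataFrame, gene_lengths: pd.Series,
         lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Fragments per kilobase per million: CPM * 1e3 / gene length."""
    if (gene_lengths <= 0).any():
        raise ValueError("non-positive gene length")
    return cpm(counts, lib_sizes).div(gene_lengths, axis=0) * 1e3


def expression_gate(
    counts: pd.DataFrame, min_cpm: float = 5.0, min_samples: int = 3
) -> pd.Index:
    """Genes with CPM strictly above ``min_cpm`` in >= ``min_samples`` libraries."""
    c = cpm(counts)
    keep = (c > min_cpm).sum(axis=1) >= min_samples
    return counts.index[keep]


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors (geometric mean 1).

    The reference sample is the one whose upper quartile of CPM is closest
    to the mean upper quartile.  For each sample, gene-wise log ratios (M)
    against the reference are trimmed by ``trim_m`` (two-sided) and by
    ``trim_a`` on average abundance (A); the factor is the precision-
    weighted mean M, exponentiated.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    mat = counts.to_numpy(dtype=float)
    uq = np.array([np.quantile(mat[:, j] / lib[j], 0.75) for j in range(mat.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref:
            continue
        factors[j] = _tmm_pair(mat[:, j], lib[j], mat[:, ref], lib[ref], trim_m, trim_a)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _tmm_pair(obs, n_obs, ref, n_ref, trim_m, trim_a) -> float:
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        raise ValueError("no genes expressed in both samples; TMM undefined")
    p_obs = obs[ok] / n_obs
    p_ref = ref[ok] / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * (np.log2(p_obs) + np.log2(p_ref))
    w = (n_obs - obs[ok]) / (n_obs * obs[ok]) + (n_ref - ref[ok]) / (n_ref * ref[ok])
    if np.allclose(m, m[0]):
        return float(2 ** m[0])
    keep = (
        (m > np.quantile(m, trim_m))
        & (m < np.quantile(m, 1 - trim_m))
        & (a > np.quantile(a, trim_a))
        & (a < np.quantile(a, 1 - trim_a))
    )
    if not keep.any():
        keep = np.ones_like(m, dtype=bool)
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2**f)


def estimate_dispersions(counts: pd.DataFrame, eff_lib: pd.Series) -> pd.Series:
    """Squeezed per-gene NB dispersions.

    Method-of-moments on offset-normalized counts, shrunk toward the common
    (median) dispersion with prior df 10 against the residual df of the
    design.
    """
    y = counts.to_numpy(dtype=float)
    s = eff_lib.to_numpy(dtype=float)
    s = s / s.mean()
    z = y / s
    m = z.mean(axis=1)
    v = z.var(axis=1, ddof=1)
    c = np.mean(1.0 / s)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (v - c * m) / m**2
    raw = np.where(np.isfinite(raw), raw, 0.0)
    raw = np.clip(raw, 0.0, 50.0)
    expressed = m > 1
    common = float(np.median(raw[expressed])) if expressed.any() else 0.0
    common = max(common, _MIN_DISP)
    df_res = max(counts.shape[1] - 2, 1)
    shrunk = (df_res * raw + _PRIOR_DF * common) / (df_res + _PRIOR_DF)
    return pd.Series(np.maximum(shrunk, _MIN_DISP), index=counts.index, name="dispersion")


def _nb_loglik(y, mu, alpha):
    """NB log-likelihood, elementwise-summed over samples (axis 1)."""
    if np.isscalar(alpha):
        alpha = np.full(y.shape[0], alpha)
    alpha = np.asarray(alpha)[:, None]
    small = alpha < 1e-7
    mu = np.maximum(mu, 1e-300)
    # Poisson limit for tiny dispersion
    pois = y * np.log(mu) - mu - gammaln(y + 1)
    r = 1.0 / np.maximum(alpha, 1e-12)
    nb = (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )
    return np.where(small, pois, nb).sum(axis=1)


def _fit_group_mean(y, s, alpha, n_iter: int = 30):
    """MLE of the per-gene mean rate q (mu_ij = s_j * q_i), by Newton on log q.

    y: genes x samples, s: samples, alpha: genes.  Returns q (genes,).
    """
    tot = y.sum(axis=1)
    q = (tot + 0.5) / s.sum()
    b = np.log(q)
    a = np.asarray(alpha)[:, None]
    for _ in range(n_iter):
        mu = s[None, :] * np.exp(b)[:, None]
        denom = 1.0 + a * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        b = b + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return np.exp(b)


def nb_test(
    counts: pd.DataFrame,
    condition: pd.Series,
    eff_lib: pd.Series | None = None,
    dispersion: pd.Series | None = None,
    prior_count: float = 0.125,
) -> pd.DataFrame:
    """Two-group NB likelihood-ratio test, flight vs ground.

    ``condition`` maps sample -> {"flight", "ground"}.  ``eff_lib`` is the
    effective library size (raw library x TMM factor); computed here if not
    given.  Returns per-gene log2fc (flight over ground, with a small prior
    count stabilizing zero groups), p (1-df LRT), q-less raw results.
    """
    groups = condition.reindex(counts.columns)
    if set(groups.unique()) != {"flight", "ground"}:
        raise ValueError("condition must contain exactly the labels 'flight' and 'ground'")
    for g in ("flight", "ground"):
        if (groups == g).sum() < 2:
            raise ValueError(f"need >= 2 replicates in group {g!r}")
    if eff_lib is None:
        eff_lib = counts.sum(axis=0) * tmm_factors(counts)
    if dispersion is None:
        dispersion = estimate_dispersions(counts, eff_lib)
    y = counts.to_numpy(dtype=float)
    s = eff_lib.to_numpy(dtype=float)
    s = s / s.mean()
    alpha = dispersion.reindex(counts.index).to_numpy()
    f_mask = (groups == "flight").to_numpy()
    g_mask = ~f_mask

    q0 = _fit_group_mean(y, s, alpha)
    qf = _fit_group_mean(y[:, f_mask], s[f_mask], alpha)
    qg = _fit_group_mean(y[:, g_mask], s[g_mask], alpha)

    mu0 = s[None, :] * q0[:, None]
    mu1 = np.empty_like(y)
    mu1[:, f_mask] = s[None, f_mask] * qf[:, None]
    mu1[:, g_mask] = s[None, g_mask] * qg[:, None]
    lrt = 2.0 * (_nb_loglik(y, mu1, alpha) - _nb_loglik(y, mu0, alpha))
    lrt = np.maximum(lrt, 0.0)
    p = chi2.sf(lrt, df=1)

    # prior-count-stabilized fold change (scaled per group library mass)
    sf = s[f_mask].sum()
    sg = s[g_mask].sum()
    qf_s = (y[:, f_mask].sum(axis=1) + prior_count * f_mask.sum()) / sf
    qg_s = (y[:, g_mask].sum(axis=1) + prior_count * g_mask.sum()) / sg
    log2fc = np.log2(qf_s / qg_s)

    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "lrt": lrt, "dispersion": alpha},
        index=counts.index,
    )


def call_degs(
    matrix: ExpressionMatrix,
    organ: str | None = None,
    fdr: float = 0.05,
    min_fold: float = 2.0,
    min_cpm: float = 5.0,
    min_cpm_samples: int = 3,
) -> pd.DataFrame:
    """Run the full DE stage for one organ and flag DEGs.

    A gene is a DEG iff q < ``fdr``, |log2fc| >= log2(``min_fold``)
    (at-least-2-fold, boundary inclusive), and its mean FPKM exceeds 0 in
    at least one condition.  Returns the per-gene table (all gated genes)
    with is_deg flags; BH is applied within the organ.
    """
    counts = matrix.counts
    samples = matrix.samples
    if organ is not None:
        keep = samples["organ"] == organ
        samples = samples.loc[keep]
        counts = counts[samples.index]
    gated = expression_gate(counts, min_cpm=min_cpm, min_samples=min_cpm_samples)
    sub = counts.loc[gated]
    eff_lib = sub.sum(axis=0) * tmm_factors(sub)
    res = nb_test(sub, samples["condition"], eff_lib=eff_lib)
    res["q"] = bh_adjust(res["p"].to_numpy())
    c = cpm(sub)
    fk = fpkm(sub, matrix.gene_lengths.loc[gated])
    fl = samples.index[samples["condition"] == "flight"]
    gr = samples.index[samples["condition"] == "ground"]
    res["mean_cpm_flight"] = c[fl].mean(axis=1)
    res["mean_cpm_ground"] = c[gr].mean(axis=1)
    res["mean_fpkm_flight"] = fk[fl].mean(axis=1)
    res["mean_fpkm_ground"] = fk[gr].mean(axis=1)
    fpkm_ok = (res["mean_fpkm_flight"] > 0) | (res["mean_fpkm_ground"] > 0)
    res["is_deg"] = (
        (res["q"] < fdr)
        & (res["log2fc"].abs() >= np.log2(min_fold) - 1e-12)
        & fpkm_ok
    )
    res.index.name = "gene_id"
    return res


def venn_counts(set_a: set, set_b: set) -> dict[str, int]:
    """Two-set Venn: sizes, shared and union (inclusion-exclusion)."""
    return {
        "a": len(set_a),
        "b": len(set_b),
        "shared": len(set_a & set_b),
        "union": len(set_a | set_b),
    }


def read_count_matrix(
    counts_path: str | Path, sample_sheet_path: str | Path, lengths_path: str | Path
) -> ExpressionMatrix:
    """Genes x samples TSV (first column gene ids), sample sheet TSV
    (sample, condition, organ, replicate), gene length TSV (gene_id, length)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    required = {"sample", "condition", "organ", "replicate"}
    if not required <= set(sheet.columns):
        raise ValueError(f"sample sheet missing fields: {sorted(required - set(sheet.columns))}")
    sheet = sheet.set_index("sample")
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    counts = counts[sheet.index]
    return ExpressionMatrix(counts=counts, samples=sheet, gene_lengths=lengths)


def write_count_matrix(matrix: ExpressionMatrix, counts_path, sheet_path, lengths_path) -> None:
    matrix.counts.to_csv(counts_path, sep="\t")
    matrix.samples.rename_axis("sample").to_csv(sheet_path, sep="\t")
    matrix.gene_lengths.rename("length").rename_axis("gene_id").to_csv(lengths_path, sep="\t")
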