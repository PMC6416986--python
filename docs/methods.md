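# Methods

This note documents the statistical procedures dmrkit implements, the
choices made where conventions differ between tools, what the synthetic
data generator does and does not emulate, and the package's known
limitations.

## Coordinates and contexts

Internally all coordinates are 0-based half-open. Exported site tables use
1-based positions (the common CX-report style); BED and bedGraph exports are
0-based half-open, as their formats require.

A cytosine's context is read 5'→3' on its own strand: CG if the next base
is G; otherwise CHG if the base after next is G; otherwise CHH. A CG call
therefore needs one readable downstream base and CHG/CHH need two; when a
required base is N or past the end of the sequence the site is UNKNOWN and
excluded from every downstream statistic. This matches the regex oracle
(`CG`, `C[ACT]G`, `C[ACT][ACT]` on the forward strand and on the reverse
complement) used in the tests and the behaviour of common callers, which
classify a terminal `CG` even when no third base exists. Symmetric CG pairs
are kept strand-resolved — merging the two strands would halve site-level
counts and change every DmC tally.

## Methylation levels and the coverage gate

A site's level is methylated/total reads; it is undefined (site excluded,
not zero) at zero coverage. A site enters the differential analysis only if,
in each condition, at least `min_reps` (default 2) replicates cover it with
at least `min_cov` (default 10) reads. The gate is monotone in both
parameters.

Condition-level summaries (genome-wide means, ten-bin level distributions,
50 kb chromosome tracks, metagene profiles) use **pooled counts**
(Σ methylated / Σ total across replicates) rather than means of replicate
levels: pooling weights replicates by their coverage and is stable at low
depth. Ten-bin level histograms use half-open bins [0, 0.1), …, with a
closed final bin [0.9, 1.0] so every defined level maps to exactly one bin.
The track window defaults to 50 kb (configurable); windows with no gated
site are omitted rather than reported as zero.

## Conversion efficiency

The chloroplast genome is treated as fully unmethylated, so its apparent
methylation is bisulfite-conversion failure: efficiency =
1 − Σ methylated / Σ total over all chloroplast cytosines of a sample,
reported pooled and per context. With ~5,000 chloroplast cytosines at 100×
the binomial standard error is ~0.0014 percentage points, so the estimate
is effectively exact at realistic depths.

## DmC calling

Replicate counts are pooled within condition and each gated site is tested
with a **two-sided Fisher's exact test** on
[[meth_f, unmeth_f], [meth_g, unmeth_g]]. The two-sided p-value sums
hypergeometric probabilities of all tables no more likely than the observed
one (the scipy convention, with the same 1 + 1e-7 relative tie tolerance).
The implementation is a vectorized log-pmf tail sum (needed for ~10^6
tables per benchmark run) and is tested to 1e-12 against an exact
integer-enumeration oracle. Replicate pooling was chosen because the
two-group comparison of methylation *rates* is exactly what the 2×2 table
tests; the cost is that between-replicate overdispersion is not modelled
(see Limitations).

Benjamini–Hochberg adjustment is applied per organ across all tested sites,
all contexts jointly (one DmC universe per organ); DmCs are sites with
q < 0.01, labelled hyper (higher in the test condition) or hypo.

## DMR calling

Windows are fixed non-overlapping 100 bp tiles anchored at position 0, per
chromosome and per context — a fixed tiling is what makes "separated by not
more than one window" well defined. A window qualifies when it contains at
least 4 DmCs, its pooled level difference (all gated sites in the window,
both conditions pooled across replicates) is at least 0.2 in absolute
value, and its window-level Fisher test on window-pooled counts reaches
q < 0.01 (BH across the windows of that organ/context). The level-difference
threshold is inclusive and evaluated with a 1e-12 absolute slack because
pooled differences such as 0.6 − 0.4 are not exactly representable in
binary floating point.

Qualifying windows of the same direction separated by at most one window
are merged; opposite-direction windows never merge (a DMR has a direction).
Merged records recompute the DmC count and pooled difference over the full
span and report the minimum member-window q. The output is canonical: no
two reported same-direction DMRs in one context are separated by one window
or less.

## Gene annotation and metagene profiles

Gene models are oriented intervals; "upstream" is the 2 kb 5' of the TSS
and "downstream" the 2 kb 3' of the TTS, strand-aware, truncated at
chromosome ends. Every (feature, gene) pair is classified independently, so
a feature inside one gene's body and a neighbour's flank is assigned to
both — dropping or tie-breaking such hits would silently lose information.
Affected-gene counts de-duplicate genes within each
(region × context × direction) cell.

Metagene profiles rescale each gene body to 100 bins and cut each 2 kb
flank into 20 fixed 100 bp bins, reading every gene 5'→3'; per bin the mean
pools site levels over genes. Genes shorter than the body bin count are
excluded rather than upsampled, which would double-count sites. Bin counts
are a display resolution choice, not a statistical one.

## Differential expression

CPM = count / library size × 10⁶ and FPKM = CPM × 10³ / gene length. Genes
with CPM strictly above 5 in at least 3 libraries are retained. Library
sizes are adjusted by trimmed-mean-of-M-values (TMM) factors (30 % M-trim,
5 % A-trim, precision-weighted, geometric mean 1, reference sample by upper
quartile) — implemented in-package since no installed Python library
provides TMM.

The test is a per-gene negative-binomial likelihood-ratio test: per-gene
method-of-moments dispersions from offset-normalized counts are squeezed
toward the common (median) dispersion with prior df 10 against the design's
residual df; group means are fitted by Newton iterations on the NB
log-likelihood with effective-library offsets; the condition effect is a
1-df chi-square LRT. Simulations in the test suite check calibration (null
p-values uniform, KS < 0.05 at 3 vs 3), empirical FDR (≤ nominal on a
90 %-null simulation) and power (≥ 0.8 at |log2FC| = 2, mean ≥ 100,
dispersion 0.1). Reported log2 fold changes add a small prior count (0.125
per sample) so all-zero groups stay finite.

A DEG requires q < 0.05 (BH within the organ), |log2FC| ≥ 1 — the 2-fold
boundary is inclusive ("at least 2-fold") — and mean FPKM > 0 in at least
one condition. The FPKM clause is nearly vacuous as stated but kept for
fidelity to the criterion it reproduces; its threshold is configurable.

## Integration

A DmC-DEG record exists for every DEG with ≥ 1 mapped DmC. Per
(region × context) the record carries the arithmetic mean of the mapped
DmC level differences (site-level diffs, not region-wide levels). The
trend label uses **all** non-absent cells and requires sign unanimity:
*opposite* if every mean difference opposes the log2FC sign, *consistent*
if all agree, *mixed* otherwise; zero differences carry no sign, and a
record whose every difference is exactly zero is unclassifiable. The mixed
category is what reconciles per-gene labels with genes whose regions
disagree. Correlations (Pearson and Spearman) are reported per cell with
n ≥ 3, otherwise NA. Reference gene sets (e.g. a ROS-signaling catalog, a
housekeeping catalog) are plain one-column TSV inputs; overlap reports
enforce that DmC-DEGs are a subset of DEGs.

## Synthetic data

The generator emulates the target study design: two conditions × one organ
× 3 replicates (organ contrasts are produced by generating two datasets —
the analysis treats organs independently throughout), a random nuclear
genome (GC 0.36) with non-overlapping genes on both strands, and a
chloroplast chromosome.

Baseline methylation is context-dependent: CG is a bimodal mixture (25 %
high mode ~Beta(8.5, 1.5), 75 % low mode ~Beta(0.5, 15), overall mean
≈ 0.24) matching the characteristic U-shaped CG level distribution; CHG
~Beta(2, 18) (mean 0.10) and CHH ~Beta(1.5, 28.5) (mean 0.05) are unimodal
low. These are conventional Arabidopsis-like values chosen once as the
simulation's operating point. Per site and sample, total reads are
Poisson(depth_mean) and methylated reads Binomial(total, level); the
chloroplast's effective level is exactly 1 − conversion efficiency
(default 0.99). Planted DmCs and DMR intervals shift the flight-condition
level by ±`dmc_effect`, with baselines re-drawn into the feasible band so
shifted levels stay inside [0, 1]. Expression counts are NB with planted
log2 fold changes and per-sample library factors in [0.75, 1.25]; a
configurable fraction of planted DEGs is "coupled" to a planted gene-body
methylation interval of opposite sign, giving the negative
methylation–expression correlation the integration stage should detect.
All randomness derives from the single config seed through spawned
generator streams; identical configs produce bit-identical outputs.

What the simulation does **not** emulate — and therefore what passing tests
do not establish about real data: read-level artefacts (mapping bias,
PCR duplicates, M-bias), non-uniform coverage, between-replicate biological
overdispersion of methylation levels, linkage between neighbouring
cytosines beyond planted intervals, transposable elements and other
annotation structure, and incomplete conversion acting on nuclear DNA
(conversion failure is applied to the chloroplast only, so the nuclear
levels are conversion-noise-free by construction).

## Numerical and benchmark choices

Benchmarks in the tests and the acceptance script run at desk scale chosen
to keep the full suite around a minute of compute: 50,000 sites × 20 seeds
for DmC FDR control, 3,000–5,000 genes × 20 seeds for DE calibration,
60–150 kb genomes for recovery runs. Fisher p-values are computed in chunks
of 4,096 tables to bound memory. Newton fits run at most 30 damped
iterations from the pooled-mean start and in practice converge in fewer
than 10; a non-converged gene would surface as a conservative (clipped
non-negative) LRT.

## Limitations

- Pooling replicates in the Fisher test treats biological replicates as
  exchangeable sequencing of one pool; genuine between-replicate variance
  inflates significance. Beta-binomial or replicate-aware models are out of
  scope by design.
- The DMR significance scale (window-pooled Fisher + BH across windows) is
  one of several defensible readings of a "0.01 significance level" for
  windows; it mirrors the site-level procedure one scale up.
- The NB test supports exactly the two-group design; no covariates, batch
  terms or multi-factor contrasts.
- The integration trend label is per gene, not per region; genes with
  conflicting regional signals are reported as mixed rather than resolved.
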