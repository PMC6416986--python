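"""The synthetic-data generator: determinism, constraint satisfaction, and
statistical fidelity of the planted signal."""

import numpy as np
import pandas as pd
import pytest

from dmrkit.genome import enumerate_sites
from dmrkit.methylome import conversion_efficiency
from dmrkit.simulate import (
    GroundTruth,
    SimulationConfig,
    simulate_dataset,
    simulate_expression,
    simulate_genome,
    simulate_methylomes,
)


SMALL = dict(n_chroms=1, chrom_length=8_000, chloroplast_length=2_000,
             n_genes=5, gene_length_mean=800, depth_mean=20,
             n_true_dmcs=10, n_true_dmrs=2, dmr_width=200, n_true_degs=3)


def test_simulate_genome_places_nonoverlapping_genes():
    cfg = SimulationConfig(seed=1, **{**SMALL, "n_genes": 10, "chrom_length": 40_000})
    genome, genes = simulate_genome(cfg)
    assert len(genes) == 10
    sizes = genome.chrom_sizes()
    by_chrom = {}
    for g in genes:
        assert g.chrom in genome.nuclear_names
        assert 0 <= g.start < g.end <= sizes[g.chrom]
        by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    for ivs in by_chrom.values():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2


def test_simulate_genome_no_genes_and_failure():
    genome, genes = simulate_genome(SimulationConfig(seed=1, **{**SMALL, "n_genes": 0}))
    assert genes == []
    with pytest.raises(ValueError):
        simulate_genome(
            SimulationConfig(seed=1, n_chroms=1, chrom_length=2_000,
                             n_genes=50, gene_length_mean=1_000)
        )


def test_simulation_deterministic_per_seed():
    cfg = SimulationConfig(seed=9, **SMALL)
    g1, genes1, s1, m1, t1 = simulate_dataset(cfg)
    g2, genes2, s2, m2, t2 = simulate_dataset(cfg)
    assert g1.sequences == g2.sequences
    assert genes1 == genes2
    for sid in s1:
        pd.testing.assert_frame_equal(s1[sid].counts, s2[sid].counts)
    pd.testing.assert_frame_equal(m1.counts, m2.counts)
    assert t1.true_dmc_sites == t2.true_dmc_sites
    assert t1.true_deg_log2fc == t2.true_deg_log2fc
    # a different seed changes the data
    g3, *_ = simulate_dataset(SimulationConfig(seed=10, **SMALL))
    assert g3.sequences != g1.sequences


def test_perfect_conversion_zeroes_chloroplast():
    cfg = SimulationConfig(seed=2, conversion_efficiency=1.0, **SMALL)
    genome, _ = simulate_genome(cfg)
    samples, _ = simulate_methylomes(genome, cfg)
    for s in samples.values():
        chl = s.counts[s.counts["chrom"] == genome.chloroplast_name]
        assert chl["methylated"].sum() == 0


def test_null_config_plants_nothing():
    cfg = SimulationConfig(seed=3, **{**SMALL, "n_true_dmcs": 0, "n_true_dmrs": 0,
                                      "dmc_effect": 0.0})
    genome, _ = simulate_genome(cfg)
    samples, truth = simulate_methylomes(genome, cfg)
    assert truth.true_dmc_sites == set()
    assert truth.true_dmr_intervals == []


def test_planted_dmc_effect_recovered_empirically():
    """A planted +-0.4 shift at 200x, 3 reps: the empirical flight-ground
    level difference lands within ~3 binomial SE (< 0.1) of the truth."""
    cfg = SimulationConfig(seed=4, n_chroms=1, chrom_length=30_000,
                           chloroplast_length=1_000, n_genes=0, depth_mean=200,
                           n_true_dmcs=50, dmc_effect=0.4, n_true_dmrs=0)
    genome, _ = simulate_genome(cfg)
    samples, truth = simulate_methylomes(genome, cfg)
    flight = [s for s in samples.values() if s.condition == "flight"]
    ground = [s for s in samples.values() if s.condition == "ground"]
    key = flight[0].counts.set_index(["chrom", "pos", "strand"]).index
    mf = sum(s.counts["methylated"].to_numpy() for s in flight)
    tf = sum(s.counts["total"].to_numpy() for s in flight)
    mg = sum(s.counts["methylated"].to_numpy() for s in ground)
    tg = sum(s.counts["total"].to_numpy() for s in ground)
    diff = mf / tf - mg / tg
    idx = key.get_indexer(list(truth.true_dmc_sites))
    assert (np.abs(np.abs(diff[idx]) - 0.4) < 0.1).all()


def test_planted_levels_stay_in_unit_interval():
    cfg = SimulationConfig(seed=5, **{**SMALL, "dmc_effect": 0.8})
    genome, _ = simulate_genome(cfg)
    samples, truth = simulate_methylomes(genome, cfg)
    for s in samples.values():
        assert (s.counts["methylated"] <= s.counts["total"]).all()
    for c, start, end, d in truth.true_dmr_intervals:
        assert 0 <= start < end <= genome.chrom_sizes()[c]


def _moment_dispersion(counts):
    """Median method-of-moments NB dispersion after library normalization."""
    y = counts.to_numpy(dtype=float)
    f = y.sum(axis=0) / y.sum(axis=0).mean()
    z = y / f
    m = z.mean(axis=1)
    v = z.var(axis=1, ddof=1)
    c = np.mean(1.0 / f)
    keep = m > 50
    return float(np.median(((v - c * m) / m**2)[keep]))


@pytest.mark.parametrize("disp", [0.0, 0.3])
def test_expression_dispersion_moments(disp):
    """Dispersion 0 gives Poisson counts (variance ~ mean); a positive
    dispersion is recovered by a moment estimate over thousands of genes."""
    from dmrkit.annotate import GeneModel

    genes = [GeneModel(f"g{i}", "Chr1", "+", i * 10, i * 10 + 5) for i in range(4_000)]
    cfg = SimulationConfig(seed=6, n_true_degs=0, nb_dispersion=disp, expr_mean=300.0)
    matrix, truth = simulate_expression(genes, cfg, planted={})
    assert truth.true_deg_log2fc == {}
    est = _moment_dispersion(matrix.counts)
    if disp == 0.0:
        assert abs(est) < 0.05
    else:
        assert est == pytest.approx(disp, rel=0.4)


def test_expression_planted_log2fc_recovered():
    rng = np.random.default_rng(0)
    cfg = SimulationConfig(seed=7, n_chroms=2, chrom_length=200_000,
                           n_genes=220, gene_length_mean=800,
                           expr_mean=500.0, nb_dispersion=0.1)
    genes = simulate_genome(cfg)[1]
    planted = {g.gene_id: 2.0 for g in genes[:200]}
    matrix, truth = simulate_expression(genes, cfg, planted=planted)
    fl = matrix.counts[matrix.condition_samples("flight")].mean(axis=1)
    gr = matrix.counts[matrix.condition_samples("ground")].mean(axis=1)
    est = np.log2(fl / gr).iloc[:200]
    assert np.median(est) == pytest.approx(2.0, abs=0.2)


def test_coupled_genes_get_opposing_methylation():
    cfg = SimulationConfig(seed=8, n_chroms=1, chrom_length=60_000, n_genes=30,
                           gene_length_mean=1_000, depth_mean=60,
                           n_true_dmcs=0, n_true_dmrs=0, dmc_effect=0.4,
                           n_true_degs=10, coupling_fraction=1.0)
    genome, genes, samples, matrix, truth = simulate_dataset(cfg)
    assert truth.coupled_gene_ids == set(truth.true_deg_log2fc)
    by_id = {g.gene_id: g for g in genes}
    flight = [s for s in samples.values() if s.condition == "flight"]
    ground = [s for s in samples.values() if s.condition == "ground"]
    mf = sum(s.counts["methylated"].to_numpy() for s in flight)
    tf = sum(s.counts["total"].to_numpy() for s in flight)
    mg = sum(s.counts["methylated"].to_numpy() for s in ground)
    tg = sum(s.counts["total"].to_numpy() for s in ground)
    sites = flight[0].counts
    for gid in truth.coupled_gene_ids:
        g = by_id[gid]
        body = (sites["chrom"] == g.chrom) & (sites["pos"] >= g.start) & (sites["pos"] < g.end)
        diff = mf[body].sum() / tf[body].sum() - mg[body].sum() / tg[body].sum()
        assert np.sign(diff) == -np.sign(truth.true_deg_log2fc[gid])


def test_config_roundtrip_and_validation(tmp_path):
    cfg = SimulationConfig(seed=11, **SMALL)
    path = tmp_path / "sim.cfg"
    cfg.to_file(path)
    back = SimulationConfig.from_file(path)
    assert back == cfg
    with pytest.raises(ValueError):
        SimulationConfig(seed=1, conversion_efficiency=1.5).validate()
    with pytest.raises(ValueError):
        SimulationConfig(seed=1, dmc_effect=2.0).validate()
    path.write_text("n_chroms = 1\n")  # seed missing
    with pytest.raises(ValueError):
        SimulationConfig.from_file(path)
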