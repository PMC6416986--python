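"""DmC calling (Fisher on pooled replicates, BH at FDR 0.01) and the
100 bp / 4-DmC / 0.2-difference DMR definition with the one-window joining
rule."""

import math

import numpy as np
import pandas as pd
import pytest

from dmrkit.diffmeth import (
    call_dmcs,
    call_dmrs,
    dmc_test,
    pooled_site_table,
    summarize_differential,
)
from dmrkit.diffmeth import test_sites as run_site_tests
from dmrkit.simulate import SimulationConfig, simulate_dmc_benchmark, simulate_genome, simulate_methylomes
from dmrkit.stats import bh_adjust, fisher_exact_2x2

from conftest import make_sample, single_site_table


def test_dmc_test_fully_separated():
    diff, p = dmc_test([(10, 10)], [(0, 10)])
    assert diff == 1.0
    assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-12)


def test_dmc_test_moderate_difference():
    diff, p = dmc_test([(8, 10)], [(2, 10)])
    assert diff == pytest.approx(0.6)
    assert p == pytest.approx(0.0230, abs=5e-4)


def test_dmc_test_pools_replicates():
    diff, p = dmc_test([(2, 5), (3, 5)], [(1, 5), (1, 5)])
    assert diff == pytest.approx(5 / 10 - 2 / 10)


def test_dmc_test_identical_counts():
    diff, p = dmc_test([(4, 10)], [(4, 10)])
    assert diff == 0.0
    assert p == pytest.approx(1.0, abs=1e-12)


def test_dmc_test_zero_pooled_coverage():
    with pytest.raises(ValueError):
        dmc_test([(0, 0)], [(1, 10)])


def _bench_tested(n_sites, frac, effect, depth, seed):
    rng = np.random.default_rng(seed)
    flight, ground, is_null = simulate_dmc_benchmark(n_sites, frac, effect, depth, 3, rng)
    mf = sum(m for m, _ in flight); tf = sum(t for _, t in flight)
    mg = sum(m for m, _ in ground); tg = sum(t for _, t in ground)
    tested = pooled_site_table(
        "Chr1", np.arange(n_sites) * 200, "CG", mf, tf, mg, tg
    )
    return tested, is_null


def test_call_dmcs_null_simulation_makes_no_calls():
    tested, _ = _bench_tested(20_000, 0.0, 0.0, 50, seed=0)
    dmcs = call_dmcs(tested, fdr=0.01)
    assert dmcs["is_dmc"].sum() == 0


def test_call_dmcs_planted_sites_called_with_direction():
    hyper = pooled_site_table("Chr1", [0], "CG", [240], [300], [90], [300])
    hypo = pooled_site_table("Chr1", [100], "CG", [90], [300], [240], [300])
    both = call_dmcs(pd.concat([hyper, hypo], ignore_index=True))
    assert both["is_dmc"].all()
    assert list(both["direction"]) == ["hyper", "hypo"]


def test_call_dmcs_empirical_fdr_controlled():
    """90% null / 10% planted at depth 100: FDP stays near the nominal 0.01."""
    fdps = []
    for seed in range(5):
        tested, is_null = _bench_tested(20_000, 0.10, 0.3, 100, seed)
        dmcs = call_dmcs(tested, fdr=0.01)
        called = dmcs["is_dmc"].to_numpy()
        fdps.append((called & is_null).sum() / max(called.sum(), 1))
    se = np.std(fdps, ddof=1) / np.sqrt(len(fdps))
    assert np.mean(fdps) <= 0.01 + 2 * se


def _window_sites(win_idx, n_dmcs, diff, depth=200, n_filler=0, context="CG", spacing=10):
    """Pooled counts for one 100 bp window: n_dmcs separated sites at the
    given level difference plus optional null filler sites."""
    rows = []
    lo = win_idx * 100
    level_f, level_g = 0.5 + diff / 2, 0.5 - diff / 2
    for i in range(n_dmcs):
        rows.append(dict(chrom="Chr1", pos=lo + i * spacing, context=context,
                         meth_f=int(depth * level_f), tot_f=depth,
                         meth_g=int(depth * level_g), tot_g=depth))
    for i in range(n_filler):
        rows.append(dict(chrom="Chr1", pos=lo + 50 + i * 5, context=context,
                         meth_f=depth // 2, tot_f=depth,
                         meth_g=depth // 2, tot_g=depth))
    return rows


def _tested_from(rows):
    r = pd.DataFrame(rows)
    return pooled_site_table(r.chrom, r.pos, r.context, r.meth_f, r.tot_f, r.meth_g, r.tot_g)


def test_call_dmrs_basic_window():
    dmrs = call_dmrs(call_dmcs(_tested_from(_window_sites(0, 5, 0.3))))
    assert len(dmrs) == 1
    r = dmrs.iloc[0]
    assert (r["start"], r["end"], r["direction"], r["n_dmcs"]) == (0, 100, "hyper", 5)
    assert r["mean_diff"] == pytest.approx(0.3)


def test_call_dmrs_requires_min_dmcs():
    dmrs = call_dmrs(call_dmcs(_tested_from(_window_sites(0, 3, 0.5))))
    assert dmrs.empty


def test_call_dmrs_requires_min_diff():
    rows = _window_sites(0, 6, 0.5, depth=400, n_filler=24)  # pooled diff 0.1
    dmrs = call_dmrs(call_dmcs(_tested_from(rows)))
    assert dmrs.empty


def test_call_dmrs_min_diff_boundary_inclusive():
    rows = _window_sites(0, 6, 0.4, depth=400, n_filler=6)  # pooled diff exactly 0.2
    dmrs = call_dmrs(call_dmcs(_tested_from(rows)))
    assert len(dmrs) == 1
    assert abs(dmrs.iloc[0]["mean_diff"]) == pytest.approx(0.2)


def test_call_dmrs_joining_rule():
    # windows 0 and 2 qualify, window 1 empty -> one merged DMR [0, 300)
    rows = _window_sites(0, 5, 0.4) + _window_sites(2, 5, 0.4)
    dmrs = call_dmrs(call_dmcs(_tested_from(rows)))
    assert len(dmrs) == 1
    r = dmrs.iloc[0]
    assert (r["start"], r["end"], r["n_windows_merged"], r["n_dmcs"]) == (0, 300, 2, 10)


def test_call_dmrs_two_window_gap_not_joined():
    rows = _window_sites(0, 5, 0.4) + _window_sites(3, 5, 0.4)
    dmrs = call_dmrs(call_dmcs(_tested_from(rows)))
    assert len(dmrs) == 2
    assert sorted(zip(dmrs["start"], dmrs["end"])) == [(0, 100), (300, 400)]


def test_call_dmrs_opposite_directions_not_merged():
    rows = _window_sites(0, 5, 0.4) + _window_sites(1, 5, -0.4)
    dmrs = call_dmrs(call_dmcs(_tested_from(rows)))
    assert len(dmrs) == 2
    assert set(dmrs["direction"]) == {"hyper", "hypo"}


def test_call_dmrs_contexts_independent():
    rows = _window_sites(0, 5, 0.4, context="CG") + _window_sites(1, 5, 0.4, context="CHH")
    dmrs = call_dmrs(call_dmcs(_tested_from(rows)))
    assert len(dmrs) == 2  # different contexts never share a DMR
    assert set(dmrs["context"]) == {"CG", "CHH"}


def test_call_dmrs_output_gaps_exceed_one_window():
    """No two reported same-direction DMRs are separated by <= 1 window."""
    rng = np.random.default_rng(3)
    rows = []
    for w in sorted(rng.choice(40, size=12, replace=False)):
        rows += _window_sites(int(w), 5, 0.4)
    dmrs = call_dmrs(call_dmcs(_tested_from(rows)))
    for ctx_dir, grp in dmrs.groupby(["context", "direction"]):
        starts = grp.sort_values("start")
        gaps = starts["start"].to_numpy()[1:] - starts["end"].to_numpy()[:-1]
        assert np.all(gaps > 100)


def test_call_dmrs_config_error():
    with pytest.raises(ValueError):
        call_dmrs(call_dmcs(_tested_from(_window_sites(0, 5, 0.4))), min_dmcs=0)


def test_summarize_differential_conservation():
    rows = _window_sites(0, 5, 0.4) + _window_sites(5, 4, -0.4, context="CHH")
    dmcs = call_dmcs(_tested_from(rows))
    dmrs = call_dmrs(dmcs)
    s = summarize_differential(dmcs, dmrs)
    assert s["dmc_counts"]["n"].sum() == s["n_dmcs"]
    assert s["n_dmcs_in_dmrs"] <= s["n_dmcs"]
    assert s["n_dmcs_in_dmrs"] == 9
    empty = summarize_differential(dmcs, dmrs.iloc[:0])
    assert empty["n_dmcs_in_dmrs"] == 0


def test_test_sites_pipeline_consistency(make_condition_samples):
    flight = make_condition_samples("flight", [(10, 12), (11, 12), (12, 12)])
    ground = make_condition_samples("ground", [(1, 12), (0, 12), (2, 12)])
    tested = run_site_tests(flight, ground)
    assert len(tested) == 1
    row = tested.iloc[0]
    assert row["diff"] == pytest.approx(33 / 36 - 3 / 36)
    d, p = dmc_test([(10, 12), (11, 12), (12, 12)], [(1, 12), (0, 12), (2, 12)])
    assert row["p"] == pytest.approx(p)


def test_planted_dmr_recovery():
    """Planted 300 bp DMRs with a 0.4 shift at 100x are recovered with
    interval sensitivity and precision >= 0.9."""
    cfg = SimulationConfig(seed=3, n_chroms=1, chrom_length=80_000, n_genes=0,
                           depth_mean=100, n_true_dmcs=0, dmc_effect=0.4,
                           n_true_dmrs=10, dmr_width=300)
    genome, _ = simulate_genome(cfg)
    samples, truth = simulate_methylomes(genome, cfg)
    flight = [s for s in samples.values() if s.condition == "flight"]
    ground = [s for s in samples.values() if s.condition == "ground"]
    dmrs = call_dmrs(call_dmcs(run_site_tests(flight, ground)))

    def overlaps_truth(r):
        return any(
            r["chrom"] == c and r["start"] < e and r["end"] > s
            for c, s, e, _ in truth.true_dmr_intervals
        )

    recovered = sum(
        any(
            d["chrom"] == c and d["start"] < e and d["end"] > s
            for _, d in dmrs.iterrows()
        )
        for c, s, e, _ in truth.true_dmr_intervals
    )
    sensitivity = recovered / len(truth.true_dmr_intervals)
    precision = np.mean([overlaps_truth(r) for _, r in dmrs.iterrows()])
    assert sensitivity >= 0.9
    assert precision >= 0.9
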