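"""Gene-region assignment (body / 2 kb upstream / 2 kb downstream,
strand-aware), affected-gene counting, and metagene profiles."""

import numpy as np
import pandas as pd
import pytest

from dmrkit.annotate import (
    GeneModel,
    assign_regions,
    genes_affected,
    metagene_profile,
    read_genes_bed,
    read_genes_gff3,
    write_genes_bed,
)
from dmrkit.genome import reverse_complement

from conftest import random_genome


def _features(positions, chrom="Chr1", **extra):
    df = pd.DataFrame({"chrom": chrom, "pos": positions})
    for k, v in extra.items():
        df[k] = v
    return df


PLUS_GENE = GeneModel("g1", "Chr1", "+", 1000, 2000)
MINUS_GENE = GeneModel("g2", "Chr1", "-", 1000, 2000)


@pytest.mark.parametrize(
    "gene,pos,region",
    [
        (PLUS_GENE, 500, "upstream"),
        (PLUS_GENE, 1500, "body"),
        (PLUS_GENE, 2500, "downstream"),
        (MINUS_GENE, 2500, "upstream"),  # 5' of the TSS at the right end
        (MINUS_GENE, 500, "downstream"),
        (MINUS_GENE, 1500, "body"),
    ],
)
def test_assign_region_conventions(gene, pos, region):
    asn = assign_regions(_features([pos]), [gene])
    assert len(asn) == 1
    assert asn.iloc[0]["region"] == region


def test_assign_region_unassigned_feature():
    asn = assign_regions(_features([5000]), [PLUS_GENE])
    assert asn.empty


def test_assign_region_overlapping_genes_all_reported():
    other = GeneModel("g3", "Chr1", "+", 1400, 3000)
    asn = assign_regions(_features([1500]), [PLUS_GENE, other])
    assert sorted(asn["gene_id"]) == ["g1", "g3"]
    assert set(asn["region"]) == {"body"}


def test_region_partition_tiles_flanked_gene():
    """For an isolated gene the three regions are disjoint and tile
    [start - 2 kb, end + 2 kb)."""
    iv = PLUS_GENE.region_intervals(flank=2000)
    spans = sorted(iv.values())
    assert spans[0][1] == spans[1][0] and spans[1][1] == spans[2][0]
    assert spans[0][0] == 0  # 2 kb flank truncated at the chromosome start
    # every position in the union maps to exactly one region
    pos = np.arange(0, 4000)
    asn = assign_regions(_features(pos), [PLUS_GENE])
    assert asn["feature_idx"].is_unique
    assert len(asn) == 4000


def test_genes_affected_deduplicates():
    asn = pd.DataFrame(
        {
            "gene_id": ["g1", "g1", "g1", "g2", "g2"],
            "region": ["body"] * 5,
            "context": ["CG", "CG", "CG", "CHH", "CHH"],
            "direction": ["hyper", "hyper", "hyper", "hyper", "hypo"],
        }
    )
    out = genes_affected(asn).set_index(["region", "context", "direction"])["n_genes"]
    assert out[("body", "CG", "hyper")] == 1  # 3 DmCs, 1 gene
    assert out[("body", "CHH", "hyper")] == 1 and out[("body", "CHH", "hypo")] == 1
    assert genes_affected(asn.iloc[:0]).empty


def test_genes_affected_matches_bruteforce():
    rng = np.random.default_rng(0)
    genes = [
        GeneModel(f"g{i}", "Chr1", "+" if i % 2 else "-", s, s + 800)
        for i, s in enumerate(range(0, 20_000, 2500))
    ]
    feats = _features(
        rng.integers(0, 22_000, size=300),
        context=rng.choice(["CG", "CHG", "CHH"], size=300),
        direction=rng.choice(["hyper", "hypo"], size=300),
    )
    asn = assign_regions(feats, genes)
    got = genes_affected(asn).set_index(["region", "context", "direction"])["n_genes"]
    # brute force: set comprehension over every (gene, region, feature) triple
    expected = {}
    for g in genes:
        for region, (lo, hi) in g.region_intervals(2000).items():
            for _, f in feats.iterrows():
                if lo <= f["pos"] < hi:
                    expected.setdefault((region, f["context"], f["direction"]), set()).add(g.gene_id)
    for key, ids in expected.items():
        assert got[key] == len(ids)
    assert len(got) == len(expected)


def _uniform_levels(n, level, chrom="Chr1", context="CG"):
    return pd.DataFrame(
        {"chrom": chrom, "pos": np.arange(n), "strand": "+",
         "context": context, "level": level}
    )


def test_metagene_flat_profile():
    levels = _uniform_levels(10_000, 0.3)
    genes = [GeneModel("g1", "Chr1", "+", 3000, 5000),
             GeneModel("g2", "Chr1", "-", 6000, 7000)]
    prof = metagene_profile(levels, genes)
    np.testing.assert_allclose(prof["mean_level"], 0.3)
    assert len(prof) == 140  # 20 + 100 + 20 bins for the single context


def test_metagene_step_between_flank_and_body():
    levels = _uniform_levels(10_000, 0.2)
    inside = (levels["pos"] >= 4000) & (levels["pos"] < 6000)
    levels.loc[inside, "level"] = 0.05
    prof = metagene_profile(levels, [GeneModel("g1", "Chr1", "+", 4000, 6000)])
    up = prof[prof["region"] == "upstream"]["mean_level"]
    body = prof[prof["region"] == "body"]["mean_level"]
    down = prof[prof["region"] == "downstream"]["mean_level"]
    np.testing.assert_allclose(up, 0.2)
    np.testing.assert_allclose(body, 0.05)
    np.testing.assert_allclose(down, 0.2)


def test_metagene_minus_strand_orientation():
    """A - strand gene's genomic *right* flank feeds the 5' (upstream) end
    of its profile."""
    levels = _uniform_levels(10_000, 0.1)
    levels.loc[levels["pos"] >= 6000, "level"] = 0.9  # right of the gene
    prof = metagene_profile(levels, [GeneModel("g1", "Chr1", "-", 4000, 6000)])
    up = prof[prof["region"] == "upstream"]["mean_level"]
    down = prof[prof["region"] == "downstream"]["mean_level"]
    np.testing.assert_allclose(up, 0.9)
    np.testing.assert_allclose(down, 0.1)


def test_metagene_skips_short_genes():
    levels = _uniform_levels(1_000, 0.5)
    prof = metagene_profile(levels, [GeneModel("g1", "Chr1", "+", 100, 150)],
                            body_bins=100)
    assert prof.empty


def test_metagene_strand_symmetry():
    """Reverse-complementing the genome coordinates and flipping gene strands
    leaves the profile unchanged."""
    rng = np.random.default_rng(1)
    n = 12_000
    levels = pd.DataFrame(
        {"chrom": "Chr1", "pos": np.arange(n), "strand": "+",
         "context": rng.choice(["CG", "CHH"], size=n), "level": rng.random(n)}
    )
    genes = [GeneModel("g1", "Chr1", "+", 3000, 4200),
             GeneModel("g2", "Chr1", "-", 7000, 8500)]
    prof = metagene_profile(levels, genes)
    mirrored_levels = levels.copy()
    mirrored_levels["pos"] = n - 1 - mirrored_levels["pos"]
    mirrored_genes = [
        GeneModel(g.gene_id, g.chrom, "-" if g.strand == "+" else "+",
                  n - g.end, n - g.start)
        for g in genes
    ]
    prof_m = metagene_profile(mirrored_levels, mirrored_genes)
    np.testing.assert_allclose(prof["mean_level"], prof_m["mean_level"], atol=1e-12)
    assert list(prof["n_sites"]) == list(prof_m["n_sites"])


def test_gene_reader_roundtrip(tmp_path):
    genes = [PLUS_GENE, MINUS_GENE]
    bed = tmp_path / "genes.bed"
    write_genes_bed(genes, bed)
    assert read_genes_bed(bed) == genes
    gff = tmp_path / "genes.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "Chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tID=g1;Name=foo\n"
        "Chr1\tsrc\tmRNA\t1001\t2000\t.\t+\t.\tID=t1;Parent=g1\n"
        "Chr1\tsrc\tgene\t1001\t2000\t.\t-\t.\tID=g2\n"
    )
    assert read_genes_gff3(gff) == genes


def test_gene_model_validation():
    with pytest.raises(ValueError):
        GeneModel("g", "Chr1", "+", 100, 100)
    with pytest.raises(ValueError):
        GeneModel("g", "Chr1", "*", 0, 10)
    assert PLUS_GENE.tss == 1000 and PLUS_GENE.tts == 1999
    assert MINUS_GENE.tss == 1999 and MINUS_GENE.tts == 1000
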