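import numpy as np
import pandas as pd
import pytest

from dmrkit.genome import Genome
from dmrkit.methylome import MethylomeSample


@pytest.fixture
def tiny_genome():
    return Genome(
        sequences={"Chr1": "ACGTCCGGCATA", "ChrC": "ACGTACGT"},
        chloroplast_name="ChrC",
    )


def make_sample(sites, methylated, total, sample_id="s", condition="flight",
                organ="root", replicate=1):
    """MethylomeSample from a site table and count arrays."""
    counts = sites.copy()
    counts["methylated"] = np.asarray(methylated)
    counts["total"] = np.asarray(total)
    return MethylomeSample(
        sample_id=sample_id, condition=condition, organ=organ,
        replicate=replicate, counts=counts,
    )


def single_site_table(chrom="Chr1", pos=0, strand="+", context="CG"):
    return pd.DataFrame(
        {"chrom": [chrom], "pos": [pos], "strand": [strand], "context": [context]}
    )


@pytest.fixture
def make_condition_samples():
    """Factory: per-replicate (meth, total) scalars at one site -> samples."""

    def _make(condition, meth_totals):
        sites = single_site_table()
        return [
            make_sample(sites, [m], [t], sample_id=f"{condition}_{i}",
                        condition=condition, replicate=i + 1)
            for i, (m, t) in enumerate(meth_totals)
        ]

    return _make


def random_genome(rng, length, n_frac=0.0, gc=0.4):
    p = [(1 - gc) / 2 * (1 - n_frac), gc / 2 * (1 - n_frac),
         gc / 2 * (1 - n_frac), (1 - gc) / 2 * (1 - n_frac), n_frac]
    p = np.array(p) / np.sum(p)
    return "".join(rng.choice(list("ACGTN"), size=length, p=p))
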