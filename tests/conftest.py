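import numpy as np
import pandas as pd
import pytest

from dmrkit.core import GeneModel, Region, SampleSpec
from dmrkit import simulate as dsim


@pytest.fixture
def two_group_samples():
    return [
        SampleSpec("1_1", "1", 1),
        SampleSpec("1_2", "1", 2),
        SampleSpec("2_1", "2", 1),
        SampleSpec("2_2", "2", 2),
    ]


@pytest.fixture
def plus_gene():
    return GeneModel(
        gene_id="NM_1",
        gene_name="geneA",
        chrom="chr1",
        start=1000,
        end=2000,
        strand="+",
        exon_intervals=((1000, 1099), (1900, 2000)),
    )


@pytest.fixture
def minus_gene():
    return GeneModel(
        gene_id="NM_2",
        gene_name="geneB",
        chrom="chr1",
        start=1000,
        end=2000,
        strand="-",
        exon_intervals=((1000, 1099), (1900, 2000)),
    )


def make_sites(records):
    """records: iterable of (sample_id, chrom, pos, meth, unmeth)."""
    rows = [
        {
            "sample_id": s,
            "chrom": c,
            "pos": p,
            "meth_reads": m,
            "unmeth_reads": u,
            "total_reads": m + u,
        }
        for s, c, p, m, u in records
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small simulated dataset shared by IO/pipeline tests (seed fixed)."""
    outdir = tmp_path_factory.mktemp("simdata")
    cfg = dsim.SimConfig(
        seed=7,
        n_chroms=2,
        chrom_length=600_000,
        n_genes=24,
        n_islands=20,
        replicates_per_group=2,
        site_density=2.0,
    )
    ds = dsim.simulate_dataset(cfg, str(outdir))
    return cfg, ds, outdir


def random_regions(rng, chrom="chr1", n=20, span=5000):
    """Small random interval set for brute-force comparisons."""
    regions = []
    for i in range(n):
        s = int(rng.integers(1, span))
        e = s + int(rng.integers(0, 400))
        regions.append(
            Region(region_id=f"r{i}", chrom=chrom, start=s, end=e, kind="window", ordinal=i + 1)
        )
    return regions
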