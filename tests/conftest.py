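"""Shared fixtures: small simulated panels reused across test modules."""

import numpy as np
import pytest

from rilmap import simdata as sd


@pytest.fixture(scope="session")
def small_layout():
    """Three 100-cM, 25-Mb chromosomes tiled by 2.5-Mb scaffolds."""
    return sd.make_layout(
        n_chromosomes=3, chrom_cM=100.0, chrom_bp=25_000_000, scaffold_bp=2_500_000
    )


@pytest.fixture(scope="session")
def small_truth(small_layout):
    return sd.simulate_pedigree(small_layout, 120, 7, seed=101)


@pytest.fixture(scope="session")
def small_matrix(small_truth):
    """Error-free 250-kb window genotype matrix (1 marker ≈ 1 cM)."""
    return sd.true_window_genotypes(small_truth, window_bp=250_000)


def make_snp_table(im_reads, alt_reads, pos=None, scaffold="s1", im767=None):
    """Hand-rolled SnpTable from per-(SNP, RIL) read-count arrays."""
    im_reads = np.atleast_2d(np.asarray(im_reads, dtype=np.int32))
    alt_reads = np.atleast_2d(np.asarray(alt_reads, dtype=np.int32))
    n_snps, n_rils = im_reads.shape
    if pos is None:
        pos = np.arange(n_snps) * 1000
    return sd.SnpTable(
        scaffold_ids=np.repeat(scaffold, n_snps),
        pos=np.asarray(pos, dtype=np.int64),
        im_base=np.repeat("A", n_snps),
        alt_base=np.repeat("C", n_snps),
        im767=np.repeat("IM", n_snps) if im767 is None else np.asarray(im767),
        ril_ids=[f"RIL{i:03d}" for i in range(n_rils)],
        im_reads=im_reads,
        alt_reads=alt_reads,
    )
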