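import numpy as np
import pytest

from cracflow import CoverageTrack, Feature


@pytest.fixture
def chrom_sizes():
    return {"chrI": 2000, "chrII": 1500}


@pytest.fixture
def features():
    return [
        Feature("gene1", "chrI", 100, 600, "+", "mRNA"),
        Feature("gene2", "chrI", 800, 1900, "-", "mRNA",
                introns=((1000, 1100),)),
        Feature("gene3", "chrII", 50, 250, "+", "CUT"),
    ]


@pytest.fixture
def uniform_track(chrom_sizes):
    """Value 2.0 everywhere on the plus strand, 0.5 on the minus strand."""
    data = {}
    for chrom, n in chrom_sizes.items():
        data[(chrom, "+")] = np.full(n, 2.0)
        data[(chrom, "-")] = np.full(n, 0.5)
    return CoverageTrack(
        sample_id="uniform", chrom_sizes=chrom_sizes, data=data,
        condition="CRAC_CL", genotype="WT",
        total_mapped=1_000_000, spike_reads=5_000,
    )


def make_track(chrom_sizes, arrays, **meta):
    """Build a track from {(chrom, strand): array-like} with zero-filled rest."""
    data = {k: np.asarray(v, dtype=float) for k, v in arrays.items()}
    meta.setdefault("sample_id", "t")
    meta.setdefault("total_mapped", 10_000)
    meta.setdefault("spike_reads", 100)
    return CoverageTrack(chrom_sizes=chrom_sizes, data=data, **meta)
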