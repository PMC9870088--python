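import numpy as np
import pandas as pd
import pytest

from hepascreen import synthdata as sd


@pytest.fixture(scope="session")
def genome_small():
    return sd.generate_genome(n_genes=60, chrom_sizes={"chrA": 3_000_000, "chrB": 3_000_000},
                              seed=7)


@pytest.fixture(scope="session")
def truth_small(genome_small):
    return sd.make_truth(genome_small, n_target_genes=12, n_markers=3, n_coexpressed=10,
                         n_samples=60, seed=7)


@pytest.fixture(scope="session")
def genome_default():
    """The default desk-scale world: 2,000 genes, five 60-Mb chromosomes."""
    return sd.generate_genome(seed=0)


def make_peaks(records):
    """Peak DataFrame from (chrom, start, end[, summit]) tuples, BED-sorted."""
    rows = []
    for i, rec in enumerate(records):
        chrom, start, end = rec[:3]
        summit = rec[3] if len(rec) > 3 else (start + end) // 2
        rows.append({"chrom": chrom, "start": start, "end": end,
                     "name": f"p{i + 1:04d}", "score": 0, "strand": ".", "summit": summit})
    df = pd.DataFrame(rows)
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def random_peaks(rng, n, chrom="chr1", span=1_000_000, width=(100, 600)):
    starts = rng.integers(0, span, size=n)
    widths = rng.integers(width[0], width[1], size=n)
    return make_peaks([(chrom, int(s), int(s + w)) for s, w in zip(starts, widths)])
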