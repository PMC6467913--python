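import numpy as np
import pandas as pd
import pytest

from svharmonize import synthetic as syn


@pytest.fixture(scope="session")
def small_genome():
    return syn.generate_genome_model(2, 2_000_000, tr_density=0.05, snv_spacing_mean=1200, seed=3)


def make_composite(rows):
    """Composite DataFrame from (chrom, pos, nonref, hap) tuples."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "nonref", "hap"])
    df["pos"] = df["pos"].astype("int64")
    df["nonref"] = df["nonref"].astype(bool)
    df["hap"] = df["hap"].astype("int8")
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def uniform_reads(chrom, start, end, n, nonref=False, hap=0, rng=None):
    rng = rng or np.random.default_rng(0)
    pos = np.sort(rng.integers(start, end, size=n))
    return [(chrom, int(p), nonref, hap) for p in pos]
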