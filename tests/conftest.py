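import numpy as np
import pandas as pd
import pytest

from condfdr.io import ReferencePanel
from condfdr.simulate import SimConfig, simulate_reference_panel, simulate_two_trait_stats


def make_summary(ids, pvals, chrom="1", pos=None, maf=None):
    """Small in-memory summary-stats frame."""
    n = len(ids)
    df = pd.DataFrame(
        {
            "snp_id": list(ids),
            "chrom": [chrom] * n if isinstance(chrom, str) else list(chrom),
            "pos": list(pos) if pos is not None else list(range(1000, 1000 + 1000 * n, 1000)),
            "pvalue": list(pvals),
        }
    )
    if maf is not None:
        df["maf"] = list(maf)
    return df


def make_merged(p1, p2, chrom="1", pos=None):
    n = len(p1)
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(n)],
            "chrom": [chrom] * n if isinstance(chrom, str) else list(chrom),
            "pos": list(pos) if pos is not None else list(range(1000, 1000 + 1000 * n, 1000)),
            "p1": np.asarray(p1, float),
            "p2": np.asarray(p2, float),
        }
    )


def write_summary_tsv(path, df, colnames=("SNP", "CHR", "BP", "P")):
    out = df.rename(
        columns=dict(zip(["snp_id", "chrom", "pos", "pvalue", "maf"], colnames))
    )
    out.to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def small_config():
    """Desk-scale simulation config for fast end-to-end tests."""
    return SimConfig(seed=11, m_snps=2000, n_samples=200)


@pytest.fixture
def small_dataset(small_config):
    a, b, truth = simulate_two_trait_stats(small_config)
    panel = simulate_reference_panel(small_config)
    return a, b, truth, panel


def random_panel(rng, n_snps, n_samples=60, chrom="1"):
    """Panel with independent Binomial(2, f) dosages (little LD)."""
    maf = rng.uniform(0.1, 0.5, n_snps)
    dosages = rng.binomial(2, maf[:, None], size=(n_snps, n_samples)).astype(np.int8)
    return ReferencePanel(
        snp_id=np.array([f"rs{i}" for i in range(n_snps)], dtype=object),
        chrom=np.array([chrom] * n_snps, dtype=object),
        pos=np.arange(1000, 1000 + 1000 * n_snps, 1000),
        dosages=dosages,
    )
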