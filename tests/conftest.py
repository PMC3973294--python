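import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_promoters():
    return pd.DataFrame(
        {
            "gene_id": ["GA", "GB", "GC"],
            "chrom": ["chr1", "chr1", "chr2"],
            "tss": [10_000, 25_000, 10_000],
            "strand": ["+", "-", "+"],
            "cpg_class": ["HCP", "LCP", "ICP"],
        }
    )


def random_annotation(rng, n_promoters=50, n_probes=400, span=60_000):
    """Random promoters and probes on two chromosomes for oracle checks."""
    promoters = pd.DataFrame(
        {
            "gene_id": [f"G{i:03d}" for i in range(n_promoters)],
            "chrom": rng.choice(["chr1", "chr2"], size=n_promoters),
            "tss": rng.integers(2_000, span, size=n_promoters),
            "strand": rng.choice(["+", "-"], size=n_promoters),
        }
    )
    starts = rng.integers(0, span, size=n_probes)
    probes = pd.DataFrame(
        {
            "probe_id": [f"p{i:04d}" for i in range(n_probes)],
            "chrom": rng.choice(["chr1", "chr2"], size=n_probes),
            "start": starts,
            "end": starts + rng.integers(30, 70, size=n_probes),
        }
    )
    return promoters, probes
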