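import numpy as np
import pandas as pd
import pytest

import pipeqtl as pq
from pipeqtl.containers import GenotypeMatrix


@pytest.fixture(scope="session")
def small_panel():
    """60-line, 2-chromosome panel used by fast unit tests."""
    cfg = pq.PanelConfig(n_lines=60, n_chrom=2, markers_per_chrom=120, seed=11)
    geno, groups = pq.simulate_panel(cfg)
    return geno, groups


@pytest.fixture(scope="session")
def demo_study():
    """Cached demo study with a planted local + distant eQTL."""
    return pq.simulate_demo_study(seed=0)


def make_genotypes(dosages, positions=None, chrom="1"):
    """GenotypeMatrix from a raw dosage array (lines x markers)."""
    dosages = np.asarray(dosages, float)
    n, m = dosages.shape
    if positions is None:
        positions = (np.arange(m) + 1) * 1000
    markers = pd.DataFrame(
        {
            "marker": [f"M{j}" for j in range(m)],
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": "T",
        }
    )
    return GenotypeMatrix(dosages, [f"L{i}" for i in range(n)], markers)
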