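import numpy as np
import pandas as pd
import pytest

from finepgs.regions import assign_blocks
from finepgs.synthetic import SimConfig, simulate_study


@pytest.fixture(scope="session")
def cc_study():
    """Small case-control study with a dense-enough architecture to carry
    signal at fixture scale."""
    return simulate_study(SimConfig(seed=11, trait_type="cc", pi=0.01, n_gwas=4000))


@pytest.fixture(scope="session")
def quant_study():
    return simulate_study(SimConfig(seed=12, trait_type="quant", pi=0.01, n_gwas=4000))


@pytest.fixture(scope="session")
def cc_annotated(cc_study):
    return assign_blocks(cc_study.sumstats, cc_study.blocks)


def toy_sumstats_frame():
    """Five well-formed rows on two chromosomes."""
    return pd.DataFrame(
        {
            "chrom": ["1", "1", "1", "2", "2"],
            "pos": [100, 200, 300, 100, 250],
            "effect_allele": ["G", "C", "T", "G", "A"],
            "other_allele": ["A", "T", "C", "A", "C"],
            "beta": [0.1, -0.2, 0.05, 0.3, -0.1],
            "se": [0.02, 0.03, 0.02, 0.05, 0.04],
            "freq": [0.3, 0.5, 0.1, 0.7, 0.25],
            "pval": [1e-6, 2e-10, 0.2, 1e-8, 0.5],
            "n_cases": [5000] * 5,
            "n_controls": [5000] * 5,
        }
    )
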