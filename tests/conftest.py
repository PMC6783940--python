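import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from stemfactor.design import code_levels, table1_design
from stemfactor.qpcr import CtTable, relative_expression
from stemfactor.scoring import score_pipeline
from stemfactor.simulate import generate_ct_table, wnt_dominant_preset


@pytest.fixture(scope="session")
def design():
    return table1_design()


@pytest.fixture(scope="session")
def coded(design):
    return code_levels(design)


@pytest.fixture(scope="session")
def noiseless_scenario():
    return wnt_dominant_preset(noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def noiseless_scores(noiseless_scenario):
    """(normalized, panels, scores) from the noiseless Wnt-dominant preset."""
    expr = relative_expression(generate_ct_table(noiseless_scenario))
    return score_pipeline(expr)


@pytest.fixture()
def small_ct():
    """Two samples, one target gene: hand-checkable comparative-Ct case.

    Calibrator ddCt baseline 4 cycles; sample S has target replicates
    (25, 26) -> mean 25.5, reference 20 -> dCt 5.5, ddCt 1.5,
    expression 2^-1.5.
    """
    records = pd.DataFrame(
        {
            "sample": ["cal", "cal", "cal", "S", "S", "S"],
            "gene": ["GENE", "GENE", "GAPDH", "GENE", "GENE", "GAPDH"],
            "replicate": [1, 2, 1, 1, 2, 1],
            "ct": [24.0, 24.0, 20.0, 25.0, 26.0, 20.0],
        }
    )
    return CtTable(records, reference_gene="GAPDH", calibrator_sample="cal")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
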