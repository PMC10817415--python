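import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mrmediate.summary_io import HarmonizedInstrumentSet

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


def build_harmonized(beta_exp, se_exp, beta_out, se_out,
                     snp_ids=None) -> HarmonizedInstrumentSet:
    """Assemble a harmonized instrument set directly from effect arrays."""
    beta_exp = np.asarray(beta_exp, float)
    k = len(beta_exp)
    table = pd.DataFrame({
        "snp_id": snp_ids or [f"rs{i + 1}" for i in range(k)],
        "beta_exp": beta_exp,
        "se_exp": np.asarray(se_exp, float),
        "eaf_exp": np.full(k, 0.3),
        "beta_out": np.asarray(beta_out, float),
        "se_out": np.asarray(se_out, float),
        "eaf_out": np.full(k, 0.3),
        "action": ["kept"] * k,
    })
    return HarmonizedInstrumentSet(exposure_id="exp", outcome_id="out",
                                   table=table, log=table.copy())


@pytest.fixture
def make_harmonized():
    return build_harmonized


@pytest.fixture
def ivw_toy():
    """The 3-SNP closed-form example: weights (100,100,25), ratios
    (0.1,0.2,0.4), IVW = 40/225."""
    return build_harmonized(beta_exp=[1.0, 1.0, 1.0], se_exp=[0.01] * 3,
                            beta_out=[0.1, 0.2, 0.4], se_out=[0.1, 0.1, 0.2])
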