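import numpy as np
import pandas as pd
import pytest

from mrchain import HarmonizedPairs, SummaryStats
from mrchain.sumstats import CANONICAL_COLUMNS


def make_pairs(beta_exp, beta_out, se_out, se_exp=None, rsid=None):
    """HarmonizedPairs from parallel lists (tiny exposure SE by default)."""
    beta_exp = np.asarray(beta_exp, float)
    if se_exp is None:
        se_exp = np.full_like(beta_exp, 1e-3)
    return HarmonizedPairs(
        beta_exp,
        se_exp,
        np.asarray(beta_out, float),
        np.asarray(se_out, float),
        rsid=rsid,
    )


def make_stats(rows, trait_label="trait", validate=True):
    """SummaryStats from a list of dicts with canonical keys."""
    df = pd.DataFrame(rows)
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return SummaryStats(df[CANONICAL_COLUMNS], trait_label=trait_label, validate=validate)


@pytest.fixture
def three_pairs():
    """Hand-checkable fixture: ratios 0.2, 0.25, 0.2 with weights 400, 400, 351.5625."""
    return make_pairs(
        beta_exp=[0.1, 0.2, 0.15],
        beta_out=[0.02, 0.05, 0.03],
        se_out=[0.005, 0.01, 0.008],
    )
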