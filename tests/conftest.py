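import numpy as np
import pandas as pd
import pytest

from musico.coxph import SurvivalOutcome
from musico.qpcr import CtTable


@pytest.fixture
def rng():
    return np.random.default_rng(20160816)


@pytest.fixture
def small_ct_table() -> CtTable:
    """Two samples, one gene, two housekeeping genes.

    The non-calibrator sample has dCt = 24 - 21 = 3, the calibrator
    dCt = 26 - 21 = 5, hence ddCt = -2 and RQ = 4.
    """
    ct = pd.DataFrame(
        {"GENE1": [26.0, 24.0], "HK1": [20.0, 20.0], "HK2": [22.0, 22.0]},
        index=["CAL", "S1"],
    )
    return CtTable(ct=ct, hkg_names=("HK1", "HK2"), calibrator_id="CAL")


@pytest.fixture
def uncensored_outcome() -> SurvivalOutcome:
    return SurvivalOutcome(
        time=np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
        event=np.ones(6, dtype=int),
    )


def make_outcome(time, event, label="OS"):
    return SurvivalOutcome(np.asarray(time, float), np.asarray(event, int), label)
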