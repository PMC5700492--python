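import dataclasses

import numpy as np
import pytest

from wmcea.params import load_default_parameters
from wmcea.survival import MortalityTable


@pytest.fixture(scope="session")
def params():
    """The shipped bundle: printed tables plus the shipped calibration."""
    return load_default_parameters()


@pytest.fixture(scope="session")
def base_result(params):
    from wmcea.cea import run_base_case

    return run_base_case(params, keep_traces=True)


@pytest.fixture()
def immortal_params(params):
    """Parameter set with no death from any cause (for boundary checks)."""
    table = MortalityTable(ages=np.arange(40, 111), annual_q=np.zeros(71))
    return dataclasses.replace(
        params,
        background_mortality=table,
        excess_mortality=dataclasses.replace(
            params.excess_mortality,
            ctp_pre_progression_per_year=0.0,
            bsc_per_year=0.0,
        ),
    )
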