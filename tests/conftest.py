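import numpy as np
import pytest

from dialyzability import (
    DialyzabilityModel,
    TwoCompartmentParams,
    load_fixture_tables,
)


@pytest.fixture(scope="session")
def drug_records():
    """The six packaged drugs under the default range convention."""
    return load_fixture_tables()


@pytest.fixture(scope="session")
def fitted_results(drug_records):
    return DialyzabilityModel(drug_records).fit()


@pytest.fixture
def rat_session_params():
    """A two-compartment vancomycin-like rat scenario: 1-h infusion of
    10 mg into Vc=0.09 L, slow redistribution, 2-h dialysis window."""
    return TwoCompartmentParams(
        v_central=0.09,
        v_peripheral=0.17,
        q_intercompartmental=0.05,
        fu=0.65,
        cl_dialyzer=0.06,
        infusion=(10.0, 0.0, 1.0),
        dialysis_windows=((1.5, 3.5),),
    )


@pytest.fixture
def dense_grid():
    return np.linspace(0.0, 12.0, 1201)
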