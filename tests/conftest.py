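import numpy as np
import pandas as pd
import pytest

from hingepre import (ConformerEnsemble, HingeModelSpec, TwoStateModel,
                      single_state_ensemble)


@pytest.fixture(scope="session")
def default_spec():
    return HingeModelSpec()


@pytest.fixture(scope="session")
def two_state_model():
    return TwoStateModel.from_minor(0.05)


@pytest.fixture(scope="session")
def state_ensembles(default_spec):
    """Moderate open/minor ensembles shared across PRE tests."""
    open_ens = single_state_ensemble(default_spec, "open", 200, seed=11)
    minor_ens = single_state_ensemble(default_spec, "minor", 200, seed=12)
    return open_ens, minor_ens


@pytest.fixture
def tiny_ensemble():
    """Three-atom, two-frame ensemble with hand-checkable geometry."""
    coords = np.array([
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [1.0, 2.0, 0.0]],
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [1.0, 4.0, 0.0]],
    ])
    meta = pd.DataFrame({
        "residue_id": [1, 2, 3],
        "atom_name": ["CA", "CA", "CA"],
        "domain": ["NTD", "HINGE", "CTD"],
    })
    return ConformerEnsemble(coords=coords, atom_meta=meta)
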