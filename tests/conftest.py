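import numpy as np
import pytest

from htpbk.clearance import ClearanceSpec
from htpbk.compound import ResolvedParameters
from htpbk.partitioning import PartitionSet
from htpbk.physiology import reference_human


@pytest.fixture(scope="session")
def ref_phys():
    return reference_human()


@pytest.fixture
def make_params():
    def _make(lipophilicity=2.0, subtype="LogD", pka=(), fu=0.5,
              clearance=10.0, mode="plasma", solubility=None, permeability=None,
              compound_id="CMP", mw=300.0):
        return ResolvedParameters(
            compound_id=compound_id, mw=mw,
            lipophilicity=lipophilicity, lipophilicity_subtype=subtype,
            pka=tuple(pka), fu=fu,
            clearance_value=clearance, clearance_mode=mode,
            solubility=solubility, permeability=permeability,
        )
    return _make


@pytest.fixture
def unit_kp(ref_phys):
    return PartitionSet("pksim", {o.name: 1.0 for o in ref_phys.perfused_organs})


@pytest.fixture
def plasma_cl():
    def _make(cl):
        return ClearanceSpec(mode="plasma", plasma_cl=cl)
    return _make


def log_times(t0, t1, n):
    return np.exp(np.linspace(np.log(t0), np.log(t1), n))
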