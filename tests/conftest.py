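import numpy as np
import pytest

from vlbind.binding_models import CooperativeParams, EquivalentNSParams


@pytest.fixture
def mb_params():
    """Cooperative constants of the methylene-blue preset (k1 > k2)."""
    return CooperativeParams(k1=207.0, k2=21.0, r0=42.0)


@pytest.fixture
def ssz_params():
    """Equivalent-sites + nonspecific constants of the sulfasalazine preset."""
    return EquivalentNSParams(k1=698.0, ns=21.0, r0=424.0)


@pytest.fixture
def mb_totals():
    """Ligand loads spanning the low-affinity dialysis range, μM."""
    return np.geomspace(1.0, 200.0, 12)


@pytest.fixture
def ssz_totals():
    return np.geomspace(100.0, 5000.0, 12)
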