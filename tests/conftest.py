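import numpy as np
import pytest

from tmbundle import BundleSpec, make_bundle


@pytest.fixture(scope="session")
def bundle():
    """Default 7-helix bundle: (structure, helices, bwmap)."""
    return make_bundle(BundleSpec())


@pytest.fixture(scope="session")
def two_helix_bundle():
    """Minimal two-helix pair for contact tests (axes 10 A apart)."""
    return make_bundle(BundleSpec(n_helices=2, bundle_radius=5.0, loop_residues=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20230505)
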