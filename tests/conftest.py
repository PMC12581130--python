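import warnings

import numpy as np
import pytest

from fibrilkit.fibril_builder import (
    ClashWarning,
    ConformerGeometry,
    LatticeSpec,
    build_lattice,
)


@pytest.fixture(autouse=True)
def _quiet_clash_warnings():
    # idealized rigid lattices report residual side-chain contacts by design
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ClashWarning)
        yield


@pytest.fixture(scope="session")
def bt_lattice():
    """Small BT-A1 lattice shared by read-only tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ClashWarning)
        return build_lattice(
            LatticeSpec(model="BT", arrangement="A1", n_sheets=2, n_chains_per_sheet=2)
        )


@pytest.fixture(scope="session")
def ba_lattice():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ClashWarning)
        return build_lattice(
            LatticeSpec(model="BA", arrangement="A1", n_sheets=2, n_chains_per_sheet=2)
        )


@pytest.fixture(scope="session")
def default_geometry():
    return ConformerGeometry()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
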