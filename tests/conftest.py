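import numpy as np
import pytest

from poregate import (
    IdealPoreSpec,
    SideChainTemplate,
    build_ideal_pore,
)


@pytest.fixture(scope="session")
def ideal_spec():
    """Plain six-helix bundle, pore helix numbered 141-174 as in dOrai."""
    return IdealPoreSpec()


@pytest.fixture(scope="session")
def decorated_spec():
    """Bundle with a PHE at 171 (chi1 = -88 deg) and a VAL at 174."""
    return IdealPoreSpec(
        decorated_residues={
            171: SideChainTemplate("PHE", "CG", -88.0),
            174: SideChainTemplate("VAL", "CG1", -60.0),
        }
    )


@pytest.fixture(scope="session")
def ideal_pore(ideal_spec):
    return build_ideal_pore(ideal_spec)


@pytest.fixture(scope="session")
def decorated_pore(decorated_spec):
    return build_ideal_pore(decorated_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_rigid_transform(rng):
    """A uniformly random rotation matrix and a translation vector."""
    from scipy.stats import special_ortho_group

    R = special_ortho_group.rvs(3, random_state=rng)
    t = rng.uniform(-50, 50, size=3)
    return R, t


def transform_structure(structure, R, t):
    return structure.with_coords(structure.coords @ R.T + t)
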