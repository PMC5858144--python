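"""Shared fixtures: phantoms and their rendered volumes are expensive, so the
canonical ones are built once per session and treated as read-only."""

import numpy as np
import pytest

from atriascar.phantom import PhantomSpec, make_shell, voxelise


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec(seed=11)


@pytest.fixture(scope="session")
def phantom_shell(default_spec):
    """(shell, truth) of the default gap-free phantom."""
    return make_shell(default_spec)


@pytest.fixture(scope="session")
def phantom_volume(default_spec, phantom_shell):
    shell, truth = phantom_shell
    return voxelise(shell, truth, default_spec)


@pytest.fixture(scope="session")
def gapped_spec():
    """Phantom with a single 36-unit gap on the left WACA ring."""
    return PhantomSpec(seed=13, gap_spec={"left": [(90.0, 36.0)]}, noise_sd=0.0)


@pytest.fixture(scope="session")
def gapped_phantom(gapped_spec):
    shell, truth = make_shell(gapped_spec)
    vol = voxelise(shell, truth, gapped_spec)
    return shell, truth, vol


@pytest.fixture
def rng():
    return np.random.default_rng(42)
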