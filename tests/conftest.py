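import numpy as np
import pytest

from ribosurf import FixtureSpec, make_shell_assembly


@pytest.fixture
def shell_assembly():
    """Canonical 2-internal/6-surface shell fixture with its truth labels."""
    return make_shell_assembly(FixtureSpec(n_internal=2, n_surface=6, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def rigid_transform(structure, rotation, translation):
    """Deep-copied structure with R @ x + t applied to every atom."""
    import copy

    out = copy.deepcopy(structure)
    for atom in out.iter_atoms():
        atom.coord = rotation @ atom.coord + np.asarray(translation, dtype=float)
    return out


def random_rotation(rng):
    """Uniform proper rotation via QR with positive diagonal correction."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
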