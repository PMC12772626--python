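import numpy as np
import pytest

from enzfield import (
    CageSpec,
    ChargedAtom,
    FrameSet,
    Topology,
    generate_cage,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def toy_topology():
    """Three charged atoms in two residues."""
    return Topology(
        [
            ChargedAtom(0, "C10", "SUB", 200, "A", -0.10, "C"),
            ChargedAtom(1, "C13", "SUB", 200, "A", 0.10, "C"),
            ChargedAtom(2, "OE1", "GLU", 19, "A", -0.50, "O"),
        ]
    )


@pytest.fixture
def random_system(rng):
    """20 random charges around a box plus a probe point away from them."""
    n = 20
    charges = rng.uniform(-1.0, 1.0, n)
    positions = rng.uniform(-5.0, 5.0, (n, 3))
    point = np.array([8.0, 8.0, 8.0])
    return charges, positions, point


@pytest.fixture(scope="session")
def cage_up():
    spec = CageSpec(n_frames=20, noise_sd=0.1, seed=11)
    return generate_cage(spec)


@pytest.fixture(scope="session")
def cage_pair_noiseless():
    """Up/down pose pair with zero positional noise (same seed)."""
    up = generate_cage(CageSpec(n_frames=3, noise_sd=0.0, seed=5))
    down = generate_cage(
        CageSpec(n_frames=3, noise_sd=0.0, seed=5, substrate_pose="down")
    )
    return up, down


def random_frameset(rng, n_frames, n_atoms, scale=5.0):
    return FrameSet(rng.uniform(-scale, scale, (n_frames, n_atoms, 3)))
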