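import numpy as np
import pytest

from cryoscape import (
    GroundTruth,
    SnapshotStack,
    define_dual_landscape,
    make_default_phantom,
    render_snapshots,
    sample_conformations,
)
from cryoscape.synthetic import euler_from_direction, fibonacci_directions


@pytest.fixture(scope="session")
def phantom():
    return make_default_phantom()


@pytest.fixture(scope="session")
def dual_landscape():
    return define_dual_landscape()


@pytest.fixture(scope="session")
def small_stack(phantom, dual_landscape):
    """A small pooled two-condition stack over 8 directions (16/direction)."""
    rng = np.random.default_rng(11)
    n_dir, per_dir = 8, 16
    n = n_dir * per_dir
    dirs = fibonacci_directions(n_dir)
    eulers = np.array([euler_from_direction(d) for d in dirs])
    half = n // 2
    cc = np.vstack(
        [
            sample_conformations(dual_landscape, "minus", half, seed=rng),
            sample_conformations(dual_landscape, "plus", n - half, seed=rng),
        ]
    )
    truth = GroundTruth(
        condition=np.array(["minus"] * half + ["plus"] * (n - half)),
        cc=cc,
        euler_deg=eulers[np.arange(n) % n_dir],
    )
    return render_snapshots(phantom, truth)


@pytest.fixture
def random_stack():
    rng = np.random.default_rng(0)
    n = 10
    return SnapshotStack(
        images=rng.normal(size=(n, 16, 16)).astype(np.float32),
        pixel_size=1.25,
        euler_deg=rng.uniform(-180, 180, (n, 3)),
        condition=np.array(["minus", "plus"] * 5, dtype=object),
        ground_truth_cc=rng.random((n, 2)),
    )
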