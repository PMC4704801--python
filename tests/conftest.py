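import numpy as np
import pytest

from dynfactor import SimulationConfig, simulate_panel


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def toy_csv(tmp_path):
    """Two subjects, three visits each, two measures, one missing cell."""
    text = (
        "subject,time,y1,y2\n"
        "a,0.0,1.0,2.0\n"
        "a,1.0,1.5,2.5\n"
        "a,2.0,2.0,\n"
        "b,0.0,0.5,1.0\n"
        "b,1.5,0.7,1.4\n"
        "b,3.0,0.9,1.8\n"
    )
    path = tmp_path / "panel.csv"
    path.write_text(text)
    return path


@pytest.fixture(scope="session")
def medium_sim():
    """A mid-sized complete panel with known truth, reused across tests."""
    return simulate_panel(SimulationConfig(n=60, p=4, T=5, seed=42))


def random_small_panel(rng, n=None, p=None, T=None, missing=0.0):
    """Helper: a small simulated panel with random dimensions."""
    n = n or int(rng.integers(3, 7))
    p = p or int(rng.integers(1, 4))
    T = T or int(rng.integers(2, 5))
    seed = int(rng.integers(0, 2**31))
    sim = simulate_panel(SimulationConfig(n=n, p=p, T=T, seed=seed))
    if missing > 0:
        for v in sim.panel.values:
            mask = rng.random(v.shape) < missing
            # never blank an entire visit
            for j in range(v.shape[0]):
                if mask[j].all():
                    mask[j, int(rng.integers(v.shape[1]))] = False
            v[mask] = np.nan
        sim.panel.__dict__.pop("_dense", None)
    return sim
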