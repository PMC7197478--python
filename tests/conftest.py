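import numpy as np
import pytest

from cyclephase import simulate as sim
from cyclephase.trend import fit_cyclic_trend


@pytest.fixture(scope="session", autouse=True)
def _warm_jit():
    """Compile the numba solver once so per-test timings are stable."""
    rng = np.random.default_rng(0)
    fit_cyclic_trend(rng.normal(size=20), rng.uniform(0, 2 * np.pi, 20))


@pytest.fixture(scope="session")
def quadrature_scores():
    """FUCCI scores in quadrature with planted plate/individual offsets."""
    n = 240
    theta = sim.simulate_phases(n, seed=2)
    plates = np.repeat([f"p{i}" for i in range(4)], n // 4)
    indivs = np.tile(np.repeat(["a", "b", "c"], n // 12), 4)
    plate_offsets = {"p0": 0.3, "p1": -0.2, "p2": 0.0, "p3": 0.5}
    indiv_offsets = {"a": 0.1, "b": -0.3, "c": 0.2}
    scores = sim.simulate_fucci_scores(
        theta, plates, indivs, noise_sd=0.1,
        plate_offsets=plate_offsets, individual_offsets=indiv_offsets, seed=3,
    )
    return {
        "scores": scores,
        "theta": theta,
        "plate_offsets": plate_offsets,
        "individual_offsets": indiv_offsets,
        "noise_sd": 0.1,
    }


@pytest.fixture(scope="session")
def sinusoid_panel():
    """Five noiseless-offset cosine marker genes with sigma = 0.3 noise."""
    n_train, n_test = 300, 100
    th_tr = sim.simulate_phases(n_train, seed=11)
    th_te = sim.simulate_phases(n_test, seed=12)
    offsets = np.linspace(0, 2 * np.pi, 5, endpoint=False)

    def gen(th, sd, seed):
        r = np.random.default_rng(seed)
        y = np.array([np.cos(th + o) for o in offsets])
        return y + r.normal(0, sd, y.shape)

    return {
        "theta_train": th_tr,
        "theta_test": th_te,
        "Y_train": gen(th_tr, 0.3, 1),
        "Y_test": gen(th_te, 0.3, 2),
        "offsets": offsets,
        "gene_ids": [f"g{i}" for i in range(5)],
    }
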