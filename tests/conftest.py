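import numpy as np
import pytest

import cyclegrn as cg


def phase_alignment_score(estimated: np.ndarray, true: np.ndarray) -> float:
    """Grid-search oracle for phase recovery.

    Maximizes, over 360 rotations and both orientations, the Pearson
    correlation between the aligned estimate and the true phase treated
    as coordinates on [0, 2*pi). The alignment search makes the plain
    correlation a valid agreement measure for circular data.
    """
    two_pi = 2 * np.pi
    best = -1.0
    tc = true - true.mean()
    for refl in (1.0, -1.0):
        for rot in np.arange(360) * two_pi / 360:
            cand = np.mod(refl * estimated + rot, two_pi)
            cc = cand - cand.mean()
            denom = np.sqrt((cc**2).sum() * (tc**2).sum())
            if denom > 0:
                best = max(best, float((cc * tc).sum() / denom))
    return best


@pytest.fixture(scope="session")
def default_sim():
    """Reference simulation at default settings (500 cells, 50 genes)."""
    cfg = cg.SimConfig(seed=0)
    expr, clock, truth = cg.simulate_dataset(cfg)
    return cfg, expr, clock, truth


@pytest.fixture(scope="session")
def default_lognorm(default_sim):
    cfg, expr, clock, truth = default_sim
    return cg.lognormalize(expr)


@pytest.fixture(scope="session")
def default_clock(default_sim, default_lognorm):
    """Clock with estimated theta and integrated theta attached."""
    cfg, expr, clock, truth = default_sim
    ck = cg.estimate_cycle_position(default_lognorm, truth.cycle_gene_list)
    ck = cg.attach_real_time(ck, clock.real_time)
    return cg.integrate_theta(ck)
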