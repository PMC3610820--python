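import numpy as np
import pandas as pd
import pytest

from circanet import (
    ExpressionSimSpec,
    NetworkSimSpec,
    simulate_expression,
    simulate_network,
)

HOURS_48 = np.arange(48.0)


@pytest.fixture(scope="session")
def hourly_grid():
    return HOURS_48.copy()


def cosine_profile(phase_h: float, baseline: float = 100.0, rel_amp: float = 0.5,
                   t: np.ndarray = HOURS_48) -> np.ndarray:
    """Raw (positive) cosine expression profile peaking at ``phase_h``."""
    return baseline * (1.0 + rel_amp * np.cos(2 * np.pi * (t - phase_h) / 24.0))


@pytest.fixture(scope="session")
def small_simulation():
    """Shared 200-gene simulation with a 100-node network and 10 planted edges."""
    expr, truth = simulate_expression(
        ExpressionSimSpec(n_genes=200, frac_rhythmic=0.4, noise_sd=0.05, seed=11)
    )
    net, planted = simulate_network(
        NetworkSimSpec(n_nodes=100, attachment_edges=3, planted_dynamic_edges=10,
                       planted_phase_offset_max=2.0, seed=12),
        truth,
    )
    return expr, truth, net, planted


@pytest.fixture()
def expr_frame(hourly_grid):
    """Tiny deterministic matrix: 3 rhythmic phases + 1 flat + 1 noisy gene."""
    rng = np.random.default_rng(5)
    rows = {
        "peak0": cosine_profile(0.0),
        "peak6": cosine_profile(6.0),
        "peak18": cosine_profile(18.0),
        "flat": np.full(48, 80.0),
        "noise": 90.0 + rng.normal(0, 5, 48),
    }
    return pd.DataFrame(rows, index=hourly_grid).T
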