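import numpy as np
import pytest

from teamstates import (
    EntropyGridConfig,
    RegimeSegment,
    ZonalModelParams,
    compute_order_parameters,
    simulate_match,
    simulate_preset,
)


@pytest.fixture(scope="session")
def entropy_cfg():
    return EntropyGridConfig()


@pytest.fixture(scope="session")
def preset_ops():
    """2000-step run + order parameters per preset (default seed), computed once."""
    out = {}
    for name in ("polar", "swarm", "milling"):
        series = simulate_preset(name, 2000, seed=0)
        out[name] = (series, compute_order_parameters(series))
    return out


@pytest.fixture(scope="session")
def three_phase_match():
    """Scripted attack/defence/out-of-play match alternated three times."""
    schedule = []
    for _ in range(3):
        schedule += [
            RegimeSegment(20.0, "polar", "defending"),
            RegimeSegment(20.0, "swarm", "attacking"),
            RegimeSegment(10.0, "out_of_play", "out_of_play"),
        ]
    series, annotation = simulate_match(schedule, ZonalModelParams(seed=0))
    return schedule, series, annotation


def unique_bin_window(cfg: EntropyGridConfig, n_players: int = 10):
    """Velocity vectors occupying cfg.window * n_players distinct grid bins."""
    nb = cfg.n_bins_per_axis
    n_vec = cfg.window * n_players
    assert n_vec <= nb * nb
    flat = np.arange(n_vec)
    centers = np.column_stack(
        [
            -cfg.domain_half_width + (flat // nb + 0.5) * cfg.bin_side,
            -cfg.domain_half_width + (flat % nb + 0.5) * cfg.bin_side,
        ]
    )
    return centers
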