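"""Shared fixtures: deterministic RNGs, hand-built swarm states, and
session-scoped scaled-down swarm runs reused by the slower integration
checks."""

from __future__ import annotations

import math

import numpy as np
import pytest

from myxofruit.swarm import SwarmConfig, SwarmState, init_swarm, run_swarm
from myxofruit.swarm.model import draw_reversal_interval


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def state_from_bodies(
    config: SwarmConfig, bodies: list[tuple[tuple[float, float], float]],
    spores: list[int] | None = None,
) -> SwarmState:
    """Build a state of straight rest-length cells from (midpoint, angle°).

    ``spores`` lists indices converted into spores at their midpoint.
    """
    n = len(bodies)
    l0 = config.l0
    pos = np.empty((n, 3, 2))
    for i, ((mx, my), ang) in enumerate(bodies):
        u = np.array([math.cos(math.radians(ang)), math.sin(math.radians(ang))])
        pos[i, 0] = (mx, my) + u * l0  # head
        pos[i, 1] = (mx, my)
        pos[i, 2] = (mx, my) - u * l0  # tail
    g = int(math.ceil(config.domain_size / config.slime_resolution))
    state = SwarmState(
        pos=pos,
        headend=np.zeros(n, dtype=np.int8),
        state=np.zeros(n, dtype=np.uint8),
        counter=np.zeros(n, dtype=np.int64),
        next_rev=np.full(n, 1e12),
        conv_step=np.full(n, -1, dtype=np.int64),
        slime_w=np.zeros((g, g)),
        slime_vx=np.zeros((g, g)),
        slime_vy=np.zeros((g, g)),
        step=0,
        seed=0,
    )
    for i in spores or []:
        state.state[i] = 1
        state.pos[i, :, :] = state.pos[i, 1]
    return state


SCALED_DISC = ((70.0, 70.0), 50.0)


def scaled_config(seed: int, threshold: int = 500) -> SwarmConfig:
    """Scaled-down single-disc study condition: ~300 cells in a 50 µm disc."""
    return SwarmConfig(
        domain_size=140.0,
        discs=(SCALED_DISC,),
        n_cells=300,
        place_in_discs=True,
        signal_threshold=threshold,
        seed=seed,
    )


@pytest.fixture(scope="session")
def scaled_runs():
    """Four scaled runs (distinct seeds), each stopped at 100 spores."""
    out = []
    for seed in (11, 12, 13, 14):
        res = run_swarm(scaled_config(seed), max_steps=12_000, stop_spore_count=100)
        out.append(res)
    return out


@pytest.fixture(scope="session")
def doubled_threshold_run():
    """Seed-11 scaled run with the sporulation threshold doubled to 1000."""
    return run_swarm(
        scaled_config(11, threshold=1000), max_steps=30_000, stop_spore_count=100
    )
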