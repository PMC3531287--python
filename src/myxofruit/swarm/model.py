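"""2D stochastic agent-based model of fruiting-body cells.

Cells are flexible three-node rods gliding on a periodic square domain.
Each step a cell may reverse polarity (intervals ~ Normal(8, 1) min,
independent of C-signal), picks a movement direction as the normalized
weighted sum of its long axis (A-motility), the mean orientation of cells
ahead (S-motility), the local slime-trail direction and a random unit vector,
displaces its head at constant speed, and relaxes its trailing nodes through
a Metropolis test on the harmonic bending/stretching energy — collisions with
other bodies or spores are resolved by bending, or the cell stalls for the
step.  Motile cells touching end to end while aligned within 30° exchange
C-signal (+1 per pair per step); at 500 events a cell converts into an
immobile round spore that remains as an obstacle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels as K

__all__ = [
    "SwarmConfig",
    "SwarmState",
    "SwarmResult",
    "init_swarm",
    "compute_direction",
    "elastic_energy",
    "relax_trailing_nodes",
    "maybe_reverse",
    "detect_end_contacts",
    "apply_signaling_and_sporulation",
    "step_swarm",
    "run_swarm",
    "draw_reversal_interval",
]

DEFAULT_DISCS = (
    ((125.0, 125.0), 50.0),
    ((125.0, 375.0), 50.0),
    ((375.0, 125.0), 50.0),
    ((375.0, 375.0), 50.0),
)


@dataclass(frozen=True)
class SwarmConfig:
    """Parameters of the 2D model.

    Geometry and rates with stated sources are fixed by the modeled system
    (domain 500 µm periodic with four 50 µm discs, reversals 8±1 min,
    30° alignment gate, threshold 500); cell dimensions and speed are typical
    *M. xanthus* values; energy coefficients, direction weights and the
    Metropolis kernel are exposed here with documented defaults.
    """

    domain_size: float = 500.0
    discs: tuple[tuple[tuple[float, float], float], ...] = DEFAULT_DISCS
    n_cells: int = 400
    cell_length: float = 5.0  # µm, rest length of the whole body
    cell_width: float = 0.5  # µm
    speed: float = 2.0  # µm/min
    dt: float = 0.1  # min per step
    bending_coefficient: float = 5.0  # energy / rad^2
    stretching_coefficient: float = 10.0  # energy / µm^2
    w_axis: float = 1.0
    w_neighbors: float = 0.5
    w_trail: float = 0.5
    w_noise: float = 0.1
    reversal_mean: float = 8.0  # min
    reversal_sd: float = 1.0  # min
    alignment_angle_max: float = 30.0  # degrees
    signal_threshold: int = 500
    # end-node proximity that counts as touching.  Collision resolution keeps
    # body surfaces >= one cell width apart (capsule radius = half width per
    # body), so the threshold carries one extra half-width of slack; at
    # exactly one width a resting end-to-end contact would never qualify.
    contact_distance: float = 1.0  # µm (= 2 x cell width)
    spore_radius: float = 1.0  # µm
    metropolis_temperature: float = 1.0
    proposal_sd_factor: float = 0.1  # Gaussian proposal sd = factor * l0
    proposal_budget: int = 10
    slime_resolution: float = 1.0  # µm per slime grid cell
    slime_half_life: float = 10.0  # min
    place_in_discs: bool = False  # restrict initial placement to the discs
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("domain_size", "cell_length", "cell_width", "speed", "dt",
                     "spore_radius", "contact_distance", "slime_resolution"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        ws = (self.w_axis, self.w_neighbors, self.w_trail, self.w_noise)
        if any(w < 0 for w in ws) or not any(w > 0 for w in ws):
            raise ValueError("direction weights must be >= 0 with at least one > 0")
        if not 0.0 < self.alignment_angle_max < 90.0:
            raise ValueError("alignment_angle_max must lie in (0, 90) degrees")
        for a, ((cxa, cya), ra) in enumerate(self.discs):
            if not (ra < cxa < self.domain_size - ra and ra < cya < self.domain_size - ra):
                raise ValueError(f"disc {a} does not fit in the domain")
            for (cxb, cyb), rb in self.discs[a + 1:]:
                if math.hypot(cxa - cxb, cya - cyb) < ra + rb:
                    raise ValueError("discs overlap")

    @property
    def l0(self) -> float:
        """Rest length of each of the two segments."""
        return self.cell_length / 2.0


def config_vector(config: SwarmConfig) -> np.ndarray:
    cfg = np.zeros(K.CFG_LEN)
    cfg[K.C_DOMAIN] = config.domain_size
    cfg[K.C_L0] = config.l0
    cfg[K.C_WIDTH] = config.cell_width
    cfg[K.C_SPEED] = config.speed
    cfg[K.C_DT] = config.dt
    cfg[K.C_KB] = config.bending_coefficient
    cfg[K.C_KS] = config.stretching_coefficient
    cfg[K.C_WA] = config.w_axis
    cfg[K.C_WS] = config.w_neighbors
    cfg[K.C_WT] = config.w_trail
    cfg[K.C_WNOISE] = config.w_noise
    cfg[K.C_REV_MEAN] = config.reversal_mean
    cfg[K.C_REV_SD] = config.reversal_sd
    cfg[K.C_ALIGN_MAX_RAD] = math.radians(config.alignment_angle_max)
    cfg[K.C_THRESHOLD] = config.signal_threshold
    cfg[K.C_CONTACT_DIST] = config.contact_distance
    cfg[K.C_SPORE_RADIUS] = config.spore_radius
    cfg[K.C_TEMP] = config.metropolis_temperature
    cfg[K.C_PROP_SD] = config.proposal_sd_factor * config.l0
    cfg[K.C_PROP_BUDGET] = config.proposal_budget
    cfg[K.C_SLIME_RES] = config.slime_resolution
    cfg[K.C_SLIME_DECAY] = 0.5 ** (config.dt / config.slime_half_life)
    cfg[K.C_SENSE_LEN] = config.cell_length
    cfg[K.C_SENSE_HALFW] = config.cell_length / 2.0
    cfg[K.C_BIN_SIZE] = config.cell_length
    return cfg


@dataclass
class SwarmState:
    """Struct-of-arrays state of all agents plus the slime field and clock."""

    pos: np.ndarray  # (n, 3, 2)
    headend: np.ndarray  # (n,) int8, 0 or 2
    state: np.ndarray  # (n,) uint8
    counter: np.ndarray  # (n,) int64
    next_rev: np.ndarray  # (n,) float64, minutes
    conv_step: np.ndarray  # (n,) int64
    slime_w: np.ndarray
    slime_vx: np.ndarray
    slime_vy: np.ndarray
    step: int = 0
    seed: int = 0

    @property
    def n_cells(self) -> int:
        return self.pos.shape[0]

    def motile_mask(self) -> np.ndarray:
        return self.state == K.MOTILE

    def midpoints(self) -> np.ndarray:
        return self.pos[:, 1, :].copy()

    def orientations(self) -> np.ndarray:
        """Unit head-ward axis per cell (NaN for spores)."""
        h = self.headend.astype(int)
        idx = np.arange(self.n_cells)
        v = self.pos[idx, h] - self.pos[idx, 2 - h]
        n = np.linalg.norm(v, axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            return np.where(n > 1e-12, v / n, np.nan)

    def copy(self) -> "SwarmState":
        return SwarmState(
            self.pos.copy(), self.headend.copy(), self.state.copy(),
            self.counter.copy(), self.next_rev.copy(), self.conv_step.copy(),
            self.slime_w.copy(), self.slime_vx.copy(), self.slime_vy.copy(),
            self.step, self.seed,
        )


def draw_reversal_interval(rng: np.random.Generator, mean: float = 8.0, sd: float = 1.0) -> float:
    """Reversal interval ~ Normal(mean, sd) truncated at zero."""
    while True:
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)


def init_swarm(config: SwarmConfig) -> SwarmState:
    """Place straight rest-length cells uniformly at random.

    A cell whose midpoint falls inside a disc is oriented tangent to the disc
    radius with its head pointing counter-clockwise, setting up a consistent
    rotation; other cells get uniform random orientations.  Per-cell reversal
    clocks are drawn from the reversal-interval distribution.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    L = config.domain_size
    if config.place_in_discs:
        if not config.discs:
            raise ValueError("place_in_discs requires at least one disc")
        mids = np.empty((n, 2))
        per = rng.integers(0, len(config.discs), size=n)
        for i in range(n):
            (cx, cy), r = config.discs[per[i]]
            rr = r * math.sqrt(rng.random())
            th = rng.uniform(0, 2 * math.pi)
            mids[i] = (cx + rr * math.cos(th), cy + rr * math.sin(th))
    else:
        mids = rng.uniform(0.0, L, size=(n, 2))
    angles = rng.uniform(0.0, 2 * math.pi, size=n)
    for (cx, cy), r in config.discs:
        d = mids - np.array([cx, cy])
        inside = (d**2).sum(axis=1) <= r**2
        # CCW tangent: rotate the radial vector by +90 degrees
        tang = np.arctan2(d[:, 0], -d[:, 1])  # atan2(x, -y) = radial angle + 90°
        angles = np.where(inside, tang, angles)
    u = np.column_stack([np.cos(angles), np.sin(angles)])
    l0 = config.l0
    pos = np.empty((n, 3, 2))
    pos[:, 0] = mids + u * l0
    pos[:, 1] = mids
    pos[:, 2] = mids - u * l0
    next_rev = np.array([draw_reversal_interval(rng, config.reversal_mean, config.reversal_sd)
                         for _ in range(n)])
    g = int(math.ceil(L / config.slime_resolution))
    return SwarmState(
        pos=pos,
        headend=np.zeros(n, dtype=np.int8),
        state=np.zeros(n, dtype=np.uint8),
        counter=np.zeros(n, dtype=np.int64),
        next_rev=next_rev,
        conv_step=np.full(n, -1, dtype=np.int64),
        slime_w=np.zeros((g, g)),
        slime_vx=np.zeros((g, g)),
        slime_vy=np.zeros((g, g)),
        step=0,
        seed=config.seed,
    )


def _hash(state: SwarmState, cfg: np.ndarray):
    return K.build_hash(state.pos, state.state, cfg[K.C_DOMAIN], cfg[K.C_BIN_SIZE])


def compute_direction(
    state: SwarmState, config: SwarmConfig, i: int,
    with_noise: bool = True, seed: int | None = None,
) -> np.ndarray:
    """Unit movement direction of motile cell ``i`` (weighted factor sum)."""
    if state.state[i] != K.MOTILE:
        raise ValueError("direction is defined for motile cells only")
    cfg = config_vector(config)
    nb, start, items = _hash(state, cfg)
    if seed is not None:
        K.seed_rng(seed)
    dx, dy = K.compute_direction_kernel(
        i, state.pos, state.headend, state.state,
        state.slime_w, state.slime_vx, state.slime_vy, cfg,
        nb, start, items, 1 if with_noise else 0,
    )
    return np.array([dx, dy])


def elastic_energy(
    nodes: np.ndarray, kb: float, ks: float, l0: float
) -> float:
    """Harmonic elastic energy ½·kb·θ² + ½·ks·Σ(lᵢ−l0)² of a 3-node body."""
    nodes = np.asarray(nodes, dtype=float)
    h = K.elastic_energy_nodes(
        nodes[0, 0], nodes[0, 1], nodes[1, 0], nodes[1, 1],
        nodes[2, 0], nodes[2, 1], kb, ks, l0,
    )
    if h < 0:
        raise ValueError("degenerate body: zero-length segment")
    return float(h)


def relax_trailing_nodes(
    state: SwarmState, config: SwarmConfig, i: int,
    new_head: np.ndarray, seed: int | None = None,
) -> bool:
    """Metropolis-relax cell ``i`` after moving its head to ``new_head``.

    Returns True if a trailing-node arrangement was accepted (state updated)
    and False if the cell stalls (head displacement reverted).
    """
    cfg = config_vector(config)
    nb, start, items = _hash(state, cfg)
    if seed is not None:
        K.seed_rng(seed)
    ok = K.relax_cell_kernel(
        i, state.pos, state.state, cfg, nb, start, items,
        float(new_head[0]), float(new_head[1]), int(state.headend[i]),
    )
    return bool(ok)


def maybe_reverse(
    state: SwarmState, config: SwarmConfig, i: int,
    now: float, rng: np.random.Generator,
) -> bool:
    """Swap head/tail identity if the cell's reversal clock has elapsed.

    Node coordinates and the C-signal counter are untouched; the next
    reversal is scheduled one truncated-normal interval after the previous
    due time (so interval statistics are independent of the step size).
    Returns True if a reversal occurred.
    """
    if state.state[i] != K.MOTILE:
        return False
    if now < state.next_rev[i]:
        return False
    state.headend[i] = 2 - state.headend[i]
    state.next_rev[i] += draw_reversal_interval(rng, config.reversal_mean, config.reversal_sd)
    return True


def detect_end_contacts(state: SwarmState, config: SwarmConfig) -> set[tuple[int, int]]:
    """Unordered pairs of motile cells in aligned end-to-end contact."""
    cfg = config_vector(config)
    nb, start, items = _hash(state, cfg)
    buf = np.empty((max(8 * state.n_cells, 64), 2), dtype=np.int64)
    cnt = K.detect_contacts_kernel(
        state.pos, state.headend, state.state, cfg, nb, start, items, buf
    )
    if cnt > buf.shape[0]:  # pragma: no cover - buffer sized generously
        raise RuntimeError("contact buffer overflow")
    return {(int(a), int(b)) for a, b in buf[:cnt]}


def apply_signaling_and_sporulation(
    state: SwarmState, pairs: set[tuple[int, int]], config: SwarmConfig
) -> int:
    """Increment both members of each pair; convert cells at the threshold.

    A cell participating in k pairs gains k this step.  Conversion collapses
    the body onto its midpoint (a disc obstacle of ``spore_radius``) and
    freezes it.  Returns the number of new spores.
    """
    for a, b in pairs:
        state.counter[a] += 1
        state.counter[b] += 1
    new = 0
    L = config.domain_size
    for i in np.nonzero((state.state == K.MOTILE) & (state.counter >= config.signal_threshold))[0]:
        state.state[i] = K.SPORE
        mid = state.pos[i, 1] % L
        state.pos[i, :, :] = mid
        state.conv_step[i] = state.step
        new += 1
    return new


def step_swarm(state: SwarmState, config: SwarmConfig) -> SwarmState:
    """Advance the state by one step of ``config.dt`` minutes (in place).

    The per-step RNG substream is derived from (state.seed, state.step), so
    trajectories are reproducible regardless of prior kernel usage.
    """
    cfg = config_vector(config)
    K.seed_rng((state.seed * 1_000_003 + state.step * 7919 + 1) % 2**31)
    pairs_buf = np.empty((max(16 * state.n_cells, 64), 2), dtype=np.int64)
    t_now = state.step * config.dt
    K.step_kernel(
        state.pos, state.headend, state.state, state.counter,
        state.next_rev, state.conv_step,
        state.slime_w, state.slime_vx, state.slime_vy,
        cfg, t_now, state.step, pairs_buf,
    )
    state.step += 1
    return state


def measure_reversal_intervals(
    n_intervals: int = 10_000, seed: int = 0, domain_size: float = 20.0
) -> np.ndarray:
    """Inter-reversal times (minutes) of one isolated cell run in the engine.

    Steps a single motile cell until ``n_intervals`` polarity flips have been
    logged and returns the intervals between consecutive flips.  Reversals
    are scheduled from the previous due time, so the step quantization does
    not bias the mean.
    """
    config = SwarmConfig(domain_size=domain_size, discs=(), n_cells=1, seed=seed)
    state = init_swarm(config)
    times = []
    last = state.headend[0]
    max_steps = int(n_intervals * (config.reversal_mean / config.dt) * 1.2) + 10_000
    for _ in range(max_steps):
        step_swarm(state, config)
        if state.headend[0] != last:
            last = state.headend[0]
            times.append(state.step * config.dt)
            if len(times) > n_intervals:
                break
    return np.diff(np.array(times))


def _disc_id(points: np.ndarray, discs) -> np.ndarray:
    out = np.full(len(points), -1, dtype=int)
    for d, ((cx, cy), r) in enumerate(discs):
        inside = ((points[:, 0] - cx) ** 2 + (points[:, 1] - cy) ** 2) <= r**2
        out[inside & (out == -1)] = d
    return out


@dataclass
class SwarmResult:
    """Trajectory snapshots and the final spore position table."""

    spores: pd.DataFrame = field(repr=False)
    snapshots: list = field(default_factory=list, repr=False)
    final_state: SwarmState | None = field(default=None, repr=False)
    config: SwarmConfig | None = None
    steps_run: int = 0


def run_swarm(
    config: SwarmConfig,
    max_steps: int = 10_000,
    stop_spore_fraction: float | None = None,
    stop_spore_count: int | None = None,
    snapshot_every: int = 0,
) -> SwarmResult:
    """Run the model until a stop rule triggers.

    Stops at ``max_steps``, or earlier once the sporulated fraction of
    initially in-disc cells reaches ``stop_spore_fraction`` or the total
    spore count reaches ``stop_spore_count``.  ``snapshot_every`` > 0 stores
    periodic (step, positions, states) snapshots.
    """
    state = init_swarm(config)
    in_disc0 = _disc_id(state.midpoints(), config.discs) >= 0
    n_in_disc = max(int(in_disc0.sum()), 1)
    snapshots = []
    steps = 0
    while steps < max_steps:
        if snapshot_every and steps % snapshot_every == 0:
            snapshots.append((steps, state.pos.copy(), state.state.copy()))
        step_swarm(state, config)
        steps += 1
        n_spores = int((state.state == K.SPORE).sum())
        if stop_spore_count is not None and n_spores >= stop_spore_count:
            break
        if stop_spore_fraction is not None:
            frac = (state.state[in_disc0] == K.SPORE).sum() / n_in_disc
            if frac >= stop_spore_fraction:
                break
    spore_idx = np.nonzero(state.state == K.SPORE)[0]
    pts = state.pos[spore_idx, 1, :] % config.domain_size
    table = pd.DataFrame(
        {
            "x_um": pts[:, 0],
            "y_um": pts[:, 1],
            "disc_id": _disc_id(pts, config.discs),
            "conversion_step": state.conv_step[spore_idx],
        }
    )
    return SwarmResult(
        spores=table, snapshots=snapshots, final_state=state,
        config=config, steps_run=steps,
    )
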