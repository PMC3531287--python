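"""One-dimensional circular-track model of jamming, contact signaling and sporulation.

Motile cells travel in one direction around a discrete ring.  A position may
hold any number of agents ("side by side" in the transverse direction, making
the model pseudo-2D).  A cell attempting to enter a site holding ``n`` spores
passes with probability ``P**n``.  Every cell produces C-signal at a basal
rate and, when a transfer rate ``T`` is set, additionally receives ``T * cbar``
per step, where ``cbar`` is the mean concentration over the motile cells one
position ahead and behind.  A cell whose concentration reaches the sporulation
threshold converts into an immobile spore at its current position.  Runs end
when every cell has sporulated; basal production alone guarantees termination
within ``ceil(threshold / basal)`` steps.

The end-state observable is the *void fraction* — the fraction of ring
positions holding no spores — which quantifies how strongly spores cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrackParams",
    "TrackState",
    "TrackResult",
    "TrackSummary",
    "init_track",
    "attempt_pass",
    "update_signals",
    "step_track",
    "run_track",
    "run_track_batch",
    "track_summary",
    "sweep_track",
    "DEFAULT_P_GRID",
    "DEFAULT_T_GRID",
]

#: Default parameter sweep: 20 passing probabilities covering 0.05..1.00 and
#: five C-signal transfer rates 0..0.4.
DEFAULT_P_GRID: tuple[float, ...] = tuple(np.round(np.arange(1, 21) * 0.05, 2))
DEFAULT_T_GRID: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4)


@dataclass(frozen=True)
class TrackParams:
    """Parameters of a single track run.

    ``track_length`` and ``n_cells`` default to 100 sites / 100 cells.  The
    density (cells per site) is the one free geometric choice of the model;
    one cell per site was calibrated once against the two published
    observables of the sweep — a ~50% relative increase in void fraction
    between free flow (P=1) and strong jamming (P~0.05-0.1) with no signal
    transfer, and per-position spore clusters reaching 5-10 at the lowest
    passing probabilities.
    """

    track_length: int = 100
    n_cells: int = 100
    passing_probability: float = 1.0
    transfer_rate: float = 0.0
    basal_increment: float = 0.005
    spore_threshold: float = 1.0
    init_concentration_range: tuple[float, float] = (0.0, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.track_length < 1:
            raise ValueError(f"track_length must be >= 1, got {self.track_length}")
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        if not 0.0 <= self.passing_probability <= 1.0:
            raise ValueError("passing_probability must lie in [0, 1]")
        if self.transfer_rate < 0.0:
            raise ValueError("transfer_rate must be >= 0")
        if self.basal_increment <= 0.0:
            raise ValueError("basal_increment must be > 0 (termination guarantee)")
        lo, hi = self.init_concentration_range
        if not (0.0 <= lo <= hi < self.spore_threshold):
            raise ValueError(
                "init_concentration_range must be a subinterval of "
                f"[0, spore_threshold), got {self.init_concentration_range}"
            )

    @property
    def max_steps(self) -> int:
        """Hard termination bound: basal production alone reaches threshold."""
        return math.ceil(self.spore_threshold / self.basal_increment)


@dataclass
class TrackState:
    """Mutable per-agent state of a run.

    ``position`` is an integer site index mod ``track_length``; ``motile`` is
    True for moving cells and False for spores; ``spore_count`` caches the
    per-site spore tally (redundant with position/motile but cheap to keep).
    """

    position: np.ndarray
    concentration: np.ndarray
    motile: np.ndarray
    spore_count: np.ndarray
    step: int = 0

    @property
    def n_cells(self) -> int:
        return self.position.size

    def copy(self) -> "TrackState":
        return TrackState(
            self.position.copy(),
            self.concentration.copy(),
            self.motile.copy(),
            self.spore_count.copy(),
            self.step,
        )


@dataclass(frozen=True)
class TrackResult:
    """End state of a completed run."""

    spore_count: np.ndarray
    steps_to_completion: int
    params: TrackParams


@dataclass(frozen=True)
class TrackSummary:
    void_fraction: float
    spore_count: np.ndarray = field(repr=False)
    max_cluster: int = 0
    mean_cluster: float = 0.0


def init_track(params: TrackParams, rng: np.random.Generator | None = None) -> TrackState:
    """Place all cells uniformly at random with uniform initial C-signal.

    Positions are i.i.d. uniform over the ring; initial concentrations are
    i.i.d. uniform on ``init_concentration_range`` (default [0, 0.5)).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n, L = params.n_cells, params.track_length
    lo, hi = params.init_concentration_range
    return TrackState(
        position=rng.integers(0, L, size=n),
        concentration=rng.uniform(lo, hi, size=n),
        motile=np.ones(n, dtype=bool),
        spore_count=np.zeros(L, dtype=np.int64),
    )


def attempt_pass(n_spores: int, P: float, rng: np.random.Generator) -> bool:
    """Decide whether a cell enters a site holding ``n_spores`` spores.

    The effective passing probability is ``P**n_spores`` (``P**0 == 1``:
    spore-free sites are always entered).
    """
    if n_spores < 0:
        raise ValueError("n_spores must be >= 0")
    if not 0.0 <= P <= 1.0:
        raise ValueError("P must lie in [0, 1]")
    if n_spores == 0:
        return True
    return bool(rng.random() < P**n_spores)


def _neighbor_mean_concentration(state: TrackState, L: int) -> np.ndarray:
    """Mean C-signal of motile cells one site ahead/behind each agent.

    Spores are excluded from the average (signaling requires movement); if the
    two neighbor sites hold no motile cell, the mean is 0.  Same-site cells do
    not contribute.
    """
    pos = state.position[state.motile]
    conc = state.concentration[state.motile]
    csum = np.bincount(pos, weights=conc, minlength=L)
    cnum = np.bincount(pos, minlength=L).astype(float)
    ahead = (state.position + 1) % L
    behind = (state.position - 1) % L
    total = csum[ahead] + csum[behind]
    count = cnum[ahead] + cnum[behind]
    with np.errstate(invalid="ignore"):
        cbar = np.where(count > 0, total / np.maximum(count, 1.0), 0.0)
    return cbar


def update_signals(state: TrackState, params: TrackParams) -> TrackState:
    """Apply one synchronous C-signal update to every motile cell.

    Each motile cell gains ``basal_increment + T * cbar`` where ``cbar`` is
    computed from pre-update concentrations.  Spores are untouched and no
    decrease is ever applied.
    """
    out = state.copy()
    cbar = _neighbor_mean_concentration(state, params.track_length)
    gain = params.basal_increment + params.transfer_rate * cbar
    out.concentration = np.where(state.motile, state.concentration + gain, state.concentration)
    return out


def _move_phase(state: TrackState, P: float, L: int, rng: np.random.Generator) -> None:
    """Advance every motile cell one site where the pass attempt succeeds.

    Spore occupancy is frozen during the phase (conversion happens later in
    the step), so per-agent outcomes are mutually independent and the update
    is computed for all agents at once.
    """
    motile = state.motile
    targets = (state.position[motile] + 1) % L
    n_spores = state.spore_count[targets]
    p_eff = np.power(float(P), n_spores.astype(float))  # P**0 == 1
    passed = rng.random(targets.size) < p_eff
    new_pos = state.position[motile]
    new_pos = np.where(passed, targets, new_pos)
    state.position[motile] = new_pos


def _convert_phase(state: TrackState, threshold: float) -> None:
    converts = state.motile & (state.concentration >= threshold)
    if converts.any():
        state.motile[converts] = False
        np.add.at(state.spore_count, state.position[converts], 1)


def step_track(
    state: TrackState, params: TrackParams, rng: np.random.Generator
) -> TrackState:
    """One full simulation step: move, signal, then convert; counter +1."""
    out = state.copy()
    if out.motile.any():
        _move_phase(out, params.passing_probability, params.track_length, rng)
        cbar = _neighbor_mean_concentration(out, params.track_length)
        gain = params.basal_increment + params.transfer_rate * cbar
        out.concentration = np.where(out.motile, out.concentration + gain, out.concentration)
        _convert_phase(out, params.spore_threshold)
    out.step += 1
    return out


def run_track(params: TrackParams, rng: np.random.Generator | None = None) -> TrackResult:
    """Run until every cell is a spore and return the final spore layout."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    state = init_track(params, rng)
    L, P, T = params.track_length, params.passing_probability, params.transfer_rate
    basal, threshold = params.basal_increment, params.spore_threshold
    step = 0
    # in-place loop (step_track copies; this is the same update sequence)
    while state.motile.any():
        _move_phase(state, P, L, rng)
        cbar = _neighbor_mean_concentration(state, L)
        state.concentration[state.motile] += basal + T * cbar[state.motile]
        _convert_phase(state, threshold)
        step += 1
        if step > params.max_steps:  # pragma: no cover - termination guarantee
            raise RuntimeError("track run exceeded its termination bound")
    return TrackResult(spore_count=state.spore_count, steps_to_completion=step, params=params)


def run_track_batch(
    params: TrackParams, reps: int, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Run ``reps`` independent replicates at once (vectorized across runs).

    Returns ``(spore_count, steps)`` with shapes ``(reps, L)`` and
    ``(reps,)``.  Statistically equivalent to ``reps`` calls of
    :func:`run_track`; used by :func:`sweep_track` to keep large parameter
    sweeps fast.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    R, N, L = reps, params.n_cells, params.track_length
    P, T = params.passing_probability, params.transfer_rate
    basal, threshold = params.basal_increment, params.spore_threshold
    lo, hi = params.init_concentration_range

    pos = rng.integers(0, L, size=(R, N))
    conc = rng.uniform(lo, hi, size=(R, N))
    motile = np.ones((R, N), dtype=bool)
    spore_flat = np.zeros(R * L, dtype=np.int64)
    steps = np.zeros(R, dtype=np.int64)
    offset = (np.arange(R) * L)[:, None]

    step = 0
    while motile.any():
        active = motile.any(axis=1)
        targets = (pos + 1) % L
        n_sp = spore_flat[offset + targets]
        passed = motile & (rng.random((R, N)) < np.power(float(P), n_sp.astype(float)))
        pos = np.where(passed, targets, pos)

        flat = (offset + pos).ravel()
        m = motile.ravel()
        csum = np.bincount(flat[m], weights=conc.ravel()[m], minlength=R * L)
        cnum = np.bincount(flat[m], minlength=R * L).astype(float)
        ahead = offset + (pos + 1) % L
        behind = offset + (pos - 1) % L
        total = csum[ahead] + csum[behind]
        count = cnum[ahead] + cnum[behind]
        cbar = np.where(count > 0, total / np.maximum(count, 1.0), 0.0)
        conc = np.where(motile, conc + basal + T * cbar, conc)

        converts = motile & (conc >= threshold)
        if converts.any():
            np.add.at(spore_flat, (offset + pos)[converts], 1)
            motile &= ~converts
        step += 1
        steps[active & ~motile.any(axis=1)] = step
        if step > params.max_steps:  # pragma: no cover - termination guarantee
            raise RuntimeError("track batch exceeded its termination bound")
    return spore_flat.reshape(R, L), steps


def track_summary(result: TrackResult) -> TrackSummary:
    """Void fraction and per-position cluster sizes of a completed run.

    A "cluster" is the number of spores accumulated at a single track
    position (sites are point-like; spores at one site sit side by side).
    """
    counts = result.spore_count
    occupied = counts > 0
    void_fraction = float((~occupied).sum() / counts.size)
    max_cluster = int(counts.max()) if counts.size else 0
    mean_cluster = float(counts[occupied].mean()) if occupied.any() else 0.0
    return TrackSummary(
        void_fraction=void_fraction,
        spore_count=counts,
        max_cluster=max_cluster,
        mean_cluster=mean_cluster,
    )


def _replicate_rows(
    P: float, T: float, reps: int, base: TrackParams, pair_index: int
) -> list[dict]:
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(base.seed, pair_index)))
    params = replace(base, passing_probability=float(P), transfer_rate=float(T))
    spores, steps = run_track_batch(params, reps, rng)
    rows = []
    for rep in range(reps):
        counts = spores[rep]
        occupied = counts > 0
        rows.append(
            {
                "P": float(P),
                "T": float(T),
                "rep": rep,
                "void_fraction": float((~occupied).sum() / counts.size),
                "max_cluster": int(counts.max()),
                "steps": int(steps[rep]),
            }
        )
    return rows


def sweep_track(
    P_grid: Sequence[float] = DEFAULT_P_GRID,
    T_grid: Sequence[float] = DEFAULT_T_GRID,
    reps: int = 100,
    base: TrackParams = TrackParams(),
    per_rep: bool = False,
) -> pd.DataFrame:
    """Void-fraction sweep over a (P, T) grid, ``reps`` runs per pair.

    Returns one row per (P, T) pair with the mean and standard deviation of
    the void fraction (``per_rep=True`` returns the raw per-replicate table
    instead).  Replicates use independent seeds derived from ``base.seed``
    and the pair/replicate indices, so the table is reproducible.
    """
    if len(P_grid) == 0 or len(T_grid) == 0:
        raise ValueError("P_grid and T_grid must be non-empty")
    rows: list[dict] = []
    pair_index = 0
    for T in T_grid:
        for P in P_grid:
            rows.extend(_replicate_rows(P, T, reps, base, pair_index))
            pair_index += 1
    raw = pd.DataFrame(rows)
    if per_rep:
        return raw
    agg = (
        raw.groupby(["P", "T"], sort=True)["void_fraction"]
        .agg(mean_void_fraction="mean", std_void_fraction="std")
        .reset_index()
    )
    agg["std_void_fraction"] = agg["std_void_fraction"].fillna(0.0)
    agg["max_cluster_median"] = (
        raw.groupby(["P", "T"], sort=True)["max_cluster"].median().to_numpy()
    )
    return agg
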