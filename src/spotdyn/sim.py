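"""Agent-based chemotaxis model with a density-dependent motility switch.

The model evolves N point agents on a periodic square pixel grid together
with a self-secreted chemoattractant field.  Motile agents perform Brownian
motion plus a receptor-law chemotactic drift up the attractant gradient.
Where the local attractant concentration exceeds a threshold ``c_star`` --
a proxy for high local cell density -- agents immobilize.  Immobilized
agents sit out a fixed refractory interval, then regain motility with a
constant per-step probability, and finally spend a gradient-blind interval
performing pure Brownian motion before normal chemotaxis resumes.  This
three-phase switch (fixed wait, stochastic release, blind walk) is what
lets dense aggregates shed cells, move, and merge instead of absorbing the
whole population.

Agents are stored structure-of-arrays (positions ``(N, 2)``, integer state
codes, per-agent state clocks) for vectorized stepping; the chemoattractant
lives on the same grid as the agents with unit pixel spacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

__all__ = [
    "MOTILE",
    "IMMOTILE_FIXED",
    "IMMOTILE_STOCHASTIC",
    "BLIND",
    "STATE_NAMES",
    "SimParams",
    "SimState",
    "chemotactic_drift",
    "update_field",
    "step_motility_state",
    "step_positions",
    "run_simulation",
    "motile_fraction",
    "calibrate_scales",
    "minutes_to_time_units",
]

# Motility-state codes.  The cycle is
# MOTILE -> IMMOTILE_FIXED -> IMMOTILE_STOCHASTIC -> BLIND -> MOTILE.
MOTILE = 0
IMMOTILE_FIXED = 1
IMMOTILE_STOCHASTIC = 2
BLIND = 3

STATE_NAMES = {
    MOTILE: "motile",
    IMMOTILE_FIXED: "immotile_fixed",
    IMMOTILE_STOCHASTIC: "immotile_stochastic",
    BLIND: "blind",
}


@dataclass(frozen=True)
class SimParams:
    """All constants governing one simulation run.

    Times are in internal time-units, lengths in pixels, concentrations in
    arbitrary units.  The control values reproduce aggregate formation with
    experiment-like relative aggregate size and spacing; the full-scale run
    uses ``n_agents=100_000`` on a 384 px grid to ``t_final=2000`` with
    ``dt=0.005``.

    Parameters
    ----------
    n_agents : int
        Number of agents; constant over a run (no growth or death).
    grid_size : int
        Pixels per side of the periodic square domain.
    dt : float
        Integration step, time-units.
    t_final : float
        Total simulated time, time-units.
    D_agent : float
        Agent diffusion coefficient, px^2 / time-unit.
    D_chem : float
        Chemoattractant diffusion coefficient, px^2 / time-unit.  Must
        satisfy the explicit-scheme stability bound ``D_chem * dt <= 0.25``.
    secretion_rate : float
        Attractant secreted per agent per time-unit (deposited into the
        agent's containing pixel).
    decay_rate : float
        First-order attractant decay rate, 1 / time-unit.
    chi0 : float
        Chemotactic sensitivity coefficient.
    c_half : float
        Receptor half-saturation concentration in the receptor-law drift.
    c_star : float
        Immobilization threshold concentration.
    t_refractory : float
        Fixed immotile interval after crossing the threshold (calibrated to
        3 min wall-clock at control scale).
    p_reactivate : float
        Per-step probability of leaving the stochastic immotile phase
        (calibrated so the expected stochastic wait is 30 min).
    t_blind : float
        Gradient-blind Brownian interval after reactivation (calibrated to
        15 min).
    r_agent : float
        Finite-size interaction radius, px; pairs closer than this receive
        a soft repulsive displacement.
    seed : int
        RNG seed; identical (params, seed) gives bit-identical runs.
    snapshot_every : int
        Steps between recorded snapshots.
    """

    n_agents: int = 100_000
    grid_size: int = 384
    dt: float = 0.005
    t_final: float = 2000.0
    D_agent: float = 0.3
    D_chem: float = 5.0
    secretion_rate: float = 1.0
    decay_rate: float = 0.2
    chi0: float = 12.0
    c_half: float = 4.0
    c_star: float = 10.0
    t_refractory: float = 0.6
    p_reactivate: float = 8.333333333333333e-4
    t_blind: float = 3.0
    r_agent: float = 0.3
    seed: int = 0
    snapshot_every: int = 200
    motility_switch: bool = True  # False disables immobilization entirely
    blind_phase: bool = True  # False skips the gradient-blind interval

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if self.grid_size < 4:
            raise ValueError("grid_size must be >= 4")
        for name in (
            "dt",
            "t_final",
            "D_agent",
            "D_chem",
            "secretion_rate",
            "decay_rate",
            "chi0",
            "c_half",
            "c_star",
            "t_refractory",
            "t_blind",
            "r_agent",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.dt == 0:
            raise ValueError("dt must be positive")
        if not 0.0 <= self.p_reactivate <= 1.0:
            raise ValueError("p_reactivate must lie in [0, 1]")
        if self.D_chem * self.dt > 0.25 + 1e-12:
            raise ValueError(
                "unstable field step: D_chem*dt = "
                f"{self.D_chem * self.dt:.4g} exceeds the stability bound 0.25"
            )
        if self.snapshot_every < 1:
            raise ValueError("snapshot_every must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_final / self.dt))


@dataclass
class SimState:
    """Agent population plus chemoattractant grid at one instant."""

    time: float
    positions: np.ndarray  # (N, 2) float, in [0, grid_size)
    states: np.ndarray  # (N,) int8 state codes
    clocks: np.ndarray  # (N,) float, time remaining in timed states
    field: np.ndarray  # (grid_size, grid_size) float, >= 0

    @property
    def n_agents(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "SimState":
        return SimState(
            self.time,
            self.positions.copy(),
            self.states.copy(),
            self.clocks.copy(),
            self.field.copy(),
        )


def chemotactic_drift(
    c_local: np.ndarray | float,
    grad_c: np.ndarray,
    params: SimParams,
) -> np.ndarray:
    """Receptor-law drift velocity ``chi0 * grad_c / (1 + c/c_half)^2``.

    Drift grows with the attractant gradient but saturates with absolute
    concentration, modeling receptor occupancy: its magnitude at fixed
    gradient is non-increasing in ``c_local``.

    ``grad_c`` may be a single 2-vector or an ``(N, 2)`` array with
    ``c_local`` a matching scalar or ``(N,)`` array.
    """
    c = np.asarray(c_local, dtype=float)
    if np.any(c < 0):
        raise ValueError("chemoattractant concentration must be non-negative")
    g = np.asarray(grad_c, dtype=float)
    sens = params.chi0 / (1.0 + c / params.c_half) ** 2
    return np.expand_dims(sens, -1) * g if g.ndim > 1 else sens * g


def update_field(
    field: np.ndarray, agent_positions: np.ndarray, params: SimParams
) -> np.ndarray:
    """One explicit step of the chemoattractant dynamics.

    Five-point-stencil diffusion with periodic wrap, then multiplicative
    decay ``(1 - decay_rate*dt)``, then ``secretion_rate*dt`` deposited into
    each agent's containing pixel.  With the stability bound satisfied the
    result is non-negative, and the total mass obeys
    ``total' = total*(1 - k*dt) + n_agents*s*dt`` exactly (periodic
    diffusion conserves mass).
    """
    c = np.asarray(field, dtype=float)
    lap = (
        np.roll(c, 1, axis=0)
        + np.roll(c, -1, axis=0)
        + np.roll(c, 1, axis=1)
        + np.roll(c, -1, axis=1)
        - 4.0 * c
    )
    out = (c + params.D_chem * params.dt * lap) * (1.0 - params.decay_rate * params.dt)
    if len(agent_positions):
        ix = np.floor(agent_positions[:, 0]).astype(np.intp) % params.grid_size
        iy = np.floor(agent_positions[:, 1]).astype(np.intp) % params.grid_size
        np.add.at(out, (ix, iy), params.secretion_rate * params.dt)
    return out


def _sample_bilinear(grid: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Bilinear interpolation with periodic wrap; grid values sit at pixel
    centers (i + 0.5, j + 0.5)."""
    coords = positions.T - 0.5
    return map_coordinates(grid, coords, order=1, mode="grid-wrap")


def _gradient_grids(field: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient on the periodic grid (unit spacing)."""
    gx = (np.roll(field, -1, axis=0) - np.roll(field, 1, axis=0)) / 2.0
    gy = (np.roll(field, -1, axis=1) - np.roll(field, 1, axis=1)) / 2.0
    return gx, gy


def sample_concentration(field: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Attractant concentration at off-lattice agent positions."""
    return _sample_bilinear(field, positions)


def sample_gradient(field: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Attractant gradient at agent positions: central differences on the
    grid, then bilinear interpolation."""
    gx, gy = _gradient_grids(field)
    return np.stack(
        [_sample_bilinear(gx, positions), _sample_bilinear(gy, positions)], axis=1
    )


def step_motility_state(
    states: np.ndarray,
    clocks: np.ndarray,
    c_local: np.ndarray,
    rng: np.random.Generator,
    params: SimParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance the motility state machine by one step (vectorized).

    Transitions, evaluated on the incoming state so an agent moves at most
    one phase per step:

    * MOTILE with ``c_local >= c_star``      -> IMMOTILE_FIXED (clock = t_refractory)
    * IMMOTILE_FIXED with expired clock      -> IMMOTILE_STOCHASTIC
    * IMMOTILE_STOCHASTIC, prob p_reactivate -> BLIND (clock = t_blind)
    * BLIND with expired clock               -> MOTILE

    A single uniform draw per agent is consumed every call regardless of
    state, keeping runs bit-reproducible independent of the state mix.
    """
    states = np.asarray(states).copy()
    clocks = np.asarray(clocks, dtype=float).copy()
    u = rng.random(states.shape[0])

    was_motile = states == MOTILE
    was_fixed = states == IMMOTILE_FIXED
    was_stoch = states == IMMOTILE_STOCHASTIC
    was_blind = states == BLIND

    clocks[was_fixed | was_blind] -= params.dt

    if params.motility_switch:
        immobilize = was_motile & (np.asarray(c_local) >= params.c_star)
        states[immobilize] = IMMOTILE_FIXED
        clocks[immobilize] = params.t_refractory

    release = was_fixed & (clocks <= 0)
    states[release] = IMMOTILE_STOCHASTIC

    reactivate = was_stoch & (u < params.p_reactivate)
    if params.blind_phase:
        states[reactivate] = BLIND
        clocks[reactivate] = params.t_blind
    else:
        states[reactivate] = MOTILE

    wake = was_blind & (clocks <= 0)
    states[wake] = MOTILE
    return states, clocks


def _soft_repulsion(
    positions: np.ndarray,
    movable: np.ndarray,
    params: SimParams,
) -> np.ndarray:
    """Finite-size correction: pairs closer than ``r_agent`` push apart by
    half the overlap each, applied only to agents that are free to move."""
    if params.r_agent <= 0 or positions.shape[0] < 2:
        return positions
    L = float(params.grid_size)
    tree = cKDTree(positions, boxsize=L)
    pairs = tree.query_pairs(params.r_agent, output_type="ndarray")
    if pairs.shape[0] == 0:
        return positions
    i, j = pairs[:, 0], pairs[:, 1]
    delta = positions[i] - positions[j]
    delta -= L * np.round(delta / L)  # minimum-image separation
    dist = np.hypot(delta[:, 0], delta[:, 1])
    ok = dist > 0  # coincident pairs have no defined direction; skip
    i, j, delta, dist = i[ok], j[ok], delta[ok], dist[ok]
    push = (0.5 * (params.r_agent - dist) / dist)[:, None] * delta
    disp = np.zeros_like(positions)
    np.add.at(disp, i, push)
    np.add.at(disp, j, -push)
    disp[~movable] = 0.0
    return (positions + disp) % L


def step_positions(
    positions: np.ndarray,
    states: np.ndarray,
    field: np.ndarray,
    rng: np.random.Generator,
    params: SimParams,
) -> np.ndarray:
    """Euler–Maruyama position update.

    MOTILE agents receive the chemotactic drift plus Brownian noise
    ``sqrt(2*D_agent*dt)`` per axis; BLIND agents the Brownian term only;
    immotile agents do not move.  A pairwise soft repulsion within
    ``r_agent`` is applied afterwards, and positions wrap periodically.

    One 2-vector normal draw per agent is consumed every call regardless of
    state, for reproducibility independent of the state mix.
    """
    positions = np.asarray(positions, dtype=float)
    states = np.asarray(states)
    L = float(params.grid_size)
    noise = rng.standard_normal(positions.shape)

    new = positions.copy()
    moving = (states == MOTILE) | (states == BLIND)
    sigma = np.sqrt(2.0 * params.D_agent * params.dt)
    new[moving] += sigma * noise[moving]

    motile = states == MOTILE
    if np.any(motile) and params.chi0 > 0:
        c = sample_concentration(field, positions[motile])
        grad = sample_gradient(field, positions[motile])
        new[motile] += chemotactic_drift(c, grad, params) * params.dt

    new %= L
    new = _soft_repulsion(new, moving, params)
    return new


def motile_fraction(states: np.ndarray) -> float:
    """Fraction of agents currently moving (MOTILE or BLIND)."""
    states = np.asarray(states)
    return float(np.mean((states == MOTILE) | (states == BLIND)))


def run_simulation(
    params: SimParams,
    sink: Callable[[SimState], None] | None = None,
) -> list[SimState]:
    """Run one simulation and return (and/or stream) snapshots.

    Initialization: agents uniform at random on the grid, all MOTILE, zero
    attractant field.  Each step applies, in order, the field update, the
    motility-state update, and the position update.  A snapshot is recorded
    at step 0, every ``snapshot_every`` steps, and at the final step.
    Identical (params, seed) produce bit-identical output.

    Parameters
    ----------
    sink
        Optional callback invoked with each snapshot as it is produced
        (e.g. an HDF5 writer); snapshots are also collected and returned.
    """
    rng = np.random.default_rng(params.seed)
    L = float(params.grid_size)
    positions = rng.uniform(0.0, L, size=(params.n_agents, 2))
    states = np.full(params.n_agents, MOTILE, dtype=np.int8)
    clocks = np.zeros(params.n_agents)
    field = np.zeros((params.grid_size, params.grid_size))

    snapshots: list[SimState] = []

    def emit(step: int) -> None:
        if not (np.all(np.isfinite(field)) and np.all(np.isfinite(positions))):
            raise FloatingPointError(
                f"non-finite state at step {step} (t={step * params.dt:.4g}); "
                "check diffusion stability and parameter magnitudes"
            )
        snap = SimState(
            time=step * params.dt,
            positions=positions.copy(),
            states=states.copy(),
            clocks=clocks.copy(),
            field=field.copy(),
        )
        snapshots.append(snap)
        if sink is not None:
            sink(snap)

    emit(0)
    n_steps = params.n_steps
    for step in range(1, n_steps + 1):
        field = update_field(field, positions, params)
        c_at = sample_concentration(field, positions)
        states, clocks = step_motility_state(states, clocks, c_at, rng, params)
        positions = step_positions(positions, states, field, rng, params)
        if step % params.snapshot_every == 0 or step == n_steps:
            emit(step)
    return snapshots


def minutes_to_time_units(minutes: float, hr_per_time_unit: float) -> float:
    """Convert a wall-clock interval in minutes to internal time-units."""
    if hr_per_time_unit <= 0:
        raise ValueError("hr_per_time_unit must be positive")
    return minutes / 60.0 / hr_per_time_unit


def calibrate_scales(
    snapshots: Sequence[SimState],
    reference_area_mm2: float,
    reference_speed_mm_hr: float,
    *,
    density_radius: float = 3.0,
    count_threshold: float = 40.0,
    min_area: int = 10,
) -> tuple[float, float]:
    """Fix physical units by matching aggregates and agent speeds.

    The spatial scale equates the mean segmented aggregate area (px^2,
    pooled over the given snapshots) with the reference experimental area:
    ``mm_per_px = sqrt(reference_area_mm2 / mean_area_px2)``.  The time
    scale equates the mean displacement-based speed of agents that are
    moving at both ends of a snapshot interval with the reference speed:
    ``hr_per_time_unit = mm_per_px * speed_px_per_tu / reference_speed``.

    Raises
    ------
    ValueError
        If no aggregates are segmented or no moving agents are found.
    """
    from .detect import local_density_map, segment_aggregates

    if len(snapshots) < 2:
        raise ValueError("calibration needs at least two snapshots")
    grid_size = snapshots[0].field.shape[0]

    areas: list[float] = []
    for snap in snapshots:
        dmap = local_density_map(snap.positions, density_radius, grid_size)
        for det in segment_aggregates(
            dmap, count_threshold=count_threshold, min_area=min_area
        ):
            areas.append(det.area)
    if not areas:
        raise ValueError("no aggregates segmented; cannot calibrate spatial scale")
    mm_per_px = float(np.sqrt(reference_area_mm2 / np.mean(areas)))

    speeds: list[float] = []
    L = float(grid_size)
    for a, b in zip(snapshots[:-1], snapshots[1:]):
        dt_snap = b.time - a.time
        if dt_snap <= 0:
            continue
        moving = ((a.states == MOTILE) | (a.states == BLIND)) & (
            (b.states == MOTILE) | (b.states == BLIND)
        )
        if not np.any(moving):
            continue
        delta = b.positions[moving] - a.positions[moving]
        delta -= L * np.round(delta / L)
        speeds.extend(np.hypot(delta[:, 0], delta[:, 1]) / dt_snap)
    if not speeds:
        raise ValueError("no moving agents found; cannot calibrate time scale")
    speed_px_per_tu = float(np.mean(speeds))
    if reference_speed_mm_hr <= 0:
        raise ValueError("reference speed must be positive")
    hr_per_time_unit = mm_per_px * speed_px_per_tu / reference_speed_mm_hr
    return mm_per_px, hr_per_time_unit
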