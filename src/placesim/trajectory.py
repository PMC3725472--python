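"""Movement simulation of the virtual rat.

Two regimes are supported.  *Random foraging* emulates a rat searching for
randomly scattered food: at each step a candidate turn is drawn uniformly
from ±``arc`` and blended with the current heading according to ``momentum``
(momentum 1 → perfectly straight paths, momentum 0 → fully random turns
within the arc).  *Waypoint following* emulates a rat trained on a fixed
route: the heading steers greedily toward the current waypoint (turn clipped
to ±``arc``) with optional positional noise for irregularity.

Guarantees, every step and both regimes: the emitted position is valid
(inside the enclosure, at least ``min_wall_dist`` from every wall), the
displacement is at most ``speed``, and the heading change is at most ``arc``.
Near walls the step direction is searched within the allowed turning cone,
the speed is reduced, and as a last resort the rat turns on the spot — it
never tunnels through or hugs a wall closer than the margin.

Angles at this interface are degrees (``arc``), matching the command-line
vocabulary; headings in :class:`AgentState` are radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .environment import FloorPlan, is_valid_position
from .errors import ParameterError, SimulationError

__all__ = [
    "AgentState",
    "MotionParams",
    "Path",
    "step_random",
    "step_path",
    "generate_trajectory",
    "initial_state",
]


@dataclass(frozen=True)
class AgentState:
    """Pose of the virtual rat: position (world units), heading (radians)."""

    pos: tuple[float, float]
    heading: float
    step_index: int = 0


@dataclass(frozen=True)
class MotionParams:
    """Statistical movement model.

    speed: world units per step.  momentum ∈ [0, 1]: weight of the previous
    direction when blending with the proposed turn; higher momentum gives
    straighter paths.  arc: maximal turn per step, degrees.  min_wall_dist:
    closest approach to any wall.  path_noise: std. dev. (world units) of the
    positional jitter in waypoint mode.
    """

    speed: float = 0.2
    momentum: float = 0.6
    arc: float = 60.0
    min_wall_dist: float = 1.0
    path_noise: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.momentum <= 1.0):
            raise ParameterError("momentum must lie in [0, 1]")
        if self.arc < 0:
            raise ParameterError("arc must be >= 0")
        if self.speed <= 0:
            raise ParameterError("speed must be > 0")


@dataclass(frozen=True)
class Path:
    """A waypoint route; with ``loop`` the route wraps around, otherwise the
    agent is reset to the first waypoint after reaching the last."""

    waypoints: tuple[tuple[float, float], ...]
    loop: bool = True
    current_target: int = 0
    best_dist: float = field(default=np.inf, compare=False)
    stalled_steps: int = field(default=0, compare=False)

    def __post_init__(self):
        if len(self.waypoints) < 2:
            raise ParameterError("a path needs at least 2 waypoints")

    @property
    def target(self) -> tuple[float, float]:
        return self.waypoints[self.current_target]


def _wrap(angle: float) -> float:
    """Wrap to (−π, π]."""
    return float((angle + np.pi) % (2 * np.pi) - np.pi)


def _unit(angle: float) -> np.ndarray:
    return np.array([np.cos(angle), np.sin(angle)])


def _candidate_offsets(arc_rad: float) -> list[float]:
    """Heading offsets searched when the straight proposal is blocked:
    alternating sides in steps of arc/8, never exceeding the turn bound."""
    offs = [0.0]
    for j in range(1, 9):
        offs.extend([j * arc_rad / 8, -j * arc_rad / 8])
    return offs


def _try_move(
    plan: FloorPlan,
    pos: np.ndarray,
    prev_heading: float,
    desired_heading: float,
    params: MotionParams,
    extra: np.ndarray | None = None,
) -> tuple[np.ndarray, float] | None:
    """Find a valid move near ``desired_heading`` within the turning cone.

    Tries the desired heading, then offsets up to ±arc from the *previous*
    heading, then the same sweep at halved speeds.  ``extra`` is an additive
    positional offset (path noise) dropped at reduced speeds.  Returns
    (new_pos, executed_heading) or None.
    """
    arc_rad = np.radians(params.arc)
    sweeps = _candidate_offsets(arc_rad)
    for speed, jitter in (
        (params.speed, extra),
        (params.speed, None),
        (params.speed / 2, None),
        (params.speed / 4, None),
    ):
        for off in sweeps:
            h = prev_heading + np.clip(
                _wrap(desired_heading + off - prev_heading), -arc_rad, arc_rad
            )
            cand = pos + speed * _unit(h)
            if jitter is not None:
                cand = cand + jitter
            if is_valid_position(plan, cand, params.min_wall_dist):
                return cand, float(_wrap(h))
        if arc_rad == 0:
            break  # no sweep possible; only speed reduction was available
    return None


def step_random(
    state: AgentState,
    params: MotionParams,
    plan: FloorPlan,
    rng: np.random.Generator,
) -> AgentState:
    """One random-foraging step.

    A turn u ~ Uniform(−arc, +arc) proposes heading h + u; the executed
    direction is the normalized blend momentum·dir(h) + (1−momentum)·dir(h+u),
    so the expected heading change in open space is zero and |Δheading| ≤ arc.
    """
    arc_rad = np.radians(params.arc)
    h = state.heading
    u = rng.uniform(-arc_rad, arc_rad) if arc_rad > 0 else 0.0
    blend = params.momentum * _unit(h) + (1 - params.momentum) * _unit(h + u)
    if np.linalg.norm(blend) < 1e-12:
        desired = h + u  # antipodal degenerate blend
    else:
        desired = float(np.arctan2(blend[1], blend[0]))
    pos = np.asarray(state.pos, dtype=float)
    move = _try_move(plan, pos, h, desired, params)
    if move is None:
        if arc_rad == 0:
            raise SimulationError(
                "agent is stuck facing a wall with arc = 0; no valid move "
                "exists (malformed plan or too-narrow passage)"
            )
        # turn on the spot, at most by arc, toward a random side
        side = 1.0 if rng.random() < 0.5 else -1.0
        return AgentState(tuple(pos), _wrap(h + side * arc_rad), state.step_index + 1)
    new_pos, new_h = move
    return AgentState(tuple(new_pos), new_h, state.step_index + 1)


def step_path(
    state: AgentState,
    path: Path,
    params: MotionParams,
    plan: FloorPlan,
    rng: np.random.Generator,
) -> tuple[AgentState, Path]:
    """One waypoint-following step.

    Steers toward the current waypoint with the turn clipped to ±arc and adds
    Gaussian positional noise of std. dev. ``path_noise``.  Within a capture
    radius of 2·speed the target advances; past the last waypoint the route
    wraps around if ``loop``, otherwise the agent is reset to the first
    waypoint.
    """
    pos = np.asarray(state.pos, dtype=float)
    wp = np.asarray(path.target, dtype=float)
    to_wp = wp - pos
    desired = float(np.arctan2(to_wp[1], to_wp[0]))
    noise = (
        rng.normal(0.0, params.path_noise, size=2)
        if params.path_noise > 0
        else None
    )
    move = _try_move(plan, pos, state.heading, desired, params, extra=noise)
    if move is None:
        new_pos, new_h = pos, state.heading
    else:
        new_pos, new_h = move
    new_state = AgentState(tuple(new_pos), new_h, state.step_index + 1)

    dist = float(np.linalg.norm(wp - np.asarray(new_pos)))
    capture = 2 * params.speed
    if dist <= capture:
        if path.current_target + 1 < len(path.waypoints):
            new_path = replace(
                path,
                current_target=path.current_target + 1,
                best_dist=np.inf,
                stalled_steps=0,
            )
        elif path.loop:
            new_path = replace(path, current_target=0, best_dist=np.inf, stalled_steps=0)
        else:
            # reset to the first waypoint and head for the second
            new_state = AgentState(path.waypoints[0], new_h, state.step_index + 1)
            new_path = replace(path, current_target=1, best_dist=np.inf, stalled_steps=0)
        return new_state, new_path

    # progress watchdog: a waypoint the agent cannot approach is an error
    if dist < path.best_dist - 1e-9:
        new_path = replace(path, best_dist=dist, stalled_steps=0)
    else:
        stalled = path.stalled_steps + 1
        if stalled > 500:
            raise SimulationError(
                f"waypoint {path.target} unreachable: no progress over "
                f"{stalled} steps"
            )
        new_path = replace(path, stalled_steps=stalled)
    return new_state, new_path


def initial_state(
    plan: FloorPlan, params: MotionParams, rng: np.random.Generator
) -> AgentState:
    """Uniform draw over valid positions (rejection sampling) with uniform
    heading."""
    x0, y0, x1, y1 = plan.bounds
    for _ in range(100_000):
        p = (rng.uniform(x0, x1), rng.uniform(y0, y1))
        if is_valid_position(plan, p, params.min_wall_dist):
            return AgentState(p, float(rng.uniform(-np.pi, np.pi)), 0)
    raise SimulationError(
        "could not find a valid start position; is the margin too large?"
    )


def generate_trajectory(
    plan: FloorPlan,
    params: MotionParams,
    n_steps: int,
    mode: str = "random",
    path: Path | None = None,
    seed: int = 0,
) -> list[AgentState]:
    """Seeded pose sequence of exactly ``n_steps`` states (start included).

    Identical seeds give bit-identical sequences.  In ``path`` mode the start
    is the first waypoint, headed toward the second.
    """
    if n_steps < 1:
        raise ParameterError("n_steps must be >= 1")
    if mode not in ("random", "path"):
        raise ParameterError(f"unknown mode {mode!r}")
    if mode == "path" and path is None:
        raise ParameterError("path mode requires a Path")
    rng = np.random.default_rng(seed)
    if mode == "path":
        for wp in path.waypoints:
            if not is_valid_position(plan, wp, params.min_wall_dist):
                raise ParameterError(f"waypoint {wp} is not a valid position")
        p0, p1 = np.asarray(path.waypoints[0]), np.asarray(path.waypoints[1])
        h0 = float(np.arctan2(*(p1 - p0)[::-1]))
        state = AgentState(tuple(p0), h0, 0)
        path = replace(path, current_target=1, best_dist=np.inf, stalled_steps=0)
    else:
        state = initial_state(plan, params, rng)
    states = [state]
    for _ in range(n_steps - 1):
        if mode == "random":
            state = step_random(state, params, plan, rng)
        else:
            state, path = step_path(state, path, params, plan, rng)
        states.append(state)
    return states


def poses_array(states: list[AgentState]) -> np.ndarray:
    """(T, 3) array of x, y, heading (radians)."""
    return np.array([(s.pos[0], s.pos[1], s.heading) for s in states])
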