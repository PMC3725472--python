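"""Probing a trained network over the enclosure.

Place-field rate maps: the enclosure is discretized into a grid of sample
positions; at every valid position the view is rendered looking in each of
eight compass directions (0°, 45°, …, 315°), the network responds with its
output signals, and per signal one map per direction plus the direction
average is recorded — the simulation analogue of a firing-rate map.  Cells
that fail the position-validity check are masked.

Head-direction tuning curves: per heading (equally spaced over 360°) each
signal's response is averaged over a seeded sample of valid positions,
giving response-vs-heading curves.

Because the ICA rotation leaves the sign of each signal arbitrary, every
signal is flipped (consistently across its nine maps) so that its spatial
maximum exceeds the magnitude of its minimum; plots are then comparable
across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .environment import FloorPlan, valid_mask
from .errors import ParameterError, StateError
from .hierarchy import Network, forward_batch
from .renderer import Frame, ViewParams, render_view
from .trajectory import AgentState

__all__ = [
    "RateMap",
    "TuningCurve",
    "DIRECTION_LABELS",
    "sample_place",
    "sample_head_direction",
    "directionality_score",
    "plot_maps",
]

#: The eight compass headings sampled for directional maps, degrees.
DIRECTIONS_DEG = np.arange(0.0, 360.0, 45.0)
DIRECTION_LABELS = [f"{int(d):03d}" for d in DIRECTIONS_DEG] + ["average"]


@dataclass
class RateMap:
    """One signal's mean response over a spatial grid.

    ``grid`` is (ny, nx) with NaN at masked (invalid) cells; ``mask`` is True
    where the cell is valid.  ``direction`` is a compass label ('000' … '315')
    or 'average'.  ``signal_index`` is 1-based, matching plot labels.
    """

    grid: np.ndarray
    mask: np.ndarray
    signal_index: int
    direction: str
    x: np.ndarray  # cell-center x coordinates (nx,)
    y: np.ndarray  # cell-center y coordinates (ny,)


@dataclass
class TuningCurve:
    """Mean response per heading for one signal (angles in degrees)."""

    angles: np.ndarray
    response: np.ndarray
    signal_index: int


def _sample_grid(
    plan: FloorPlan, spacing: float, margin: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if spacing <= 0:
        raise ParameterError("spacing must be > 0")
    x0, y0, x1, y1 = plan.bounds
    xs = np.arange(x0 + spacing / 2, x1, spacing)
    ys = np.arange(y0 + spacing / 2, y1, spacing)
    pts = np.stack(np.meshgrid(xs, ys), axis=-1)  # (ny, nx, 2)
    mask = valid_mask(plan, pts.reshape(-1, 2), margin).reshape(pts.shape[:2])
    return xs, ys, mask


def default_spacing(plan: FloorPlan) -> float:
    """1/20 of the enclosure's larger extent."""
    x0, y0, x1, y1 = plan.bounds
    return max(x1 - x0, y1 - y0) / 20.0


def sample_place(
    network: Network,
    plan: FloorPlan,
    view: ViewParams,
    spacing: float | None = None,
    margin: float = 1.0,
    signals: tuple[int, int] | None = None,
) -> list[RateMap]:
    """Record every signal at each valid grid position for the eight compass
    headings plus their average: (last−first+1) × 9 rate maps.

    ``signals`` is an inclusive 1-based (first, last) range; default all.
    Sampling does not modify the network.
    """
    if not network.fully_trained:
        raise StateError("network is not fully trained")
    if spacing is None:
        spacing = default_spacing(plan)
    xs, ys, mask = _sample_grid(plan, spacing, margin)
    ny, nx = mask.shape
    valid_idx = np.argwhere(mask)  # (P, 2) row, col
    frames = []
    headings = np.radians(DIRECTIONS_DEG)
    for r, c in valid_idx:
        pos = (float(xs[c]), float(ys[r]))
        for h in headings:
            frames.append(render_view(plan, AgentState(pos, float(h)), view).pixels)
    responses = forward_batch(network, np.array(frames))
    k = responses.shape[1]
    responses = responses.reshape(len(valid_idx), len(headings), k)

    first, last = signals if signals is not None else (1, k)
    if not (1 <= first <= last <= k):
        raise ParameterError(f"signal range must lie within 1..{k}")

    maps: list[RateMap] = []
    for sig in range(first - 1, last):
        grids = np.full((len(headings), ny, nx), np.nan)
        for d in range(len(headings)):
            grids[d][mask] = responses[:, d, sig]
        avg = np.full((ny, nx), np.nan)
        avg[mask] = responses[:, :, sig].mean(axis=1)
        # resolve the ICA/SFA sign ambiguity on the averaged map and apply
        # the same flip to all directional maps of this signal
        vals = avg[mask]
        if vals.size and (vals.max() < -vals.min()):
            grids = -grids
            avg = -avg
        for d, label in enumerate(DIRECTION_LABELS[:-1]):
            maps.append(RateMap(grids[d], mask, sig + 1, label, xs, ys))
        maps.append(RateMap(avg, mask, sig + 1, "average", xs, ys))
    return maps


def sample_head_direction(
    network: Network,
    plan: FloorPlan,
    view: ViewParams,
    n_angles: int = 36,
    n_positions: int = 50,
    margin: float = 1.0,
    seed: int = 0,
) -> list[TuningCurve]:
    """Average each signal's response over a seeded sample of valid positions,
    per heading: one tuning curve (length ``n_angles``) per signal."""
    if not network.fully_trained:
        raise StateError("network is not fully trained")
    if n_angles < 8:
        raise ParameterError("n_angles must be >= 8")
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = plan.bounds
    positions = []
    while len(positions) < n_positions:
        p = (rng.uniform(x0, x1), rng.uniform(y0, y1))
        if valid_mask(plan, np.array(p), margin):
            positions.append(p)
    angles_deg = np.arange(n_angles) * 360.0 / n_angles
    frames = []
    for a in np.radians(angles_deg):
        for pos in positions:
            frames.append(render_view(plan, AgentState(pos, float(a)), view).pixels)
    responses = forward_batch(network, np.array(frames))
    k = responses.shape[1]
    responses = responses.reshape(n_angles, n_positions, k).mean(axis=1)
    return [
        TuningCurve(angles_deg.copy(), responses[:, sig].copy(), sig + 1)
        for sig in range(k)
    ]


def directionality_score(maps: list[RateMap]) -> float:
    """Direction dependence of one signal's place code, in [0, 1].

    Takes that signal's eight directional maps plus the average and returns
    1 − min over directions of the Pearson correlation between directional
    and averaged map (masked cells excluded), clamped to [0, 1]: 0 means the
    code is perfectly direction-invariant.
    """
    avg = [m for m in maps if m.direction == "average"]
    dirs = [m for m in maps if m.direction != "average"]
    if len(avg) != 1 or len(dirs) != 8:
        raise ParameterError("expected 8 directional maps plus one average")
    a = avg[0]
    vals_a = a.grid[a.mask]
    if vals_a.std() == 0:
        raise ParameterError("constant averaged map: correlation undefined")
    rs = []
    for m in dirs:
        if not np.array_equal(m.mask, a.mask):
            raise ParameterError("maps do not share a sampling grid/mask")
        v = m.grid[m.mask]
        if v.std() == 0:
            raise ParameterError("constant directional map: correlation undefined")
        rs.append(float(np.corrcoef(v, vals_a)[0, 1]))
    return float(np.clip(1.0 - min(rs), 0.0, 1.0))


def plot_maps(
    maps: list[RateMap] | list[TuningCurve],
    out_dir: str | Path,
) -> list[Path]:
    """Write one PNG per rate map / tuning curve and return the manifest.

    Layout: ``<out_dir>/place/<direction>/sig_<k>.png`` for rate maps and
    ``<out_dir>/hd/sig_<k>.png`` for tuning curves; a ``manifest.txt`` with
    one path per line is written alongside.  Filenames are deterministic, so
    re-running overwrites in place.  Map color scales are per-map min–max.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    manifest: list[Path] = []
    for m in maps:
        if isinstance(m, RateMap):
            path = out_dir / "place" / m.direction / f"sig_{m.signal_index:02d}.png"
            path.parent.mkdir(parents=True, exist_ok=True)
            fig, ax = plt.subplots(figsize=(4, 4))
            masked = np.ma.masked_invalid(m.grid)
            ax.imshow(
                masked,
                origin="lower",
                extent=(m.x[0], m.x[-1], m.y[0], m.y[-1]),
                cmap="jet",
                interpolation="nearest",
            )
            ax.set_title(f"signal {m.signal_index} [{m.direction}]")
        else:
            path = out_dir / "hd" / f"sig_{m.signal_index:02d}.png"
            path.parent.mkdir(parents=True, exist_ok=True)
            fig, ax = plt.subplots(
                figsize=(4, 4), subplot_kw={"projection": "polar"}
            )
            theta = np.radians(np.append(m.angles, m.angles[0]))
            resp = np.append(m.response, m.response[0])
            ax.plot(theta, resp)
            ax.set_title(f"signal {m.signal_index} head direction")
        fig.savefig(path, dpi=80)
        plt.close(fig)
        manifest.append(path)
    (out_dir / "manifest.txt").write_text(
        "\n".join(str(p.relative_to(out_dir)) for p in manifest) + "\n"
    )
    return manifest
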