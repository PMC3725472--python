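"""Enclosure geometry: wall segments, floor-plan presets, raycast and
position-validity queries, and the wallcheck overview rendering.

The world is a continuous 2-D plane: origin at the lower-left of the plan's
bounding box, y pointing up, angles counter-clockwise from +x.  Angles are
radians internally and degrees at user interfaces.  An enclosure is a set of
textured vertical wall segments whose boundary forms one or more closed loops;
axis-aligned rectangular boxes can be added as obstacles and participate in
raycasting and validity exactly like walls.

The even-odd crossing rule over *all* segments (boundary plus obstacle groups,
each a closed loop) classifies a point as inside the navigable region iff a
ray from it crosses an odd number of segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FloorPlanError, GapWarning, ParameterError, RaycastError
from .textures import TextureRegistry

__all__ = [
    "WallSegment",
    "FloorPlan",
    "make_box",
    "make_circle",
    "make_star_maze",
    "load_floorplan",
    "ray_cast",
    "ray_cast_many",
    "is_valid_position",
    "valid_mask",
    "find_gaps",
    "render_wallcheck",
]

#: Endpoint coincidence tolerance for the closed-loop gap check (world units).
EPS_GAP = 1e-6

#: Default wall height (world units); free configuration, arbitrary units.
DEFAULT_WALL_HEIGHT = 2.0


@dataclass(frozen=True)
class WallSegment:
    """A textured vertical wall from p1 to p2 (world units)."""

    p1: tuple[float, float]
    p2: tuple[float, float]
    texture_id: str = "stripes_v"

    def __post_init__(self):
        if np.hypot(self.p2[0] - self.p1[0], self.p2[1] - self.p1[1]) == 0:
            raise ParameterError("wall segment endpoints must differ")

    @property
    def length(self) -> float:
        return float(np.hypot(self.p2[0] - self.p1[0], self.p2[1] - self.p1[1]))


class FloorPlan:
    """An enclosure: boundary segments plus optional obstacle boxes.

    ``segments`` is the ordered boundary; ``obstacles`` holds 4-segment groups
    for each rectangular box.  Geometry queries are vectorized over the union
    of both.
    """

    def __init__(
        self,
        segments: list[WallSegment],
        wall_height: float = DEFAULT_WALL_HEIGHT,
        registry: TextureRegistry | None = None,
    ):
        if not segments:
            raise FloorPlanError("floor plan has no wall segments")
        self.segments = list(segments)
        self.obstacles: list[list[WallSegment]] = []
        self.wall_height = float(wall_height)
        self.registry = registry if registry is not None else TextureRegistry()
        self._cache = None

    # -- construction -----------------------------------------------------

    def add_obstacle(self, x0: float, y0: float, x1: float, y1: float) -> None:
        """Add an axis-aligned rectangular box obstacle (must lie inside)."""
        if x1 <= x0 or y1 <= y0:
            raise ParameterError("obstacle must have positive extent")
        bx0, by0, bx1, by1 = self.bounds
        if not (bx0 <= x0 and x1 <= bx1 and by0 <= y0 and y1 <= by1):
            raise ParameterError("obstacle lies outside the floor-plan bounds")
        reg = self.registry
        n0 = len(self.all_segments)
        corners = [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]
        group = [
            WallSegment(corners[i], corners[(i + 1) % 4], reg.id_for_index(n0 + i))
            for i in range(4)
        ]
        self.obstacles.append(group)
        self._cache = None

    # -- derived geometry --------------------------------------------------

    @property
    def all_segments(self) -> list[WallSegment]:
        return self.segments + [s for g in self.obstacles for s in g]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the boundary segments."""
        pts = np.array([p for s in self.segments for p in (s.p1, s.p2)])
        return (
            float(pts[:, 0].min()),
            float(pts[:, 1].min()),
            float(pts[:, 0].max()),
            float(pts[:, 1].max()),
        )

    def _arrays(self):
        """Segment endpoints as arrays, cached: (a, d) with d = b − a."""
        if self._cache is None:
            segs = self.all_segments
            a = np.array([s.p1 for s in segs], dtype=float)
            b = np.array([s.p2 for s in segs], dtype=float)
            self._cache = (a, b - a, b)
        return self._cache

    def __len__(self) -> int:
        return len(self.all_segments)


# -- presets ---------------------------------------------------------------


def _close_loop(points: np.ndarray, registry: TextureRegistry) -> list[WallSegment]:
    n = len(points)
    return [
        WallSegment(
            tuple(points[i]), tuple(points[(i + 1) % n]), registry.id_for_index(i)
        )
        for i in range(n)
    ]


def make_box(
    width: float,
    height: float,
    wall_height: float = DEFAULT_WALL_HEIGHT,
    registry: TextureRegistry | None = None,
) -> FloorPlan:
    """Rectangular enclosure with corners (0, 0)–(width, height)."""
    if width <= 0 or height <= 0:
        raise ParameterError("box dimensions must be positive")
    reg = registry if registry is not None else TextureRegistry()
    pts = np.array([(0, 0), (width, 0), (width, height), (0, height)], dtype=float)
    return FloorPlan(_close_loop(pts, reg), wall_height, reg)


def make_circle(
    radius: float,
    n_segments: int = 36,
    wall_height: float = DEFAULT_WALL_HEIGHT,
    registry: TextureRegistry | None = None,
) -> FloorPlan:
    """Circular enclosure: a regular n-gon inscribed in the given radius,
    centered at (radius, radius) so the bounding box starts at the origin."""
    if radius <= 0:
        raise ParameterError("radius must be positive")
    if n_segments < 3:
        raise ParameterError("a circle maze needs at least 3 segments")
    reg = registry if registry is not None else TextureRegistry()
    ang = 2 * np.pi * np.arange(n_segments) / n_segments
    pts = radius + radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    return FloorPlan(_close_loop(pts, reg), wall_height, reg)


def make_star_maze(
    arms: int,
    arm_width: float,
    arm_length: float,
    center_radius: float,
    wall_height: float = DEFAULT_WALL_HEIGHT,
    registry: TextureRegistry | None = None,
) -> FloorPlan:
    """Radial-arm maze: ``arms`` equidistant arms of the given width and
    length radiating from a central region of the given radius.

    Each arm contributes two side walls and an end cap; adjacent arms are
    joined by one center wall, giving 4·arms segments in a single closed loop.
    """
    if arms < 3:
        raise ParameterError("a star maze needs at least 3 arms")
    if arm_width <= 0 or arm_length <= 0 or center_radius <= 0:
        raise ParameterError("star-maze dimensions must be positive")
    if arm_width / 2 >= center_radius:
        raise ParameterError("arm_width/2 must be smaller than center_radius")
    half_ang = np.arcsin((arm_width / 2) / center_radius)
    if half_ang >= np.pi / arms:
        raise ParameterError(
            f"adjacent arms overlap at the center: an arm of width {arm_width} "
            f"subtends ±{np.degrees(half_ang):.1f}° at radius {center_radius}, "
            f"but only ±{180 / arms:.1f}° is available per arm; reduce "
            "arm_width or increase center_radius"
        )
    reg = registry if registry is not None else TextureRegistry()
    shift = center_radius + arm_length  # keep all coordinates non-negative
    pts = []
    r_tip = center_radius + arm_length
    for i in range(arms):
        th = 2 * np.pi * i / arms
        v = np.array([np.cos(th), np.sin(th)])
        p = np.array([-v[1], v[0]])
        half = arm_width / 2
        # walk counter-clockwise: right base → right tip → left tip → left base
        pts.append(center_radius * v - half * p)
        pts.append(r_tip * v - half * p)
        pts.append(r_tip * v + half * p)
        pts.append(center_radius * v + half * p)
    pts = np.array(pts) + shift
    return FloorPlan(_close_loop(pts, reg), wall_height, reg)


# -- floor-plan files ------------------------------------------------------


def load_floorplan(
    path: str | Path,
    registry: TextureRegistry | None = None,
    wall_height: float = DEFAULT_WALL_HEIGHT,
) -> FloorPlan:
    """Read a plain-text floor plan: one wall segment per line.

    Dialect: ``x1 y1 x2 y2 [texture_name]``, whitespace-separated, ``#``
    starts a comment.  Unresolved texture names fall back to the registry
    default.  A gap check runs after parsing; an open loop produces a
    :class:`GapWarning` naming the dangling endpoints.
    """
    path = Path(path)
    reg = registry if registry is not None else TextureRegistry()
    segments = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (4, 5):
            raise FloorPlanError(
                f"{path.name}:{lineno}: expected 'x1 y1 x2 y2 [texture]', "
                f"got {raw!r}"
            )
        try:
            x1, y1, x2, y2 = (float(v) for v in parts[:4])
        except ValueError as exc:
            raise FloorPlanError(f"{path.name}:{lineno}: {exc}") from exc
        tex = parts[4] if len(parts) == 5 else reg.id_for_index(len(segments))
        if tex not in reg:
            tex = reg.default_id
        try:
            segments.append(WallSegment((x1, y1), (x2, y2), tex))
        except ParameterError as exc:
            raise FloorPlanError(f"{path.name}:{lineno}: {exc}") from exc
    if not segments:
        raise FloorPlanError(f"{path}: no wall segments found")
    plan = FloorPlan(segments, wall_height, reg)
    gaps = find_gaps(plan)
    if gaps:
        warnings.warn(
            "floor plan is not closed; dangling endpoints: "
            + ", ".join(f"({x:g}, {y:g})" for x, y in gaps),
            GapWarning,
            stacklevel=2,
        )
    return plan


def save_floorplan(plan: FloorPlan, path: str | Path) -> None:
    """Write a plan's boundary segments in the text dialect."""
    lines = ["# placesim floor plan: x1 y1 x2 y2 texture"]
    for s in plan.segments:
        lines.append(
            f"{s.p1[0]:g} {s.p1[1]:g} {s.p2[0]:g} {s.p2[1]:g} {s.texture_id}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def find_gaps(plan: FloorPlan) -> list[tuple[float, float]]:
    """Endpoints of boundary segments that do not pair up within EPS_GAP.

    In a closed plan every endpoint coincides with exactly one endpoint of
    another segment; unpaired endpoints are returned (empty list = closed).
    """
    pts = []
    for s in plan.segments:
        pts.append(s.p1)
        pts.append(s.p2)
    pts = np.array(pts, dtype=float)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    # endpoint i of segment k must match an endpoint of a *different* segment
    seg_of = np.arange(len(pts)) // 2
    same_seg = seg_of[:, None] == seg_of[None, :]
    matches = (d <= EPS_GAP) & ~same_seg
    dangling = [tuple(pts[i]) for i in range(len(pts)) if matches[i].sum() != 1]
    return dangling


# -- geometry queries ------------------------------------------------------


def ray_cast_many(
    plan: FloorPlan, origin: tuple[float, float], angles: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest wall intersections for many rays from one origin.

    Returns (distances, segment indices into ``plan.all_segments``, texture
    coordinates u ∈ [0, 1] along the hit segment).  Rays that hit nothing get
    distance inf and segment index −1.
    """
    a, d, _ = plan._arrays()
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    o = np.asarray(origin, dtype=float)
    r = np.stack([np.cos(angles), np.sin(angles)], axis=1)  # (R, 2)
    # solve o + t r = a + u d  per (ray, segment)
    ao = (a - o)[None, :, :]  # (1, S, 2)
    det = r[:, None, 0] * (-d[None, :, 1]) - r[:, None, 1] * (-d[None, :, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ao[:, :, 0] * (-d[None, :, 1]) - ao[:, :, 1] * (-d[None, :, 0])) / det
        u = (r[:, None, 0] * ao[:, :, 1] - r[:, None, 1] * ao[:, :, 0]) / det
    ok = (np.abs(det) > 1e-14) & (t > 1e-9) & (u >= -1e-12) & (u <= 1 + 1e-12)
    t = np.where(ok, t, np.inf)
    idx = np.argmin(t, axis=1)
    rows = np.arange(len(angles))
    dist = t[rows, idx]
    uu = np.clip(u[rows, idx], 0.0, 1.0)
    idx = np.where(np.isfinite(dist), idx, -1)
    return dist, idx, uu


def ray_cast(
    plan: FloorPlan, origin: tuple[float, float], angle: float
) -> tuple[float, WallSegment, float]:
    """Nearest intersection of one ray with the enclosure walls.

    Returns (distance, hit segment, u) where u is the normalized position of
    the hit along the segment.  The origin must lie strictly inside the
    enclosure; a ray escaping an open plan raises :class:`RaycastError`.
    """
    if not is_valid_position(plan, origin, margin=0.0):
        raise RaycastError(f"ray origin {origin} is not inside the enclosure")
    dist, idx, u = ray_cast_many(plan, origin, np.array([angle]))
    if idx[0] < 0:
        raise RaycastError(
            f"ray from {origin} at {np.degrees(angle):.1f}° hits no wall "
            "(open floor plan?)"
        )
    return float(dist[0]), plan.all_segments[int(idx[0])], float(u[0])


def _segment_distances(plan: FloorPlan, p: np.ndarray) -> np.ndarray:
    """Distance from points (..., 2) to every segment: (..., S)."""
    a, d, _ = plan._arrays()
    ap = p[..., None, :] - a  # (..., S, 2)
    denom = np.einsum("sk,sk->s", d, d)
    t = np.clip(np.einsum("...sk,sk->...s", ap, d) / denom, 0.0, 1.0)
    closest = a + t[..., None] * d
    return np.linalg.norm(p[..., None, :] - closest, axis=-1)


# fixed, slightly irrational probe direction: avoids vertex/parallel degeneracy
_PROBE = (np.cos(0.3891), np.sin(0.3891))


def _inside(plan: FloorPlan, p: np.ndarray) -> np.ndarray:
    """Even-odd rule over all segments for points (..., 2)."""
    a, d, _ = plan._arrays()
    r = np.asarray(_PROBE)
    ap = a - p[..., None, :]  # (..., S, 2)
    det = r[0] * (-d[:, 1]) - r[1] * (-d[:, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ap[..., 0] * (-d[:, 1]) - ap[..., 1] * (-d[:, 0])) / det
        u = (r[0] * ap[..., 1] - r[1] * ap[..., 0]) / det
    cross = (np.abs(det) > 1e-14) & (t > 0) & (u >= 0) & (u < 1)
    return cross.sum(axis=-1) % 2 == 1


def is_valid_position(
    plan: FloorPlan, p: tuple[float, float], margin: float = 0.0
) -> bool:
    """True iff ``p`` is inside the boundary, outside every obstacle, and at
    least ``margin`` away from every wall segment."""
    p = np.asarray(p, dtype=float)
    if not bool(_inside(plan, p)):
        return False
    if margin > 0:
        return bool(_segment_distances(plan, p).min() >= margin)
    return True


def valid_mask(plan: FloorPlan, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
    """Vectorized validity for an array of points (..., 2)."""
    points = np.asarray(points, dtype=float)
    ok = _inside(plan, points)
    if margin > 0:
        ok &= _segment_distances(plan, points).min(axis=-1) >= margin
    return ok


# -- wallcheck overview ----------------------------------------------------


def render_wallcheck(
    plan: FloorPlan,
    raster_overlay: bool = True,
    grid_spacing: float = 5.0,
    dpi: int = 100,
) -> np.ndarray:
    """Top-down overview of the floor plan as an RGB image.

    With ``raster_overlay`` a labeled coordinate grid at ``grid_spacing``
    world units is drawn so waypoint coordinates can be read off the image.
    Wall segments are drawn without antialiasing in pure black so the wall
    pixels are identical with and without the overlay; dangling endpoints of
    an open plan are marked with red circles.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    x0, y0, x1, y1 = plan.bounds
    pad = 0.05 * max(x1 - x0, y1 - y0, 1.0)
    fig, ax = plt.subplots(figsize=(6, 6), dpi=dpi)
    ax.set_xlim(x0 - pad, x1 + pad)
    ax.set_ylim(y0 - pad, y1 + pad)
    ax.set_aspect("equal")
    if raster_overlay:
        xt = np.arange(np.floor(x0), np.ceil(x1) + grid_spacing / 2, grid_spacing)
        yt = np.arange(np.floor(y0), np.ceil(y1) + grid_spacing / 2, grid_spacing)
        ax.set_xticks(xt)
        ax.set_yticks(yt)
        for x in xt:
            ax.axvline(x, color="0.8", lw=1, antialiased=False, zorder=0)
        for y in yt:
            ax.axhline(y, color="0.8", lw=1, antialiased=False, zorder=0)
    else:
        ax.set_xticks([])
        ax.set_yticks([])
    for s in plan.all_segments:
        ax.plot(
            [s.p1[0], s.p2[0]],
            [s.p1[1], s.p2[1]],
            color="black",
            lw=2,
            antialiased=False,
            solid_capstyle="projecting",
            zorder=3,
        )
    for gx, gy in find_gaps(plan):
        ax.plot(gx, gy, "o", mfc="none", mec="red", ms=12, mew=2, zorder=4)
    fig.canvas.draw()
    img = np.asarray(fig.canvas.buffer_rgba())[:, :, :3].copy()
    plt.close(fig)
    return img
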