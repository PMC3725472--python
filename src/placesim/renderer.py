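"""Rat's-eye panoramic rendering by software raycasting.

Each image column corresponds to one azimuth within the field of view; the
mapping uses W−1 equal divisions so both FoV edge rays are rendered:

    azimuth(c) = heading + fov/2 − c · fov/(W−1),  c = 0 .. W−1.

This is an equidistant-azimuth (cylindrical) projection — appropriate for the
rat's 320° panoramic field, where a planar perspective projection is not
defined.  Per column a single ray is cast; the hit wall occupies a vertical
pixel span proportional to wall_height/distance, centered on the horizon and
clamped to the frame, textured by nearest-neighbour sampling.  Pixels above
the wall are sky, below are floor, at fixed distinct gray levels.  Rendering
is deterministic: identical pose, plan and view parameters give bit-identical
frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environment import FloorPlan, ray_cast_many
from .errors import ParameterError, RaycastError
from .trajectory import AgentState

__all__ = ["ViewParams", "Frame", "render_view", "to_grayscale", "crop_center",
           "column_azimuths"]

SKY_LEVEL = 200
FLOOR_LEVEL = 40
#: World units of wall length covered by one horizontal texture repeat.
TEXTURE_WORLD_WIDTH = 2.0

#: Rat panoramic field of view (degrees) and the narrow digital-camera mode.
FOV_RAT = 320.0
FOV_CAMERA = 55.0


@dataclass(frozen=True)
class ViewParams:
    """Rendering geometry: field of view (degrees) and frame size."""

    fov: float = FOV_RAT
    width: int = 320
    height: int = 40
    color_mode: str = "grayscale"  # color | grayscale | both

    def __post_init__(self):
        if not (0 < self.fov <= 360):
            raise ParameterError("fov must lie in (0, 360]")
        if self.width < 4 or self.height < 2:
            raise ParameterError("frame must be at least 4x2 pixels")
        if self.color_mode not in ("color", "grayscale", "both"):
            raise ParameterError(f"unknown color mode {self.color_mode!r}")


@dataclass(frozen=True)
class Frame:
    """A rendered view: (H, W) or (H, W, 3) uint8 pixels plus the pose."""

    pixels: np.ndarray
    pos: tuple[float, float]
    heading: float

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]


def column_azimuths(view: ViewParams, heading: float = 0.0) -> np.ndarray:
    """World azimuth (radians) of each image column's ray, left to right."""
    fov = np.radians(view.fov)
    c = np.arange(view.width)
    return heading + fov / 2 - c * fov / (view.width - 1)


def render_view(
    plan: FloorPlan,
    state: AgentState,
    view: ViewParams,
    registry=None,
) -> Frame:
    """Render the panoramic view at a pose.

    ``registry`` defaults to the plan's own texture registry.  Returns a
    color frame for color mode and both, grayscale otherwise (grayscale is
    the luminance conversion of the color render, so the two modes are
    consistent).
    """
    reg = registry if registry is not None else plan.registry
    w, h = view.width, view.height
    az = column_azimuths(view, state.heading)
    dist, seg_idx, u = ray_cast_many(plan, state.pos, az)
    if np.any(seg_idx < 0):
        raise RaycastError(
            f"view from {state.pos} hits no wall in some direction "
            "(open floor plan?)"
        )
    segs = plan.all_segments
    img = np.empty((h, w, 3), dtype=np.uint8)
    horizon = h / 2.0
    wall_h = plan.wall_height
    half_span = (h * wall_h) / (2.0 * np.maximum(dist, 1e-9))
    top_f = horizon - half_span
    bot_f = horizon + half_span
    r0 = np.clip(np.floor(top_f).astype(int), 0, h)
    r1 = np.clip(np.ceil(bot_f).astype(int), 0, h)
    for c in range(w):
        seg = segs[int(seg_idx[c])]
        tex = reg.get(seg.texture_id)
        th, tw = tex.shape[:2]
        along = u[c] * seg.length
        tx = int(along / TEXTURE_WORLD_WIDTH * tw) % tw
        col = img[:, c, :]
        col[: r0[c]] = SKY_LEVEL
        col[r1[c]:] = FLOOR_LEVEL
        if r1[c] > r0[c]:
            rows = np.arange(r0[c], r1[c])
            frac = (rows + 0.5 - top_f[c]) / (bot_f[c] - top_f[c])
            ty = np.clip((frac * th).astype(int), 0, th - 1)
            col[r0[c]: r1[c]] = tex[ty, tx]
    frame = Frame(img, tuple(map(float, state.pos)), float(state.heading))
    if view.color_mode == "grayscale":
        return to_grayscale(frame)
    return frame


def render_sequence(
    plan: FloorPlan, states, view: ViewParams, registry=None
) -> np.ndarray:
    """Render a pose sequence into a (T, H, W[, 3]) uint8 frame stack — the
    network's training data."""
    return np.stack(
        [render_view(plan, s, view, registry).pixels for s in states]
    )


_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(frame: Frame) -> Frame:
    """Luminance conversion (ITU-R BT.601 weights); passthrough if already
    single-channel, hence idempotent."""
    if frame.pixels.ndim == 2:
        return frame
    gray = np.clip(frame.pixels.astype(float) @ _LUMA, 0, 255)
    return Frame(np.rint(gray).astype(np.uint8), frame.pos, frame.heading)


def crop_center(frame: Frame, out_w: int, out_h: int) -> Frame:
    """Centered crop; for odd remainders the extra pixel stays on the
    right/bottom.  Used to conform arbitrary image sequences (generic
    lower-layer training data) to the network's input size."""
    h, w = frame.pixels.shape[:2]
    if out_w > w or out_h > h:
        raise ParameterError(
            f"crop {out_w}x{out_h} exceeds image size {w}x{h}"
        )
    if out_w < 1 or out_h < 1:
        raise ParameterError("crop size must be positive")
    x0 = (w - out_w) // 2
    y0 = (h - out_h) // 2
    return Frame(
        frame.pixels[y0: y0 + out_h, x0: x0 + out_w].copy(),
        frame.pos,
        frame.heading,
    )
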