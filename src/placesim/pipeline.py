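"""Experiment pipeline I/O: the frame container, the key=value configuration
file, the recording stage outputs, and network (de)serialization.

The four pipeline stages (record → convert → train → sample) each consume
only the previous stage's declared outputs, so any stage can be re-run or
replaced in isolation:

* record: per-step PNG frames, a plain-text pose file, an experiment summary
  and a trajectory-overlay image;
* convert: one binary frame container per color mode (documented layout
  below) with a plain-text pose sidecar;
* train: a versioned network file (NumPy .npz archive, no pickling);
* sample: labeled plot directories plus a manifest.

Frame container layout: 8-byte magic ``b"PSFRAME1"``, then six little-endian
uint32 values — version, T (frame count), H, W, C (channels, 1 or 3), and the
color-mode tag (0 grayscale, 1 color) — followed by T·H·W·C bytes of
row-major uint8 pixels.  The header must match the payload size exactly.
"""

from __future__ import annotations

import dataclasses
import json
import struct
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, IntegrityError, ParameterError
from .hierarchy import Layer, LayerSpec, Network, SFANode
from .sfa import ICAModel, SFAModel

__all__ = [
    "ExperimentConfig",
    "load_config",
    "save_config",
    "write_container",
    "read_container",
    "write_pose_file",
    "read_pose_file",
    "save_network",
    "load_network",
    "load_waypoints",
]

MAGIC = b"PSFRAME1"
CONTAINER_VERSION = 1
NETWORK_FORMAT = "placesim-net-v1"

_MODE_TAGS = {"grayscale": 0, "color": 1}
_TAG_MODES = {v: k for k, v in _MODE_TAGS.items()}


# -- configuration ---------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Central configuration: the technical values that typically stay fixed
    across simulations, editable as a ``key = value`` text file."""

    speed: float = 0.2
    momentum: float = 0.6
    arc: float = 60.0
    min_wall_dist: float = 1.0
    path_noise: float = 0.5
    fov: float = 320.0
    frame_width: int = 320
    frame_height: int = 40
    color_mode: str = "grayscale"
    wall_height: float = 2.0
    spacing: float = 0.0          # 0 → 1/20 of the larger enclosure extent
    grid_spacing: float = 5.0     # wallcheck raster overlay
    batch_size: int = 10_000
    noise_sigma: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.color_mode not in ("color", "grayscale", "both"):
            raise ConfigurationError(f"unknown color_mode {self.color_mode!r}")


def load_config(path: str | Path, base: ExperimentConfig | None = None) -> ExperimentConfig:
    """Parse a key=value config file; every key is validated against the
    schema and unknown keys are errors."""
    cfg = dataclasses.replace(base) if base else ExperimentConfig()
    fields = {f.name: f.type for f in dataclasses.fields(ExperimentConfig)}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(
                f"{path}:{lineno}: expected 'key = value', got {raw!r}"
            )
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in fields:
            raise ConfigurationError(f"{path}:{lineno}: unknown key {key!r}")
        typ = fields[key]
        try:
            if typ in ("int", int):
                parsed = int(value)
            elif typ in ("float", float):
                parsed = float(value)
            else:
                parsed = value
        except ValueError as exc:
            raise ConfigurationError(f"{path}:{lineno}: {exc}") from exc
        setattr(cfg, key, parsed)
    cfg.__post_init__()
    return cfg


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    lines = ["# placesim configuration"]
    for f in dataclasses.fields(cfg):
        lines.append(f"{f.name} = {getattr(cfg, f.name)}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_waypoints(path: str | Path) -> list[tuple[float, float]]:
    """Waypoint file: one 'x y' pair per line, '#' comments."""
    pts = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ParameterError(f"{path}:{lineno}: expected 'x y', got {raw!r}")
        pts.append((float(parts[0]), float(parts[1])))
    if len(pts) < 2:
        raise ParameterError(f"{path}: a path needs at least 2 waypoints")
    return pts


# -- frame container -------------------------------------------------------


def write_container(path: str | Path, frames: np.ndarray, color_mode: str) -> None:
    """Write a (T, H, W) or (T, H, W, 3) uint8 frame stack as one binary
    container file."""
    frames = np.ascontiguousarray(frames, dtype=np.uint8)
    if frames.ndim == 3:
        t, h, w = frames.shape
        c = 1
    elif frames.ndim == 4 and frames.shape[3] == 3:
        t, h, w, c = frames.shape
    else:
        raise ParameterError("frames must be (T, H, W) or (T, H, W, 3) uint8")
    tag = _MODE_TAGS.get(color_mode)
    if tag is None:
        raise ParameterError(f"unknown color mode {color_mode!r}")
    header = MAGIC + struct.pack("<6I", CONTAINER_VERSION, t, h, w, c, tag)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(frames.tobytes())


def read_container(path: str | Path) -> tuple[np.ndarray, str]:
    """Read a frame container; returns (frames, color_mode).  A header that
    does not match the payload raises :class:`IntegrityError`."""
    data = Path(path).read_bytes()
    hdr_len = len(MAGIC) + struct.calcsize("<6I")
    if len(data) < hdr_len or data[: len(MAGIC)] != MAGIC:
        raise IntegrityError(f"{path}: not a placesim frame container")
    version, t, h, w, c, tag = struct.unpack(
        "<6I", data[len(MAGIC): hdr_len]
    )
    if version != CONTAINER_VERSION:
        raise IntegrityError(
            f"{path}: container version {version} not supported "
            f"(expected {CONTAINER_VERSION})"
        )
    expected = t * h * w * c
    payload = data[hdr_len:]
    if len(payload) != expected:
        raise IntegrityError(
            f"{path}: payload has {len(payload)} bytes, header declares "
            f"{expected} (truncated or corrupt file)"
        )
    frames = np.frombuffer(payload, dtype=np.uint8)
    shape = (t, h, w) if c == 1 else (t, h, w, c)
    return frames.reshape(shape).copy(), _TAG_MODES.get(tag, "grayscale")


def write_pose_file(path: str | Path, poses: np.ndarray) -> None:
    """Plain-text pose sidecar: one 'x y heading_deg' line per step."""
    lines = [
        f"{x:.10g} {y:.10g} {np.degrees(h):.10g}" for x, y, h in np.asarray(poses)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_pose_file(path: str | Path) -> np.ndarray:
    """(T, 3) array of x, y, heading (radians)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.strip():
            x, y, hdeg = (float(v) for v in line.split())
            rows.append((x, y, np.radians(hdeg)))
    return np.array(rows)


# -- network serialization -------------------------------------------------


def _model_meta(model: SFAModel) -> dict:
    return {
        "expansion": model.expansion,
        "noise_sigma": model.noise_sigma,
        "n_train": model.n_train,
        "input_dim": model.input_dim,
        "training_stats": model.training_stats,
    }


def save_network(network: Network, path: str | Path) -> None:
    """Write a trained (or partially trained) network as a versioned NumPy
    .npz archive; re-saving a loaded network is bit-identical."""
    meta = {
        "format": NETWORK_FORMAT,
        "input_w": network.input_w,
        "input_h": network.input_h,
        "layers": [
            {
                "spec": dataclasses.asdict(layer.spec),
                "trained": layer.trained,
                "frozen": layer.frozen,
                "nodes": [
                    {"stage1": _model_meta(n.stage1), "stage2": _model_meta(n.stage2)}
                    for n in layer.nodes
                ],
            }
            for layer in network.layers
        ],
        "ica": None
        if network.ica is None
        else {"converged": network.ica.converged, "n_iter": network.ica.n_iter},
        "meta": network.meta,
    }
    arrays = dict(sorted(network.state_arrays().items()))
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_network(path: str | Path) -> Network:
    """Load a network file written by :func:`save_network`."""
    try:
        with np.load(path, allow_pickle=False) as npz:
            data = {k: npz[k] for k in npz.files}
    except (OSError, ValueError, zipfile.BadZipFile, KeyError) as exc:
        raise IntegrityError(f"{path}: not a placesim network file ({exc})") from exc
    if "__meta__" not in data:
        raise IntegrityError(f"{path}: network file has no metadata record")
    meta = json.loads(bytes(data["__meta__"]).decode())
    if meta.get("format") != NETWORK_FORMAT:
        raise IntegrityError(
            f"{path}: incompatible network format {meta.get('format')!r} "
            f"(expected {NETWORK_FORMAT!r})"
        )
    specs = [LayerSpec(**_tupled(lm["spec"])) for lm in meta["layers"]]
    network = Network(meta["input_w"], meta["input_h"], specs)
    for layer, lm in zip(network.layers, meta["layers"]):
        layer.trained = lm["trained"]
        layer.frozen = lm["frozen"]
        li = network.layers.index(layer)
        for ni, nm in enumerate(lm["nodes"]):
            models = []
            for si, key in ((1, "stage1"), (2, "stage2")):
                pre = f"layer{li}/node{ni}/stage{si}"
                mm = nm[key]
                models.append(
                    SFAModel(
                        expansion=mm["expansion"],
                        exp_mean=data[f"{pre}/exp_mean"],
                        whitening=data[f"{pre}/whitening"],
                        sfa_vectors=data[f"{pre}/sfa_vectors"],
                        delta_values=data[f"{pre}/delta_values"],
                        noise_sigma=mm["noise_sigma"],
                        n_train=mm["n_train"],
                        input_dim=mm["input_dim"],
                        training_stats=mm.get("training_stats", {}),
                    )
                )
            layer.nodes.append(SFANode(*models))
    if meta["ica"] is not None:
        network.ica = ICAModel(
            rotation=data["ica/rotation"],
            converged=meta["ica"]["converged"],
            n_iter=meta["ica"]["n_iter"],
        )
    network.meta = meta["meta"]
    return network


def _tupled(spec_dict: dict) -> dict:
    out = dict(spec_dict)
    out["rf"] = tuple(out["rf"])
    out["stride"] = tuple(out["stride"])
    return out


# -- record / convert stages ----------------------------------------------


def plot_trajectory(plan, states, out_path: str | Path) -> None:
    """Overview image of the area covered by the rat: floor plan, the path
    as a dotted line, and the final pose as a red arrow."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    from .trajectory import poses_array

    poses = poses_array(states)
    fig, ax = plt.subplots(figsize=(6, 6))
    for s in plan.all_segments:
        ax.plot([s.p1[0], s.p2[0]], [s.p1[1], s.p2[1]], "k-", lw=2)
    ax.plot(poses[:, 0], poses[:, 1], "w.", ms=2, zorder=2)
    ax.plot(poses[:, 0], poses[:, 1], "-", color="0.6", lw=0.5, zorder=1)
    x, y, h = poses[-1]
    ax.annotate(
        "",
        xy=(x + np.cos(h), y + np.sin(h)),
        xytext=(x, y),
        arrowprops={"color": "red", "arrowstyle": "-|>", "lw": 2},
    )
    ax.set_aspect("equal")
    ax.set_facecolor("0.3")
    fig.savefig(out_path, dpi=90)
    plt.close(fig)


def record_experiment(
    plan,
    cfg: ExperimentConfig,
    n_steps: int,
    out_dir: str | Path,
    mode: str = "random",
    waypoints=None,
    loop: bool = True,
) -> Path:
    """The record stage: simulate, render, and write per-step images, the
    pose file, a summary, and the trajectory overview."""
    import imageio.v3 as iio

    from .renderer import ViewParams, render_view, to_grayscale
    from .trajectory import MotionParams, Path as WayPath, generate_trajectory, poses_array

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = MotionParams(
        speed=cfg.speed,
        momentum=cfg.momentum,
        arc=cfg.arc,
        min_wall_dist=cfg.min_wall_dist,
        path_noise=cfg.path_noise,
    )
    way = WayPath(tuple(waypoints), loop=loop) if waypoints else None
    states = generate_trajectory(plan, params, n_steps, mode, way, cfg.seed)
    view = ViewParams(cfg.fov, cfg.frame_width, cfg.frame_height, "color")
    want_color = cfg.color_mode in ("color", "both")
    want_gray = cfg.color_mode in ("grayscale", "both")
    for sub, wanted in (("frames_color", want_color), ("frames_gray", want_gray)):
        if wanted:
            (out_dir / sub).mkdir(exist_ok=True)
    for i, state in enumerate(states):
        frame = render_view(plan, state, view)
        if want_color:
            iio.imwrite(out_dir / "frames_color" / f"frame_{i:06d}.png", frame.pixels)
        if want_gray:
            gray = to_grayscale(frame)
            iio.imwrite(out_dir / "frames_gray" / f"frame_{i:06d}.png", gray.pixels)
    write_pose_file(out_dir / "poses.txt", poses_array(states))
    plot_trajectory(plan, states, out_dir / "trajectory.png")
    summary = [
        "placesim experiment summary",
        f"steps = {n_steps}",
        f"mode = {mode}",
        f"loop = {loop}" if mode == "path" else "",
        f"color_mode = {cfg.color_mode}",
        f"fov = {cfg.fov}",
        f"frame = {cfg.frame_width}x{cfg.frame_height}",
        f"speed = {cfg.speed}  momentum = {cfg.momentum}  arc = {cfg.arc}",
        f"min_wall_dist = {cfg.min_wall_dist}  path_noise = {cfg.path_noise}",
        f"seed = {cfg.seed}",
        f"segments = {len(plan.all_segments)}",
    ]
    (out_dir / "experiment.txt").write_text(
        "\n".join(s for s in summary if s) + "\n"
    )
    return out_dir


def convert_directory(record_dir: str | Path) -> list[Path]:
    """The convert stage: collect each recorded image set into one frame
    container (plus pose sidecar); returns the container paths."""
    import imageio.v3 as iio

    record_dir = Path(record_dir)
    out_paths = []
    for sub, mode in (("frames_gray", "grayscale"), ("frames_color", "color")):
        d = record_dir / sub
        if not d.is_dir():
            continue
        files = sorted(d.glob("frame_*.png"))
        if not files:
            raise IntegrityError(f"{d}: no frames found")
        for i, f in enumerate(files):
            if f.name != f"frame_{i:06d}.png":
                raise IntegrityError(
                    f"{d}: frame index {i} is missing or misnamed "
                    f"(found {f.name})"
                )
        frames = np.stack([iio.imread(f) for f in files])
        out = record_dir / f"{sub}.dat"
        write_container(out, frames, mode)
        pose_src = record_dir / "poses.txt"
        if pose_src.exists():
            (record_dir / f"{sub}.pose.txt").write_text(pose_src.read_text())
        out_paths.append(out)
    if not out_paths:
        raise IntegrityError(f"{record_dir}: no recorded image sets found")
    return out_paths
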