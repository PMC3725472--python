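"""The layered SFA network with overlapping receptive fields and the
optional top ICA node.

A single SFA instance on full frames is computationally infeasible (the
quadratic expansion of a 320×40 image is enormous), so the network splits the
input among small nodes arranged in overlapping-receptive-field grids:

* layer 1: 63 × 9 nodes on the 320 × 40 pixel frame (rf 10 × 8, stride 5 × 4),
* layer 2: 8 × 2 nodes on the 63 × 9 grid of layer-1 outputs (rf 14 × 5,
  stride 7 × 4),
* layer 3: a single node integrating all sixteen layer-2 nodes,
* optionally an ICA node rotating the 32 top signals into a sparse code.

Every node has identical internals: a linear SFA reduction to 16 dimensions,
a quadratic expansion (16 → 152), and a second SFA step to 32 output signals.
Receptive fields tile their input exactly; layers are trained strictly bottom
up, each on the propagated outputs of the previous one, with moment statistics
accumulated over batches (the whole sequence is treated as one continuous
recording, so the result is independent of the batch size).

A reduced architecture (input 64 × 16, grids 12 × 3 / 3 × 1 / 1) with the same
node internals is provided for fast experiments and tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ParameterError, StateError
from .sfa import (
    ICAModel,
    SFAModel,
    SFATrainer,
    apply_ica,
    apply_sfa,
    fit_ica,
)

__all__ = [
    "LayerSpec",
    "SFANode",
    "Layer",
    "Network",
    "tile",
    "default_architecture",
    "reduced_architecture",
    "train",
    "train_generic",
    "train_top",
    "add_ica",
    "forward",
    "forward_batch",
]

log = logging.getLogger("placesim")

STAGE1_DIM = 16
PER_NODE_OUT = 32


def tile(
    input_w: int, input_h: int, rf: tuple[int, int], stride: tuple[int, int]
) -> tuple[int, int]:
    """Grid dimensions (cols, rows) of receptive fields of size ``rf``
    (width, height) with the given (horizontal, vertical) stride; the tiling
    must cover the input exactly."""
    rf_w, rf_h = rf
    s_h, s_v = stride
    res_w = (input_w - rf_w) % s_h
    res_h = (input_h - rf_h) % s_v
    if res_w or res_h or rf_w > input_w or rf_h > input_h:
        raise ConfigurationError(
            f"receptive fields {rf} with stride {stride} do not tile "
            f"{input_w}x{input_h} exactly (residues {res_w}, {res_h})"
        )
    return (input_w - rf_w) // s_h + 1, (input_h - rf_h) // s_v + 1


@dataclass
class LayerSpec:
    """Geometry of one node layer over its input grid."""

    rf: tuple[int, int]       # (width, height) in input-grid units
    stride: tuple[int, int]   # (horizontal, vertical)
    cols: int
    rows: int
    per_node_out: int = PER_NODE_OUT
    stage1_dim: int = STAGE1_DIM

    @classmethod
    def for_input(
        cls,
        input_w: int,
        input_h: int,
        rf: tuple[int, int],
        stride: tuple[int, int],
        per_node_out: int = PER_NODE_OUT,
        stage1_dim: int = STAGE1_DIM,
    ) -> "LayerSpec":
        cols, rows = tile(input_w, input_h, rf, stride)
        return cls(rf, stride, cols, rows, per_node_out, stage1_dim)


@dataclass
class SFANode:
    """One network node: linear SFA reduction followed by quadratic SFA."""

    stage1: SFAModel
    stage2: SFAModel

    def apply(self, x: np.ndarray) -> np.ndarray:
        return apply_sfa(self.stage2, apply_sfa(self.stage1, x))

    @property
    def out_dim(self) -> int:
        return self.stage2.out_dim


@dataclass
class Layer:
    spec: LayerSpec
    nodes: list = field(default_factory=list)  # row-major list of SFANode
    trained: bool = False
    frozen: bool = False

    def node(self, row: int, col: int) -> SFANode:
        return self.nodes[row * self.spec.cols + col]


class Network:
    """The full hierarchy: layer specs, fitted node models, optional ICA."""

    def __init__(self, input_w: int, input_h: int, layers: list[LayerSpec]):
        self.input_w = int(input_w)
        self.input_h = int(input_h)
        self.layers = [Layer(spec) for spec in layers]
        self.ica: ICAModel | None = None
        self.meta: dict = {}

    @property
    def n_trained_layers(self) -> int:
        return sum(layer.trained for layer in self.layers)

    @property
    def fully_trained(self) -> bool:
        return all(layer.trained for layer in self.layers)

    @property
    def out_dim(self) -> int:
        if not self.layers[-1].trained:
            return self.layers[-1].spec.per_node_out
        return self.layers[-1].nodes[0].out_dim

    def grid_shapes(self) -> list[tuple[int, int]]:
        """(cols, rows) per layer."""
        return [(layer.spec.cols, layer.spec.rows) for layer in self.layers]

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All model matrices under stable keys (serialization, hashing)."""
        out: dict[str, np.ndarray] = {}
        for li, layer in enumerate(self.layers):
            for ni, node in enumerate(layer.nodes):
                for si, model in ((1, node.stage1), (2, node.stage2)):
                    pre = f"layer{li}/node{ni}/stage{si}"
                    out[f"{pre}/exp_mean"] = model.exp_mean
                    out[f"{pre}/whitening"] = model.whitening
                    out[f"{pre}/sfa_vectors"] = model.sfa_vectors
                    out[f"{pre}/delta_values"] = model.delta_values
        if self.ica is not None:
            out["ica/rotation"] = self.ica.rotation
        return out

    def parameter_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        arrays = self.state_arrays()
        for key in sorted(arrays):
            h.update(key.encode())
            h.update(np.ascontiguousarray(arrays[key]).tobytes())
        return h.hexdigest()


def default_architecture(input_w: int = 320, input_h: int = 40) -> Network:
    """The full-scale architecture: grids 63 × 9, 8 × 2, and a single top
    node, on 320 × 40 input frames (other input sizes must be tiled by the
    same receptive fields)."""
    specs = [
        LayerSpec.for_input(input_w, input_h, rf=(10, 8), stride=(5, 4)),
    ]
    l1 = specs[0]
    specs.append(LayerSpec.for_input(l1.cols, l1.rows, rf=(14, 5), stride=(7, 4)))
    l2 = specs[1]
    specs.append(
        LayerSpec.for_input(l2.cols, l2.rows, rf=(l2.cols, l2.rows), stride=(1, 1))
    )
    return Network(input_w, input_h, specs)


def reduced_architecture(input_w: int = 64, input_h: int = 16) -> Network:
    """Desk-scale architecture (grids 12 × 3, 3 × 1, 1) with the same node
    internals as the full network."""
    specs = [LayerSpec.for_input(input_w, input_h, rf=(9, 8), stride=(5, 4))]
    l1 = specs[0]
    specs.append(LayerSpec.for_input(l1.cols, l1.rows, rf=(4, 3), stride=(4, 1)))
    l2 = specs[1]
    specs.append(
        LayerSpec.for_input(l2.cols, l2.rows, rf=(l2.cols, l2.rows), stride=(1, 1))
    )
    return Network(input_w, input_h, specs)


# -- training --------------------------------------------------------------


def _as_float_frames(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames)
    if frames.dtype == np.uint8:
        frames = frames.astype(float) / 255.0
    return frames.astype(float, copy=False)


def _check_frames(network: Network, frames: np.ndarray) -> np.ndarray:
    frames = _as_float_frames(frames)
    if frames.ndim != 3:
        raise ConfigurationError(
            "frames must be a (T, H, W) grayscale array; convert color data "
            "with to_grayscale first"
        )
    t, h, w = frames.shape
    if (h, w) != (network.input_h, network.input_w):
        raise ConfigurationError(
            f"frame size {w}x{h} does not match network input "
            f"{network.input_w}x{network.input_h}"
        )
    return frames


def _batch_slices(t: int, batch_size: int) -> list[slice]:
    if batch_size < 2:
        raise ParameterError("batch_size must be >= 2")
    return [slice(i, min(i + batch_size, t)) for i in range(0, t, batch_size)]


def _node_input(data: np.ndarray, spec: LayerSpec, row: int, col: int) -> np.ndarray:
    """Receptive-field gather: (T, rf_h, rf_w, C) window flattened to 2-D."""
    rf_w, rf_h = spec.rf
    s_h, s_v = spec.stride
    r0, c0 = row * s_v, col * s_h
    win = data[:, r0: r0 + rf_h, c0: c0 + rf_w, :]
    return win.reshape(win.shape[0], -1)


def _train_layer(
    layer: Layer,
    data: np.ndarray,
    batches: list[slice],
    noise_sigma: float,
    seeds: np.random.SeedSequence,
) -> None:
    spec = layer.spec
    node_seeds = seeds.spawn(spec.rows * spec.cols)
    layer.nodes = []
    for row in range(spec.rows):
        for col in range(spec.cols):
            x = _node_input(data, spec, row, col)
            s1_seed, _ = node_seeds[row * spec.cols + col].spawn(2)
            t1 = SFATrainer(
                min(spec.stage1_dim, x.shape[1]), "none", noise_sigma, s1_seed
            )
            for b in batches:
                t1.partial_fit(x[b])
            stage1 = t1.finalize()
            y1 = apply_sfa(stage1, x)
            t2 = SFATrainer(spec.per_node_out, "quadratic", 0.0, 0)
            for b in batches:
                t2.partial_fit(y1[b])
            layer.nodes.append(SFANode(stage1, t2.finalize()))
    layer.trained = True


def _propagate_layer(layer: Layer, data: np.ndarray) -> np.ndarray:
    """Forward a whole sequence through one layer: (T, rows, cols, out)."""
    spec = layer.spec
    t = data.shape[0]
    out_dim = layer.nodes[0].out_dim
    out = np.empty((t, spec.rows, spec.cols, out_dim))
    for row in range(spec.rows):
        for col in range(spec.cols):
            node = layer.node(row, col)
            y = node.apply(_node_input(data, spec, row, col))
            if y.shape[1] != out_dim:  # rank-limited node: pad with zeros
                pad = np.zeros((t, out_dim - y.shape[1]))
                y = np.concatenate([y, pad], axis=1)
            out[:, row, col, :] = y
    return out


def _train_layers(
    network: Network,
    frames: np.ndarray,
    batch_size: int,
    noise_sigma: float,
    seed: int,
    first: int,
    last: int,
    with_ica: bool,
    ica_seed_offset: int = 10_000,
) -> Network:
    frames = _check_frames(network, frames)
    t = frames.shape[0]
    batches = _batch_slices(t, batch_size)
    root = np.random.SeedSequence(seed)
    layer_seeds = root.spawn(len(network.layers) + 1)
    data = frames[:, :, :, None]
    for li, layer in enumerate(network.layers):
        if li > last:
            break
        if li < first:
            if not layer.trained:
                raise StateError(f"layer {li + 1} must be trained first")
            data = _propagate_layer(layer, data)
            continue
        log.info(
            "training layer %d (%dx%d nodes) on %d frames in %d batches",
            li + 1, layer.spec.cols, layer.spec.rows, t, len(batches),
        )
        _train_layer(layer, data, batches, noise_sigma, layer_seeds[li])
        if li < last:
            data = _propagate_layer(layer, data)
    if with_ica:
        if not network.layers[-1].trained:
            raise StateError("cannot fit ICA before the top layer is trained")
        top = _propagate_layer(network.layers[-1], data)
        y = top.reshape(t, -1)
        log.info("fitting ICA rotation on %d signals", y.shape[1])
        network.ica = fit_ica(y, seed=layer_seeds[-1])
    network.meta.update(
        {
            "frames_seen": t,
            "batch_size": batch_size,
            "n_batches": len(batches),
            "noise_sigma": noise_sigma,
            "seed": seed,
            "with_ica": with_ica,
        }
    )
    return network


def train(
    network: Network,
    frames: np.ndarray,
    batch_size: int = 10_000,
    with_ica: bool = True,
    noise_sigma: float = 1e-4,
    seed: int = 0,
) -> Network:
    """Train all layers bottom-up on a (T, H, W) frame sequence, then
    optionally fit the top ICA rotation.  Deterministic for a given seed."""
    for layer in network.layers:
        if layer.frozen:
            raise StateError(
                "network has frozen layers; use train_top to fit the "
                "remaining layers"
            )
    return _train_layers(
        network, frames, batch_size, noise_sigma, seed,
        first=0, last=len(network.layers) - 1, with_ica=with_ica,
    )


def train_generic(
    network: Network,
    natural_frames: np.ndarray,
    batch_size: int = 10_000,
    noise_sigma: float = 1e-4,
    seed: int = 0,
) -> Network:
    """Train the lower layers (all but the top) on generic image statistics
    — e.g. natural-image sequences conformed with ``crop_center`` — and
    freeze them.  The top layer (and ICA) are then fitted per environment
    with :func:`train_top`."""
    _train_layers(
        network, natural_frames, batch_size, noise_sigma, seed,
        first=0, last=len(network.layers) - 2, with_ica=False,
    )
    for layer in network.layers[:-1]:
        layer.frozen = True
    return network


def train_top(
    network: Network,
    env_frames: np.ndarray,
    batch_size: int = 10_000,
    with_ica: bool = True,
    noise_sigma: float = 1e-4,
    seed: int = 0,
) -> Network:
    """Fit only the top layer (plus optional ICA) within one environment;
    lower (frozen) layers are untouched."""
    if not all(layer.trained for layer in network.layers[:-1]):
        raise StateError("lower layers are untrained; run train_generic first")
    network.ica = None
    return _train_layers(
        network, env_frames, batch_size, noise_sigma, seed,
        first=len(network.layers) - 1, last=len(network.layers) - 1,
        with_ica=with_ica,
    )


def add_ica(network: Network, frames: np.ndarray, seed: int = 0) -> Network:
    """Fit the missing ICA rotation on the top-node outputs of an already
    trained network; the SFA layers are not modified."""
    if not network.fully_trained:
        raise StateError("all SFA layers must be trained before adding ICA")
    if network.ica is not None:
        raise StateError("network already has an ICA layer")
    frames = _check_frames(network, frames)
    y = _sfa_outputs(network, frames)
    network.ica = fit_ica(y, seed=np.random.SeedSequence(seed).spawn(1)[0])
    network.meta["with_ica"] = True
    return network


# -- forward pass ----------------------------------------------------------


def _sfa_outputs(network: Network, frames: np.ndarray) -> np.ndarray:
    data = frames[:, :, :, None]
    for layer in network.layers:
        data = _propagate_layer(layer, data)
    return data.reshape(frames.shape[0], -1)


def forward_batch(network: Network, frames: np.ndarray) -> np.ndarray:
    """Network response for a (T, H, W) sequence: (T, 32) output signals
    (ICA-rotated when an ICA layer is present)."""
    if not network.fully_trained:
        raise StateError("network is not fully trained")
    frames = _check_frames(network, frames)
    y = _sfa_outputs(network, frames)
    if network.ica is not None:
        y = apply_ica(network.ica, y)
    return y


def forward(network: Network, frame) -> np.ndarray:
    """Response to a single frame (a Frame or (H, W) array): one 32-vector."""
    pixels = getattr(frame, "pixels", frame)
    pixels = np.asarray(pixels)
    if pixels.ndim == 3:
        from .renderer import Frame, to_grayscale

        pixels = to_grayscale(Frame(pixels, (0.0, 0.0), 0.0)).pixels
    return forward_batch(network, pixels[None])[0]
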