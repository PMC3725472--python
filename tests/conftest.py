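"""Shared fixtures.

The expensive end-to-end artifacts — an open-field-trained network and a
route-trained network, with their sampled rate maps — are built once per
session and shared by the hierarchy, sampling and acceptance tests.
"""

import numpy as np
import pytest
from hypothesis import settings

import placesim as ps
from placesim import hierarchy, sampling

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

#: Study conditions of the scaled open-field run: a 20,000-step random walk
#: in a 10x10 box rendered at 64x16, reduced architecture, fixed seed.
OPEN_FIELD = {
    "box": (10.0, 10.0),
    "n_steps": 20_000,
    "seed": 11,
    "train_seed": 12,
    "spacing": 0.5,
    "margin": 1.0,
}


@pytest.fixture(scope="session")
def box_plan():
    return ps.make_box(*OPEN_FIELD["box"])


@pytest.fixture(scope="session")
def reduced_view():
    return ps.ViewParams(320.0, 64, 16, "grayscale")


@pytest.fixture(scope="session")
def open_field_net(box_plan, reduced_view):
    """Reduced-architecture network trained on a 20,000-step random walk."""
    params = ps.MotionParams()
    states = ps.generate_trajectory(
        box_plan, params, OPEN_FIELD["n_steps"], seed=OPEN_FIELD["seed"]
    )
    frames = ps.render_sequence(box_plan, states, reduced_view)
    net = hierarchy.reduced_architecture()
    hierarchy.train(
        net, frames, batch_size=5_000, with_ica=True, noise_sigma=1e-4,
        seed=OPEN_FIELD["train_seed"],
    )
    return net


@pytest.fixture(scope="session")
def open_field_maps(open_field_net, box_plan, reduced_view):
    return sampling.sample_place(
        open_field_net, box_plan, reduced_view,
        spacing=OPEN_FIELD["spacing"], margin=OPEN_FIELD["margin"],
    )


@pytest.fixture(scope="session")
def route_net(box_plan, reduced_view):
    """Network trained on a one-way loop route through the same box: the
    stereotyped-path regime in which directional invariance is lost."""
    params = ps.MotionParams(path_noise=0.3)
    route = ps.Path(((3.0, 3.0), (7.0, 3.0), (7.0, 7.0), (3.0, 7.0)), loop=True)
    states = ps.generate_trajectory(
        box_plan, params, 12_000, mode="path", path=route, seed=21
    )
    frames = ps.render_sequence(box_plan, states, reduced_view)
    net = hierarchy.reduced_architecture()
    hierarchy.train(
        net, frames, batch_size=5_000, with_ica=True, noise_sigma=1e-4, seed=22
    )
    return net


@pytest.fixture(scope="session")
def route_maps(route_net, box_plan, reduced_view):
    return sampling.sample_place(
        route_net, box_plan, reduced_view,
        spacing=OPEN_FIELD["spacing"], margin=OPEN_FIELD["margin"],
    )


@pytest.fixture(scope="session")
def hd_net(box_plan, reduced_view):
    """Network trained under heading-dominated movement statistics: high
    momentum and small arc make heading the slowest variable, so the
    hierarchy learns head-direction rather than place tuning."""
    params = ps.MotionParams(speed=0.5, momentum=0.8, arc=30.0)
    states = ps.generate_trajectory(box_plan, params, 12_000, seed=41)
    frames = ps.render_sequence(box_plan, states, reduced_view)
    net = hierarchy.reduced_architecture()
    hierarchy.train(
        net, frames, batch_size=5_000, with_ica=True, noise_sigma=1e-4, seed=42
    )
    return net


def signal_maps(maps, signal):
    """The 8 directional maps plus average for one 1-based signal index."""
    return [m for m in maps if m.signal_index == signal]


@pytest.fixture(scope="session")
def smooth_frames():
    """Synthetic non-degenerate 16x8 'video': spatially smooth drifting
    patterns, rich enough for every receptive field to have full rank."""
    rng = np.random.default_rng(5)
    t, h, w = 1_500, 8, 16
    yy, xx = np.mgrid[0:h, 0:w]
    frames = np.zeros((t, h, w))
    phases = rng.uniform(0, 2 * np.pi, size=(6, 3))
    for kx, ky, ph in phases:
        speed = rng.uniform(0.02, 0.08)
        ang = np.outer(np.ones(t), kx * xx.ravel() + ky * yy.ravel())
        ang += (np.arange(t) * speed + ph)[:, None]
        frames += np.sin(ang).reshape(t, h, w)
    frames += 0.05 * rng.normal(size=frames.shape)
    frames -= frames.min()
    frames /= frames.max()
    return frames


def tiny_network(per_node_out=8, stage1_dim=8):
    """A 2-layer network over 16x8 input, cheap enough for exact-equality
    experiments."""
    l1 = hierarchy.LayerSpec.for_input(
        16, 8, rf=(8, 8), stride=(8, 1), per_node_out=per_node_out,
        stage1_dim=stage1_dim,
    )
    l2 = hierarchy.LayerSpec.for_input(
        l1.cols, l1.rows, rf=(l1.cols, l1.rows), stride=(1, 1),
        per_node_out=per_node_out, stage1_dim=stage1_dim,
    )
    return hierarchy.Network(16, 8, [l1, l2])
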