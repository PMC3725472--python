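"""Simulate the virtual rat's movement statistics.

A random-foraging walk (turns drawn within +-arc, blended by momentum) and a
waypoint-following run on a fixed route.  The printed statistics show the
contracts the simulation keeps: valid positions, bounded turns, and the
effect of momentum on path straightness.
"""

import numpy as np

import placesim as ps
from placesim.trajectory import poses_array

plan = ps.make_box(10, 10)

for momentum in (0.0, 0.6, 1.0):
    params = ps.MotionParams(speed=0.2, momentum=momentum, arc=60.0)
    states = ps.generate_trajectory(plan, params, 5000, seed=4)
    h = poses_array(states)[:, 2]
    turns = np.degrees((np.diff(h) + np.pi) % (2 * np.pi) - np.pi)
    print(f"momentum {momentum:.1f}: mean |turn| {np.abs(turns).mean():5.2f} deg, "
          f"max |turn| {np.abs(turns).max():5.2f} deg (bound 60)")

params = ps.MotionParams(speed=0.2, path_noise=0.3)
route = ps.Path(((3, 3), (7, 3), (7, 7), (3, 7)), loop=True)
states = ps.generate_trajectory(plan, params, 2000, mode="path", path=route,
                                seed=5)
pts = poses_array(states)[:, :2]
print(f"route run: {len(states)} steps, all positions valid:",
      bool(ps.valid_mask(plan, pts, params.min_wall_dist).all()))
# how often the rat comes close to each waypoint: a one-way loop circuit
for i, wp in enumerate(route.waypoints):
    visits = (np.linalg.norm(pts - wp, axis=1) < 0.5).sum()
    print(f"  waypoint {i} at {wp}: {visits} near-visits")
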