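"""Build enclosures, query their geometry, and write wallcheck overviews.

Shows the box / circle / star-maze presets, a raycast query (the rat's
distance to the wall in a given direction), and the validity test that keeps
the simulated animal a margin away from every wall.
"""

import numpy as np
import imageio.v3 as iio

import placesim as ps

box = ps.make_box(10, 10)
circle = ps.make_circle(5, n_segments=36)
star = ps.make_star_maze(5, 20, 80, 40)

for name, plan in [("box", box), ("circle", circle), ("star maze", star)]:
    gaps = ps.find_gaps(plan)
    print(f"{name:10s} {len(plan.all_segments):3d} wall segments, "
          f"bounds {plan.bounds}, closed loop: {not gaps}")

# Raycast from the box center: straight east hits the wall at 5 world units,
# the 45-degree diagonal at 5*sqrt(2).
for deg in (0, 45):
    d, seg, u = ps.ray_cast(box, (5, 5), np.radians(deg))
    print(f"ray at {deg:2d} deg: distance {d:.4f}, hit at u={u:.2f} "
          f"along a '{seg.texture_id}' wall")

# Validity: the rat is not allowed within min_wall_dist of a wall.
print("center valid at margin 1:", ps.is_valid_position(box, (5, 5), 1.0))
print("near-wall valid at margin 1:", ps.is_valid_position(box, (0.5, 5), 1.0))

# The wallcheck overview: one image with a labeled coordinate raster (used
# to read off waypoint coordinates) and one without.
iio.imwrite("wallcheck_raster.png", ps.render_wallcheck(star, True, 20.0))
iio.imwrite("wallcheck.png", ps.render_wallcheck(star, False))
print("wrote wallcheck.png and wallcheck_raster.png")
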