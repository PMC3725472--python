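"""Slow Feature Analysis on a toy nonlinear mixture.

Two sources — a slow and a fast sinusoid — are observed only through the
mixture (s1 + s2^2, s2).  Quadratic SFA recovers the slow source as its
slowest output, illustrating the optimisation: minimal Delta = <ydot^2>
under zero mean, unit variance, and decorrelation.
"""

import numpy as np

import placesim as ps

t = np.arange(3000)
s1 = np.sin(2 * np.pi * t / 3000)         # slow source
s2 = np.sin(2 * np.pi * 11 * t / 3000)    # 11x faster source
x = np.stack([s1 + s2**2, s2], axis=1)    # nonlinear mixture

model = ps.fit_sfa(x, out_dim=3, expansion="quadratic")
y = ps.apply_sfa(model, x)

print("Delta values (ascending, smaller = slower):",
      np.round(model.delta_values, 6))
print("constraints on training data:")
print("  max |mean|      ", f"{np.abs(y.mean(axis=0)).max():.2e}")
print("  max |var - 1|   ", f"{np.abs(y.var(axis=0) - 1).max():.2e}")
cov = np.cov(y.T, bias=True)
print("  max |off-diag|  ", f"{np.abs(cov - np.diag(np.diag(cov))).max():.2e}")
r = np.corrcoef(y[:, 0], s1)[0, 1]
print(f"|corr(slowest output, slow source)| = {abs(r):.4f} "
      "(the slow source is recovered)")

# the ICA rotation turns decorrelated signals into a sparse code
rng = np.random.default_rng(0)
lap = rng.laplace(size=(6000, 2))
lap = (lap - lap.mean(0)) / lap.std(0)
th = np.radians(30)
mixed = lap @ np.array([[np.cos(th), -np.sin(th)],
                        [np.sin(th), np.cos(th)]]).T
ica = ps.fit_ica(mixed, seed=0)
angle = -np.degrees(np.arctan2(ica.rotation[0, 1], ica.rotation[0, 0])) % 90
print(f"ICA recovered rotation angle {angle:.2f} deg (mixing was 30 deg; "
      "60 = -30 mod 90 undoes it)")
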