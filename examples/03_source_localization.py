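"""Plant a cortical source, project it to the scalp, and localize it.

Builds a three-concentric-spheres leadfield, places a 10 Hz dipole
under the montage, adds sensor noise at 10 dB, then runs REST
re-referencing and the evidence-optimized smoothness-prior inverse.
Prints the localization error and the free-energy trace length.
"""

import numpy as np

from oscillosource.inverse import rest_transform, solve_inverse
from oscillosource.synthdata import make_spherical_leadfield

lf = make_spherical_leadfield(n_sensors=32, n_vertices=300, seed=2)
geom = lf.geometry
rng = np.random.default_rng(0)
v_true = int(np.argmax(geom.vertex_positions[:, 2]))  # under the vertex

S = np.zeros((300, 250))
S[v_true] = np.sin(2 * np.pi * 10 * np.arange(250) / 1000.0)
clean = lf.L @ S
y = clean + clean.std() / 10**0.5 * rng.standard_normal(clean.shape)

y_rest = rest_transform(y, lf)
est = solve_inverse(y_rest, lf)
v_hat = int(np.argmax(np.mean(est.S**2, axis=1)))
err_cm = 100 * np.linalg.norm(geom.vertex_positions[v_hat]
                              - geom.vertex_positions[v_true])
print(f"true vertex {v_true}, estimated {v_hat}, "
      f"localization error {err_cm:.2f} cm")
print(f"free energy rose monotonically over {est.free_energy.size} "
      f"iterations: {bool(np.all(np.diff(est.free_energy) >= -1e-9))}")
print("errors below ~2 cm mean the smoothness prior found the right patch")
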