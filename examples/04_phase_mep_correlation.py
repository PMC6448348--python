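"""Link prestimulus phase to a per-trial response with cluster control.

Simulates trials whose alpha-band source phase at one prestimulus
sample determines a motor-evoked-potential-like response, runs the
full source-level analysis (REST -> inverse -> NA-EMD -> Hilbert
phase), and tests the phase-response correlation with a cluster
permutation test.  A significant cluster overlapping the construction
sample means the pipeline recovered the planted brain-behaviour link.
"""

import numpy as np

from oscillosource.pipeline import (PipelineConfig, make_simulation_setup,
                                    run_experimental_analysis)
from oscillosource.synthdata import SimulationConfig, assemble_trials

L_gen, L_rec, soi = make_simulation_setup(
    n_sensors=10, n_vertices_gen=120, n_vertices_rec=80, seed=3,
    roi_radius_m=0.03)
sim = SimulationConfig(soi_vertex=soi, distractor_spec=[], snr_db=10.0,
                       n_trials=24, fs=250.0, seed=8)
epochs, truths = assemble_trials(L_gen, sim)

rng = np.random.default_rng(9)
t0 = 125  # the sample whose alpha phase drives the response
mep = np.array([np.cos(t.phases[0, t0]) for t in truths]) \
    + 0.1 * rng.standard_normal(len(truths))

cfg = PipelineConfig(n_realizations=2, max_imfs=7, seed=12)
results = run_experimental_analysis(
    epochs, mep, L_rec, variant="1_source", cfg=cfg, n_perm=300,
    target_position=L_gen.geometry.vertex_positions[soi])

for band, res in results.items():
    sig = res.significant
    if sig:
        spans = [(min(c.members), max(c.members), c.p_value) for c in sig]
        print(f"{band:6s}: significant clusters {spans}")
    else:
        print(f"{band:6s}: no significant cluster")
print(f"(the planted dependence sits at sample {t0} in the alpha band; "
      "a neighbouring band can fire too when its selected IMF shares "
      "the oscillation)")
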