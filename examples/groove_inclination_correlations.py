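"""Correlate structural fluctuations with helix bending.

Generates a trajectory whose generator couples bending to the total
axial groove width and to base-pair inclination, then measures Pearson
correlations between each per-frame fluctuation (SD along the
conformation) and the frame bending angle. The planted structure gives
the characteristic hierarchy: total groove width correlates strongest,
major-only modestly, minor-only weakest; inclination sits near 0.4.
"""

import helixbend as hb

cfg = hb.GeneratorConfig(seed=11, n_frames=5000, n_bp=20, form_name="B",
                         true_P_nm=48.0, bulk_mM=0.0, ext_occupancy=0.0,
                         major_occupancy=0.0, minor_occupancy=0.0)
traj = hb.sample_trajectory(cfg)

rep = hb.correlate_with_bend(traj)
print("Pearson r of per-frame fluctuation vs bending angle:")
print(rep.table.to_string(index=False))

screen = hb.parameter_screen(traj)
strongest = screen.table.reindex(
    screen.table.r.abs().sort_values(ascending=False).index).head(4)
print("\nStrongest of the 16 structural observables:")
print(strongest.to_string(index=False))
print("\nMost base-pair parameters correlate weakly with bend; the")
print("fluctuations of total groove width and inclination stand out.")
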