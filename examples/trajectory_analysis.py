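"""Segment analysis of a surrogate simulation trajectory.

Generates a 20,000-frame discrete-WLC trajectory of a 20-bp A-form
duplex at the dsRNA / 150 mM NaCl reference stiffness, pools the bending
angles of all eligible 13-bp windows (terminal 3 bp excluded) and
recovers the persistence length from the pooled histogram.
"""

import helixbend as hb

P_true = hb.load_reference_values()["md_rna_nacl_150mM"]
cfg = hb.GeneratorConfig(seed=3, n_frames=20_000, n_bp=20, form_name="A",
                         true_P_nm=P_true, bulk_mM=0.0, ext_occupancy=0.0,
                         major_occupancy=0.0, minor_occupancy=0.0)
traj = hb.sample_trajectory(cfg)

ens = hb.collect_segments(traj, n_bp=13, exclude_terminal=3)
fit = hb.fit_P_from_pdf(hb.angle_histogram(ens), ens.segment_Lc_nm)

print(f"frames: {traj.n_frames}, windows/frame: {ens.source['n_windows']}, "
      f"angles pooled: {len(ens)}")
print(f"segment contour length (from measured rise): {ens.segment_Lc_nm:.3f} nm")
print(f"ground truth P: {P_true} nm; recovered: {fit.P_nm:.2f} +- {fit.P_se_nm:.2f} nm")
print("A 13-bp A-form window spans ~3.36 nm of contour, matching the")
print("11-bp B-form window used for dsDNA.")
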