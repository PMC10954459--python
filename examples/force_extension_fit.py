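"""Fit worm-like-chain parameters to a synthetic magnetic-tweezers record.

Generates ten noisy force-extension curves of a 13,751-bp dsDNA at
150 mM NaCl (ground-truth P = 47 nm, rise 0.34 nm/bp) and fits each in
log-force space. The mean fitted P should sit on the ground truth to a
few percent; the fitted contour length divided by the number of steps
recovers the per-bp rise.
"""

import numpy as np

import helixbend as hb

ref = hb.load_reference_values()
P_true = ref["mt_dna_nacl_150mM"]
n_bp = int(ref["construct_n_bp"])
Lc_true = ref["rise_dna"] * (n_bp - 1)
forces = np.geomspace(0.05, 30.0, 40)

fits = []
for seed in range(1, 11):
    curve = hb.synth_force_extension(P_true, Lc_true, forces, noise_x_nm=5.0,
                                     seed=seed, n_bp=n_bp)
    fits.append(hb.fit_force_extension(curve))

agg = hb.aggregate_condition(fits)
print(f"ground truth: P = {P_true} nm, rise = {ref['rise_dna']} nm/bp")
print(f"fitted:       P = {agg['P_nm']['mean']:.2f} +- {agg['P_nm']['se']:.2f} nm "
      f"(10 molecules)")
print(f"              rise = {agg['rise_nm_per_bp']['mean']:.4f} nm/bp")
print("The 5-nm extension noise is large per point but tiny relative to the")
print("~4600-nm contour, so the stiffness comes back to well under 5%.")
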