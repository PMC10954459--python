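{
  "comment": "Published reference values for dsRNA/dsDNA bending stiffness, used as ground truth for the synthetic-data generator. Keys: mt_* = magnetic-tweezers persistence lengths (nm), md_* = persistence lengths from all-atom simulation trajectories (nm), intrinsic_* = non-electrostatic (high-salt / neutral-backbone) persistence lengths (nm), rise_* = contour length per base pair (nm/bp), chargefrac_* = net bound cation charge fraction per nucleotide around phosphates, pel_* = electrostatic persistence length at 150 mM NaCl (nm), pnel_bj_* = non-electrostatic persistence length fitted with the Barrat-Joanny salt model (nm).",
  "mt_rna_nacl_150mM": 54.0,
  "mt_rna_nacl_4M": 41.0,
  "mt_dna_nacl_150mM": 47.0,
  "mt_dna_nacl_4M": 38.0,
  "mt_rna_licl_150mM": 53.0,
  "mt_rna_licl_6M": 38.0,
  "mt_dna_licl_150mM": 45.0,
  "mt_dna_licl_6M": 39.0,
  "md_rna_nacl_150mM": 55.0,
  "md_rna_nacl_4M": 40.0,
  "md_dna_nacl_150mM": 48.0,
  "md_dna_nacl_4M": 39.0,
  "md_rna_licl_150mM": 54.0,
  "md_rna_licl_6M": 39.0,
  "md_dna_licl_150mM": 46.0,
  "md_dna_licl_6M": 39.0,
  "intrinsic_rna": 39.0,
  "intrinsic_dna": 38.0,
  "rise_dna": 0.34,
  "rise_rna": 0.28,
  "chargefrac_rna_nacl_150mM": 0.24,
  "chargefrac_dna_nacl_150mM": 0.36,
  "chargefrac_rna_nacl_4M": 0.89,
  "chargefrac_dna_nacl_4M": 0.91,
  "pel_rna_nacl_150mM": 17.0,
  "pel_dna_nacl_150mM": 10.0,
  "pnel_bj_rna": 38.4,
  "pnel_bj_dna": 38.5,
  "construct_n_bp": 13751
}
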