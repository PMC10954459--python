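# helixbend

Bending-stiffness analysis of double-stranded RNA and DNA.

A-form dsRNA is visibly stiffer in bending than B-form dsDNA at
physiological salt, yet at very high monovalent salt (or with a
neutralized backbone) both converge to a similar *intrinsic* persistence
length of roughly 39 nm. `helixbend` implements the desk-scale analysis
machinery behind that comparison, for biophysicists working with
single-molecule stretching data or coarse duplex trajectories:

- **Worm-like-chain force–extension fitting.** Curves are fitted with
  the Marko–Siggia interpolation plus a seventh-order polynomial
  correction,

  `F = kBT/P [ 1/(4(1 − x/Lc)²) − 1/4 + x/Lc + Σᵢ₌₂⁷ αᵢ (x/Lc)ⁱ ]`,

  minimizing squared residuals of log F, returning the persistence
  length `P` and contour length `Lc` per molecule with per-condition
  aggregation.
- **Persistence length from bending-angle distributions.** Segment
  bending angles θ (between the tangents of the two end base steps)
  pooled over trajectory frames are histogrammed in 0.5° bins and fitted
  with `−ln(p(θ)/sin θ) = Pθ²/2Lc`; the equivalent bending-energy route
  `ΔE_bend(θ)/kBT = Pθ²/2Lc` is provided as a cross-check.
- **Ion binding-shell classification.** Ions within a helical (axis)
  distance of 8.5 Å inside a groove sector are *internal* (major/minor);
  remaining ions within 6 Å of a phosphate are *external*; grooves take
  precedence. Net bound cation-over-anion charge per nucleotide measures
  backbone neutralization.
- **Electrostatic / intrinsic decomposition.** A screened-Coulomb
  (Debye–Hückel) model gives the electrostatic bending energy
  `ΔE_el(θ) = E_el(θ) − E_el(0)`; `ΔE_nel = ΔE_bend − ΔE_el`, and
  quadratic fits convert each profile to `P`, `P_el`, `P_nel` with
  `P = P_el + P_nel`.
- **Groove and inclination geometry.** Axial major/minor groove widths
  (D, d) from backbone crossings, base-pair inclination, per-frame
  fluctuations along the conformation, and Pearson correlations with
  the bending angle (including a 16-observable base-pair-parameter
  screen).
- **Salt-dependence models.** OSF (`P = P_nel + l_B/4κ²b²`, ∝ 1/c) and
  BJ (`P = P_nel + A·κ⁻¹`, ∝ c^(−1/2)) fits with RSS model comparison.
- **A seeded synthetic-data generator** standing in for the instrument
  and the simulation engine: WLC angle ensembles, noisy force–extension
  records, idealized A/B-form helices with controllable bends, groove
  widths, inclinations and ion occupancies.

## Worked example

```python
import helixbend as hb

P_true = hb.load_reference_values()["md_rna_nacl_150mM"]   # 55 nm
ens  = hb.sample_wlc_angles(P_true, Lc_nm=3.3, n=200_000, seed=7)
hist = hb.angle_histogram(ens, bin_width_deg=0.5)
fit  = hb.fit_P_from_pdf(hist, 3.3)
print(fit.P_nm, fit.P_se_nm)
```

prints

```
54.88 0.13
```

— 2×10⁵ worm-like-chain bending angles for 3.3-nm segments were sampled
at a ground-truth persistence length of 55 nm (the dsRNA value at 150 mM
NaCl), and the distribution fit recovers 54.9 ± 0.1 nm. The
`examples/` directory has one short script per capability
(force–extension fitting, trajectory segment analysis, ion shells,
energy decomposition, groove/inclination correlations, salt-model
fits), each printing the numbers it computes and what they mean.

A thin CLI wraps the same calls:

```sh
helixbend simulate --config cfg.json --out out/
helixbend bend out/trajectory.pdb --nbp 13 --out ensemble.csv
helixbend run --seed 1 --out report/
```

`helixbend run` chains all stages over a salt series and writes CSV
tables (fitted P per condition, shell charge fractions, fluctuation
correlations, energy decomposition, OSF/BJ fits) plus a manifest of
every parameter and seed.

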