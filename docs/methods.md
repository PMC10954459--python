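# Methods

This note documents the models, conventions and design choices behind
`helixbend`: what each estimator computes, what the synthetic-data
generator does and does not emulate, and the numerical details a user
would need to reproduce or modify an analysis.

Internal units throughout: lengths in nm, angles in degrees at
interfaces (radians inside harmonic fits), energies in kBT, charges in
e, forces in pN, concentrations in mM. kBT = 4.114 pN·nm at 298 K,
scaled linearly in T; force–extension records default to 295 K (22 °C,
the usual tweezers bench temperature).

## Force–extension model and fit

The force of a stretched worm-like chain is evaluated with the
Marko–Siggia interpolation plus the standard seventh-order polynomial
correction (coefficients α₂…α₇ of Bouchiat et al., stored as a named
constant set; the all-zero set recovers the bare interpolation and is
available for comparison). The fit minimizes Σ(log F_obs − log
F_model(x_obs))² over (P, Lc) with bounded nonlinear least squares
(`scipy.optimize.least_squares`), initial guess P = 50 nm, Lc = 1.05 ×
max(x), and Lc constrained above the largest observed extension.
Fitting log-force weights the low-force plateau properly — a plain
least-squares fit in F would be dominated by the stiff high-force
points. Standard errors are asymptotic (from the Jacobian at the
optimum). Synthetic curves use a 0.05–30 pN force window, 40
log-spaced points, and Gaussian extension noise (default σ = 5 nm —
large per point, but small against a multi-μm construct); points
outside a 0.01–50 pN validity window are flagged, not silently used.

## Persistence length from bending angles

A segment's bending angle is the angle between the tangents of its two
*end base steps*. For coarse frames whose base-pair reference points
lie on the local axis by construction, tangents are raw normalized
differences of consecutive reference points; no smoothing is applied by
default (`smooth_bp=1`). A 3-bp moving-average axis (`central_axis`,
`smooth_bp=3`) is available for noisy reference points; smoothing
shortens the effective tangent separation and would bias P upward by a
few percent on these frames, which is why extraction defaults to the
unsmoothed axis.

Angles from all eligible windows (13 bp for A-form, 11 bp for B-form —
both ≈ 3.3–3.4 nm of contour — excluding 3 terminal base pairs at each
end) are pooled over frames and histogrammed in 0.5° bins. The fit
regresses −ln(p/sin θ) on θ²/2Lc (θ in radians) by weighted least
squares with bin counts as weights, over bins with ≥ 20 counts and
below the 99th count percentile (log-of-small-count noise otherwise
dominates the tail). The regression carries a free intercept that
absorbs the normalization constant of p; a no-intercept variant is
available via `intercept=False`. The segment contour length is the
trajectory's own mean rise × (window − 1), not the nominal form value.
The bending-energy route (quadratic fit of ΔE(θ)/kBT = −ln(p/sin θ),
minimum shifted to zero over populated bins, empty bins masked) is the
same regression up to a constant and returns identical P on identical
grids — kept as an explicit cross-check because the two routes are
conventionally reported separately.

## Synthetic trajectories: what is emulated

Each frame is an independent draw of a *discrete worm-like chain*:
consecutive step tangents differ by a random junction bend drawn (by
4096-point inverse-CDF sampling) from p(β) ∝ sin β·exp(−Pβ²/2h) at
contour step h = rise, in a uniform random azimuth, with the material
frame twisted by the form's helical twist per step.

One deliberate calibration: an m-bp window contains m−2 junctions, while
the conventional window contour length is (m−1)·h. The generator
therefore adds an independent half-step tangent wobble to every base
step (per-component variance h/2P), making the end-step angle variance
exactly 2h(m−1)/P for *every* window length simultaneously. Without it,
fitted P would be biased by (m−1)/(m−2) ≈ +11% for 11-bp windows.

Ideal-helix constants (generator fixtures, not measured claims): A-form
rise 0.28 nm, twist 32.7°, inclination +17°, minor-groove pitch fraction
0.55; B-form rise 0.34 nm, twist 34.3°, inclination −1°, fraction 0.35;
phosphate radius 1.0 nm for both. Phosphates sit on two strands
separated azimuthally by the minor-groove gap (= 360° × minor
fraction), which fixes the axial groove widths of the ideal helix at
d = fraction × pitch, D = pitch − d.

Controlled bending (`bend_helix`) maps the helix onto a circular arc
whose curvature makes the end-step tangents subtend the requested
angle, with per-strand axial arc-length compensation so inter-phosphate
distances along each strand are preserved to ≪ 1% at 30°. A
single-step `kink` mode exists for constructing axis-kink fixtures; it
necessarily distorts the cross-kink backbone and is not the default.
(An early design applied the bend as a single kink by default; the
bond-geometry requirement ruled that out.)

Planted couplings — these emulate *observed* structure–bending
relationships that a coarse geometric model cannot produce from first
principles, and are explicit generator knobs:

- **Inclination–bend coupling.** Bending toward the major groove raises
  base-pair inclination at the pivot, toward the minor groove lowers it
  (linear coefficient, default 0.12°/° with 5° per-bp noise). In
  trajectories the coupling enters with a sinusoidal phase along the
  helix, so the per-frame inclination fluctuation grows with bend; the
  defaults put the Pearson correlation of inclination-fluctuation vs
  bend near 0.4, the observed scale.
- **Groove-width–bend coupling.** The per-step rise jitter amplitude
  (default 3%) grows with the frame bend (default +4 per radian), so
  the fluctuation of the *total* axial groove width tracks bending.
  An axial jitter on strand-0 phosphates (default 0.06 nm) shifts each
  position oppositely into d and D at exactly fixed total, which
  reproduces the observed hierarchy: total-width fluctuation correlates
  most strongly with bend, major-only modestly, minor-only weakest.
- **Ion–bend coupling** (off by default): external occupancy varying
  linearly with frame bend, for planted-signal tests of the
  bend-vs-binding analysis.

Ion placement: bound-cation counts per shell are Poisson with the
configured per-nucleotide occupancies; external ions sit 2.2–5 Å
outside a random phosphate pointing away from the axis (Li⁺ closer by a
configurable 0.5 Å — an affinity *parameter*, never derived), internal
ions inside the groove sector at < 8.5 Å axis distance; bulk ions are
uniform in a rectangular box with a 3-nm margin at the configured
concentration, with extra counterions added for exact box
electroneutrality whenever the duplex is charged. Nothing about water,
sequence, or ion–ion correlation is modeled.

What passing tests therefore show: the *estimators* are correct and
unbiased under the stated noise models and recover planted truths at
the stated tolerances. They do not show that real duplex trajectories
satisfy those noise models — the generator is a surrogate with matched
first and second moments, not a force field.

## Ion shells

"Helical distance" is read as perpendicular distance to the local
helical axis; the 8.5 Å cutoff is the helical radius (~10 Å) minus a
phosphate radius (~1.5 Å). Internal classification also requires the
axial offset to the nearest base pair to be within one rise (ions off
the helix ends are not groove ions). Groove sectors are bounded by the
two strands' phosphate azimuths in the local base-pair frame, minor on
the side containing the minor-groove vector. External = within 6 Å of
any phosphate (second solvation shell of Na⁺/Li⁺) and not internal;
groove labels take precedence. Neighbor searches use a k-d tree above
~2×10⁵ pairwise distances, brute force below (and `brute=True` forces
the oracle path). Charge fractions are net cation-minus-anion charge
per nucleotide per shell, frame-averaged, with uncertainties as SDs of
4 equal trajectory-block means. The radial concentration profile uses
exact cylindrical shell volumes within the helix's axial span; for a
charged duplex it sits above bulk at moderate r (the counterion cloud),
and converges to bulk for a neutral one.

## Electrostatics

E_el = l_B Σ_{i<j} q_i q_j exp(−κ r_ij)/r_ij in kBT, with l_B =
e²/4πε₀ε_s kBT (0.719 nm at 298 K, ε_s = 78) and κ from the 1:1 Debye
constant (κ⁻¹ = 0.78 nm at 150 mM). Charges are −1e per phosphorus
site (0 under the neutral-backbone flag); the solute dielectric
(default 8) is recorded for PQR interop but unused by the pair sum — a
uniform-dielectric screened-Coulomb model replaces a grid
Poisson–Boltzmann solver deliberately: it is dependency-free, exact for
the decomposition identities, and a PQR writer lets an external PB
solver be substituted where absolute electrostatic magnitudes matter.
Consequently P_el values from this model (a few nm for coarse −1e
charges) are qualitative; the decomposition algebra, not the magnitude,
is the tested contract. ΔE_el(θ) is averaged over bend azimuths by
default (4 directions), which cancels the direction-dependent linear
term of the discrete charge spiral and leaves the quadratic response;
a single bending plane can be requested explicitly. Quadratic fits use
θ in radians with an intercept, so P = 2Lc × slope; additivity
P = P_el + P_nel is exact for quadratic profiles.

## Groove widths and base-pair parameters

Axial groove widths are computed in unwrapped cylindrical coordinates:
each phosphate gets an axial arc coordinate (along the base-pair-center
polyline) and an azimuth in its base pair's material frame unwrapped by
the cumulative inter-bp twist. For each strand-0 phosphate, the minor
width d is the axial gap to the strand-1 backbone crossing at the same
unwrapped azimuth, the major width D the gap to the crossing one full
turn below; crossings are linear interpolations on the cross-strand
(azimuth → axial) polyline, positions whose crossings leave the helix
are NaN, and a helix shorter than one turn warns. On an ideal helix
D + d equals the pitch exactly and a strand-0 axial shift moves d and D
by ∓δ with the total invariant — both used as exact oracles in tests.

Base-pair-step parameters decompose the rotation between consecutive
orthonormalized bp frames (x = minor-groove direction, y = long axis,
z = local helical direction) into tilt/roll/twist (rotation-vector
components in the lower frame) and the displacement into
shift/slide/rise. Inclination is the signed angle between the long
axis and the plane perpendicular to the local axis. The
16-observable screen correlates the per-frame mean and SD of the seven
parameters (inclination + six step parameters) plus the per-frame SDs
of D and d with the frame bending angle. Fluctuation SDs of groove
widths are normalized per unit contour length by default.

## Salt models

OSF: P(c) = P_nel + l_B/(4κ²b²) with charge spacing b fitted (bounded
positive); BJ: P(c) = P_nel + A·κ⁻¹ with free amplitude A ≥ 0. The BJ
form is the scaling variant (electrostatic term ∝ c^(−1/2)); the
literature also contains a variational form, and the amplitude
parameterization covers either up to the fitted constant. Weighted
least squares with weights 1/SE²; when genuine standard errors are
supplied the parameter covariance is *not* rescaled by the reduced χ²
(`absolute_sigma=True`), otherwise it is. RSS (unweighted) is the
model-comparison statistic.

## Pipeline sizes and file formats

The pipeline defaults analyze 20-bp duplexes with 4000 frames for
bending statistics, 2000 for groove/inclination correlations and 200
for ion statistics, 10 force–extension molecules per condition — sizes
chosen so a full run completes in well under a minute on one core while
keeping fit SEs at the few-percent level; every size is a config field.
The NaCl series uses the packaged reference stiffness values at 150 mM
and 4 M with a BJ-interpolated 1 M point.

Trajectories serialize as multi-model PDB (strand phosphorus atoms on
chains A/B, base-pair pseudo-atoms CEN/LAX/MNR/NRM on chain C encoding
the triads as 0.5-nm tips, ions as HETATM with formal charges, Å
coordinates, a REMARK 99 line carrying the phosphate charge) or as an
equivalent long-format CSV in nm. PDB stores 3 decimals in Å, so
round trips are exact to 10⁻³ Å and cross-format persistence lengths
agree to ~10⁻³ relative — the format precision, not the estimator, is
the limit. Internal indexing is 0-based; PDB residue numbers stay
1-based labels.

## Known limitations

- The generator's frames are temporally independent; autocorrelation,
  and hence effective-sample-size corrections, cannot be studied.
- Screened-Coulomb P_el is not comparable in magnitude to nonlinear PB
  results; use the PQR export for that.
- Groove-width extraction requires the unwrapped cross-strand azimuth
  to be monotone; severely distorted frames (azimuthal jitter
  approaching the per-step twist) raise rather than guess.
- Sequence effects, twist/stretch elasticity and their couplings are
  out of scope.
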