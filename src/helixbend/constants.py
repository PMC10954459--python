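"""Physical constants and canonical helix geometries.

Internal unit conventions used throughout the package: lengths in nm,
angles in degrees at interfaces (radians inside harmonic fits), energies
in units of kBT, charges in units of the elementary charge e, forces in
pN, salt concentrations in mM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Thermal energy at 298 K in pN nm.
KBT_298 = 4.114

#: Avogadro's number (1/mol).
N_AVOGADRO = 6.02214076e23

#: Elementary charge (C), vacuum permittivity prefactor e^2/(4 pi eps0) in J nm.
_E2_OVER_4PIEPS0_J_NM = 2.307077e-19  # = (1.602176634e-19)^2 / 1.11265006e-10 * 1e9

#: Boltzmann constant (J/K).
_KB_J = 1.380649e-23


def thermal_energy(T: float = 298.0) -> float:
    """kBT in pN nm at absolute temperature ``T`` (K)."""
    return KBT_298 * T / 298.0


def bjerrum_length(T: float = 298.0, eps_s: float = 78.0) -> float:
    """Bjerrum length l_B = e^2 / (4 pi eps0 eps_s kB T) in nm.

    At 298 K in water (eps_s = 78) this is ~0.719 nm: the separation at
    which two unit charges interact with thermal energy kBT.
    """
    return _E2_OVER_4PIEPS0_J_NM / (eps_s * _KB_J * T)


def ion_number_density(c_mM: float) -> float:
    """Number density (per nm^3) of one ion species at concentration c (mM)."""
    return c_mM * 1e-3 * N_AVOGADRO * 1e-24


# Seventh-order polynomial correction coefficients alpha_2..alpha_7 for the
# worm-like-chain force-extension interpolation (Bouchiat et al. 1999).
# The pure Marko-Siggia interpolation corresponds to all-zero coefficients.
BOUCHIAT_COEFFS = np.array(
    [-0.5164228, -2.737418, 16.07497, -38.87607, 39.49944, -14.17718]
)
MARKO_SIGGIA_COEFFS = np.zeros(6)


@dataclass(frozen=True)
class HelixForm:
    """Idealized duplex geometry of one canonical helical family.

    Parameters
    ----------
    name:
        ``"A"`` (dsRNA-like) or ``"B"`` (dsDNA-like).
    rise_nm:
        Axial rise per base pair (nm).
    twist_deg:
        Helical twist per base-pair step (degrees).
    inclination_deg:
        Signed tilt of the base-pair long axis out of the plane
        perpendicular to the helical axis (degrees).
    radius_nm:
        Radial distance of phosphorus atoms from the helical axis (nm).
    minor_fraction:
        Fraction of the helical pitch spanned axially by the minor
        groove; the major groove takes the complementary fraction.
    """

    name: str
    rise_nm: float
    twist_deg: float
    inclination_deg: float
    radius_nm: float
    minor_fraction: float

    def __post_init__(self) -> None:
        if not self.rise_nm > 0:
            raise ValueError("rise_nm must be positive")
        if not 0.0 < self.twist_deg < 60.0:
            raise ValueError("twist_deg must lie in (0, 60) degrees")
        if not 0.0 < self.minor_fraction < 1.0:
            raise ValueError("groove fractions must split the pitch")

    @property
    def major_fraction(self) -> float:
        return 1.0 - self.minor_fraction

    @property
    def pitch_nm(self) -> float:
        """Axial length of one full helical turn (nm)."""
        return 360.0 / self.twist_deg * self.rise_nm

    @property
    def minor_gap_deg(self) -> float:
        """Azimuthal gap between the two strands across the minor groove."""
        return 360.0 * self.minor_fraction


# Rise and radius follow the measured duplex dimensions (~0.28 / ~0.34 nm
# per bp; phosphate radius ~1.0 nm from the axis); twist and inclination
# are standard fiber-geometry constants. These are generator fixture
# constants, not fitted quantities.
A_FORM = HelixForm(
    name="A", rise_nm=0.28, twist_deg=32.7, inclination_deg=17.0,
    radius_nm=1.0, minor_fraction=0.55,
)
B_FORM = HelixForm(
    name="B", rise_nm=0.34, twist_deg=34.3, inclination_deg=-1.0,
    radius_nm=1.0, minor_fraction=0.35,
)

#: Default ion-shell cutoffs (nm): groove (helical-axis) cutoff is the
#: helical radius (~1.0 nm) minus the phosphate-group radius (~0.15 nm);
#: the phosphate-shell cutoff corresponds to the second solvation shell
#: of Na+/Li+ around phosphates.
HELICAL_CUTOFF_NM = 0.85
PHOSPHATE_CUTOFF_NM = 0.60

#: Length of the long magnetic-tweezers construct in base pairs.
CONSTRUCT_N_BP = 13751
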