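"""Worm-like-chain force-extension model and per-molecule fitting.

The model is the Marko-Siggia interpolation with a seventh-order
polynomial correction::

    F = kBT/P [ 1/(4 (1 - x/Lc)^2) - 1/4 + x/Lc + sum_{i=2..7} a_i (x/Lc)^i ]

with force F in pN, extension x and contour length Lc in nm, and P the
bending persistence length in nm. Fits minimise squared residuals of
log F (extension and log-force as fitting variables), which prevents the
high-force points from dominating and keeps the low-force plateau
informative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .constants import BOUCHIAT_COEFFS, thermal_energy

__all__ = [
    "ForceExtensionCurve",
    "WLCFitResult",
    "eval_wlc_force",
    "fit_force_extension",
    "aggregate_condition",
]

#: Recommended force validity window for synthetic fixtures (pN).
FORCE_WINDOW_PN = (0.01, 50.0)


@dataclass
class ForceExtensionCurve:
    """One molecule's (extension, force) record at one salt condition."""

    extension_nm: np.ndarray
    force_pN: np.ndarray
    temperature_K: float = 295.0
    molecule_id: str = ""
    ion: str = "Na"
    salt_mM: float = 150.0
    valid: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.extension_nm = np.asarray(self.extension_nm, dtype=float)
        self.force_pN = np.asarray(self.force_pN, dtype=float)
        if self.extension_nm.shape != self.force_pN.shape:
            raise ValueError("extension and force must have equal length")
        if np.any(self.force_pN <= 0):
            raise ValueError("forces must be positive")
        if self.valid is None:
            self.valid = np.ones_like(self.force_pN, dtype=bool)

    def __len__(self) -> int:
        return self.extension_nm.size


@dataclass
class WLCFitResult:
    """Fitted persistence length and contour length of one curve."""

    P_nm: float
    Lc_nm: float
    P_se_nm: float
    Lc_se_nm: float
    residual_norm: float
    n_points: int
    n_bp: int | None = None
    molecule_id: str = ""
    ion: str = ""
    salt_mM: float = float("nan")

    @property
    def rise_per_bp_nm(self) -> float:
        """Contour length per base-pair step, Lc / (n_bp - 1)."""
        if self.n_bp is None:
            raise ValueError("n_bp not provided for this fit")
        return self.Lc_nm / (self.n_bp - 1)


def eval_wlc_force(
    P_nm: float,
    Lc_nm: float,
    x_nm,
    T: float = 298.0,
    coeffs: np.ndarray = BOUCHIAT_COEFFS,
) -> np.ndarray:
    """Force (pN) of the corrected WLC interpolation at extension ``x_nm``.

    ``coeffs`` are the unitless polynomial coefficients (a_2 .. a_7);
    the all-zero set gives the bare Marko-Siggia interpolation.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (6,):
        raise ValueError("exactly six polynomial coefficients (a_2..a_7) required")
    if P_nm <= 0 or Lc_nm <= 0:
        raise ValueError("P and Lc must be positive")
    x = np.asarray(x_nm, dtype=float)
    if np.any(x < 0) or np.any(x >= Lc_nm):
        raise ValueError("extension must satisfy 0 <= x < Lc")
    u = x / Lc_nm
    poly = np.zeros_like(u)
    for i, a in enumerate(coeffs, start=2):
        poly += a * u**i
    bracket = 0.25 / (1.0 - u) ** 2 - 0.25 + u + poly
    return thermal_energy(T) / P_nm * bracket


def _check_monotonic_window(coeffs: np.ndarray) -> None:
    # The Bouchiat-corrected bracket is strictly increasing on [0, 1);
    # arbitrary user coefficients may not be, which breaks root-finding.
    u = np.linspace(0.0, 0.99, 512)
    b = 0.25 / (1 - u) ** 2 - 0.25 + u
    for i, a in enumerate(coeffs, start=2):
        b = b + a * u**i
    if np.any(np.diff(b) <= 0):
        warnings.warn("WLC bracket not monotone for these coefficients")


def fit_force_extension(
    curve: ForceExtensionCurve,
    coeffs: np.ndarray = BOUCHIAT_COEFFS,
    p0_nm: float = 50.0,
    min_points: int = 8,
) -> WLCFitResult:
    """Least-squares fit of (P, Lc) to a force-extension curve.

    Minimises sum of (log F_obs - log F_model(x_obs))^2, as appropriate
    for data spanning decades of force. Lc is constrained above the
    largest observed extension. Asymptotic standard errors come from the
    Jacobian at the optimum.
    """
    x = curve.extension_nm[curve.valid]
    F = curve.force_pN[curve.valid]
    if x.size < min_points:
        raise ValueError(
            f"insufficient data: {x.size} points (need >= {min_points})"
        )
    order = np.argsort(x)
    x, F = x[order], F[order]
    logF = np.log(F)
    xmax = float(x.max())
    lc0 = 1.05 * xmax

    def residuals(params):
        P, Lc = params
        model = eval_wlc_force(P, Lc, x, T=curve.temperature_K, coeffs=coeffs)
        return np.log(model) - logF

    lower = [1e-3, xmax * (1.0 + 1e-9)]
    upper = [1e5, 10.0 * xmax]
    sol = optimize.least_squares(
        residuals, x0=[p0_nm, lc0], bounds=(lower, upper), xtol=1e-14, ftol=1e-14
    )
    if not sol.success:
        raise RuntimeError(f"WLC fit failed to converge: {sol.message}")
    P_hat, Lc_hat = sol.x
    # asymptotic covariance from J^T J
    dof = max(x.size - 2, 1)
    s2 = 2.0 * sol.cost / dof
    JTJ = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(JTJ)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.array([np.nan, np.nan])
    return WLCFitResult(
        P_nm=float(P_hat),
        Lc_nm=float(Lc_hat),
        P_se_nm=float(se[0]),
        Lc_se_nm=float(se[1]),
        residual_norm=float(np.sqrt(2.0 * sol.cost)),
        n_points=int(x.size),
        n_bp=curve.meta.get("n_bp"),
        molecule_id=curve.molecule_id,
        ion=curve.ion,
        salt_mM=curve.salt_mM,
    )


def aggregate_condition(results: list[WLCFitResult]) -> dict:
    """Mean, SD and SE of P and Lc across molecules of one condition."""
    if not results:
        raise ValueError("no fit results to aggregate")
    P = np.array([r.P_nm for r in results])
    Lc = np.array([r.Lc_nm for r in results])
    n = len(results)
    def _stats(v):
        sd = float(np.std(v, ddof=1)) if n > 1 else 0.0
        return {
            "mean": float(np.mean(v)),
            "sd": sd,
            "se": sd / np.sqrt(n) if n > 1 else 0.0,
        }
    out = {"n_molecules": n, "P_nm": _stats(P), "Lc_nm": _stats(Lc)}
    if all(r.n_bp for r in results):
        rises = np.array([r.rise_per_bp_nm for r in results])
        out["rise_nm_per_bp"] = _stats(rises)
    return out
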