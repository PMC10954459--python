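"""Bending-angle extraction and persistence-length estimation.

A segment's bending angle is the angle between the tangents of its two
end base steps along the smoothed central axis. Pooled over all eligible
segments and frames, the angles are histogrammed (0.5 degree bins) and
the persistence length follows from the worm-like-chain relation

    -ln( p(theta) / sin theta ) = P theta^2 / (2 Lc) + const,

fitted as a weighted linear regression with theta in radians. The same
quantity read as an energy, dE_bend(theta)/kBT = -ln(p/sin theta), gives
an equivalent second route to P via its quadratic coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frames import HelixFrame, HelixTrajectory

__all__ = [
    "BendingEnsemble",
    "AngleHistogram",
    "BendingEnergyProfile",
    "PersistenceFit",
    "central_axis",
    "step_tangents",
    "bending_angle",
    "collect_segments",
    "angle_histogram",
    "fit_P_from_pdf",
    "bending_energy",
    "fit_P_from_energy",
]


@dataclass
class BendingEnsemble:
    """Pooled bending angles (degrees) of fixed-contour-length segments."""

    angles_deg: np.ndarray
    segment_Lc_nm: float
    segment_bp: int | None = None
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.segment_Lc_nm <= 0:
            raise ValueError("segment contour length must be positive")
        if self.angles_deg.size and (
            self.angles_deg.min() < 0 or self.angles_deg.max() > 180
        ):
            raise ValueError("bending angles must lie in [0, 180] degrees")

    def __len__(self) -> int:
        return self.angles_deg.size


@dataclass
class AngleHistogram:
    """Normalized histogram of bending angles on fixed-width bins."""

    edges_deg: np.ndarray
    p: np.ndarray          # probability density per degree
    counts: np.ndarray

    @property
    def centers_deg(self) -> np.ndarray:
        return 0.5 * (self.edges_deg[:-1] + self.edges_deg[1:])

    @property
    def bin_width_deg(self) -> float:
        return float(self.edges_deg[1] - self.edges_deg[0])


@dataclass
class BendingEnergyProfile:
    """dE_bend(theta)/kBT on histogram bin centers; empty bins are NaN."""

    theta_deg: np.ndarray
    energy_kBT: np.ndarray
    counts: np.ndarray


@dataclass
class PersistenceFit:
    P_nm: float
    P_se_nm: float
    intercept: float | None
    n_bins: int


def angle_histogram(
    ensemble: BendingEnsemble, bin_width_deg: float = 0.5, theta_max_deg: float = 180.0
) -> AngleHistogram:
    """Histogram ensemble angles with the stated bin width (default 0.5 deg)."""
    n_bins = int(round(theta_max_deg / bin_width_deg))
    edges = np.linspace(0.0, theta_max_deg, n_bins + 1)
    counts, _ = np.histogram(ensemble.angles_deg, bins=edges)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty ensemble")
    p = counts / (total * bin_width_deg)
    return AngleHistogram(edges_deg=edges, p=p, counts=counts)


def central_axis(frame: HelixFrame, smooth_bp: int = 3) -> np.ndarray:
    """Axis polyline: one point per base pair, smoothed over a short window.

    The raw axis points are the base-pair reference points; a centered
    moving average (window ``smooth_bp``, truncated at the ends) removes
    the residual helical wobble of coarse reference points.
    """
    c = frame.centers
    if c.shape[0] < 4:
        raise ValueError("need at least 4 base pairs for an axis")
    d = np.linalg.norm(np.diff(c, axis=0), axis=1)
    if np.any(d < 1e-9):
        raise ValueError("degenerate axis: coincident base-pair centers")
    if smooth_bp <= 1:
        return c.copy()
    half = smooth_bp // 2
    n = c.shape[0]
    out = np.empty_like(c)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = c[lo:hi].mean(axis=0)
    return out


def step_tangents(axis: np.ndarray) -> np.ndarray:
    """Unit tangent of every base step: normalized axis-point differences."""
    d = np.diff(axis, axis=0)
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def bending_angle(
    frame: HelixFrame,
    start_bp: int = 0,
    n_bp: int | None = None,
    smooth_bp: int = 1,
) -> float:
    """Bending angle (degrees) of the segment [start_bp, start_bp + n_bp).

    The angle between the tangents of the segment's two end base steps.
    Coarse frames place their base-pair reference points directly on the
    local axis, so no smoothing is applied by default; pass
    ``smooth_bp=3`` for noisy reference points.
    """
    if n_bp is None:
        n_bp = frame.n_bp - start_bp
    if start_bp < 0 or start_bp + n_bp > frame.n_bp:
        raise IndexError("segment out of bounds")
    if n_bp < 3:
        raise ValueError("segment must span at least 3 base pairs")
    axis = central_axis(frame, smooth_bp=smooth_bp)
    t = step_tangents(axis)
    t0 = t[start_bp]
    t1 = t[start_bp + n_bp - 2]
    cosang = np.clip(np.dot(t0, t1), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _trajectory_tangents(traj: HelixTrajectory, smooth_bp: int = 1) -> np.ndarray:
    """(n_frames, n_bp-1, 3) unit step tangents of the smoothed axes."""
    c = traj.centers
    n = c.shape[1]
    if n < 4:
        raise ValueError("need at least 4 base pairs")
    if smooth_bp > 1:
        half = smooth_bp // 2
        sm = np.empty_like(c)
        for i in range(n):
            lo, hi = max(0, i - half), min(n, i + half + 1)
            sm[:, i] = c[:, lo:hi].mean(axis=1)
    else:
        sm = c
    d = np.diff(sm, axis=1)
    return d / np.linalg.norm(d, axis=2, keepdims=True)


def collect_segments(
    traj: HelixTrajectory,
    n_bp: int,
    exclude_terminal: int = 3,
    smooth_bp: int = 1,
) -> BendingEnsemble:
    """Pool segment bending angles over every frame of a trajectory.

    Every window of ``n_bp`` base pairs whose ends avoid the terminal
    ``exclude_terminal`` base pairs contributes one angle per frame. The
    segment contour length is computed from the trajectory's own mean
    rise (Lc = mean rise x (n_bp - 1)), so that fluctuating geometries
    report their actual contour length rather than a nominal one.
    """
    if traj.n_frames < 2:
        raise ValueError("insufficient sample: need more than one frame")
    n_total = traj.n_bp
    starts = range(exclude_terminal, n_total - exclude_terminal - n_bp + 1)
    starts = list(starts)
    if not starts:
        raise ValueError("no eligible segment windows after terminal exclusion")
    t = _trajectory_tangents(traj, smooth_bp=smooth_bp)
    angles = []
    for s in starts:
        t0 = t[:, s]
        t1 = t[:, s + n_bp - 2]
        cosang = np.clip(np.einsum("ij,ij->i", t0, t1), -1.0, 1.0)
        angles.append(np.degrees(np.arccos(cosang)))
    pooled = np.concatenate(angles)
    lc = traj.mean_rise() * (n_bp - 1)
    return BendingEnsemble(
        angles_deg=pooled,
        segment_Lc_nm=lc,
        segment_bp=n_bp,
        source={
            "n_frames": traj.n_frames,
            "n_windows": len(starts),
            "exclude_terminal": exclude_terminal,
        },
    )


def _select_bins(hist: AngleHistogram, min_count: int, quantile: float):
    counts = hist.counts
    mask = counts >= min_count
    if quantile < 1.0 and counts.sum() > 0:
        cdf = np.cumsum(counts) / counts.sum()
        mask &= cdf <= quantile
    return mask


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray, intercept: bool):
    """Weighted least squares y ~ a*x (+ b); returns (a, se_a, b)."""
    sw = np.sqrt(w)
    if intercept:
        X = np.column_stack([x, np.ones_like(x)])
    else:
        X = x[:, None]
    Xw = X * sw[:, None]
    yw = y * sw
    beta, res, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    dof = max(x.size - X.shape[1], 1)
    resid = yw - Xw @ beta
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(Xw.T @ Xw)
    a = float(beta[0])
    se_a = float(np.sqrt(cov[0, 0]))
    b = float(beta[1]) if intercept else None
    return a, se_a, b


def fit_P_from_pdf(
    hist: AngleHistogram,
    Lc_nm: float,
    intercept: bool = True,
    min_count: int = 20,
    quantile: float = 0.99,
) -> PersistenceFit:
    """Persistence length from the angle histogram via the WLC relation.

    Regresses y = -ln(p/sin theta) on theta^2/(2 Lc) (theta in radians)
    over bins with at least ``min_count`` entries and below the stated
    count quantile; the slope is P in nm. Bin counts serve as regression
    weights (the variance of a log-count is ~1/count). The free
    intercept absorbs the normalization constant of p.
    """
    mask = _select_bins(hist, min_count, quantile)
    theta = np.radians(hist.centers_deg[mask])
    p = hist.p[mask]
    counts = hist.counts[mask].astype(float)
    ok = (p > 0) & (theta > 0)
    theta, p, counts = theta[ok], p[ok], counts[ok]
    if theta.size < 10:
        raise ValueError(f"too few populated bins for the fit ({theta.size})")
    y = -np.log(p / np.sin(theta))
    x = theta**2 / (2.0 * Lc_nm)
    a, se_a, b = _wls_line(x, y, counts, intercept)
    return PersistenceFit(P_nm=a, P_se_nm=se_a, intercept=b, n_bins=int(theta.size))


def bending_energy(hist: AngleHistogram) -> BendingEnergyProfile:
    """Bending free-energy profile dE(theta)/kBT = -ln(p/sin theta).

    Defined on bin centers; shifted so the minimum over populated bins is
    zero; empty bins are NaN (masked, never interpolated).
    """
    theta = np.radians(hist.centers_deg)
    e = np.full(theta.shape, np.nan)
    pop = (hist.counts > 0) & (theta > 0)
    if not np.any(pop):
        raise ValueError("empty histogram")
    e[pop] = -np.log(hist.p[pop] / np.sin(theta[pop]))
    e -= np.nanmin(e)
    return BendingEnergyProfile(
        theta_deg=hist.centers_deg.copy(), energy_kBT=e, counts=hist.counts.copy()
    )


def fit_P_from_energy(
    profile: BendingEnergyProfile,
    Lc_nm: float,
    intercept: bool = True,
    min_count: int = 20,
    quantile: float = 0.99,
) -> PersistenceFit:
    """Persistence length from the energy profile (quadratic coefficient).

    Identical regression to :func:`fit_P_from_pdf` — the energy profile
    is the same quantity up to an additive constant, which the intercept
    absorbs — so both routes give identical P on identical grids.
    """
    counts = profile.counts
    mask = counts >= min_count
    if quantile < 1.0 and counts.sum() > 0:
        cdf = np.cumsum(counts) / counts.sum()
        mask &= cdf <= quantile
    theta = np.radians(profile.theta_deg[mask])
    e = profile.energy_kBT[mask]
    w = counts[mask].astype(float)
    ok = np.isfinite(e) & (theta > 0)
    theta, e, w = theta[ok], e[ok], w[ok]
    if theta.size < 10:
        raise ValueError(f"too few populated bins for the fit ({theta.size})")
    x = theta**2 / (2.0 * Lc_nm)
    a, se_a, b = _wls_line(x, e, w, intercept)
    return PersistenceFit(P_nm=a, P_se_nm=se_a, intercept=b, n_bins=int(theta.size))
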