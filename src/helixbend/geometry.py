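"""Base-pair geometry: inclination, axial groove widths, fluctuations.

Axial groove widths are measured along the helical axis: for each
strand-0 phosphate, the two strands' backbones are followed in unwrapped
cylindrical coordinates (axial position vs cumulative azimuth) and the
minor/major widths are the axial gaps to the cross-strand backbone
crossings at the same azimuth — the minor-groove crossing at the same
unwrap branch, the major-groove crossing one full turn below. On an
ideal helix their sum is exactly the local pitch.

Fluctuations "along a conformation" are standard deviations over
positions within one frame; correlating those per-frame fluctuations
with the frame's bending angle reproduces the bend-coupling analysis of
groove widths and base-pair inclination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from scipy.stats import pearsonr

from .bending import _trajectory_tangents
from .frames import HelixFrame, HelixTrajectory

__all__ = [
    "GrooveWidthSeries",
    "CorrelationReport",
    "inclination",
    "axial_groove_widths",
    "fluctuation_profile",
    "correlate_with_bend",
    "helical_parameters",
    "parameter_screen",
    "frame_bending_angles",
]


# --------------------------------------------------------------------------
# local frames

def _bp_tangents(frame: HelixFrame) -> np.ndarray:
    """Per-bp local axis direction: mean of adjacent step tangents."""
    d = np.diff(frame.centers, axis=0)
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    t = np.empty_like(frame.centers)
    t[0], t[-1] = d[0], d[-1]
    mid = d[:-1] + d[1:]
    t[1:-1] = mid / np.linalg.norm(mid, axis=1, keepdims=True)
    return t


def inclination(frame: HelixFrame, bp: int | None = None):
    """Signed base-pair inclination (degrees).

    The angle between the base-pair long axis and the plane perpendicular
    to the local helical axis; positive when the long axis tips toward
    the 3' direction of the axis.
    """
    t = _bp_tangents(frame)
    if not np.all(np.isfinite(t)):
        raise ValueError("degenerate local axis")
    s = np.einsum("ij,ij->i", frame.long_axes, t)
    inc = np.degrees(np.arcsin(np.clip(s, -1.0, 1.0)))
    return inc if bp is None else float(inc[bp])


def _trajectory_inclinations(traj: HelixTrajectory) -> np.ndarray:
    """(n_frames, n_bp) signed inclinations, vectorized."""
    d = np.diff(traj.centers, axis=1)
    d = d / np.linalg.norm(d, axis=2, keepdims=True)
    t = np.empty_like(traj.centers)
    t[:, 0], t[:, -1] = d[:, 0], d[:, -1]
    mid = d[:, :-1] + d[:, 1:]
    t[:, 1:-1] = mid / np.linalg.norm(mid, axis=2, keepdims=True)
    s = np.einsum("fij,fij->fi", traj.long_axes, t)
    return np.degrees(np.arcsin(np.clip(s, -1.0, 1.0)))


# --------------------------------------------------------------------------
# axial groove widths

@dataclass
class GrooveWidthSeries:
    """Axial groove widths indexed by strand-0 phosphate."""

    bp_index: np.ndarray
    major_nm: np.ndarray   # D
    minor_nm: np.ndarray   # d
    total_nm: np.ndarray   # D + d

    def finite(self) -> "GrooveWidthSeries":
        ok = np.isfinite(self.total_nm)
        return GrooveWidthSeries(
            self.bp_index[ok], self.major_nm[ok], self.minor_nm[ok], self.total_nm[ok]
        )


def _unwrapped_backbone(frame: HelixFrame):
    """Axial arc coordinate and unwrapped azimuth of every phosphate.

    Azimuths are measured in each base pair's material frame (zero at the
    minor-groove direction) and unwrapped by the cumulative inter-bp
    twist, so both strands live on one continuous azimuth scale.
    """
    c = frame.centers
    t = _bp_tangents(frame)
    m = frame.minor_axes
    m = m - np.einsum("ij,ij->i", m, t)[:, None] * t
    m = m / np.linalg.norm(m, axis=1, keepdims=True)
    v = np.cross(t, m)

    s_bp = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(c, axis=0), axis=1))])
    # cumulative twist between consecutive material frames
    cosang = np.einsum("ij,ij->i", m[:-1], m[1:])
    sinang = np.einsum("ij,ij->i", np.cross(m[:-1], m[1:]), t[:-1])
    step_twist = np.degrees(np.arctan2(sinang, cosang)) % 360.0
    phi = np.concatenate([[0.0], np.cumsum(step_twist)])

    coords = []
    for s in range(2):
        rel = frame.phosphates[s] - c
        axial = s_bp + np.einsum("ij,ij->i", rel, t)
        lam = np.degrees(np.arctan2(
            np.einsum("ij,ij->i", rel, v), np.einsum("ij,ij->i", rel, m)
        ))
        coords.append((axial, phi + lam))
    return coords


def axial_groove_widths(frame: HelixFrame) -> GrooveWidthSeries:
    """Axial major (D) and minor (d) groove widths per strand-0 phosphate.

    The minor width is the axial gap from the phosphate to the
    cross-strand backbone crossing at the same unwrapped azimuth; the
    major width is the gap to the crossing one full turn (360 deg)
    below. Positions whose crossings fall outside the helix are NaN.
    """
    (s1, a1), (s2, a2) = _unwrapped_backbone(frame)
    if np.any(np.diff(a2) <= 0):
        raise ValueError("strand backbone azimuth not monotone; frame too distorted")
    turn = 360.0
    if a2[-1] - a2[0] < turn:
        warnings.warn("fewer than one full turn: groove series truncated")
    d = np.interp(a1, a2, s2, left=np.nan, right=np.nan) - s1
    upper = np.interp(a1 - turn, a2, s2, left=np.nan, right=np.nan)
    D = s1 - upper
    # out-of-range interp returns edge values when left/right not NaN;
    # explicitly mask targets outside the sampled azimuth range
    d[(a1 < a2[0]) | (a1 > a2[-1])] = np.nan
    D[(a1 - turn < a2[0]) | (a1 - turn > a2[-1])] = np.nan
    total = D + d
    return GrooveWidthSeries(
        bp_index=np.arange(s1.size), major_nm=D, minor_nm=d, total_nm=total
    )


# --------------------------------------------------------------------------
# fluctuations and correlations

_GROOVE_OBS = {"total_groove_width", "major_groove_width", "minor_groove_width"}


def frame_bending_angles(traj: HelixTrajectory) -> np.ndarray:
    """Whole-helix bending angle per frame (degrees, end-step tangents)."""
    t = _trajectory_tangents(traj)
    cosang = np.clip(np.einsum("fj,fj->f", t[:, 0], t[:, -1]), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def fluctuation_profile(
    traj: HelixTrajectory,
    observable: str = "total_groove_width",
    per_contour: bool | None = None,
) -> dict:
    """Per-frame SD of an observable along the conformation.

    observable: one of total_groove_width, major_groove_width,
    minor_groove_width (nm; normalized per unit contour length by
    default) or inclination (degrees). Returns the per-frame SDs with
    the trajectory mean and 4-block SD.
    """
    if traj.n_bp < 3:
        raise ValueError("frames too short for a fluctuation profile")
    if observable == "inclination":
        series = _trajectory_inclinations(traj)
        sds = np.std(series, axis=1, ddof=1)
        if per_contour:
            sds = sds / traj.contour_lengths()
    elif observable in _GROOVE_OBS:
        key = {"total_groove_width": "total_nm",
               "major_groove_width": "major_nm",
               "minor_groove_width": "minor_nm"}[observable]
        per_contour = True if per_contour is None else per_contour
        lcs = traj.contour_lengths()
        sds = np.empty(traj.n_frames)
        for i in range(traj.n_frames):
            g = axial_groove_widths(traj.frame(i)).finite()
            vals = getattr(g, key)
            if vals.size < 2:
                raise ValueError("single-step groove series; helix too short")
            sds[i] = np.std(vals, ddof=1)
        if per_contour:
            sds = sds / lcs
    else:
        raise ValueError(f"unknown observable {observable!r}")
    from .ions import _block_sd

    return {
        "observable": observable,
        "per_frame_sd": sds,
        "mean": float(np.mean(sds)),
        "block_sd": _block_sd(sds),
    }


@dataclass
class CorrelationReport:
    """Pearson correlations of per-frame observables with bending angle."""

    table: pd.DataFrame  # columns: observable, r, n

    def r(self, observable: str) -> float:
        row = self.table[self.table.observable == observable]
        if row.empty:
            raise KeyError(observable)
        return float(row.r.iloc[0])


def correlate_with_bend(
    traj: HelixTrajectory,
    observables=("total_groove_width", "major_groove_width",
                 "minor_groove_width", "inclination"),
    frame_angles_deg: np.ndarray | None = None,
) -> CorrelationReport:
    """Pearson r between per-frame fluctuation SDs and bending angle."""
    theta = frame_bending_angles(traj) if frame_angles_deg is None else np.asarray(frame_angles_deg, float)
    rows = []
    for obs in observables:
        sds = fluctuation_profile(traj, obs)["per_frame_sd"]
        ok = np.isfinite(sds)
        if np.std(sds[ok]) == 0 or ok.sum() < 3:
            rows.append({"observable": f"sd_{obs}", "r": np.nan, "n": int(ok.sum())})
            continue
        r, _ = pearsonr(theta[ok], sds[ok])
        rows.append({"observable": f"sd_{obs}", "r": float(r), "n": int(ok.sum())})
    return CorrelationReport(table=pd.DataFrame(rows))


# --------------------------------------------------------------------------
# base-pair step parameters

_STEP_PARAMS = ("shift_nm", "slide_nm", "rise_nm", "tilt_deg", "roll_deg", "twist_deg")


def _bp_frames_matrix(traj: HelixTrajectory) -> np.ndarray:
    """(F, n, 3, 3) orthonormal bp frames with columns (x=minor, y=long, z=axis)."""
    z = traj.normals
    x = traj.minor_axes - np.einsum("fij,fij->fi", traj.minor_axes, z)[..., None] * z
    x = x / np.linalg.norm(x, axis=2, keepdims=True)
    y = np.cross(z, x)
    return np.stack([x, y, z], axis=-1)


def helical_parameters(traj: HelixTrajectory) -> dict[str, np.ndarray]:
    """Standard base-pair-step parameters per frame and step.

    Rotations between consecutive base-pair frames are decomposed into
    tilt (about the minor-groove axis), roll (about the long axis) and
    twist (about the local helical axis); displacements in the first
    frame's coordinates give shift, slide and rise. Returns arrays of
    shape (n_frames, n_steps), plus per-bp inclination.
    """
    F, n = traj.n_frames, traj.n_bp
    M = _bp_frames_matrix(traj)
    A = M[:, :-1].reshape(-1, 3, 3)
    B = M[:, 1:].reshape(-1, 3, 3)
    R = np.einsum("nij,nik->njk", A, B)  # A^T B
    rotvec = Rotation.from_matrix(R).as_rotvec(degrees=True).reshape(F, n - 1, 3)
    disp = np.einsum("fnij,fni->fnj", M[:, :-1], np.diff(traj.centers, axis=1))
    out = {
        "shift_nm": disp[..., 0],
        "slide_nm": disp[..., 1],
        "rise_nm": disp[..., 2],
        "tilt_deg": rotvec[..., 0],
        "roll_deg": rotvec[..., 1],
        "twist_deg": rotvec[..., 2],
        "inclination_deg": _trajectory_inclinations(traj),
    }
    return out


def parameter_screen(
    traj: HelixTrajectory, frame_angles_deg: np.ndarray | None = None
) -> CorrelationReport:
    """Weak-correlation screen of 16 structural observables vs bend.

    For each of the seven helical parameters (inclination plus the six
    step parameters), the per-frame mean and the per-frame SD along the
    conformation are correlated with the frame bending angle (14
    observables); the per-frame SDs of the axial major and minor groove
    widths complete the screen (16).
    """
    theta = frame_bending_angles(traj) if frame_angles_deg is None else np.asarray(frame_angles_deg, float)
    params = helical_parameters(traj)
    rows = []

    def _add(name, series):
        if np.std(series) == 0:
            rows.append({"observable": name, "r": np.nan, "n": series.size})
            return
        r, _ = pearsonr(theta, series)
        rows.append({"observable": name, "r": float(r), "n": series.size})

    for name, arr in params.items():
        _add(f"mean_{name}", arr.mean(axis=1))
        _add(f"sd_{name}", arr.std(axis=1, ddof=1))
    for obs in ("major_groove_width", "minor_groove_width"):
        sds = fluctuation_profile(traj, obs)["per_frame_sd"]
        _add(f"sd_{obs}", sds)
    return CorrelationReport(table=pd.DataFrame(rows))
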