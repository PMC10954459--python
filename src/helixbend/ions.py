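"""Ion-shell classification and charge-fraction analysis.

Binding ions around a duplex are partitioned into mutually exclusive
shells: *internal* ions sit within a helical (axis) distance of 8.5 A
inside the major- or minor-groove sector; *external* ions are the
remaining ions within 6 A of a phosphate atom; everything else is bulk.
Groove ions take precedence over the phosphate shell. Charge fractions
report the net bound cation-over-anion charge per nucleotide, the
measure of backbone neutralization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from .constants import HELICAL_CUTOFF_NM, PHOSPHATE_CUTOFF_NM
from .frames import HelixFrame, HelixTrajectory, IonSet

__all__ = [
    "ShellClassification",
    "ChargeFractionReport",
    "classify_ions",
    "charge_fractions",
    "radial_concentration_profile",
    "bend_vs_binding",
    "SHELLS",
]

SHELLS = ("external", "internal_major", "internal_minor", "bulk")


@dataclass
class ShellClassification:
    """Per-ion shell labels and the distances that produced them."""

    labels: np.ndarray               # (n_ions,) str from SHELLS
    axis_distance_nm: np.ndarray     # perpendicular distance to local axis
    phosphate_distance_nm: np.ndarray  # distance to nearest P atom

    def __len__(self) -> int:
        return self.labels.size


@dataclass
class ChargeFractionReport:
    """Signed bound charge per nucleotide by shell (e/nt)."""

    per_frame: pd.DataFrame     # columns: external, internal_major, internal_minor, total
    mean: dict
    block_sd: dict              # SD over 4 equal trajectory blocks
    n_frames: int
    n_nt: int


def _local_geometry(frame: HelixFrame, positions: np.ndarray):
    """Nearest-bp local cylindrical coordinates of ion positions.

    Returns (bp index, axial offset, axis distance, azimuth deg relative
    to the minor-groove direction).
    """
    d2 = ((positions[:, None, :] - frame.centers[None, :, :]) ** 2).sum(axis=2)
    bp = np.argmin(d2, axis=1)
    rel = positions - frame.centers[bp]
    t = frame.normals[bp]
    axial = np.einsum("ij,ij->i", rel, t)
    rho_vec = rel - axial[:, None] * t
    rho = np.linalg.norm(rho_vec, axis=1)
    m = frame.minor_axes[bp]
    v = np.cross(t, m)
    az = np.degrees(np.arctan2(
        np.einsum("ij,ij->i", rho_vec, v), np.einsum("ij,ij->i", rho_vec, m)
    ))
    return bp, axial, rho, az


def _phosphate_azimuth_bounds(frame: HelixFrame):
    """Per-bp azimuths (deg, relative to the minor direction) of both strands.

    The minor-groove sector at bp i spans azimuths between the two
    strands' phosphates on the side containing the minor-groove vector.
    """
    c, t, m = frame.centers, frame.normals, frame.minor_axes
    v = np.cross(t, m)
    bounds = np.empty((2, frame.n_bp))
    for s in range(2):
        rel = frame.phosphates[s] - c
        rel = rel - np.einsum("ij,ij->i", rel, t)[:, None] * t
        bounds[s] = np.degrees(np.arctan2(
            np.einsum("ij,ij->i", rel, v), np.einsum("ij,ij->i", rel, m)
        ))
    return bounds  # bounds[0] ~ +gap/2, bounds[1] ~ -gap/2


def classify_ions(
    frame: HelixFrame,
    positions: np.ndarray,
    helical_cutoff_nm: float = HELICAL_CUTOFF_NM,
    phosphate_cutoff_nm: float = PHOSPHATE_CUTOFF_NM,
    brute: bool = False,
) -> ShellClassification:
    """Assign every ion to exactly one shell.

    internal  <=>  axis distance <= 8.5 A, axial offset within one rise of
    a base pair, and azimuth inside the (major | minor) groove sector of
    the local base-pair frame; external <=> not internal and within 6 A
    of some phosphate atom; otherwise bulk.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = positions.shape[0]
    if frame.n_bp < 2:
        raise ValueError("frame lacks a helical axis")
    bp, axial, rho, az = _local_geometry(frame, positions)

    rise = np.linalg.norm(np.diff(frame.centers, axis=0), axis=1).mean()
    near_axis = (rho <= helical_cutoff_nm) & (np.abs(axial) <= rise)

    bounds = _phosphate_azimuth_bounds(frame)
    upper = bounds[0][bp]
    lower = bounds[1][bp]
    in_minor = (az >= lower) & (az <= upper)

    p_flat = frame.phosphates.reshape(-1, 3)
    if brute or n * p_flat.shape[0] <= 200_000:
        pd_min = np.sqrt(
            ((positions[:, None, :] - p_flat[None, :, :]) ** 2).sum(axis=2)
        ).min(axis=1)
    else:
        tree = cKDTree(p_flat)
        pd_min, _ = tree.query(positions, k=1)

    labels = np.full(n, "bulk", dtype=object)
    labels[(pd_min <= phosphate_cutoff_nm) & ~near_axis] = "external"
    labels[near_axis & ~in_minor] = "internal_major"
    labels[near_axis & in_minor] = "internal_minor"
    return ShellClassification(
        labels=np.asarray(labels, dtype=str),
        axis_distance_nm=rho,
        phosphate_distance_nm=pd_min,
    )


def _frame_fractions(frame, charges, positions, **kw):
    cls = classify_ions(frame, positions, **kw)
    out = {}
    for shell in ("external", "internal_major", "internal_minor"):
        out[shell] = float(charges[cls.labels == shell].sum()) / frame.n_nt
    out["total"] = out["external"] + out["internal_major"] + out["internal_minor"]
    return out


def _block_sd(values: np.ndarray, n_blocks: int = 4) -> float:
    """SD of block means over ``n_blocks`` equal trajectory intervals."""
    n = values.size
    if n < n_blocks:
        return float("nan")
    blocks = np.array_split(values, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return float(np.std(means, ddof=1))


def charge_fractions(
    traj: HelixTrajectory, ions: IonSet | None = None, **kw
) -> ChargeFractionReport:
    """Per-shell signed bound charge per nucleotide, averaged over frames.

    Uncertainty is the standard deviation of the means of 4 equal
    trajectory blocks.
    """
    ions = ions if ions is not None else traj.ions
    if ions is None:
        raise ValueError("trajectory has no ions")
    if traj.n_bp == 0:
        raise ValueError("zero nucleotides")
    rows = []
    for i in range(traj.n_frames):
        _, q, pos = ions.frame(i)
        rows.append(_frame_fractions(traj.frame(i), q, pos, **kw))
    df = pd.DataFrame(rows)
    return ChargeFractionReport(
        per_frame=df,
        mean={c: float(df[c].mean()) for c in df.columns},
        block_sd={c: _block_sd(df[c].to_numpy()) for c in df.columns},
        n_frames=traj.n_frames,
        n_nt=traj.frame(0).n_nt,
    )


def radial_concentration_profile(
    traj: HelixTrajectory,
    species: str,
    r_max_nm: float = 3.5,
    dr_nm: float = 0.25,
    ions: IonSet | None = None,
) -> pd.DataFrame:
    """Cylindrical concentration profile c(r) around the helical axis (mM).

    Ions of the requested species are binned by perpendicular distance to
    the straight axis fit of each frame, within the helix's axial span;
    counts are converted to mM with the exact cylindrical shell volumes.
    Shells extending beyond the simulation box are geometrically
    undercounted; keep r_max within the box margin.
    """
    ions = ions if ions is not None else traj.ions
    if ions is None:
        raise ValueError("trajectory has no ions")
    if traj.n_frames < 10:
        raise ValueError("need at least 10 frames for a profile")
    edges = np.arange(0.0, r_max_nm + dr_nm / 2, dr_nm)
    counts = np.zeros(edges.size - 1)
    length_total = 0.0
    for i in range(traj.n_frames):
        frame = traj.frame(i)
        sp, _, pos = ions.frame(i)
        sel = sp == species
        if not np.any(sel):
            length_total += np.linalg.norm(frame.centers[-1] - frame.centers[0])
            continue
        p = pos[sel]
        o = frame.centers[0]
        t = frame.centers[-1] - o
        L = np.linalg.norm(t)
        t = t / L
        z = (p - o) @ t
        rho = np.linalg.norm(p - o - z[:, None] * t, axis=1)
        inside = (z >= 0) & (z <= L)
        c, _ = np.histogram(rho[inside], bins=edges)
        counts += c
        length_total += L
    shell_vol = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2) * (length_total)
    conc_mM = counts / (6.02214076e-4 * shell_vol)
    return pd.DataFrame(
        {
            "r_nm": 0.5 * (edges[:-1] + edges[1:]),
            "conc_mM": conc_mM,
            "count": counts,
        }
    )


def bend_vs_binding(
    traj: HelixTrajectory,
    ions: IonSet | None = None,
    frame_angles_deg: np.ndarray | None = None,
    n_bins: int = 8,
    **kw,
) -> dict:
    """Shell charge fractions as functions of the frame bending angle.

    Returns the angle-binned table (mean fractions with 4-block SDs per
    bin) and the Pearson correlation of the external fraction with the
    bending angle across frames.
    """
    from .bending import _trajectory_tangents

    ions = ions if ions is not None else traj.ions
    if ions is None:
        raise ValueError("trajectory has no ions")
    if frame_angles_deg is None:
        t = _trajectory_tangents(traj)
        cosang = np.clip(np.einsum("ij,ij->i", t[:, 0], t[:, -1]), -1, 1)
        frame_angles_deg = np.degrees(np.arccos(cosang))
    frame_angles_deg = np.asarray(frame_angles_deg, dtype=float)

    rows = []
    for i in range(traj.n_frames):
        _, q, pos = ions.frame(i)
        rows.append(_frame_fractions(traj.frame(i), q, pos, **kw))
    df = pd.DataFrame(rows)
    df["theta_deg"] = frame_angles_deg

    edges = np.quantile(frame_angles_deg, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if edges.size - 1 < 3:
        raise ValueError("fewer than 3 populated bending-angle bins")
    df["bin"] = pd.cut(df["theta_deg"], bins=edges, include_lowest=True)
    binned = df.groupby("bin", observed=True).agg(
        theta_deg=("theta_deg", "mean"),
        external=("external", "mean"),
        internal=("internal_major", lambda s: float(np.mean(s))),
        total=("total", "mean"),
        n=("total", "size"),
    ).reset_index(drop=True)
    binned["internal"] = (
        df.groupby("bin", observed=True)[["internal_major", "internal_minor"]]
        .mean()
        .sum(axis=1)
        .to_numpy()
    )
    r_ext, p_ext = pearsonr(df["theta_deg"], df["external"])
    return {
        "binned": binned,
        "pearson_external": float(r_ext),
        "pearson_external_pvalue": float(p_ext),
        "per_frame": df,
    }
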