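"""File formats: coarse multi-model PDB, CSV frame tables, PQR, CSV IO.

The coarse trajectory scheme stores, per MODEL: strand phosphorus atoms
on chains A and B (one residue per nucleotide), base-pair pseudo-atoms
on chain C (CEN center plus LAX/MNR/NRM tips at +0.5 nm along the long
axis, minor-groove and normal vectors, so triads survive the round
trip), and ions as HETATM records. Coordinates are written in Angstrom
(PDB convention) and converted to nm internally; internal indexing is
0-based with PDB residue numbers preserved as 1-based labels.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import A_FORM, B_FORM
from .forceext import ForceExtensionCurve, WLCFitResult
from .frames import HelixFrame, HelixTrajectory, IonSet, ION_CHARGES

__all__ = [
    "load_reference_values",
    "write_trajectory_pdb",
    "read_trajectory_pdb",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "read_trajectory",
    "write_pqr",
    "read_force_extension_csv",
    "write_force_extension_csv",
    "fit_results_frame",
]

_TIP = 0.5  # nm: pseudo-atom tip offset encoding unit vectors


def load_reference_values() -> dict:
    """Published reference stiffness values used as generator ground truth."""
    with resources.files("helixbend.data").joinpath("reference_values.json").open() as fh:
        return json.load(fh)


# --------------------------------------------------------------------------
# PDB

def _pdb_line(serial, name, resname, chain, resseq, xyz_nm, hetatm=False,
              element="", charge=""):
    rec = "HETATM" if hetatm else "ATOM  "
    x, y, z = (c * 10.0 for c in xyz_nm)  # nm -> Angstrom
    return (
        f"{rec}{serial:>5d} {name:<4s} {resname:>3s} {chain}{resseq:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{element:>2s}{charge:<2s}"
    )


def write_trajectory_pdb(traj: HelixTrajectory, path) -> None:
    """Write a trajectory as multi-model PDB (MODEL/ENDMDL blocks)."""
    path = Path(path)
    form = traj.form.name if traj.form is not None else "?"
    with open(path, "w") as fh:
        fh.write(f"REMARK  99 HELIXBEND COARSE TRAJECTORY FORM {form}\n")
        fh.write(f"REMARK  99 PHOSPHATE_CHARGE {traj.phosphate_charge:.2f}\n")
        for i in range(traj.n_frames):
            frame = traj.frame(i)
            fh.write(f"MODEL {i + 1:>8d}\n")
            serial = 1
            for s, chain in enumerate("AB"):
                for b in range(frame.n_bp):
                    fh.write(_pdb_line(serial, "P", "DNT", chain, b + 1,
                                       frame.phosphates[s, b], element="P") + "\n")
                    serial += 1
            tips = {
                "CEN": frame.centers,
                "LAX": frame.centers + _TIP * frame.long_axes,
                "MNR": frame.centers + _TIP * frame.minor_axes,
                "NRM": frame.centers + _TIP * frame.normals,
            }
            for b in range(frame.n_bp):
                for name, arr in tips.items():
                    fh.write(_pdb_line(serial, name, "BPF", "C", b + 1,
                                       arr[b], element="C") + "\n")
                    serial += 1
            if traj.ions is not None:
                sp, q, pos = traj.ions.frame(i)
                for k in range(pos.shape[0]):
                    el = sp[k].upper()
                    ch = f"{abs(int(q[k]))}{'+' if q[k] > 0 else '-'}"
                    fh.write(_pdb_line(serial, el, el[:3], "I", k + 1, pos[k],
                                       hetatm=True, element=el[:2], charge=ch) + "\n")
                    serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _finish_model(records, ions_acc):
    phos = {"A": {}, "B": {}}
    bp = {}
    ions = []
    for rec in records:
        kind, name, chain, resseq, xyz, charge = rec
        if kind == "ion":
            ions.append((name, charge, xyz))
        elif chain in phos and name == "P":
            phos[chain][resseq] = xyz
        elif chain == "C":
            bp.setdefault(resseq, {})[name] = xyz
    if not bp or not phos["A"]:
        raise ValueError("model lacks phosphate or base-pair records")
    bps = sorted(bp)
    centers = np.array([bp[b]["CEN"] for b in bps])
    long_axes = np.array([bp[b]["LAX"] for b in bps]) - centers
    minor_axes = np.array([bp[b]["MNR"] for b in bps]) - centers
    normals = np.array([bp[b]["NRM"] for b in bps]) - centers
    for arr in (long_axes, minor_axes, normals):
        arr /= np.linalg.norm(arr, axis=1, keepdims=True)
    phosphates = np.stack([
        np.array([phos["A"][b] for b in sorted(phos["A"])]),
        np.array([phos["B"][b] for b in sorted(phos["B"])]),
    ])
    ions_acc.append(ions)
    return centers, long_axes, minor_axes, normals, phosphates


def read_trajectory_pdb(path) -> HelixTrajectory:
    """Read a coarse multi-model PDB trajectory.

    Files without MODEL delimiters are read as a single frame (with a
    warning); malformed fixed-column records raise with the line number.
    """
    import warnings

    path = Path(path)
    frames_raw: list = []
    ions_acc: list = []
    records: list = []
    phosphate_charge = -1.0
    form = None
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tag = line[:6]
            if line.startswith("REMARK  99 PHOSPHATE_CHARGE"):
                phosphate_charge = float(line.split()[-1])
            elif line.startswith("REMARK  99 HELIXBEND"):
                token = line.split()[-1]
                form = {"A": A_FORM, "B": B_FORM}.get(token)
            elif tag == "MODEL ":
                saw_model = True
                records = []
            elif tag == "ENDMDL":
                frames_raw.append(_finish_model(records, ions_acc))
                records = []
            elif tag in ("ATOM  ", "HETATM"):
                try:
                    name = line[12:16].strip()
                    chain = line[21]
                    resseq = int(line[22:26])
                    xyz = np.array(
                        [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                    ) / 10.0  # Angstrom -> nm
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from exc
                if tag == "HETATM":
                    sp = name.capitalize()
                    chg = line[78:80].strip()
                    if chg:
                        q = float(chg[0]) * (1 if chg.endswith("+") else -1)
                    else:
                        q = ION_CHARGES.get(sp, 0.0)
                    records.append(("ion", sp, chain, resseq, xyz, q))
                else:
                    records.append(("atom", name, chain, resseq, xyz, 0.0))
    if records and not saw_model:
        warnings.warn("no MODEL delimiters: reading as a single frame")
        frames_raw.append(_finish_model(records, ions_acc))
    if not frames_raw:
        raise ValueError(f"{path}: no frames found")

    traj = HelixTrajectory(
        centers=np.stack([f[0] for f in frames_raw]),
        long_axes=np.stack([f[1] for f in frames_raw]),
        minor_axes=np.stack([f[2] for f in frames_raw]),
        normals=np.stack([f[3] for f in frames_raw]),
        phosphates=np.stack([f[4] for f in frames_raw]),
        phosphate_charge=phosphate_charge,
        form=form,
    )
    if any(len(i) for i in ions_acc):
        traj.ions = _ions_from_lists(ions_acc)
    return traj


def _ions_from_lists(per_frame: list) -> IonSet:
    # block slot layout (cations first, anions second) so the per-slot
    # species/charge arrays are frame-independent even when counts vary
    F = len(per_frame)
    cats = [[i for i in ions if i[1] > 0] for ions in per_frame]
    ans = [[i for i in ions if i[1] <= 0] for ions in per_frame]
    max_cat = max((len(c) for c in cats), default=0)
    max_an = max((len(a) for a in ans), default=0)
    n_slots = max_cat + max_an
    species = np.array(["Na"] * max_cat + ["Cl"] * max_an, dtype=object)
    charges = np.concatenate([np.ones(max_cat), -np.ones(max_an)])
    positions = np.full((F, n_slots, 3), 1e6)
    active = np.zeros((F, n_slots), dtype=bool)
    for f in range(F):
        for k, (sp, q, xyz) in enumerate(cats[f]):
            positions[f, k] = xyz
            active[f, k] = True
            species[k] = sp
            charges[k] = q
        for k, (sp, q, xyz) in enumerate(ans[f]):
            positions[f, max_cat + k] = xyz
            active[f, max_cat + k] = True
            species[max_cat + k] = sp
            charges[max_cat + k] = q
    return IonSet(species=np.asarray(species, dtype=str), charges=charges,
                  positions=positions, active=active)


# --------------------------------------------------------------------------
# CSV frame tables

_ENTITY_VEC = {"bp_long_tip": "long_axes", "bp_minor_tip": "minor_axes",
               "bp_normal_tip": "normals"}


def write_trajectory_csv(traj: HelixTrajectory, path) -> None:
    """Long-format CSV: frame, entity_type, chain, residue_index, x, y, z, charge."""
    rows = []
    for i in range(traj.n_frames):
        frame = traj.frame(i)
        for s, chain in enumerate("AB"):
            for b in range(frame.n_bp):
                rows.append((i, "phosphate", chain, b, "P",
                             *frame.phosphates[s, b], frame.phosphate_charge))
        for b in range(frame.n_bp):
            rows.append((i, "bp_center", "C", b, "CEN", *frame.centers[b], 0.0))
            for ent, attr in _ENTITY_VEC.items():
                tip = frame.centers[b] + _TIP * getattr(frame, attr)[b]
                rows.append((i, ent, "C", b, ent, *tip, 0.0))
        if traj.ions is not None:
            sp, q, pos = traj.ions.frame(i)
            for k in range(pos.shape[0]):
                rows.append((i, "ion", "I", k, sp[k], *pos[k], q[k]))
    df = pd.DataFrame(rows, columns=["frame", "entity_type", "chain",
                                     "residue_index", "species",
                                     "x_nm", "y_nm", "z_nm", "charge"])
    df.to_csv(path, index=False)


def read_trajectory_csv(path) -> HelixTrajectory:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty frame table")
    frames_raw = []
    ions_acc = []
    charge = -1.0
    for _, g in df.groupby("frame", sort=True):
        phos = []
        for chain in "AB":
            sel = g[(g.entity_type == "phosphate") & (g.chain == chain)]
            sel = sel.sort_values("residue_index")
            phos.append(sel[["x_nm", "y_nm", "z_nm"]].to_numpy())
            if not sel.empty:
                charge = float(sel.charge.iloc[0])
        cen = g[g.entity_type == "bp_center"].sort_values("residue_index")
        centers = cen[["x_nm", "y_nm", "z_nm"]].to_numpy()
        vecs = {}
        for ent in _ENTITY_VEC:
            tips = g[g.entity_type == ent].sort_values("residue_index")
            v = tips[["x_nm", "y_nm", "z_nm"]].to_numpy() - centers
            vecs[ent] = v / np.linalg.norm(v, axis=1, keepdims=True)
        frames_raw.append((centers, vecs["bp_long_tip"], vecs["bp_minor_tip"],
                           vecs["bp_normal_tip"], np.stack(phos)))
        ion_rows = g[g.entity_type == "ion"]
        ions_acc.append([
            (r.species, r.charge, np.array([r.x_nm, r.y_nm, r.z_nm]))
            for r in ion_rows.itertuples()
        ])
    traj = HelixTrajectory(
        centers=np.stack([f[0] for f in frames_raw]),
        long_axes=np.stack([f[1] for f in frames_raw]),
        minor_axes=np.stack([f[2] for f in frames_raw]),
        normals=np.stack([f[3] for f in frames_raw]),
        phosphates=np.stack([f[4] for f in frames_raw]),
        phosphate_charge=charge,
    )
    if any(len(i) for i in ions_acc):
        traj.ions = _ions_from_lists(ions_acc)
    return traj


def read_trajectory(path, fmt: str | None = None) -> HelixTrajectory:
    """Read a trajectory, dispatching on extension (.pdb / .csv)."""
    path = Path(path)
    fmt = fmt or ("pdb_multimodel" if path.suffix.lower() == ".pdb" else "csv_frames")
    if fmt == "pdb_multimodel":
        return read_trajectory_pdb(path)
    if fmt == "csv_frames":
        return read_trajectory_csv(path)
    raise ValueError(f"unknown trajectory format {fmt!r}")


# --------------------------------------------------------------------------
# PQR (external Poisson-Boltzmann solver interop)

def write_pqr(frame: HelixFrame, path, radius_nm: float = 0.2) -> None:
    """Write the frame's charge sites as a standard PQR file.

    Phosphates carry the frame's phosphate charge and the given radius;
    coordinates in Angstrom. Lets an external grid PB solver be
    substituted for the screened-Coulomb surrogate.
    """
    with open(Path(path), "w") as fh:
        serial = 1
        for s, chain in enumerate("AB"):
            for b in range(frame.n_bp):
                x, y, z = frame.phosphates[s, b] * 10.0
                fh.write(
                    f"ATOM  {serial:>5d}  P   DNT {chain}{b + 1:>4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f} {frame.phosphate_charge:7.4f} "
                    f"{radius_nm * 10.0:6.4f}\n"
                )
                serial += 1
        fh.write("END\n")


# --------------------------------------------------------------------------
# force-extension CSV

def read_force_extension_csv(path) -> list[ForceExtensionCurve]:
    """Curves from a CSV with columns molecule_id, salt_mM, ion, extension_nm, force_pN."""
    df = pd.read_csv(path)
    required = {"molecule_id", "salt_mM", "ion", "extension_nm", "force_pN"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    curves = []
    for (mol, salt, ion), g in df.groupby(["molecule_id", "salt_mM", "ion"]):
        kwargs = {}
        if "temperature_K" in g.columns:
            kwargs["temperature_K"] = float(g.temperature_K.iloc[0])
        curves.append(ForceExtensionCurve(
            extension_nm=g.extension_nm.to_numpy(),
            force_pN=g.force_pN.to_numpy(),
            molecule_id=str(mol), ion=str(ion), salt_mM=float(salt), **kwargs,
        ))
    return curves


def write_force_extension_csv(curves: list[ForceExtensionCurve], path) -> None:
    rows = []
    for c in curves:
        for x, F in zip(c.extension_nm, c.force_pN):
            rows.append((c.molecule_id, c.salt_mM, c.ion, c.temperature_K, x, F))
    pd.DataFrame(rows, columns=["molecule_id", "salt_mM", "ion",
                                "temperature_K", "extension_nm",
                                "force_pN"]).to_csv(path, index=False)


def fit_results_frame(results: list[WLCFitResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "molecule_id": r.molecule_id, "ion": r.ion, "salt_mM": r.salt_mM,
        "P_nm": r.P_nm, "P_se_nm": r.P_se_nm, "Lc_nm": r.Lc_nm,
        "Lc_se_nm": r.Lc_se_nm, "n_points": r.n_points,
        "residual_norm": r.residual_norm,
    } for r in results])
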