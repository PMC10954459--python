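"""End-to-end pipeline driver.

Chains the analysis stages over a set of salt conditions and emits CSV
tables mirroring the study's figure panels: per-condition persistence
lengths from force-extension fits and from bending-angle ensembles,
charge fractions by binding shell, groove-width and inclination
fluctuations with their bend correlations, the electrostatic/intrinsic
energy decomposition, and OSF/BJ salt-model fits. A JSON manifest
records every parameter and seed.

All randomness flows from the config seed; per-stage and per-condition
seeds are derived deterministically from it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bending import angle_histogram, bending_energy, collect_segments, fit_P_from_pdf
from .constants import A_FORM, B_FORM
from .electrostatics import ElectrostaticModel, decompose, delta_E_el
from .forceext import aggregate_condition, fit_force_extension
from .geometry import correlate_with_bend, fluctuation_profile, parameter_screen
from .io import fit_results_frame, load_reference_values
from .ions import charge_fractions
from .saltfit import SaltSeries, fit_salt_series
from .synthetic import GeneratorConfig, make_ideal_helix, sample_trajectory, sample_wlc_angles, synth_force_extension

log = logging.getLogger("helixbend")

SEGMENT_BP = {"rna": 13, "dna": 11}
_EXT_OCC = {  # external charge fractions by (molecule, conc band)
    ("rna", 150.0): 0.24, ("dna", 150.0): 0.36,
    ("rna", 1000.0): 0.60, ("dna", 1000.0): 0.65,
    ("rna", 4000.0): 0.89, ("dna", 4000.0): 0.91,
}


def default_conditions() -> list[dict]:
    """NaCl series per molecule; P ground truths from the reference table.

    The intermediate 1 M point is interpolated with the BJ form through
    the published 150 mM and 4 M values.
    """
    ref = load_reference_values()
    out = []
    for mol in ("rna", "dna"):
        p150 = ref[f"md_{mol}_nacl_150mM"]
        p4m = ref[f"md_{mol}_nacl_4M"]
        from .electrostatics import debye_length

        k150, k4m, k1m = (debye_length(c) for c in (150.0, 4000.0, 1000.0))
        A = (p150 - p4m) / (k150 - k4m)
        pnel = p150 - A * k150
        p1m = pnel + A * k1m
        for conc, P in ((150.0, p150), (1000.0, round(p1m, 1)), (4000.0, p4m)):
            out.append({
                "molecule": mol, "ion": "Na", "conc_mM": conc, "P_nm": P,
                "ext_occupancy": _EXT_OCC[(mol, conc)],
            })
    return out


@dataclass
class PipelineConfig:
    """Stage toggles, cutoffs and sizes; defaults match the study settings."""

    seed: int = 0
    out_dir: str = "helixbend_out"
    stages: tuple = ("forceext", "bend", "ions", "grooves", "decompose", "saltfit")
    conditions: list = field(default_factory=default_conditions)
    n_molecules: int = 10          # force-extension replicates per condition
    noise_x_nm: float = 5.0
    n_frames_bend: int = 4000
    n_frames_ions: int = 200
    n_frames_grooves: int = 2000
    n_bp: int = 20
    bin_width_deg: float = 0.5
    exclude_terminal: int = 3
    helical_cutoff_nm: float = 0.85
    phosphate_cutoff_nm: float = 0.60

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        cfg = cls(**{k: v for k, v in data.items() if k in cls.__dataclass_fields__})
        cfg.stages = tuple(cfg.stages)
        return cfg


def _cond_seed(base: int, *parts) -> int:
    # stable across processes (unlike built-in str hashing)
    import zlib

    h = base
    for p in parts:
        h = (h * 1000003 + zlib.crc32(str(p).encode())) % (2**31 - 1)
    return int(h)


def _gen_config(cfg: PipelineConfig, cond: dict, n_frames: int, with_ions: bool, tag: str) -> GeneratorConfig:
    occ = cond.get("ext_occupancy", 0.0) if with_ions else 0.0
    return GeneratorConfig(
        seed=_cond_seed(cfg.seed, tag, cond["molecule"], cond["ion"], cond["conc_mM"]),
        n_frames=n_frames,
        n_bp=cfg.n_bp,
        form_name="A" if cond["molecule"] == "rna" else "B",
        true_P_nm=cond["P_nm"],
        cation=cond["ion"],
        bulk_mM=cond["conc_mM"] if with_ions else 0.0,
        ext_occupancy=occ,
        major_occupancy=0.10 if with_ions else 0.0,
        minor_occupancy=0.05 if with_ions else 0.0,
    )


def _stage_forceext(cfg: PipelineConfig, ref: dict) -> pd.DataFrame:
    rows = []
    for cond in cfg.conditions:
        mol = cond["molecule"]
        n_bp = int(ref["construct_n_bp"])
        rise = ref[f"rise_{mol}"]
        Lc = rise * (n_bp - 1)
        fits = []
        for k in range(cfg.n_molecules):
            curve = synth_force_extension(
                cond["P_nm"], Lc, np.geomspace(0.05, 30.0, 40),
                noise_x_nm=cfg.noise_x_nm,
                seed=_cond_seed(cfg.seed, "fx", mol, cond["conc_mM"], k),
                molecule_id=f"{mol}-{k}", ion=cond["ion"],
                salt_mM=cond["conc_mM"], n_bp=n_bp,
            )
            fits.append(fit_force_extension(curve))
        agg = aggregate_condition(fits)
        rows.append({
            "molecule": mol, "ion": cond["ion"], "salt_mM": cond["conc_mM"],
            "true_P_nm": cond["P_nm"],
            "P_mean_nm": agg["P_nm"]["mean"], "P_se_nm": agg["P_nm"]["se"],
            "Lc_mean_nm": agg["Lc_nm"]["mean"],
            "rise_nm_per_bp": agg["Lc_nm"]["mean"] / (n_bp - 1),
            "n_molecules": agg["n_molecules"],
        })
    return pd.DataFrame(rows)


def _stage_bend(cfg: PipelineConfig) -> pd.DataFrame:
    rows = []
    for cond in cfg.conditions:
        mol = cond["molecule"]
        traj = sample_trajectory(_gen_config(cfg, cond, cfg.n_frames_bend, False, "bend"))
        ens = collect_segments(traj, SEGMENT_BP[mol], exclude_terminal=cfg.exclude_terminal)
        hist = angle_histogram(ens, bin_width_deg=cfg.bin_width_deg)
        fit = fit_P_from_pdf(hist, ens.segment_Lc_nm)
        rows.append({
            "molecule": mol, "ion": cond["ion"], "salt_mM": cond["conc_mM"],
            "true_P_nm": cond["P_nm"], "P_fit_nm": fit.P_nm,
            "P_se_nm": fit.P_se_nm, "segment_bp": SEGMENT_BP[mol],
            "segment_Lc_nm": ens.segment_Lc_nm, "n_angles": len(ens),
        })
    return pd.DataFrame(rows)


def _stage_ions(cfg: PipelineConfig) -> pd.DataFrame:
    rows = []
    for cond in cfg.conditions:
        traj = sample_trajectory(_gen_config(cfg, cond, cfg.n_frames_ions, True, "ions"))
        rep = charge_fractions(
            traj,
            helical_cutoff_nm=cfg.helical_cutoff_nm,
            phosphate_cutoff_nm=cfg.phosphate_cutoff_nm,
        )
        row = {"molecule": cond["molecule"], "ion": cond["ion"],
               "salt_mM": cond["conc_mM"],
               "planted_external": cond.get("ext_occupancy", 0.0)}
        for shell in ("external", "internal_major", "internal_minor", "total"):
            row[f"{shell}_e_per_nt"] = rep.mean[shell]
            row[f"{shell}_sd"] = rep.block_sd[shell]
        rows.append(row)
    return pd.DataFrame(rows)


def _stage_grooves(cfg: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    fluc_rows, pcc_frames = [], []
    for cond in cfg.conditions:
        traj = sample_trajectory(_gen_config(cfg, cond, cfg.n_frames_grooves, False, "grooves"))
        for obs in ("total_groove_width", "inclination"):
            prof = fluctuation_profile(traj, obs)
            fluc_rows.append({
                "molecule": cond["molecule"], "ion": cond["ion"],
                "salt_mM": cond["conc_mM"], "observable": obs,
                "mean_sd": prof["mean"], "block_sd": prof["block_sd"],
            })
        rep = correlate_with_bend(traj)
        scr = parameter_screen(traj)
        t = pd.concat([rep.table, scr.table], ignore_index=True).drop_duplicates("observable")
        t.insert(0, "salt_mM", cond["conc_mM"])
        t.insert(0, "molecule", cond["molecule"])
        pcc_frames.append(t)
    return pd.DataFrame(fluc_rows), pd.concat(pcc_frames, ignore_index=True)


def _stage_decompose(cfg: PipelineConfig) -> pd.DataFrame:
    rows = []
    for cond in cfg.conditions:
        if cond["conc_mM"] != 150.0:
            continue
        mol = cond["molecule"]
        form = A_FORM if mol == "rna" else B_FORM
        n_seg = SEGMENT_BP[mol]
        Lc = form.rise_nm * (n_seg - 1)
        ens = sample_wlc_angles(
            cond["P_nm"], Lc, 200_000,
            seed=_cond_seed(cfg.seed, "decomp", mol),
        )
        hist = angle_histogram(ens, bin_width_deg=2.0)
        prof = bending_energy(hist)
        mask = hist.counts >= 50
        theta = prof.theta_deg[mask]
        de_bend = prof.energy_kBT[mask]
        model = ElectrostaticModel(salt_mM=cond["conc_mM"])
        seg = make_ideal_helix(form, n_seg)
        de_el = delta_E_el(seg, theta, model)
        dec = decompose(theta, de_bend, de_el, Lc, weights=hist.counts[mask].astype(float))
        rows.append({
            "molecule": mol, "salt_mM": cond["conc_mM"], "Lc_nm": Lc,
            "P_nm": dec.P_nm, "P_el_nm": dec.P_el_nm, "P_nel_nm": dec.P_nel_nm,
        })
    return pd.DataFrame(rows)


def _stage_saltfit(tables: dict) -> pd.DataFrame:
    src = tables.get("bend_P")
    col = "P_fit_nm"
    if src is None:
        src = tables.get("fx_fits")
        col = "P_mean_nm"
    if src is None:
        raise ValueError("salt fitting needs the bend or forceext stage output")
    rows = []
    for (mol, ion), g in src.groupby(["molecule", "ion"]):
        if g.salt_mM.nunique() < 3:
            log.warning("saltfit: fewer than 3 concentrations for %s/%s", mol, ion)
            continue
        series = SaltSeries(conc_mM=g.salt_mM.to_numpy(), P_nm=g[col].to_numpy(),
                            ion=ion, molecule=mol)
        for model in ("OSF", "BJ"):
            fit = fit_salt_series(series, model)
            rows.append({
                "molecule": mol, "ion": ion, "model": model,
                "P_nel_nm": fit.P_nel_nm, "amplitude": fit.amplitude,
                "rss": fit.rss, "n_points": len(series),
            })
    return pd.DataFrame(rows)


_STAGE_FILES = {
    "fx_fits": "fx_fits.csv", "bend_P": "bend_P.csv", "ion_fractions": "ion_fractions.csv",
    "groove_fluctuations": "groove_fluctuations.csv", "pcc": "pcc.csv",
    "decomposition": "decomposition.csv", "salt_fits": "salt_fits.csv",
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured stages; returns (and writes) the report tables.

    Stage failures are logged and their dependents skipped; completed
    tables are still written. A manifest.json records the full
    configuration, package version and derived seeds.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref = load_reference_values()
    tables: dict[str, pd.DataFrame] = {}

    def _run(name, fn, *args):
        try:
            tables[name] = fn(*args)
        except Exception:
            log.exception("stage %s failed; dependents will be skipped", name)

    if "forceext" in cfg.stages:
        _run("fx_fits", _stage_forceext, cfg, ref)
    if "bend" in cfg.stages:
        _run("bend_P", _stage_bend, cfg)
    if "ions" in cfg.stages:
        _run("ion_fractions", _stage_ions, cfg)
    if "grooves" in cfg.stages:
        try:
            fluc, pcc = _stage_grooves(cfg)
            tables["groove_fluctuations"], tables["pcc"] = fluc, pcc
        except Exception:
            log.exception("stage grooves failed")
    if "decompose" in cfg.stages:
        _run("decomposition", _stage_decompose, cfg)
    if "saltfit" in cfg.stages:
        _run("salt_fits", _stage_saltfit, tables)

    for name, df in tables.items():
        df.to_csv(out / _STAGE_FILES[name], index=False)
    manifest = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "tables": {k: _STAGE_FILES[k] for k in tables},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return tables
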