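"""Synthetic-data generator: the stand-in for instrument and simulation.

Everything the analysis pipeline consumes can be produced here with known
ground truth: idealized A-/B-form helices, controllably bent conformations,
worm-like-chain (WLC) bending-angle ensembles, tangent-diffusion helix
trajectories with planted structural couplings, ion placements with
configured shell occupancies, and noisy force-extension curves from the
corrected WLC interpolation. Every generator is a pure function of its
configuration and seed.

Trajectory construction. Each frame is a discrete WLC: consecutive local
tangents differ by a random bend drawn from the WLC junction density
p(beta) ~ sin(beta) exp(-P beta^2 / 2h) at contour step h (the rise), with
uniform random azimuth, plus an independent half-step tangent wobble on
each base step (per-component variance h/2P). The wobble makes the
variance of the angle between the two *end-step* tangents of an m-bp
window equal to 2 h (m-1)/P for every m, i.e. exactly the WLC value for
the conventional window contour length Lc = (m-1) h, so that downstream
persistence-length estimates are unbiased for all segment lengths
simultaneously.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .bending import BendingEnsemble
from .constants import A_FORM, B_FORM, HelixForm, ion_number_density
from .forceext import ForceExtensionCurve, eval_wlc_force, FORCE_WINDOW_PN, BOUCHIAT_COEFFS
from .frames import HelixFrame, HelixTrajectory, IonSet

__all__ = [
    "GeneratorConfig",
    "make_ideal_helix",
    "bend_helix",
    "sample_wlc_angles",
    "sample_trajectory",
    "place_ions",
    "synth_force_extension",
]


# --------------------------------------------------------------------------
# small vector helpers

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _rodrigues(v: np.ndarray, axis: np.ndarray, angle) -> np.ndarray:
    """Rotate vectors ``v`` about unit ``axis`` by ``angle`` (radians).

    Shapes broadcast: v (..., 3), axis (..., 3), angle (...) or scalar.
    """
    angle = np.asarray(angle)[..., None]
    c, s = np.cos(angle), np.sin(angle)
    return (
        v * c
        + np.cross(axis, v) * s
        + axis * np.sum(axis * v, axis=-1, keepdims=True) * (1.0 - c)
    )


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# configuration

@dataclass
class GeneratorConfig:
    """Full configuration of the synthetic trajectory generator.

    Default values reproduce the near-physiological study condition:
    a 20-bp B-form duplex at 150 mM NaCl with a bending persistence
    length of 48 nm and an external cation occupancy of 0.36 e per
    nucleotide.
    """

    seed: int = 0
    n_frames: int = 2000
    n_bp: int = 20
    form_name: str = "B"                 # "A" (dsRNA-like) or "B" (dsDNA-like)
    true_P_nm: float = 48.0
    # structural noise
    phosphate_noise_nm: float = 0.02
    center_noise_nm: float = 0.0
    rise_noise_frac: float = 0.03        # per-step rise jitter (total groove width)
    groove_split_noise_nm: float = 0.06  # axial strand-0 jitter (d vs D split)
    groove_bend_coupling: float = 4.0    # rise-jitter amplitude vs frame bend (per rad)
    inclination_bend_coupling: float = 0.12  # deg inclination per deg frame bend
    inclination_noise_deg: float = 5.0
    # ion atmosphere
    cation: str = "Na"
    bulk_mM: float = 150.0
    ext_occupancy: float = 0.36          # bound cations per nucleotide, phosphate shell
    major_occupancy: float = 0.10        # bound cations per nucleotide, major groove
    minor_occupancy: float = 0.05        # bound cations per nucleotide, minor groove
    ion_bend_coupling: float = 0.0       # external occupancy vs frame bend
    li_binding_offset_nm: float = 0.05   # Li+ binds closer than Na+ by this much
    box_margin_nm: float = 3.0
    neutral_phosphates: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_bp < 4:
            raise ValueError("n_bp must be at least 4")
        if self.n_frames < 1:
            raise ValueError("n_frames must be at least 1")
        if self.true_P_nm <= 0:
            raise ValueError("true_P_nm must be positive")
        for name in ("ext_occupancy", "major_occupancy", "minor_occupancy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.bulk_mM < 0:
            raise ValueError("bulk concentration cannot be negative")
        if self.form_name not in ("A", "B"):
            raise ValueError("form_name must be 'A' or 'B'")

    @property
    def form(self) -> HelixForm:
        return A_FORM if self.form_name == "A" else B_FORM

    def to_dict(self) -> dict:
        return asdict(self)


# --------------------------------------------------------------------------
# ideal helices and controlled bends

def make_ideal_helix(form: HelixForm, n_bp: int, phosphate_charge: float = -1.0) -> HelixFrame:
    """Straight idealized duplex of ``n_bp`` base pairs.

    Base-pair centers lie on the z axis spaced by the form's rise;
    phosphorus atoms sit on two helical strands of the form's radius,
    separated azimuthally by the minor-groove gap; every base pair
    carries the form's inclination.
    """
    if n_bp < 4:
        raise ValueError("n_bp must be at least 4")
    i = np.arange(n_bp)
    chi = np.radians(i * form.twist_deg)
    centers = np.zeros((n_bp, 3))
    centers[:, 2] = i * form.rise_nm
    m = np.column_stack([np.cos(chi), np.sin(chi), np.zeros(n_bp)])  # minor dir
    t = np.tile([0.0, 0.0, 1.0], (n_bp, 1))
    v = np.cross(t, m)
    eta = np.radians(form.inclination_deg)
    long_axes = np.cos(eta) * v + np.sin(eta) * t
    half_gap = np.radians(form.minor_gap_deg / 2.0)
    phos = np.empty((2, n_bp, 3))
    for s, sign in enumerate((+1.0, -1.0)):
        ang = chi + sign * half_gap
        phos[s] = centers + form.radius_nm * np.column_stack(
            [np.cos(ang), np.sin(ang), np.zeros(n_bp)]
        )
    return HelixFrame(
        centers=centers,
        long_axes=long_axes,
        minor_axes=m,
        normals=t,
        phosphates=phos,
        phosphate_charge=phosphate_charge,
        form=form,
    )


def _bend_direction(frame: HelixFrame, direction, pivot: int, t_hat: np.ndarray) -> np.ndarray:
    """Unit bend-plane direction (the way the helix axis tilts), in-plane."""
    m = frame.minor_axes[pivot]
    m_perp = _unit(m - np.dot(m, t_hat) * t_hat)
    if isinstance(direction, str):
        if direction == "minor":
            return m_perp
        if direction == "major":
            return -m_perp
        raise ValueError("direction must be 'major', 'minor' or an azimuth in degrees")
    az = np.radians(float(direction))  # 0 = toward minor groove, 180 = toward major
    w = np.cross(t_hat, m_perp)
    return np.cos(az) * m_perp + np.sin(az) * w


def bend_helix(
    frame: HelixFrame,
    theta_deg: float,
    direction="major",
    pivot_step: int | None = None,
    mode: str = "arc",
    inclination_coupling: float = 0.2,
) -> HelixFrame:
    """Bend a (near-straight) helix by ``theta_deg`` toward a groove.

    ``mode="arc"`` (default) maps the helix onto a circular arc of
    constant curvature chosen so that the tangents of the two end base
    steps subtend ``theta_deg``; per-strand axial arc-length compensation
    keeps inter-phosphate distances along each strand essentially
    unchanged. ``mode="kink"`` concentrates the whole bend at the pivot
    step (useful for constructing axis-kink fixtures; it distorts the
    cross-kink backbone geometry).

    Bending toward the major groove raises the base-pair inclination
    around the pivot, toward the minor groove lowers it, through an
    explicit linear coupling (``inclination_coupling`` degrees of
    inclination per degree of local bend toward the major groove).
    """
    if not 0.0 <= theta_deg <= 90.0:
        raise ValueError("theta must lie in [0, 90] degrees")
    out = frame.copy()
    if theta_deg == 0.0:
        return out
    n = frame.n_bp
    if pivot_step is None:
        pivot_step = n // 2
    if not 0 <= pivot_step < n - 1:
        raise ValueError("pivot_step must index a base step")

    o = frame.centers[0]
    t_hat = _unit(frame.centers[-1] - o)
    d_hat = _bend_direction(frame, direction, pivot_step, t_hat)
    a_hat = np.cross(t_hat, d_hat)  # rotation axis: tilts t_hat toward d_hat
    theta = np.radians(theta_deg)

    z_c = (frame.centers - o) @ t_hat
    z_pivot = 0.5 * (z_c[pivot_step] + z_c[pivot_step + 1])

    def decompose(pts):
        z = (pts - o) @ t_hat
        q = pts - o - np.outer(z, t_hat)
        x = q @ d_hat
        y = q - np.outer(x, d_hat)
        return z, x, y

    if mode == "arc":
        # curvature over the axial span between the midpoints of the two
        # end base steps, so the end-step tangents subtend exactly theta
        span = 0.5 * (z_c[-1] + z_c[-2]) - 0.5 * (z_c[0] + z_c[1])
        kappa = theta / span
        R = 1.0 / kappa

        def bend_points(pts, compensate_strand=False):
            z, x, y = decompose(pts)
            if compensate_strand:
                # restore per-strand chord lengths: stretch axial spacing
                # where the strand runs on the inner side of the bend
                dz = np.diff(z)
                xbar = 0.5 * (x[:-1] + x[1:])
                dz_c = dz / (1.0 - kappa * xbar)
                z = np.concatenate([[z[0]], z[0] + np.cumsum(dz_c)])
            phi = kappa * (z - z_pivot)
            radial = R - x
            pos = (
                o
                + np.outer(np.full(z.shape, z_pivot), t_hat)
                + R * d_hat
                + np.outer(-radial * np.cos(phi), d_hat)
                + np.outer(radial * np.sin(phi), t_hat)
                + y
            )
            return pos, phi

        out.centers, phi_bp = bend_points(frame.centers)
        for s in range(2):
            out.phosphates[s], _ = bend_points(frame.phosphates[s], compensate_strand=True)
        rot_angle = phi_bp
    elif mode == "kink":
        hinge = o + z_pivot * t_hat
        rotated = lambda pts, above: np.where(
            above[:, None], hinge + _rodrigues(pts - hinge, a_hat, theta), pts
        )
        zc = z_c
        out.centers = rotated(frame.centers, zc > z_pivot)
        for s in range(2):
            zp = (frame.phosphates[s] - o) @ t_hat
            out.phosphates[s] = rotated(frame.phosphates[s], zp > z_pivot)
        rot_angle = np.where(zc > z_pivot, theta, 0.0)
    else:
        raise ValueError("mode must be 'arc' or 'kink'")

    # rotate the triads with their base pairs
    for name in ("long_axes", "minor_axes", "normals"):
        vec = getattr(frame, name)
        setattr(out, name, _rodrigues(vec, a_hat, rot_angle))

    # planted inclination response: local bend toward the major groove
    # raises inclination, toward the minor groove lowers it
    if inclination_coupling != 0.0:
        m_perp = out.minor_axes - np.sum(out.minor_axes * out.normals, axis=1, keepdims=True) * out.normals
        m_perp = _unit(m_perp)
        toward_major = -(m_perp @ d_hat)
        deta = np.radians(inclination_coupling * theta_deg * toward_major)
        l, nrm = out.long_axes, out.normals
        u = np.cross(l, nrm)
        u = _unit(u)
        out.long_axes = _unit(
            l * np.cos(deta)[:, None] + np.cross(u, l) * np.sin(deta)[:, None]
        )
    return out


# --------------------------------------------------------------------------
# WLC angle sampling

def _wlc_grid_cdf(P_nm: float, Lc_nm: float, n_grid: int = 4096):
    """Grid and CDF of p(theta) ~ sin(theta) exp(-P theta^2 / 2 Lc)."""
    scale = np.sqrt(Lc_nm / P_nm)
    theta_max = min(np.pi, 15.0 * scale)
    grid = np.linspace(0.0, theta_max, n_grid)
    pdf = np.sin(grid) * np.exp(-P_nm * grid**2 / (2.0 * Lc_nm))
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    return grid, cdf


def sample_wlc_angles(
    P_nm: float, Lc_nm: float, n: int, seed=0, n_grid: int = 4096
) -> BendingEnsemble:
    """Sample ``n`` i.i.d. WLC bending angles for segments of length Lc.

    Numerical inverse-CDF sampling of p(theta) ~ sin(theta)
    exp(-P theta^2 / 2 Lc) on theta in [0, pi], on an ``n_grid``-point
    grid. Reproducible for a fixed seed.
    """
    if P_nm <= 0 or Lc_nm <= 0:
        raise ValueError("P and Lc must be positive")
    if n < 1:
        raise ValueError("need at least one sample")
    rng = _rng(seed)
    grid, cdf = _wlc_grid_cdf(P_nm, Lc_nm, n_grid)
    u = rng.random(n)
    theta = np.interp(u, cdf, grid)
    return BendingEnsemble(
        angles_deg=np.degrees(theta),
        segment_Lc_nm=Lc_nm,
        source={"P_nm": P_nm, "sampler": "inverse-cdf", "n_grid": n_grid},
    )


# --------------------------------------------------------------------------
# trajectories

def _tangent_walk(cfg: GeneratorConfig, rng: np.random.Generator):
    """Discrete-WLC tangent/minor-vector walk, vectorized over frames.

    Builds the n-1 true step tangents S (junction bends sit *between*
    consecutive steps) and per-base-pair material frames, then applies
    the half-step tangent wobble to the step directions.

    Returns per-bp tangents T (F, n, 3), per-bp minor vectors M
    (F, n, 3), wobbled step directions D (F, n-1, 3) and per-frame
    end-step bend angles theta_f (radians, between D[:, 0] and D[:, -1]).
    """
    F, n = cfg.n_frames, cfg.n_bp
    h = cfg.form.rise_nm
    P = cfg.true_P_nm
    twist = np.radians(cfg.form.twist_deg)

    n_junctions = n - 2
    beta = np.radians(
        sample_wlc_angles(P, h, F * n_junctions, seed=rng).angles_deg
    ).reshape(F, n_junctions)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=(F, n_junctions))

    S = np.empty((F, n - 1, 3))   # true step tangents
    Ms = np.empty((F, n - 1, 3))  # minor direction at each step
    t = np.tile([0.0, 0.0, 1.0], (F, 1))
    m = np.tile([1.0, 0.0, 0.0], (F, 1))
    S[:, 0], Ms[:, 0] = t, m
    for j in range(n_junctions):
        # twist the material frame, then bend tangent and frame together
        m = _rodrigues(m, t, twist)
        w = np.cross(t, m)
        axis = np.cos(phi[:, j, None]) * m + np.sin(phi[:, j, None]) * w
        t = _rodrigues(t, axis, beta[:, j])
        m = _rodrigues(m, axis, beta[:, j])
        m = _unit(m - np.sum(m * t, axis=1, keepdims=True) * t)
        S[:, j + 1], Ms[:, j + 1] = t, m

    # per-base-pair frames: bp i uses its outgoing step's frame, the last
    # bp the incoming one with a final twist increment
    T = np.empty((F, n, 3))
    M = np.empty((F, n, 3))
    T[:, : n - 1], M[:, : n - 1] = S, Ms
    T[:, n - 1] = S[:, n - 2]
    M[:, n - 1] = _rodrigues(Ms[:, n - 2], S[:, n - 2], twist)

    # half-step tangent wobble on each base step (see module docstring)
    sigma_w = np.sqrt(h / (2.0 * P))
    w1 = rng.normal(0.0, sigma_w, size=(F, n - 1))
    w2 = rng.normal(0.0, sigma_w, size=(F, n - 1))
    Wvec = np.cross(S, Ms)
    D = _unit(S + w1[..., None] * Ms + w2[..., None] * Wvec)

    cos_tf = np.clip(np.einsum("fi,fi->f", D[:, 0], D[:, -1]), -1.0, 1.0)
    theta_f = np.arccos(cos_tf)
    return T, M, D, theta_f


def sample_trajectory(cfg: GeneratorConfig) -> HelixTrajectory:
    """Generate a seeded surrogate trajectory with planted couplings.

    Frame-to-frame conformations are independent discrete-WLC draws at
    the configured persistence length; structural couplings (groove-width
    fluctuation vs bend, inclination fluctuation vs bend, external ion
    occupancy vs bend) are planted with the configured coefficients.
    """
    rng = _rng(cfg.seed)
    F, n = cfg.n_frames, cfg.n_bp
    form = cfg.form
    h, r = form.rise_nm, form.radius_nm
    eta0 = form.inclination_deg

    T, M, D, theta_f = _tangent_walk(cfg, rng)

    # per-step rise field; its amplitude grows with frame bend, which
    # plants the total-groove-width-fluctuation vs bend correlation
    amp = cfg.rise_noise_frac * (1.0 + cfg.groove_bend_coupling * theta_f)
    rises = h * (1.0 + amp[:, None] * rng.normal(size=(F, n - 1)))
    rises = np.clip(rises, 0.2 * h, 2.0 * h)
    centers = np.zeros((F, n, 3))
    centers[:, 1:] = np.cumsum(rises[..., None] * D, axis=1)
    if cfg.center_noise_nm > 0:
        centers = centers + rng.normal(0.0, cfg.center_noise_nm, size=centers.shape)

    # strand phosphates; an axial jitter on strand 0 shifts each position
    # oppositely into the minor and major axial widths while leaving
    # their sum exactly unchanged (the d/D split noise)
    half_gap = np.radians(form.minor_gap_deg / 2.0)
    V = np.cross(T, M)
    cosg, sing = np.cos(half_gap), np.sin(half_gap)
    phos = np.empty((F, 2, n, 3))
    phos[:, 0] = centers + r * (cosg * M + sing * V)
    phos[:, 1] = centers + r * (cosg * M - sing * V)
    if cfg.groove_split_noise_nm > 0:
        split = rng.normal(0.0, cfg.groove_split_noise_nm, size=(F, n))
        phos[:, 0] += split[..., None] * T
    if cfg.phosphate_noise_nm > 0:
        phos = phos + rng.normal(0.0, cfg.phosphate_noise_nm, size=phos.shape)

    # base-pair long axes with planted inclination fluctuation
    chi = np.cumsum(np.full((F, n), np.radians(form.twist_deg)), axis=1)
    psi = rng.uniform(0.0, 2.0 * np.pi, size=(F, 1))
    eta = (
        eta0
        + cfg.inclination_bend_coupling * np.degrees(theta_f)[:, None] * np.sin(chi + psi)
        + cfg.inclination_noise_deg * rng.normal(size=(F, n))
    )
    eta_r = np.radians(eta)[..., None]
    long_axes = np.cos(eta_r) * V + np.sin(eta_r) * T

    charge = 0.0 if cfg.neutral_phosphates else -1.0
    traj = HelixTrajectory(
        centers=centers,
        long_axes=long_axes,
        minor_axes=M,
        normals=T,
        phosphates=phos,
        phosphate_charge=charge,
        form=form,
        metadata={
            "config": cfg.to_dict(),
            "frame_bend_deg": np.degrees(theta_f),
        },
    )

    if cfg.bulk_mM > 0 or cfg.ext_occupancy > 0 or cfg.major_occupancy > 0 or cfg.minor_occupancy > 0:
        traj.ions = _place_ions_trajectory(traj, cfg, theta_f, rng)
    return traj


# --------------------------------------------------------------------------
# ions

def _box_bounds(points: np.ndarray, margin: float):
    lo = points.reshape(-1, 3).min(axis=0) - margin
    hi = points.reshape(-1, 3).max(axis=0) + margin
    return lo, hi


def _place_ions_one(
    frame: HelixFrame,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    ext_occupancy: float | None = None,
    box=None,
):
    """Place ions around one frame; returns (species, charges, positions)."""
    form = frame.form or cfg.form
    n_bp = frame.n_bp
    n_nt = frame.n_nt
    occ_ext = cfg.ext_occupancy if ext_occupancy is None else ext_occupancy
    cat = cfg.cation
    d_off = cfg.li_binding_offset_nm if cat == "Li" else 0.0

    if box is None:
        box = _box_bounds(frame.phosphates, cfg.box_margin_nm)
    lo, hi = box
    vol = float(np.prod(hi - lo))

    species, charges, positions = [], [], []

    def _append(n, sp, q, pos):
        if n:
            species.extend([sp] * n)
            charges.extend([q] * n)
            positions.append(pos)

    # external: just outside a random phosphate, pointing away from the axis
    n_ext = rng.poisson(max(occ_ext, 0.0) * n_nt)
    if n_ext:
        idx = rng.integers(0, n_nt, size=n_ext)
        strand, bp = idx // n_bp, idx % n_bp
        p = frame.phosphates[strand, bp]
        u = _unit(p - frame.centers[bp])
        dist = rng.uniform(0.22, 0.50, size=n_ext) - d_off
        jitter = rng.normal(0.0, 0.03, size=(n_ext, 3))
        _append(n_ext, cat, 1.0, p + dist[:, None] * u + jitter)

    # internal: inside a groove sector at sub-cutoff axis distance
    gap_half = form.minor_gap_deg / 2.0
    margin = 15.0
    for occ, which in ((cfg.major_occupancy, "major"), (cfg.minor_occupancy, "minor")):
        n_int = rng.poisson(occ * n_nt)
        if not n_int:
            continue
        bp = rng.integers(0, n_bp, size=n_int)
        if which == "major":
            az = rng.uniform(gap_half + margin, 360.0 - gap_half - margin, size=n_int)
        else:
            az = rng.uniform(-gap_half + margin, gap_half - margin, size=n_int)
        az = np.radians(az)
        rho = rng.uniform(0.2, 0.8, size=n_int)
        axial = rng.uniform(-0.5, 0.5, size=n_int) * form.rise_nm
        m = frame.minor_axes[bp]
        t = frame.normals[bp]
        v = np.cross(t, m)
        pos = (
            frame.centers[bp]
            + rho[:, None] * (np.cos(az)[:, None] * m + np.sin(az)[:, None] * v)
            + axial[:, None] * t
        )
        _append(n_int, cat, 1.0, pos)

    n_bound = sum(1 for q in charges if q > 0)

    # bulk pairs at the configured concentration, plus the counterions
    # needed for exact electroneutrality of the charged duplex
    n_pairs = rng.poisson(ion_number_density(cfg.bulk_mM) * vol)
    helix_charge = n_nt if frame.phosphate_charge < 0 else 0
    deficit = helix_charge - n_bound
    n_cat_bulk = n_pairs + max(deficit, 0)
    n_an_bulk = n_pairs + max(-deficit, 0)

    n_total = n_bound + n_cat_bulk + n_an_bulk
    if n_total * 0.027 > 0.5 * vol:  # ~0.3 nm cube per ion packing limit
        raise ValueError(
            f"box too small to hold {n_total} ions (volume {vol:.0f} nm^3)"
        )
    _append(n_cat_bulk, cat, 1.0, rng.uniform(lo, hi, size=(n_cat_bulk, 3)))
    _append(n_an_bulk, "Cl", -1.0, rng.uniform(lo, hi, size=(n_an_bulk, 3)))

    if positions:
        pos = np.concatenate(positions)
    else:
        pos = np.empty((0, 3))
    return np.array(species), np.array(charges, dtype=float), pos


def place_ions(frame: HelixFrame, cfg: GeneratorConfig, seed=None) -> IonSet:
    """Place ions around a single frame per the configured occupancies.

    Expected per-nucleotide bound-cation counts in the external /
    internal-major / internal-minor shells equal the configured
    occupancies (Poisson realization); remaining ions are uniform in the
    simulation box at the bulk concentration, with counterions added so
    the box is exactly charge-neutral whenever the duplex is charged.
    """
    rng = _rng(cfg.seed if seed is None else seed)
    sp, q, pos = _place_ions_one(frame, cfg, rng)
    return IonSet(species=sp, charges=q, positions=pos[None])


def _place_ions_trajectory(
    traj: HelixTrajectory,
    cfg: GeneratorConfig,
    theta_f: np.ndarray,
    rng: np.random.Generator,
) -> IonSet:
    """Per-frame ion placement with optional bend-coupled occupancy."""
    F = traj.n_frames
    box = _box_bounds(traj.phosphates, cfg.box_margin_nm)
    if cfg.ion_bend_coupling != 0.0 and F > 1:
        tbar = float(np.mean(theta_f))
        occs = cfg.ext_occupancy * (
            1.0 + cfg.ion_bend_coupling * (theta_f - tbar) / max(tbar, 1e-9)
        )
        occs = np.clip(occs, 0.0, 1.0)
    else:
        occs = np.full(F, cfg.ext_occupancy)

    per_frame = [
        _place_ions_one(traj.frame(i), cfg, rng, ext_occupancy=float(occs[i]), box=box)
        for i in range(F)
    ]
    # fixed slot layout: cation block first, anion block second, so the
    # shared species/charge arrays are frame-independent; unused slots
    # are inactive and parked far outside the box
    n_cat = [int(np.sum(q > 0)) for _, q, _ in per_frame]
    n_an = [int(np.sum(q < 0)) for _, q, _ in per_frame]
    max_cat, max_an = max(n_cat), max(n_an)
    n_slots = max_cat + max_an
    species = np.array([cfg.cation] * max_cat + ["Cl"] * max_an)
    charges = np.concatenate([np.ones(max_cat), -np.ones(max_an)])
    positions = np.full((F, n_slots, 3), 1e6)
    active = np.zeros((F, n_slots), dtype=bool)
    for i, (sp, q, pos) in enumerate(per_frame):
        cat_pos, an_pos = pos[q > 0], pos[q < 0]
        positions[i, : n_cat[i]] = cat_pos
        active[i, : n_cat[i]] = True
        positions[i, max_cat : max_cat + n_an[i]] = an_pos
        active[i, max_cat : max_cat + n_an[i]] = True
    return IonSet(species=species, charges=charges, positions=positions, active=active)


# --------------------------------------------------------------------------
# force-extension curves

def synth_force_extension(
    P_nm: float,
    Lc_nm: float,
    forces_pN: np.ndarray,
    noise_x_nm: float = 5.0,
    seed=0,
    T: float = 295.0,
    coeffs: np.ndarray = BOUCHIAT_COEFFS,
    molecule_id: str = "",
    ion: str = "Na",
    salt_mM: float = 150.0,
    n_bp: int | None = None,
) -> ForceExtensionCurve:
    """Noisy synthetic force-extension curve from the corrected WLC model.

    For each force the exact extension is found by monotone root finding
    on x in [0, Lc); Gaussian noise of the stated sigma is then added to
    the extensions (extension, not force, is the noisy observable in a
    magnetic-tweezers record).
    """
    from scipy.optimize import brentq

    if P_nm <= 0 or Lc_nm <= 0:
        raise ValueError("P and Lc must be positive")
    forces = np.asarray(forces_pN, dtype=float)
    valid = (forces > FORCE_WINDOW_PN[0]) & (forces < FORCE_WINDOW_PN[1])
    if not np.all(valid):
        warnings.warn(
            "some forces lie outside the recommended validity window "
            f"{FORCE_WINDOW_PN}; they are flagged in curve.valid"
        )
    rng = _rng(seed)
    x = np.empty_like(forces)
    for i, F in enumerate(forces):
        f = lambda u: eval_wlc_force(P_nm, Lc_nm, u * Lc_nm, T=T, coeffs=coeffs) - F
        x[i] = brentq(f, 0.0, 1.0 - 1e-10, xtol=1e-14, rtol=1e-15) * Lc_nm
    if noise_x_nm > 0:
        x = x + rng.normal(0.0, noise_x_nm, size=x.shape)
        x = np.clip(x, 0.0, None)
    meta = {"true_P_nm": P_nm, "true_Lc_nm": Lc_nm}
    if n_bp is not None:
        meta["n_bp"] = n_bp
    return ForceExtensionCurve(
        extension_nm=x,
        force_pN=forces,
        temperature_K=T,
        molecule_id=molecule_id,
        ion=ion,
        salt_mM=salt_mM,
        valid=valid,
        meta=meta,
    )
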