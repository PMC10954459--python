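"""In-memory containers for coarse helix conformations and trajectories.

A conformation ("frame") stores, per base pair: the base-pair reference
point (center), an orthonormal-ish triad encoded as three unit vectors
(long axis, minor-groove direction, local helical direction), and the two
strands' phosphorus positions. Ions live in a separate :class:`IonSet`
aligned with the trajectory's frame axis. All coordinates are in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .constants import HelixForm

__all__ = ["HelixFrame", "HelixTrajectory", "IonSet", "ION_CHARGES"]

#: Default signed charge (e) by ion species.
ION_CHARGES = {"Na": 1.0, "Li": 1.0, "K": 1.0, "Cl": -1.0}


def _as_unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / n


@dataclass
class HelixFrame:
    """One coarse duplex conformation.

    Attributes
    ----------
    centers : (n_bp, 3) array
        Base-pair reference points.
    long_axes : (n_bp, 3) array
        Unit base-pair long axes (the direction spanning the pair).
    minor_axes : (n_bp, 3) array
        Unit vectors pointing from the axis into the minor groove.
    normals : (n_bp, 3) array
        Unit local helical directions at each base pair.
    phosphates : (2, n_bp, 3) array
        Phosphorus positions of strand 0 and strand 1.
    phosphate_charge : float
        Charge per phosphate in e (-1 normally, 0 for the electrically
        neutral variants).
    form : HelixForm or None
        Construction geometry, when the frame came from the generator.
    """

    centers: np.ndarray
    long_axes: np.ndarray
    minor_axes: np.ndarray
    normals: np.ndarray
    phosphates: np.ndarray
    phosphate_charge: float = -1.0
    form: HelixForm | None = None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        n = self.centers.shape[0]
        for name in ("long_axes", "minor_axes", "normals"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n, 3):
                raise ValueError(f"{name} must have shape ({n}, 3)")
            setattr(self, name, arr)
        self.phosphates = np.asarray(self.phosphates, dtype=float)
        if self.phosphates.shape != (2, n, 3):
            raise ValueError(f"phosphates must have shape (2, {n}, 3)")

    @property
    def n_bp(self) -> int:
        return self.centers.shape[0]

    @property
    def n_nt(self) -> int:
        """Number of nucleotides (phosphate sites)."""
        return 2 * self.n_bp

    def copy(self) -> "HelixFrame":
        return HelixFrame(
            centers=self.centers.copy(),
            long_axes=self.long_axes.copy(),
            minor_axes=self.minor_axes.copy(),
            normals=self.normals.copy(),
            phosphates=self.phosphates.copy(),
            phosphate_charge=self.phosphate_charge,
            form=self.form,
        )

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "HelixFrame":
        """Rigidly transformed copy: x -> R x + t."""
        R = np.asarray(R, dtype=float)
        t = np.asarray(t, dtype=float)
        return HelixFrame(
            centers=self.centers @ R.T + t,
            long_axes=_as_unit(self.long_axes @ R.T),
            minor_axes=_as_unit(self.minor_axes @ R.T),
            normals=_as_unit(self.normals @ R.T),
            phosphates=self.phosphates @ R.T + t,
            phosphate_charge=self.phosphate_charge,
            form=self.form,
        )


@dataclass
class IonSet:
    """Ions of a trajectory, constant identity across frames.

    ``positions`` has shape (n_frames, n_ions, 3); ``active`` marks which
    ion slots are present in each frame (slots allow frame-dependent
    occupancies without ragged storage).
    """

    species: np.ndarray          # (n_ions,) str
    charges: np.ndarray          # (n_ions,) float, e
    positions: np.ndarray        # (n_frames, n_ions, 3) nm
    active: np.ndarray | None = None  # (n_frames, n_ions) bool

    def __post_init__(self) -> None:
        self.species = np.asarray(self.species)
        self.charges = np.asarray(self.charges, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim == 2:
            self.positions = self.positions[None]
        if self.active is None:
            self.active = np.ones(self.positions.shape[:2], dtype=bool)
        else:
            self.active = np.asarray(self.active, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_ions(self) -> int:
        return self.positions.shape[1]

    def frame(self, i: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(species, charges, positions) of the ions present in frame i."""
        m = self.active[i]
        return self.species[m], self.charges[m], self.positions[i][m]


@dataclass
class HelixTrajectory:
    """Ordered frames of a coarse duplex, with optional ions.

    Per-frame arrays are stacked along the leading axis; ``frame(i)``
    returns a :class:`HelixFrame` view-copy of frame ``i``.
    """

    centers: np.ndarray      # (n_frames, n_bp, 3)
    long_axes: np.ndarray
    minor_axes: np.ndarray
    normals: np.ndarray
    phosphates: np.ndarray   # (n_frames, 2, n_bp, 3)
    phosphate_charge: float = -1.0
    form: HelixForm | None = None
    ions: IonSet | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.centers.shape[0]

    @property
    def n_bp(self) -> int:
        return self.centers.shape[1]

    def frame(self, i: int) -> HelixFrame:
        return HelixFrame(
            centers=self.centers[i],
            long_axes=self.long_axes[i],
            minor_axes=self.minor_axes[i],
            normals=self.normals[i],
            phosphates=self.phosphates[i],
            phosphate_charge=self.phosphate_charge,
            form=self.form,
        )

    def __iter__(self) -> Iterator[HelixFrame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    @classmethod
    def from_frames(
        cls,
        frames: list[HelixFrame],
        ions: IonSet | None = None,
        metadata: dict | None = None,
    ) -> "HelixTrajectory":
        if not frames:
            raise ValueError("cannot build a trajectory from zero frames")
        return cls(
            centers=np.stack([f.centers for f in frames]),
            long_axes=np.stack([f.long_axes for f in frames]),
            minor_axes=np.stack([f.minor_axes for f in frames]),
            normals=np.stack([f.normals for f in frames]),
            phosphates=np.stack([f.phosphates for f in frames]),
            phosphate_charge=frames[0].phosphate_charge,
            form=frames[0].form,
            ions=ions,
            metadata=metadata or {},
        )

    def mean_rise(self) -> float:
        """Mean base-pair step length over all frames (nm)."""
        steps = np.diff(self.centers, axis=1)
        return float(np.mean(np.linalg.norm(steps, axis=-1)))

    def contour_lengths(self) -> np.ndarray:
        """Per-frame contour length along the base-pair centers (nm)."""
        steps = np.diff(self.centers, axis=1)
        return np.linalg.norm(steps, axis=-1).sum(axis=1)
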