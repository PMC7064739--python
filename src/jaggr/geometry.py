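"""Shared geometric primitives: periodic boxes, molecules, axes.

All coordinates are in Angstrom and all masses in amu. Boxes are
orthorhombic; the minimum-image convention is applied component-wise.
Molecules are assumed whole (no atom pair split across periodic images);
:func:`Configuration.validate_whole` checks this.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Box",
    "MoleculeRecord",
    "Configuration",
    "Trajectory",
    "AxisFrame",
    "center_of_mass",
    "longest_principal_axis",
    "minimum_image_vector",
    "minimum_image_distance",
    "pair_angle",
    "compute_axis_frame",
    "p2",
    "DegenerateAxisError",
]

#: relative eigenvalue-gap tolerance below which the longest axis is
#: considered degenerate (e.g. square-planar or spherical molecules)
DEGENERACY_RTOL = 1e-6

#: unit-vector norm tolerance accepted by :func:`pair_angle`
UNIT_TOL = 1e-6


class DegenerateAxisError(ValueError):
    """Raised when a molecule has no unique longest principal axis."""


def p2(x):
    """Second Legendre polynomial P2(x) = (3x^2 - 1)/2."""
    x = np.asarray(x, dtype=float)
    return 1.5 * x * x - 0.5


@dataclass(frozen=True)
class Box:
    """Orthorhombic periodic cell with edge lengths in Angstrom."""

    lx: float
    ly: float
    lz: float

    def __post_init__(self):
        if not (self.lx > 0 and self.ly > 0 and self.lz > 0):
            raise ValueError(f"box edges must be positive, got {self}")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.lx, self.ly, self.lz], dtype=float)

    @property
    def volume(self) -> float:
        return float(self.lx * self.ly * self.lz)

    @property
    def half_min_edge(self) -> float:
        return 0.5 * min(self.lx, self.ly, self.lz)

    def wrap(self, points: np.ndarray) -> np.ndarray:
        """Wrap coordinates into [0, L) along each axis."""
        pts = np.asarray(points, dtype=float)
        return pts - np.floor(pts / self.lengths) * self.lengths


@dataclass
class MoleculeRecord:
    """One molecule: atom positions (n,3), masses (n,), optional head/tail.

    ``head_atom``/``tail_atom`` are atom indices that orient the long axis
    (head -> tail); when absent, the axis sign is only canonical, not
    physically oriented.
    """

    molecule_id: int
    positions: np.ndarray
    masses: np.ndarray
    head_atom: Optional[int] = None
    tail_atom: Optional[int] = None

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.masses = np.atleast_1d(np.asarray(self.masses, dtype=float))
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_atoms, 3)")
        if self.masses.shape[0] != self.positions.shape[0]:
            raise ValueError("masses length must match number of atoms")
        if self.positions.shape[0] < 1:
            raise ValueError("molecule needs at least one atom")
        if np.any(self.masses <= 0):
            raise ValueError("all atomic masses must be positive")
        if self.head_atom is not None and self.head_atom == self.tail_atom:
            raise ValueError("head_atom and tail_atom must differ")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @property
    def has_orientation(self) -> bool:
        return self.head_atom is not None and self.tail_atom is not None


@dataclass
class Configuration:
    """A single frame: molecules plus the periodic box."""

    molecules: Sequence[MoleculeRecord]
    box: Box
    frame_index: int = 0

    def __post_init__(self):
        ids = [m.molecule_id for m in self.molecules]
        if len(set(ids)) != len(ids):
            raise ValueError("molecule_ids must be unique within a frame")

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    def validate_whole(self) -> None:
        """Error if any intra-molecular atom pair exceeds half the box.

        Molecules split across periodic images would silently corrupt
        centers of mass and axes; this check refuses such input.
        """
        limit = self.box.half_min_edge
        for mol in self.molecules:
            span = mol.positions.max(axis=0) - mol.positions.min(axis=0)
            if np.linalg.norm(span) > limit:
                raise ValueError(
                    f"molecule {mol.molecule_id} spans {np.linalg.norm(span):.2f} A, "
                    f"more than half the smallest box edge ({limit:.2f} A); "
                    "molecules must be whole (unwrapped) within each frame"
                )


@dataclass
class Trajectory:
    """An ordered sequence of configurations (frames)."""

    frames: Sequence[Configuration] = field(default_factory=list)

    def __post_init__(self):
        self.frames = list(self.frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class AxisFrame:
    """Per-molecule reduced representation of one frame.

    ``coms`` (n,3) and ``axes`` (n,3, unit norm) in the frame's box.
    ``oriented`` is True only when every molecule carried a head/tail
    convention, i.e. axis signs are physically meaningful and pair angles
    span the full 0-180 degrees.
    """

    molecule_ids: np.ndarray
    coms: np.ndarray
    axes: np.ndarray
    box: Box
    oriented: bool

    @property
    def n_molecules(self) -> int:
        return self.coms.shape[0]


def center_of_mass(mol: MoleculeRecord) -> np.ndarray:
    """Mass-weighted mean atom position, in Angstrom.

    Atoms are assumed pre-unwrapped within the molecule.
    """
    total = mol.masses.sum()
    if total <= 0:
        raise ValueError("total molecular mass must be positive")
    return (mol.masses[:, None] * mol.positions).sum(axis=0) / total


def longest_principal_axis(mol: MoleculeRecord) -> tuple[np.ndarray, bool]:
    """Unit vector along the molecule's longest spatial extent.

    Computed as the largest-variance eigenvector of the mass-weighted
    gyration tensor, which for rod-like molecules coincides with the
    smallest-moment-of-inertia direction. Returns ``(axis, oriented)``:
    if head/tail atoms are set the sign points head -> tail and
    ``oriented`` is True; otherwise the sign is canonicalized (first
    component of magnitude > tolerance made positive).

    Raises
    ------
    DegenerateAxisError
        If all atoms coincide, or the two largest eigenvalues agree to
        within ``DEGENERACY_RTOL`` (no unique longest axis).
    """
    if mol.n_atoms < 2:
        raise DegenerateAxisError("need at least two atoms to define an axis")
    com = center_of_mass(mol)
    rel = mol.positions - com
    w = mol.masses / mol.masses.sum()
    gyr = (w[:, None, None] * rel[:, :, None] * rel[:, None, :]).sum(axis=0)
    evals, evecs = np.linalg.eigh(gyr)  # ascending
    if evals[-1] <= 0 or not np.isfinite(evals).all():
        raise DegenerateAxisError("all atoms coincident: no spatial extent")
    gap = (evals[-1] - evals[-2]) / evals[-1]
    if gap < DEGENERACY_RTOL:
        raise DegenerateAxisError(
            f"longest axis degenerate: two largest gyration eigenvalues "
            f"({evals[-1]:.6g}, {evals[-2]:.6g}) agree to within {DEGENERACY_RTOL}"
        )
    axis = evecs[:, -1]
    axis = axis / np.linalg.norm(axis)
    if mol.has_orientation:
        direction = mol.positions[mol.tail_atom] - mol.positions[mol.head_atom]
        if float(axis @ direction) < 0:
            axis = -axis
        return axis, True
    # canonical sign: first non-negligible component positive
    for comp in axis:
        if abs(comp) > 1e-12:
            if comp < 0:
                axis = -axis
            break
    return axis, False


def minimum_image_vector(a: np.ndarray, b: np.ndarray, box: Box) -> np.ndarray:
    """Nearest-image displacement b - a, each component in (-L/2, L/2]."""
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    L = box.lengths
    return d - L * np.ceil(d / L - 0.5)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: Box) -> float:
    return float(np.linalg.norm(minimum_image_vector(a, b, box)))


def pair_angle(axis_i: np.ndarray, axis_j: np.ndarray, oriented: bool) -> float:
    """Angle between two molecular axes, in degrees.

    Oriented axes give the full [0, 180] range; unoriented axes are
    folded to [0, 90] because their sign is arbitrary.
    """
    a = np.asarray(axis_i, dtype=float)
    b = np.asarray(axis_j, dtype=float)
    for v in (a, b):
        if abs(np.linalg.norm(v) - 1.0) > UNIT_TOL:
            raise ValueError(f"axis is not a unit vector: |v| = {np.linalg.norm(v)}")
    c = float(np.clip(a @ b, -1.0, 1.0))
    if not oriented:
        c = abs(c)
    return float(np.degrees(np.arccos(c)))


def compute_axis_frame(config: Configuration) -> AxisFrame:
    """Reduce a configuration to per-molecule COMs and long axes.

    The frame is oriented only if every molecule defines head/tail atoms.
    """
    coms = np.empty((config.n_molecules, 3))
    axes = np.empty((config.n_molecules, 3))
    oriented = True
    ids = np.empty(config.n_molecules, dtype=int)
    for k, mol in enumerate(config.molecules):
        coms[k] = center_of_mass(mol)
        axis, ok = longest_principal_axis(mol)
        axes[k] = axis
        oriented = oriented and ok
        ids[k] = mol.molecule_id
    return AxisFrame(molecule_ids=ids, coms=coms, axes=axes, box=config.box,
                     oriented=oriented)
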