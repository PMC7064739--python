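"""Synthetic rod-molecule configurations with known ground truth.

Stands in for atomistic MD frames of a small number of rod-like dye
molecules near a lipid bilayer: molecules are rigid rods of equally
spaced, equal-mass atoms; bilayer templating is emulated by a nematic
director with a target order parameter S and an optional slab that
confines centers of mass in z. Planted-cluster mode produces
configurations whose single-linkage decomposition at a chosen cutoff is
known exactly.

Axis sampling for a target S uses the two-component mixture
``S * delta(director) + (1-S) * isotropic``: its single-molecule
orientational order <P2(a.n)> equals S exactly in expectation, and for
independent molecules the pairwise order <P2(a_i.a_j)> equals S**2 (the
Legendre addition theorem for azimuthally symmetric distributions).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import (
    Box,
    Configuration,
    MoleculeRecord,
    Trajectory,
    minimum_image_distance,
)

__all__ = ["GeneratorSpec", "PackingError", "generate_aligned",
           "generate_clustered", "generate_pair"]

#: rejection-sampling attempts per molecule before giving up
REJECTION_BUDGET = 100_000

#: mass assigned to every rod atom (amu); rods are homogeneous so the
#: value never affects COMs or axes
ATOM_MASS = 12.0


class PackingError(RuntimeError):
    """Raised when rejection sampling cannot place molecules at the
    requested density / separation."""


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic rod ensemble.

    All lengths in Angstrom. ``order_target`` is the nematic order S in
    [0, 1] relative to ``director``. ``slab_thickness`` (if set) confines
    COM z-coordinates to the slab centered at mid-box, emulating
    adsorption at a bilayer. ``planted_clusters`` is a list of
    ``(size, intra_max_separation)`` tuples used by
    :func:`generate_clustered`. Frames are i.i.d. redraws standing in for
    an ensemble-and-time average.
    """

    n_molecules: int = 15
    atoms_per_molecule: int = 3
    rod_length: float = 10.0
    director: tuple[float, float, float] = (0.0, 0.0, 1.0)
    order_target: float = 0.0
    box: tuple[float, float, float] = (100.0, 100.0, 100.0)
    slab_thickness: Optional[float] = None
    planted_clusters: Sequence[tuple[int, float]] = field(default_factory=tuple)
    n_isolated: int = 0
    min_separation: float = 0.0
    frames: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules < 0 or self.n_isolated < 0 or self.frames < 1:
            raise ValueError("counts must be non-negative and frames >= 1")
        if self.atoms_per_molecule < 2:
            raise ValueError("rods need at least 2 atoms")
        if self.rod_length <= 0:
            raise ValueError("rod_length must be positive")
        if not 0.0 <= self.order_target <= 1.0:
            raise ValueError(f"order_target S must be in [0, 1], got {self.order_target}")
        if any(e <= 0 for e in self.box):
            raise ValueError("box edges must be positive")
        if self.slab_thickness is not None and self.slab_thickness <= 0:
            raise ValueError("slab_thickness must be positive")
        for size, sep in self.planted_clusters:
            if size < 2:
                raise ValueError("planted cluster sizes must be >= 2")
            if sep <= 0:
                raise ValueError("intra-cluster separation must be positive")
        if self.planted_clusters:
            total = sum(s for s, _ in self.planted_clusters) + self.n_isolated
            if total != self.n_molecules:
                raise ValueError(
                    f"n_molecules ({self.n_molecules}) must equal planted cluster "
                    f"sizes + n_isolated ({total})"
                )

    @property
    def box_obj(self) -> Box:
        return Box(*self.box)

    @property
    def director_unit(self) -> np.ndarray:
        d = np.asarray(self.director, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("director must be a nonzero vector")
        return d / n


def _sample_axes(n: int, director: np.ndarray, s: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Draw n unit axes with <P2(a.n)> = s via the delta/isotropic mixture."""
    axes = np.empty((n, 3))
    aligned = rng.random(n) < s
    n_iso = int((~aligned).sum())
    if n_iso:
        z = rng.uniform(-1.0, 1.0, n_iso)
        phi = rng.uniform(0.0, 2.0 * np.pi, n_iso)
        sin = np.sqrt(1.0 - z * z)
        iso = np.column_stack([sin * np.cos(phi), sin * np.sin(phi), z])
        # rotate the z-pole onto the director so the isotropic component
        # is expressed in the same frame (uniform is rotation invariant,
        # but keeping one frame simplifies reasoning)
        axes[~aligned] = iso
    axes[aligned] = director
    return axes


def _make_rod(molecule_id: int, com: np.ndarray, axis: np.ndarray,
              length: float, n_atoms: int) -> MoleculeRecord:
    """Rigid rod of equally spaced equal-mass atoms, head at -axis end."""
    t = np.linspace(-0.5, 0.5, n_atoms)
    positions = com[None, :] + (t * length)[:, None] * axis[None, :]
    return MoleculeRecord(
        molecule_id=molecule_id,
        positions=positions,
        masses=np.full(n_atoms, ATOM_MASS),
        head_atom=0,
        tail_atom=n_atoms - 1,
    )


def _place_coms(n: int, box: Box, slab: Optional[float], min_sep: float,
                rng: np.random.Generator) -> np.ndarray:
    """Uniform COMs in box (or slab), rejection-sampled for min_sep."""
    lengths = box.lengths
    coms = np.empty((n, 3))
    z0 = 0.5 * lengths[2]
    for i in range(n):
        for attempt in range(REJECTION_BUDGET):
            p = rng.uniform(0.0, 1.0, 3) * lengths
            if slab is not None:
                p[2] = z0 + rng.uniform(-0.5, 0.5) * slab
            if min_sep > 0 and any(
                minimum_image_distance(p, coms[j], box) < min_sep
                for j in range(i)
            ):
                continue
            coms[i] = p
            break
        else:
            raise PackingError(
                f"could not place molecule {i + 1}/{n} with min_separation "
                f"{min_sep} A in box {tuple(lengths)} after {REJECTION_BUDGET} "
                "attempts; density too high for the requested separation"
            )
    return coms


def generate_aligned(spec: GeneratorSpec) -> Trajectory:
    """Generate frames of rods with target nematic order S.

    Each molecule's axis is drawn independently from the delta/isotropic
    mixture about the director; COMs are uniform in the box (or slab),
    respecting ``min_separation`` under the minimum image convention.
    Deterministic for a given spec and seed.
    """
    if spec.planted_clusters:
        raise ValueError("generate_aligned takes no planted clusters; "
                         "use generate_clustered")
    rng = np.random.default_rng(spec.seed)
    box = spec.box_obj
    director = spec.director_unit
    frames = []
    for f in range(spec.frames):
        coms = _place_coms(spec.n_molecules, box, spec.slab_thickness,
                           spec.min_separation, rng)
        axes = _sample_axes(spec.n_molecules, director, spec.order_target, rng)
        mols = [
            _make_rod(i, coms[i], axes[i], spec.rod_length,
                      spec.atoms_per_molecule)
            for i in range(spec.n_molecules)
        ]
        frames.append(Configuration(molecules=mols, box=box, frame_index=f))
    return Trajectory(frames)


def generate_clustered(spec: GeneratorSpec,
                       cutoff: float) -> tuple[Trajectory, np.ndarray]:
    """Generate frames whose single-linkage clusters at ``cutoff`` are known.

    Each planted cluster's members lie within a ball of radius
    ``intra_max_separation / 2`` around a cluster center, so all
    intra-cluster pairwise COM distances are <= intra_max_separation
    (and <= cutoff). Cluster centers and isolated molecules are kept more
    than ``cutoff + max intra diameter`` apart, so no spurious links can
    form. Returns the trajectory and the per-molecule ground-truth labels
    (cluster index, or -1 for isolated), identical across frames.
    """
    if not spec.planted_clusters:
        raise ValueError("generate_clustered requires planted_clusters")
    for size, sep in spec.planted_clusters:
        if sep > cutoff:
            raise ValueError(
                f"intra-cluster max separation {sep} A exceeds cutoff {cutoff} A; "
                "planted clusters would not be single-linkage connected"
            )
    rng = np.random.default_rng(spec.seed)
    box = spec.box_obj
    director = spec.director_unit
    max_radius = max(sep for _, sep in spec.planted_clusters) / 2.0
    margin = cutoff + 2.0 * max_radius + 1.0  # safe inter-group distance
    if margin >= box.half_min_edge:
        raise ValueError(
            f"inter-group margin {margin:.1f} A exceeds half the smallest box "
            f"edge ({box.half_min_edge:.1f} A); enlarge the box"
        )
    n_groups = len(spec.planted_clusters) + spec.n_isolated
    labels = np.empty(spec.n_molecules, dtype=int)
    frames = []
    for f in range(spec.frames):
        centers = _place_coms(n_groups, box, spec.slab_thickness, margin, rng)
        coms = np.empty((spec.n_molecules, 3))
        idx = 0
        for ci, (size, sep) in enumerate(spec.planted_clusters):
            radius = sep / 2.0
            for _ in range(size):
                # uniform in a ball of the allowed radius
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                r = radius * rng.random() ** (1.0 / 3.0)
                coms[idx] = centers[ci] + r * v
                labels[idx] = ci
                idx += 1
        for k in range(spec.n_isolated):
            coms[idx] = centers[len(spec.planted_clusters) + k]
            labels[idx] = -1
            idx += 1
        axes = _sample_axes(spec.n_molecules, director, spec.order_target, rng)
        mols = [
            _make_rod(i, coms[i], axes[i], spec.rod_length,
                      spec.atoms_per_molecule)
            for i in range(spec.n_molecules)
        ]
        frames.append(Configuration(molecules=mols, box=box, frame_index=f))
    return Trajectory(frames), labels


def generate_pair(theta: float, r: float, box: Box,
                  rod_length: float = 10.0,
                  atoms_per_molecule: int = 3) -> Configuration:
    """Two identical rods at COM separation exactly ``r`` (Angstrom) with
    inter-axis angle exactly ``theta`` (degrees).

    The first rod's axis lies along x; the second is rotated by theta in
    the xy-plane; the COM offset is along z, perpendicular to both axes.
    """
    if not 0.0 <= theta <= 180.0:
        raise ValueError(f"theta must be in [0, 180] degrees, got {theta}")
    if not 0.0 < r < box.half_min_edge:
        raise ValueError(
            f"separation r must be in (0, {box.half_min_edge}) A for an "
            f"unambiguous minimum image, got {r}"
        )
    center = 0.5 * box.lengths
    th = np.radians(theta)
    axis1 = np.array([1.0, 0.0, 0.0])
    axis2 = np.array([np.cos(th), np.sin(th), 0.0])
    com1 = center - np.array([0.0, 0.0, r / 2.0])
    com2 = center + np.array([0.0, 0.0, r / 2.0])
    mols = [
        _make_rod(0, com1, axis1, rod_length, atoms_per_molecule),
        _make_rod(1, com2, axis2, rod_length, atoms_per_molecule),
    ]
    return Configuration(molecules=mols, box=box, frame_index=0)


def spec_to_dict(spec: GeneratorSpec) -> dict:
    """JSON-ready representation of a spec (for output sidecars)."""
    d = dataclasses.asdict(spec)
    d["planted_clusters"] = [list(t) for t in spec.planted_clusters]
    d["director"] = list(spec.director)
    d["box"] = list(spec.box)
    return d
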