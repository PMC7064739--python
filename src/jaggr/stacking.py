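"""Geometric J- vs H-aggregate classification of close molecule pairs.

In the point-dipole exciton picture, a pair of stacked dye molecules is a
J-aggregate (red-shifted, slipped / head-to-tail stacking) when the
stacking angle between the transition-dipole direction and the line
joining the molecular centers is below the magic angle, 54.7 degrees —
the zero of P2(cos theta) — and an H-aggregate (blue-shifted, card-pack
stacking) for angles between 54.7 and 90 degrees. The long geometric axis
serves as the transition-dipole proxy, and the stacking angle is built
from the bisector of the two (sign-aligned) molecular axes, a convention
that is robust for the near-parallel pairs the exciton model assumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .clusters import ClusterAssignment
from .geometry import (
    Box,
    Configuration,
    MoleculeRecord,
    center_of_mass,
    longest_principal_axis,
    Trajectory,
    minimum_image_vector,
    pair_angle,
)

__all__ = ["PairGeometry", "ClusterClass", "JH_BOUNDARY_DEG",
           "pair_geometry", "classify_pair", "classify_clusters",
           "jh_boundary_angle"]

#: magic-angle J/H boundary in degrees; the zero of P2(cos theta)
JH_BOUNDARY_DEG = 54.7

#: inter-axis angle above which the near-parallel dipole assumption of the
#: exciton convention is questionable
_COPLANARITY_WARN_DEG = 30.0


@dataclass(frozen=True)
class PairGeometry:
    """Stacking geometry of one molecule pair.

    ``inter_axis_angle``: angle between the long axes (degrees; [0, 180]
    when oriented, else [0, 90]). ``stacking_angle``: angle between the
    mean molecular axis (bisector of the sign-aligned axes) and the
    inter-COM direction, folded to [0, 90] degrees. ``separation``:
    minimum-image COM distance in Angstrom.
    """

    inter_axis_angle: float
    stacking_angle: float
    separation: float


@dataclass(frozen=True)
class ClusterClass:
    """Per-cluster aggregate classification summary."""

    cluster_label: int
    size: int
    n_linked_pairs: int
    j_pair_fraction: float
    label: str  # "J", "H" or "mixed"


def pair_geometry(mol_i: MoleculeRecord, mol_j: MoleculeRecord,
                  box: Box) -> PairGeometry:
    """Stacking geometry of a molecule pair under periodic boundaries.

    The second axis is sign-aligned with the first before taking the
    bisector, so the stacking angle does not depend on head/tail
    conventions. Warns when the pair is far from parallel, where the J/H
    dichotomy loses its exciton-model meaning.
    """
    axis_i, ori_i = longest_principal_axis(mol_i)
    axis_j, ori_j = longest_principal_axis(mol_j)
    inter_axis = pair_angle(axis_i, axis_j, oriented=ori_i and ori_j)
    if axis_i @ axis_j < 0:
        axis_j = -axis_j
    bisector = axis_i + axis_j
    norm = np.linalg.norm(bisector)
    if norm < 1e-12:
        raise ValueError("axes are exactly perpendicular-degenerate: "
                         "bisector undefined")
    bisector /= norm
    rij = minimum_image_vector(center_of_mass(mol_i), center_of_mass(mol_j), box)
    sep = float(np.linalg.norm(rij))
    if sep <= 0:
        raise ValueError("coincident centers of mass: separation must be > 0")
    r_hat = rij / sep
    cos_stack = abs(float(np.clip(bisector @ r_hat, -1.0, 1.0)))
    stacking = float(np.degrees(np.arccos(cos_stack)))
    folded_inter = min(inter_axis, 180.0 - inter_axis)
    if folded_inter > _COPLANARITY_WARN_DEG:
        warnings.warn(
            f"inter-axis angle {folded_inter:.1f} degrees exceeds "
            f"{_COPLANARITY_WARN_DEG} degrees: the J/H dichotomy assumes "
            "near-parallel transition dipoles",
            stacklevel=2,
        )
    return PairGeometry(inter_axis_angle=inter_axis, stacking_angle=stacking,
                        separation=sep)


def classify_pair(geom: PairGeometry) -> str:
    """"J" if the stacking angle is strictly below 54.7 degrees, else "H".

    The boundary itself is assigned to H (strict inequality for J).
    """
    if not 0.0 <= geom.stacking_angle <= 90.0:
        raise ValueError(
            f"stacking angle must be in [0, 90] degrees, got {geom.stacking_angle}"
        )
    return "J" if geom.stacking_angle < JH_BOUNDARY_DEG else "H"


def classify_clusters(config: Configuration,
                      assignment: ClusterAssignment) -> list[ClusterClass]:
    """Classify each detected cluster as J, H or mixed.

    For every cluster, all linked pairs (members within the clustering
    cutoff) are classified; the cluster is J if every linked pair is J,
    H if every linked pair is H, otherwise mixed.
    """
    if assignment.n_molecules != config.n_molecules:
        raise ValueError(
            "assignment does not match configuration: "
            f"{assignment.n_molecules} labels vs {config.n_molecules} molecules"
        )
    config_ids = np.array([m.molecule_id for m in config.molecules])
    if not np.array_equal(config_ids, assignment.molecule_ids):
        raise ValueError("assignment molecule_ids do not match configuration")
    cutoff = assignment.params.cutoff
    out: list[ClusterClass] = []
    for label in range(assignment.n_clusters):
        members = np.flatnonzero(assignment.labels == label)
        n_j = 0
        n_linked = 0
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                mi = config.molecules[members[a]]
                mj = config.molecules[members[b]]
                geom = pair_geometry(mi, mj, config.box)
                if geom.separation <= cutoff:
                    n_linked += 1
                    if classify_pair(geom) == "J":
                        n_j += 1
        frac = n_j / n_linked if n_linked else float("nan")
        if n_linked == 0:
            verdict = "mixed"
        elif n_j == n_linked:
            verdict = "J"
        elif n_j == 0:
            verdict = "H"
        else:
            verdict = "mixed"
        out.append(ClusterClass(cluster_label=label, size=len(members),
                                n_linked_pairs=n_linked, j_pair_fraction=frac,
                                label=verdict))
    return out


def jh_boundary_angle(xtol: float = 1e-6) -> float:
    """Zero crossing of the pairwise order parameter on [0, 90] degrees.

    Evaluates P2(cos theta) for two-rod fixtures as a function of the
    inter-axis angle and bisects for the sign change. The result,
    arccos(1/sqrt(3)) ~ 54.7 degrees, ties the J/H classification
    boundary to the order-parameter formalism.
    """
    from .order import order_profile
    from .synthetic import generate_pair

    box = Box(100.0, 100.0, 100.0)

    def pair_order(theta: float) -> float:
        config = generate_pair(theta=theta, r=5.0, box=box)
        profile = order_profile(Trajectory([config]), bin_width=0.5, r_max=10.0)
        populated = np.flatnonzero(profile.pair_counts > 0)
        return float(profile.o_values[populated[0]])

    return float(brentq(pair_order, 1.0, 89.0, xtol=xtol))
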