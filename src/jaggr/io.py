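"""Readers and writers: tabular configurations, structure/trajectory files.

Two input routes are supported. The self-describing tabular format is a
CSV of atoms (frame, molecule_id, atom_index, x, y, z, mass, in Angstrom
and amu) plus a JSON sidecar holding the box, seed and generator
parameters; it round-trips the synthetic generator exactly. Standard
structure/trajectory files (PDB or GRO, optionally with DCD or XTC) are
read through MDAnalysis, which reports coordinates in Angstrom regardless
of the on-disk unit (GRO files store nm).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import Box, Configuration, MoleculeRecord, Trajectory

__all__ = ["write_configuration_csv", "read_configuration_csv",
           "read_trajectory", "write_pdb"]


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".meta.json")


def write_configuration_csv(traj: Trajectory, csv_path: str | Path,
                            meta: Optional[dict] = None) -> None:
    """Write a trajectory to the tabular format plus its JSON sidecar.

    ``meta`` (seed, generator parameters, ground truth ...) is stored in
    the sidecar verbatim under "meta".
    """
    csv_path = Path(csv_path)
    rows = []
    head_tail = {}
    for frame in traj:
        for mol in frame.molecules:
            head_tail[str(mol.molecule_id)] = [mol.head_atom, mol.tail_atom]
            for a in range(mol.n_atoms):
                rows.append((frame.frame_index, mol.molecule_id, a,
                             mol.positions[a, 0], mol.positions[a, 1],
                             mol.positions[a, 2], mol.masses[a]))
    df = pd.DataFrame(rows, columns=["frame", "molecule_id", "atom_index",
                                     "x", "y", "z", "mass"])
    df.to_csv(csv_path, index=False, float_format="%.10g")
    box = traj[0].box
    sidecar = {
        "box": [box.lx, box.ly, box.lz],
        "n_frames": traj.n_frames,
        "head_tail": head_tail,
        "meta": meta or {},
    }
    with open(_sidecar_path(csv_path), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)


def read_configuration_csv(csv_path: str | Path) -> Trajectory:
    """Read a trajectory written by :func:`write_configuration_csv`."""
    csv_path = Path(csv_path)
    sidecar_file = _sidecar_path(csv_path)
    if not sidecar_file.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar_file}: the tabular format needs its "
            "JSON metadata (box, head/tail atoms)"
        )
    with open(sidecar_file) as fh:
        sidecar = json.load(fh)
    box = Box(*sidecar["box"])
    head_tail = sidecar.get("head_tail", {})
    df = pd.read_csv(csv_path)
    frames = []
    for frame_index, fdf in df.groupby("frame", sort=True):
        mols = []
        for mol_id, mdf in fdf.groupby("molecule_id", sort=True):
            mdf = mdf.sort_values("atom_index")
            ht = head_tail.get(str(mol_id), [None, None])
            mols.append(MoleculeRecord(
                molecule_id=int(mol_id),
                positions=mdf[["x", "y", "z"]].to_numpy(float),
                masses=mdf["mass"].to_numpy(float),
                head_atom=None if ht[0] is None else int(ht[0]),
                tail_atom=None if ht[1] is None else int(ht[1]),
            ))
        frames.append(Configuration(molecules=mols, box=box,
                                    frame_index=int(frame_index)))
    if not frames:
        raise ValueError(f"{csv_path}: no frames found")
    return Trajectory(frames)


def _box_from_dimensions(dimensions, source: str) -> Box:
    if dimensions is None or not np.any(dimensions[:3] > 0):
        raise ValueError(
            f"{source}: no periodic cell found (missing or zero box record); "
            "analyses need the box for minimum-image distances"
        )
    lx, ly, lz, alpha, beta, gamma = [float(v) for v in dimensions]
    if not np.allclose([alpha, beta, gamma], 90.0, atol=1e-3):
        raise ValueError(
            f"{source}: triclinic cell (angles {alpha}, {beta}, {gamma}) is "
            "unsupported; only orthorhombic boxes are handled"
        )
    return Box(lx, ly, lz)


def read_trajectory(structure_path: str | Path,
                    trajectory_path: Optional[str | Path] = None,
                    selection: str = "all",
                    head_atom_name: Optional[str] = None,
                    tail_atom_name: Optional[str] = None,
                    expected_count: Optional[int] = None) -> Trajectory:
    """Read dye molecules from structure (and optional trajectory) files.

    ``selection`` is an MDAnalysis selection string (e.g. ``"resname ICG"``);
    each selected residue becomes one molecule. ``head_atom_name`` /
    ``tail_atom_name`` pick the atoms that orient the long axis.
    ``expected_count`` asserts the number of selected molecules per frame,
    catching topology/selection mistakes early.
    """
    import MDAnalysis as mda

    structure_path = Path(structure_path)
    if trajectory_path is not None:
        universe = mda.Universe(str(structure_path), str(trajectory_path))
    else:
        universe = mda.Universe(str(structure_path))
    group = universe.select_atoms(selection)
    if len(group) == 0:
        raise ValueError(
            f"selection {selection!r} matches no atoms in {structure_path}"
        )
    residues = group.residues
    if expected_count is not None and len(residues) != expected_count:
        raise ValueError(
            f"selection {selection!r} matched {len(residues)} molecules, "
            f"expected {expected_count}"
        )
    frames = []
    for fi, _ in enumerate(universe.trajectory):
        box = _box_from_dimensions(universe.dimensions, str(structure_path))
        mols = []
        for mol_id, res in enumerate(residues):
            atoms = res.atoms.intersection(group)
            masses = atoms.masses.astype(float)
            if not np.all(masses > 0):
                if fi == 0 and mol_id == 0:
                    warnings.warn(
                        f"{structure_path}: masses missing from the topology "
                        "and not guessable; using equal masses (centers of "
                        "mass become centroids)",
                        stacklevel=2,
                    )
                masses = np.ones_like(masses)
            names = list(atoms.names)
            head = names.index(head_atom_name) if head_atom_name in names else None
            tail = names.index(tail_atom_name) if tail_atom_name in names else None
            if (head_atom_name or tail_atom_name) and (head is None or tail is None):
                raise ValueError(
                    f"residue {res.resid}: head/tail atoms "
                    f"({head_atom_name!r}, {tail_atom_name!r}) not both present"
                )
            mols.append(MoleculeRecord(
                molecule_id=mol_id,
                positions=atoms.positions.astype(float),
                masses=masses,
                head_atom=head,
                tail_atom=tail,
            ))
        frames.append(Configuration(molecules=mols, box=box, frame_index=fi))
    return Trajectory(frames)


def write_pdb(config: Configuration, path: str | Path) -> None:
    """Write one configuration to PDB with a CRYST1 box record.

    Every molecule becomes one residue (resname MOL); masses are not
    representable in PDB and live only in the tabular format.
    """
    import MDAnalysis as mda

    n_atoms = sum(m.n_atoms for m in config.molecules)
    n_res = len(config.molecules)
    universe = mda.Universe.empty(
        n_atoms, n_residues=n_res,
        atom_resindex=np.repeat(np.arange(n_res),
                                [m.n_atoms for m in config.molecules]),
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    universe.add_TopologyAttr("resname", ["MOL"] * n_res)
    universe.add_TopologyAttr("name", ["C"] * n_atoms)
    universe.add_TopologyAttr("elements", ["C"] * n_atoms)
    universe.add_TopologyAttr(
        "resid", [m.molecule_id + 1 for m in config.molecules])
    universe.atoms.positions = np.vstack(
        [m.positions for m in config.molecules])
    universe.dimensions = [config.box.lx, config.box.ly, config.box.lz,
                           90.0, 90.0, 90.0]
    universe.atoms.write(str(path))
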