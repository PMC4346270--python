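"""Reading and writing system descriptions and trajectories.

Structures are accepted in GRO or PDB dialects (parsed with MDAnalysis) and
annotated from a CSV table mapping (residue_name, bead_name) to species, roles
and van der Waals radius.  Trajectories are accepted in XTC/TRR/DCD (again via
MDAnalysis) and in a plain-text fallback format::

    NBEADS <n>
    FRAME <t_ns> <Lx> <Ly> <Lz>
    <bead_id> <x> <y> <z>        (n lines, nm)
    FRAME ...

The text format is the lingua franca of the synthetic generator and of the
test suite; coordinates are written with 6 decimals so a write/read round
trip preserves them to the written precision.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .system import (Frame, MembraneSystem, SystemError_, Trajectory,
                     LIPID_SPECIES, ROLES, SPECIES)

ANNOTATION_COLUMNS = ("residue_name", "bead_name", "species", "roles",
                      "vdw_radius_A")

_TRAJ_SUFFIXES_MDA = {".xtc", ".trr", ".dcd"}
_STRUCT_SUFFIXES = {".gro", ".pdb"}


class FormatError(ValueError):
    """Malformed structure/annotation/trajectory file."""


class AnnotationError(KeyError):
    """A residue/bead present in the structure has no annotation."""


# ---------------------------------------------------------------------------
# annotation table
# ---------------------------------------------------------------------------

def read_annotation(path) -> pd.DataFrame:
    """Read the (residue_name, bead_name) -> species/roles/radius table.

    ``bead_name`` may be ``*`` to match every bead of the residue; the roles
    column is semicolon-joined.
    """
    table = pd.read_csv(path, dtype=str, comment="#", skipinitialspace=True)
    missing = set(ANNOTATION_COLUMNS) - set(table.columns)
    if missing:
        raise FormatError(f"annotation table {path} lacks columns {sorted(missing)}")
    for _, row in table.iterrows():
        if row["species"] not in SPECIES:
            raise FormatError(f"annotation table: unknown species {row['species']!r}")
        for role in _parse_roles(row["roles"]):
            if role not in ROLES:
                raise FormatError(f"annotation table: unknown role {role!r}")
    return table


def write_annotation(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, columns=list(ANNOTATION_COLUMNS))


def _parse_roles(cell) -> frozenset:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return frozenset()
    return frozenset(p.strip() for p in str(cell).split(";") if p.strip())


def _annotation_lookup(table: pd.DataFrame):
    exact, wild = {}, {}
    for _, row in table.iterrows():
        rec = (row["species"], _parse_roles(row["roles"]),
               float(row["vdw_radius_A"]))
        if row["bead_name"] == "*":
            wild[row["residue_name"]] = rec
        else:
            exact[(row["residue_name"], row["bead_name"])] = rec

    def lookup(resname, beadname):
        rec = exact.get((resname, beadname))
        if rec is None:
            rec = wild.get(resname)
        return rec

    return lookup


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def load_system(structure_path, annotation_path) -> MembraneSystem:
    """Build an annotated :class:`MembraneSystem` from a structure file.

    Raises :class:`AnnotationError` naming the first residue whose beads are
    not covered by the annotation table, and :class:`FormatError` for files
    the structure parser rejects.
    """
    names, resids, resnames, _, box = _read_structure(structure_path)
    lookup = _annotation_lookup(read_annotation(annotation_path))

    n = len(names)
    species = np.empty(n, dtype=object)
    roles = [frozenset()] * n
    radii = np.empty(n, dtype=float)
    for i in range(n):
        rec = lookup(resnames[i], names[i])
        if rec is None:
            raise AnnotationError(
                f"no annotation for residue {resnames[i]!r} (bead {names[i]!r}, "
                f"residue id {resids[i]})")
        species[i], roles[i], radii[i] = rec

    molecule_id = _assign_molecules(species, resids)
    system = MembraneSystem(
        bead_id=np.arange(1, n + 1),
        name=names, residue_id=resids, residue_name=resnames,
        molecule_id=molecule_id, species=species, roles=roles,
        vdw_radius=radii, box=box)
    system.validate()
    return system


def _read_structure(path):
    """Parse a GRO/PDB file -> (names, resids, resnames, positions_nm, box_nm)."""
    import MDAnalysis as mda

    path = Path(path)
    if path.suffix.lower() not in _STRUCT_SUFFIXES:
        raise FormatError(f"unsupported structure format {path.suffix!r} "
                          "(expected .gro or .pdb)")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:  # noqa: BLE001 - surface parser diagnostics
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if u.dimensions is None or not np.all(u.dimensions[:3] > 0):
        raise FormatError(f"{path}: no periodic box in structure file")
    names = np.array([a.name for a in u.atoms], dtype=object)
    resids = np.array([a.resid for a in u.atoms], dtype=int)
    resnames = np.array([a.resname for a in u.atoms], dtype=object)
    pos = u.atoms.positions.astype(float) / 10.0  # Angstrom -> nm
    box = tuple(float(x) / 10.0 for x in u.dimensions[:3])
    return names, resids, resnames, pos, box


def load_frame(structure_path) -> Frame:
    """Coordinates of a structure file as a single Frame (time 0)."""
    *_, pos, box = _read_structure(structure_path)
    return Frame(0.0, pos, box)


def _assign_molecules(species, resids) -> np.ndarray:
    """All PROTEIN beads form molecule 0; every other residue is a molecule."""
    n = len(species)
    molecule_id = np.empty(n, dtype=int)
    next_id = 1 if np.any(species == "PROTEIN") else 0
    current_key, current_id = None, None
    for i in range(n):
        if species[i] == "PROTEIN":
            molecule_id[i] = 0
            continue
        key = (species[i], resids[i])
        if key != current_key:
            current_key, current_id = key, next_id
            next_id += 1
        molecule_id[i] = current_id
    return molecule_id


def write_gro(system: MembraneSystem, frame: Frame, path, title="memlip system") -> None:
    """Write a GRO-dialect structure file (nm, fixed columns)."""
    with open(path, "w") as fh:
        fh.write(f"{title}\n{system.n_beads:5d}\n")
        for i in range(system.n_beads):
            x, y, z = frame.positions[i]
            fh.write("%5d%-5s%5s%5d%8.3f%8.3f%8.3f\n" % (
                system.residue_id[i] % 100000, system.residue_name[i][:5],
                system.name[i][:5], system.bead_id[i] % 100000, x, y, z))
        fh.write("%10.5f%10.5f%10.5f\n" % frame.box)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def load_trajectory(path, system: MembraneSystem) -> Trajectory:
    """Load a trajectory and check it against the system's bead roster.

    Dispatches on file suffix: XTC/TRR/DCD via MDAnalysis, GRO/PDB as
    (possibly single-frame) coordinate files, anything else as the text
    fallback format.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in _TRAJ_SUFFIXES_MDA:
        traj = _load_mda_trajectory(path, system.n_beads)
    elif suffix in _STRUCT_SUFFIXES:
        frame = load_frame(path)
        traj = Trajectory([frame.time], frame.positions[None], [frame.box])
    else:
        traj = read_text_trajectory(path)
    if traj.n_beads != system.n_beads:
        raise FormatError(
            f"trajectory has {traj.n_beads} beads but system has "
            f"{system.n_beads}")
    if traj.sampling_interval is None:
        warnings.warn("single-frame trajectory: sampling interval undefined",
                      stacklevel=2)
    return traj


def _load_mda_trajectory(path, n_beads) -> Trajectory:
    import MDAnalysis as mda

    u = mda.Universe.empty(n_beads, trajectory=True)
    try:
        u.load_new(str(path))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read trajectory {path}: {exc}") from exc
    times, positions, boxes = [], [], []
    for ts in u.trajectory:
        times.append(float(ts.time) / 1000.0)      # ps -> ns
        positions.append(ts.positions.astype(float) / 10.0)  # A -> nm
        if ts.dimensions is None:
            raise FormatError(f"{path}: frame without box dimensions")
        boxes.append(tuple(float(x) / 10.0 for x in ts.dimensions[:3]))
    return Trajectory(np.array(times), np.array(positions), np.array(boxes))


def read_text_trajectory(path) -> Trajectory:
    """Parse the documented plain-text trajectory fallback format."""
    times, positions, boxes = [], [], []
    with open(path) as fh:
        header = fh.readline()
        parts = header.split()
        if len(parts) != 2 or parts[0] != "NBEADS":
            raise FormatError(f"{path}:1: expected 'NBEADS <n>', got {header!r}")
        try:
            n = int(parts[1])
        except ValueError as exc:
            raise FormatError(f"{path}:1: bad bead count {parts[1]!r}") from exc
        lineno = 1
        while True:
            line = fh.readline()
            if not line:
                break
            lineno += 1
            if not line.strip():
                continue
            parts = line.split()
            if parts[0] != "FRAME" or len(parts) != 5:
                raise FormatError(
                    f"{path}:{lineno}: expected 'FRAME t Lx Ly Lz', got {line!r}")
            t = float(parts[1])
            box = tuple(float(x) for x in parts[2:5])
            pos = np.empty((n, 3))
            for k in range(n):
                row = fh.readline()
                lineno += 1
                if not row:
                    raise FormatError(f"{path}:{lineno}: truncated frame")
                cells = row.split()
                if len(cells) != 4:
                    raise FormatError(
                        f"{path}:{lineno}: expected 'bead_id x y z', got {row!r}")
                pos[k] = [float(c) for c in cells[1:4]]
            times.append(t)
            positions.append(pos)
            boxes.append(box)
    if not times:
        raise FormatError(f"{path}: no frames")
    try:
        return Trajectory(np.array(times), np.array(positions), np.array(boxes))
    except SystemError_ as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_text_trajectory(traj: Trajectory, path, system: MembraneSystem | None = None) -> None:
    bead_ids = (system.bead_id if system is not None
                else np.arange(1, traj.n_beads + 1))
    with open(path, "w") as fh:
        fh.write(f"NBEADS {traj.n_beads}\n")
        for f in traj:
            fh.write("FRAME %.6f %.6f %.6f %.6f\n" % (f.time, *f.box))
            for bid, (x, y, z) in zip(bead_ids, f.positions):
                fh.write("%d %.6f %.6f %.6f\n" % (bid, x, y, z))
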