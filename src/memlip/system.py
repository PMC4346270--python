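"""Core data model: annotated bead systems, frames, trajectories and leaflets.

Internal units are nm for lengths and ns for times everywhere; van der Waals
radii (and pore radii) are carried in Angstrom because they are only consumed
and reported at the Angstrom scale.

A *bead* is either a coarse-grained particle or an atom; a *molecule* is a
lipid, ion, solvent residue or the whole protein.  Species labels follow the
bacterial inner-membrane composition the package targets: a zwitterionic
majority lipid (POPE), an anionic lipid (POPG), the doubly-charged
four-tailed cardiolipin (CL), plus POPC, the protein, ions and solvent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

SPECIES = ("PROTEIN", "POPE", "POPG", "CL", "POPC", "ION", "SOLVENT")
LIPID_SPECIES = ("POPE", "POPG", "CL", "POPC")
ROLES = ("HEADGROUP", "BACKBONE_CA", "TAIL")

INNER = "INNER"
OUTER = "OUTER"


def wrap(x: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into the primary periodic cell [0, box)."""
    return np.mod(x, box)


def min_image(d: np.ndarray, box) -> np.ndarray:
    """Minimum-image convention applied to displacement vectors.

    Works on the trailing axis; ``box`` may have fewer components than the
    displacement (e.g. a 2-vector box against xy displacements).
    """
    box = np.asarray(box, dtype=float)
    return d - box * np.round(d / box)


def pairwise_distances(a: np.ndarray, b: np.ndarray, box) -> np.ndarray:
    """All-pairs minimum-image Euclidean distances, shape (len(a), len(b))."""
    d = a[:, None, :] - b[None, :, :]
    d = min_image(d, box)
    return np.sqrt((d * d).sum(axis=-1))


class SystemError_(ValueError):
    """Raised when a system description violates its invariants."""


@dataclass
class MembraneSystem:
    """Annotated bead roster of a protein/membrane system.

    Parameters
    ----------
    bead_id : int array
        Unique bead identifiers (file order).
    name, residue_name : str arrays
        Bead and residue names as read from the structure file.
    residue_id : int array
        1-based residue numbers taken verbatim from the input structure, so
        crystal-structure residue labels (e.g. R4, R299, K321) map directly.
    molecule_id : int array
        Molecule index; all PROTEIN beads share one molecule, every other
        residue is its own molecule.
    species : str array
        One of :data:`SPECIES` per bead.
    roles : list of frozenset
        Subset of :data:`ROLES` per bead.
    vdw_radius : float array
        Van der Waals radius in Angstrom (used by the pore profiler).
    box : (Lx, Ly, Lz) in nm.
    """

    bead_id: np.ndarray
    name: np.ndarray
    residue_id: np.ndarray
    residue_name: np.ndarray
    molecule_id: np.ndarray
    species: np.ndarray
    roles: list
    vdw_radius: np.ndarray
    box: tuple

    def __post_init__(self):
        self.bead_id = np.asarray(self.bead_id, dtype=int)
        self.residue_id = np.asarray(self.residue_id, dtype=int)
        self.molecule_id = np.asarray(self.molecule_id, dtype=int)
        self.name = np.asarray(self.name, dtype=object)
        self.residue_name = np.asarray(self.residue_name, dtype=object)
        self.species = np.asarray(self.species, dtype=object)
        self.vdw_radius = np.asarray(self.vdw_radius, dtype=float)
        self.box = tuple(float(x) for x in self.box)

    # -- basic queries -----------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.bead_id)

    def role_mask(self, role: str) -> np.ndarray:
        return np.fromiter((role in r for r in self.roles), bool, self.n_beads)

    @property
    def headgroup_mask(self) -> np.ndarray:
        return self.role_mask("HEADGROUP")

    @property
    def ca_mask(self) -> np.ndarray:
        return self.role_mask("BACKBONE_CA")

    def species_mask(self, species: str) -> np.ndarray:
        if species not in SPECIES:
            raise SystemError_(f"unknown species {species!r}")
        return self.species == species

    def headgroup_indices(self, species: str) -> np.ndarray:
        """Bead indices of the HEADGROUP beads of one lipid species."""
        m = self.species_mask(species) & self.headgroup_mask
        return np.nonzero(m)[0]

    def molecules_of(self, species: str) -> np.ndarray:
        return np.unique(self.molecule_id[self.species_mask(species)])

    @property
    def protein_mask(self) -> np.ndarray:
        return self.species_mask("PROTEIN")

    def protein_residues(self) -> np.ndarray:
        return np.unique(self.residue_id[self.protein_mask])

    def residue_beads(self, residue_id: int) -> np.ndarray:
        """Bead indices of one PROTEIN residue."""
        m = self.protein_mask & (self.residue_id == residue_id)
        return np.nonzero(m)[0]

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        if len(np.unique(self.bead_id)) != self.n_beads:
            raise SystemError_("bead ids are not unique")
        if any(l <= 0 for l in self.box):
            raise SystemError_(f"box lengths must be positive, got {self.box}")
        n = self.n_beads
        for arr in (self.name, self.residue_id, self.residue_name,
                    self.molecule_id, self.species, self.vdw_radius):
            if len(arr) != n:
                raise SystemError_("field length mismatch")
        if len(self.roles) != n:
            raise SystemError_("roles length mismatch")
        hg = self.headgroup_mask
        for sp in LIPID_SPECIES:
            sp_mask = self.species_mask(sp)
            for mol in np.unique(self.molecule_id[sp_mask]):
                if not np.any(hg & (self.molecule_id == mol)):
                    raise SystemError_(
                        f"lipid molecule {mol} ({sp}) has no HEADGROUP bead")
        ca = self.ca_mask
        for res in self.protein_residues():
            n_ca = int(np.sum(ca & self.protein_mask & (self.residue_id == res)))
            if n_ca != 1:
                raise SystemError_(
                    f"protein residue {res} has {n_ca} BACKBONE_CA beads "
                    "(expected exactly 1)")


@dataclass
class Frame:
    """A single snapshot: time (ns), per-bead positions (nm), box (nm)."""

    time: float
    positions: np.ndarray
    box: tuple

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = tuple(float(x) for x in self.box)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise SystemError_("positions must have shape (n_beads, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise SystemError_("non-finite coordinates in frame")


class Trajectory:
    """Time-ordered frames over a fixed bead roster.

    Positions are stored wrapped into the periodic cell; analyses apply
    minimum-image distances and, where needed (MSD), unwrap displacements.
    """

    def __init__(self, times, positions, boxes):
        self.times = np.asarray(times, dtype=float)
        self.positions = np.asarray(positions)
        self.boxes = np.asarray(boxes, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise SystemError_("positions must have shape (n_frames, n_beads, 3)")
        if len(self.times) != len(self.positions) or len(self.boxes) != len(self.times):
            raise SystemError_("times/positions/boxes length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise SystemError_("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[1]

    @property
    def sampling_interval(self):
        """Nominal sampling interval in ns (median dt); None for <2 frames."""
        if self.n_frames < 2:
            return None
        return float(np.median(np.diff(self.times)))

    def frame(self, i: int) -> Frame:
        return Frame(float(self.times[i]), np.asarray(self.positions[i], dtype=float),
                     tuple(self.boxes[i]))

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)


@dataclass
class LeafletAssignment:
    """Mapping lipid molecule_id -> leaflet; OUTER is the greater-z side."""

    leaflet_of: dict
    midplane_z: float

    def molecules(self, leaflet: str) -> np.ndarray:
        return np.array(sorted(m for m, l in self.leaflet_of.items() if l == leaflet),
                        dtype=int)


def assign_leaflets(frame: Frame, system: MembraneSystem) -> LeafletAssignment:
    """Assign every lipid molecule to the INNER or OUTER leaflet.

    The bilayer midplane is the mean z of all lipid HEADGROUP beads; a lipid
    goes to OUTER when its headgroup mean z exceeds the midplane.  A headgroup
    exactly on the midplane falls back to the molecule-mean z of all its
    beads; a persisting tie goes to INNER (documented convention).
    """
    hg = system.headgroup_mask
    lipid = np.isin(system.species, LIPID_SPECIES)
    hg_lipid = hg & lipid
    if not np.any(hg_lipid):
        raise SystemError_("no lipid headgroup beads present")
    z = frame.positions[:, 2]
    midplane = float(np.mean(z[hg_lipid]))
    out = {}
    for mol in np.unique(system.molecule_id[lipid]):
        mol_mask = system.molecule_id == mol
        zm = float(np.mean(z[mol_mask & hg_lipid]))
        if zm == midplane:
            zm = float(np.mean(z[mol_mask]))
        out[int(mol)] = OUTER if zm > midplane else INNER
    return LeafletAssignment(out, midplane)
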