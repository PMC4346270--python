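"""Per-leaflet lateral density maps and the annular enrichment ratio S.

S divides the mean lipid number density in the annulus adjacent to the
protein (0-3 nm from the protein centre of mass) by the mean density in a
bulk annulus (3.5-6 nm); S > 1 means enrichment.  A site-local variant
replaces the numerator with the density inside the binding-site discs only.

Protein-footprint masking is ON by default: positions (and area) inside the
protein's lateral footprint are excluded from both annuli, so S compares
densities over lipid-accessible area only.  With masking off the footprint
dilutes the near annulus and uniform lipids give S < 1; both behaviours are
intentional and tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, cKDTree

from .system import (INNER, LIPID_SPECIES, MembraneSystem, SystemError_,
                     Trajectory, assign_leaflets, min_image)
from .motion import superpose

DEFAULT_ANNULI = ((0.0, 3.0), (3.5, 6.0))


@dataclass
class DensityMap:
    """2D lateral number-density grid (nm^-2) for one species and leaflet."""

    leaflet: str
    species: str
    density: np.ndarray          # (ny, nx)
    x_edges: np.ndarray
    y_edges: np.ndarray
    cell_size: float
    accessible: np.ndarray       # (ny, nx) bool; False inside protein footprint
    n_frames: int
    center: np.ndarray           # protein COM (x, y) in the reference frame

    @property
    def cell_centers(self):
        cx = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        cy = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        return np.meshgrid(cx, cy)


@dataclass
class EnrichmentResult:
    species: str
    leaflet: str
    S: float
    annulus_near: tuple
    annulus_bulk: tuple
    variant: str                 # "annulus" or "site_local"
    masked: bool
    se: float | None = None
    n_frames: int = 0


class _Footprint:
    """Lateral protein footprint: convex hull of protein beads, dilated by a
    pad (default: the largest protein bead radius)."""

    def __init__(self, protein_xy: np.ndarray, pad: float):
        self.pad = float(pad)
        self.tree = cKDTree(protein_xy)
        self.hull = None
        if len(protein_xy) >= 3:
            try:
                self.hull = Delaunay(protein_xy)
            except Exception:  # collinear beads: distance test only
                self.hull = None

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        inside = np.zeros(len(pts), dtype=bool)
        if self.hull is not None:
            inside |= self.hull.find_simplex(pts) >= 0
        if self.pad > 0:
            inside |= self.tree.query(pts)[0] <= self.pad
        return inside


def _protein_footprint(system: MembraneSystem, positions: np.ndarray,
                       pad: float | None = None) -> _Footprint:
    prot = np.nonzero(system.protein_mask)[0]
    if prot.size == 0:
        raise SystemError_("no protein beads in system")
    if pad is None:
        pad = float(system.vdw_radius[prot].max()) / 10.0  # Angstrom -> nm
    return _Footprint(positions[prot, :2].astype(float), pad)


def _protein_com(system: MembraneSystem, positions: np.ndarray) -> np.ndarray:
    """Protein centre of mass from backbone-CA beads (global, both leaflets)."""
    ca = np.nonzero(system.ca_mask & system.protein_mask)[0]
    if ca.size == 0:
        raise SystemError_("no BACKBONE_CA beads to define the protein COM")
    return positions[ca, :2].astype(float).mean(axis=0)


def _leaflet_headgroups(system: MembraneSystem, frame, species: str,
                        leaflet: str) -> np.ndarray:
    hg_idx = system.headgroup_indices(species)
    if hg_idx.size == 0:
        return hg_idx
    assignment = assign_leaflets(frame, system)
    keep = np.array([assignment.leaflet_of[int(m)] == leaflet
                     for m in system.molecule_id[hg_idx]])
    return hg_idx[keep]


def density_map(traj: Trajectory, system: MembraneSystem, species: str,
                leaflet: str, cell_size: float = 0.2,
                superpose_protein: bool = True,
                footprint_pad: float | None = None) -> DensityMap:
    """Time-averaged lateral headgroup density around the protein.

    Each frame's protein backbone-CA beads are rigidly superposed onto the
    first frame, the same transform is applied to the lipids, and headgroup
    positions are binned on a fixed grid; the per-cell density is
    counts / (frames x cell area).  The default 0.2 nm cells resolve the
    ~0.5 nm-spaced packing rings of annular lipids.
    """
    if species not in LIPID_SPECIES:
        raise SystemError_(f"not a lipid species: {species!r}")
    Lx, Ly = traj.boxes[0][0], traj.boxes[0][1]
    x_edges = np.arange(0.0, Lx + cell_size / 2, cell_size)
    y_edges = np.arange(0.0, Ly + cell_size / 2, cell_size)
    counts = np.zeros((len(y_edges) - 1, len(x_edges) - 1))

    ref_frame = traj.frame(0)
    ca = np.nonzero(system.ca_mask & system.protein_mask)[0]
    ref_ca = ref_frame.positions[ca]
    empty = True
    for i in range(traj.n_frames):
        frame = traj.frame(i)
        hg_idx = _leaflet_headgroups(system, frame, species, leaflet)
        if hg_idx.size == 0:
            continue
        empty = False
        pts = frame.positions[hg_idx]
        if superpose_protein and ca.size >= 3:
            R, t, _ = superpose(frame.positions[ca], ref_ca)
            pts = pts @ R.T + t
        h, _, _ = np.histogram2d(pts[:, 1], pts[:, 0], bins=(y_edges, x_edges))
        counts += h
    if empty:
        warnings.warn(f"no {species} lipids in leaflet {leaflet}: density map "
                      "is all zero", stacklevel=2)

    density = counts / (traj.n_frames * cell_size * cell_size)
    fp = _protein_footprint(system, ref_frame.positions, footprint_pad)
    cx, cy = np.meshgrid(0.5 * (x_edges[:-1] + x_edges[1:]),
                         0.5 * (y_edges[:-1] + y_edges[1:]))
    centers = np.column_stack([cx.ravel(), cy.ravel()])
    accessible = ~fp.contains(centers).reshape(counts.shape)
    return DensityMap(leaflet, species, density, x_edges, y_edges, cell_size,
                      accessible, traj.n_frames,
                      _protein_com(system, ref_frame.positions))


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def _accessible_area(footprint, center, r_lo, r_hi, box2, grid=0.02,
                     masked=True) -> float:
    """Numerical area of {r_lo <= |p - center| <= r_hi} minus the footprint."""
    xs = np.arange(grid / 2, box2[0], grid)
    ys = np.arange(grid / 2, box2[1], grid)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    d = min_image(pts - center, box2)
    r = np.sqrt((d * d).sum(axis=1))
    sel = (r >= r_lo) & (r <= r_hi)
    if masked:
        sel &= ~footprint.contains(pts)
    return float(sel.sum()) * grid * grid


def _enrichment_from_map(dmap: DensityMap, annuli=DEFAULT_ANNULI,
                         masked: bool = True) -> EnrichmentResult:
    cx, cy = dmap.cell_centers
    r = np.sqrt((cx - dmap.center[0]) ** 2 + (cy - dmap.center[1]) ** 2)
    (n_lo, n_hi), (b_lo, b_hi) = annuli
    acc = dmap.accessible if masked else np.ones_like(dmap.accessible)
    near = acc & (r >= n_lo) & (r <= n_hi)
    bulk = acc & (r >= b_lo) & (r <= b_hi)
    if not bulk.any():
        raise SystemError_("bulk annulus has no accessible cells")
    bulk_mean = dmap.density[bulk].mean()
    if bulk_mean == 0:
        warnings.warn("zero bulk density: S undefined", stacklevel=2)
        s = float("nan")
    else:
        s = float(dmap.density[near].mean() / bulk_mean)
    return EnrichmentResult(dmap.species, dmap.leaflet, s, tuple(annuli[0]),
                            tuple(annuli[1]), "annulus", masked,
                            n_frames=dmap.n_frames)


def _enrichment_from_traj(traj: Trajectory, system: MembraneSystem,
                          species: str, leaflet: str, annuli=DEFAULT_ANNULI,
                          masked: bool = True, n_blocks: int = 10,
                          footprint_pad: float | None = None) -> EnrichmentResult:
    """Grid-free S: per-frame radial counts over numerically integrated
    accessible areas, with a block-average standard error."""
    (n_lo, n_hi), (b_lo, b_hi) = annuli
    box2 = np.asarray(traj.boxes[0][:2])
    ref = traj.frame(0)
    fp = _protein_footprint(system, ref.positions, footprint_pad)
    center = _protein_com(system, ref.positions)
    a_near = _accessible_area(fp, center, n_lo, n_hi, box2, masked=masked)
    a_bulk = _accessible_area(fp, center, b_lo, b_hi, box2, masked=masked)
    if a_bulk <= 0:
        raise SystemError_("bulk annulus has no accessible area")

    near_counts = np.zeros(traj.n_frames)
    bulk_counts = np.zeros(traj.n_frames)
    hg_idx = _leaflet_headgroups(system, ref, species, leaflet)
    if hg_idx.size == 0:
        warnings.warn(f"no {species} lipids in leaflet {leaflet}", stacklevel=2)
    for i in range(traj.n_frames):
        frame_center = _protein_com(system, traj.positions[i].astype(float))
        pts = traj.positions[i][hg_idx, :2].astype(float)
        d = min_image(pts - frame_center, box2)
        r = np.sqrt((d * d).sum(axis=1))
        keep = (~fp.contains(pts)) if masked else np.ones(len(pts), dtype=bool)
        near_counts[i] = np.sum(keep & (r >= n_lo) & (r <= n_hi))
        bulk_counts[i] = np.sum(keep & (r >= b_lo) & (r <= b_hi))

    def s_of(nc, bc):
        bulk_mean = bc.mean() / a_bulk
        return np.nan if bulk_mean == 0 else (nc.mean() / a_near) / bulk_mean

    s = float(s_of(near_counts, bulk_counts))
    se = None
    if n_blocks >= 2 and traj.n_frames >= n_blocks:
        edges = np.linspace(0, traj.n_frames, n_blocks + 1, dtype=int)
        vals = np.array([s_of(near_counts[a:b], bulk_counts[a:b])
                         for a, b in zip(edges[:-1], edges[1:])])
        vals = vals[np.isfinite(vals)]
        if len(vals) >= 2:
            se = float(vals.std(ddof=1) / np.sqrt(len(vals)))
    if np.isnan(s):
        warnings.warn("zero bulk density: S undefined", stacklevel=2)
    return EnrichmentResult(species, leaflet, s, tuple(annuli[0]),
                            tuple(annuli[1]), "annulus", masked, se,
                            traj.n_frames)


def enrichment_ratio(obj, *args, **kwargs) -> EnrichmentResult:
    """Annular enrichment ratio S from a DensityMap or from a Trajectory.

    ``enrichment_ratio(dmap, annuli=..., masked=...)`` or
    ``enrichment_ratio(traj, system, species, leaflet, annuli=..., ...)``.
    """
    if isinstance(obj, DensityMap):
        return _enrichment_from_map(obj, *args, **kwargs)
    if isinstance(obj, Trajectory):
        return _enrichment_from_traj(obj, *args, **kwargs)
    raise TypeError("expected a DensityMap or Trajectory")


def site_local_enrichment(traj: Trajectory, system: MembraneSystem, sites,
                          species: str, capture_radius: float,
                          leaflet: str | None = None,
                          annulus_bulk=DEFAULT_ANNULI[1],
                          masked: bool = True, n_blocks: int = 10,
                          footprint_pad: float | None = None) -> EnrichmentResult:
    """S computed with the numerator restricted to the binding-site discs.

    The numerator is the mean density inside discs of ``capture_radius``
    around each site's anchor-residue midpoint (sites filtered to
    ``leaflet`` when given); the denominator is the usual bulk annulus.
    The footprint mask applies to the bulk annulus only: bound lipids sit
    at the protein surface, so masking the site discs themselves would
    remove exactly the density this variant measures.
    """
    ref = traj.frame(0)
    box2 = np.asarray(traj.boxes[0][:2])
    use = [s for s in sites if leaflet is None or s.leaflet == leaflet]
    if not use:
        raise SystemError_("no sites on the requested leaflet")
    centers = []
    for s in use:
        beads = np.concatenate([system.residue_beads(r) for r in s.anchor_residues])
        if beads.size == 0:
            raise SystemError_(f"site {s.site_id}: anchors not found")
        centers.append(ref.positions[beads, :2].mean(axis=0))
    centers = np.asarray(centers)

    fp = _protein_footprint(system, ref.positions, footprint_pad)
    com = _protein_com(system, ref.positions)
    b_lo, b_hi = annulus_bulk
    a_bulk = _accessible_area(fp, com, b_lo, b_hi, box2, masked=masked)

    # accessible area of the union of site discs (numerical, same grid)
    grid = 0.02
    xs = np.arange(grid / 2, box2[0], grid)
    ys = np.arange(grid / 2, box2[1], grid)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    in_disc = np.zeros(len(pts), dtype=bool)
    for cptr in centers:
        d = min_image(pts - cptr, box2)
        in_disc |= (d * d).sum(axis=1) <= capture_radius ** 2
    a_site = float(in_disc.sum()) * grid * grid
    if a_site <= 0:
        raise SystemError_("site discs have no accessible area")

    lf = leaflet if leaflet is not None else use[0].leaflet
    hg_idx = _leaflet_headgroups(system, ref, species, lf)
    site_counts = np.zeros(traj.n_frames)
    bulk_counts = np.zeros(traj.n_frames)
    for i in range(traj.n_frames):
        pts_f = traj.positions[i][hg_idx, :2].astype(float)
        keep = (~fp.contains(pts_f)) if masked else np.ones(len(pts_f), dtype=bool)
        in_site = np.zeros(len(pts_f), dtype=bool)
        for cptr in centers:
            d = min_image(pts_f - cptr, box2)
            in_site |= (d * d).sum(axis=1) <= capture_radius ** 2
        frame_center = _protein_com(system, traj.positions[i].astype(float))
        d = min_image(pts_f - frame_center, box2)
        r = np.sqrt((d * d).sum(axis=1))
        site_counts[i] = np.sum(in_site)
        bulk_counts[i] = np.sum(keep & (r >= b_lo) & (r <= b_hi))

    def s_of(sc, bc):
        bulk_mean = bc.mean() / a_bulk
        return np.nan if bulk_mean == 0 else (sc.mean() / a_site) / bulk_mean

    s = float(s_of(site_counts, bulk_counts))
    se = None
    if n_blocks >= 2 and traj.n_frames >= n_blocks:
        edges = np.linspace(0, traj.n_frames, n_blocks + 1, dtype=int)
        vals = np.array([s_of(site_counts[a:b], bulk_counts[a:b])
                         for a, b in zip(edges[:-1], edges[1:])])
        vals = vals[np.isfinite(vals)]
        if len(vals) >= 2:
            se = float(vals.std(ddof=1) / np.sqrt(len(vals)))
    return EnrichmentResult(species, lf, s, ("sites", capture_radius),
                            tuple(annulus_bulk), "site_local", masked, se,
                            traj.n_frames)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def density_map_to_dataframe(dmap: DensityMap) -> pd.DataFrame:
    cx, cy = dmap.cell_centers
    return pd.DataFrame({"x_nm": cx.ravel(), "y_nm": cy.ravel(),
                         "density_nm2": dmap.density.ravel(),
                         "accessible": dmap.accessible.ravel()})


def write_dx(dmap: DensityMap, path) -> None:
    """Write the density grid as an OpenDX scalar field (2D grid, z = 1)."""
    ny, nx = dmap.density.shape
    ox, oy = dmap.x_edges[0] + dmap.cell_size / 2, dmap.y_edges[0] + dmap.cell_size / 2
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} 1\n")
        fh.write(f"origin {ox:.6f} {oy:.6f} 0.0\n")
        fh.write(f"delta {dmap.cell_size:.6f} 0 0\n")
        fh.write(f"delta 0 {dmap.cell_size:.6f} 0\n")
        fh.write("delta 0 0 1.0\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} 1\n")
        fh.write(f"object 3 class array type double rank 0 items {nx * ny} "
                 "data follows\n")
        vals = dmap.density.T.ravel()  # x fastest-varying last per DX layout
        for i in range(0, len(vals), 3):
            fh.write(" ".join(f"{v:.6g}" for v in vals[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')
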