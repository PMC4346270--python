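"""Synthetic membrane-trajectory generator with known ground truth.

The generator emulates the statistical structure that the downstream
analyses assume, at desk scale: a static protein rendered as a disc of
radius ``protein_radius`` in the middle of a periodic bilayer patch, lipids
reduced to one headgroup bead each confined to their leaflet plane,
Brownian lateral diffusion, an optional annular potential well around the
protein (Boltzmann-exact enrichment), and discrete sticky sites on the
protein rim with exponential escape and a "rattling in a cage" bound state.

Dynamics are Metropolis-adjusted Brownian steps rather than force-based
Langevin integration: a symmetric Gaussian proposal with per-axis variance
2*D*dt, rejected when it enters the protein disc, and accepted against the
well energy u(r) (u = -eps inside the annulus, 0 outside) with probability
min(1, exp(-du)).  Detailed balance then gives a closed-form equilibrium
density proportional to exp(-u) on the accessible area, which is what makes
the enrichment ratio exactly testable; for small dt the free diffusion
constant remains D.

Binding sites hold at most one lipid.  An unbound lipid within
``capture_radius`` of a free site's anchor (same leaflet) binds with
probability ``p_on`` per step; while bound its position is resampled
uniformly in the accessible part of the capture disc each step (the cage),
and it escapes each step with probability 1 - exp(-dt/tau), i.e. residence
is exponential with mean tau per species.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .system import (Frame, INNER, OUTER, MembraneSystem, SystemError_,
                     Trajectory, min_image, wrap)

# nm^2/ns per cm^2/s
_CM2S_TO_NM2NS = 1.0e5

#: paper-scale lateral diffusion constants of a protein-free CG bilayer
DEFAULT_DIFFUSION = {"POPE": 6.2e-7, "POPG": 5.9e-7, "CL": 4.5e-7}


@dataclass(frozen=True)
class SiteParams:
    """One sticky site on the protein rim.

    tau / p_on are per-species dictionaries (ns and probability per step);
    species missing from p_on never bind.
    """

    site_id: str
    leaflet: str
    anchor_angle: float                 # radians around the protein rim
    capture_radius: float = 0.7         # nm
    tau: dict = field(default_factory=dict)
    p_on: dict = field(default_factory=dict)
    anchor_half_separation: float = 0.25  # nm along the rim, per anchor bead
    #: radial offset of the binding-pocket centre beyond the rim; lipid
    #: headgroups bind at contact distance from the anchor residues, not on
    #: top of the backbone bead.  0 keeps the pocket flush with the rim.
    anchor_radial_offset: float = 0.0


def default_sites() -> list:
    """Three sites mirroring the transporter's layout: two cytosolic (inner
    leaflet), one periplasmic (outer), cardiolipin-favouring, with residence
    ranking site 1 > site 2 > site 3."""
    mk = lambda cl, pg, pe: {"CL": cl, "POPG": pg, "POPE": pe}
    return [
        SiteParams("site1", INNER, 0.0,
                   tau=mk(30.0, 6.0, 2.0), p_on=mk(0.5, 0.3, 0.2)),
        SiteParams("site2", INNER, 2.0 * np.pi / 3.0,
                   tau=mk(20.0, 4.0, 1.5), p_on=mk(0.5, 0.3, 0.2)),
        SiteParams("site3", OUTER, 4.0 * np.pi / 3.0,
                   tau=mk(12.0, 3.0, 1.0), p_on=mk(0.5, 0.3, 0.2)),
    ]


@dataclass(frozen=True)
class SynthParams:
    """Generator settings.

    Defaults emulate the study system at its native scale: a 14 x 14 nm
    patch around a ~2 nm-radius transporter with about 400 phospholipids in
    a 75/20/5 POPE/POPG/CL mixture, sampled every 0.3 ns.
    """

    box: tuple = (14.0, 14.0)            # (Lx, Ly) nm
    leaflet_z: float = 1.9               # headgroup planes at +/- z nm
    protein_radius: float = 2.0          # nm
    lipid_counts: dict = field(default_factory=lambda: {
        "POPE": (150, 150), "POPG": (40, 40), "CL": (10, 10)})
    diffusion: dict = field(default_factory=lambda: dict(DEFAULT_DIFFUSION))
    dt: float = 0.3                      # ns per step (= sampling interval)
    n_steps: int = 2000
    sites: tuple = field(default_factory=lambda: tuple(default_sites()))
    well: tuple = (2.0, 3.0, 0.25)       # (r_inner, r_outer, depth eps in kT)
    n_ring: int = 32                     # plain rim residues per leaflet
    record_stride: int = 1
    min_spacing: float = 0.35            # nm, initial placement only
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "sites", tuple(self.sites))
        if self.protein_radius >= min(self.box) / 2.0:
            raise SystemError_("protein disc must fit inside half the box")
        if not 0 <= self.well[2] or self.well[0] > self.well[1]:
            raise SystemError_("invalid annulus well")
        for s in self.sites:
            if any(t <= 0 for t in s.tau.values()):
                raise SystemError_(f"{s.site_id}: tau must be positive")
            if any(not 0 <= p <= 1 for p in s.p_on.values()):
                raise SystemError_(f"{s.site_id}: p_on must be in [0, 1]")


@dataclass(frozen=True)
class SiteDefinition:
    """Analysis-side view of a binding site: two anchor protein residues."""

    site_id: str
    leaflet: str
    anchor_residues: tuple


@dataclass
class GroundTruth:
    """Everything an estimator is expected to recover."""

    params: SynthParams
    sites: list                      # SiteDefinition per site
    anchor_xy: dict                  # site_id -> (x, y) nm
    expected_density_ratio: float    # exp(eps): in-well vs out-of-well density
    tau: dict                        # site_id -> {species: ns}
    diffusion: dict                  # species -> cm^2/s
    leaflet_of_molecule: dict        # molecule_id -> INNER/OUTER


def knockout_sites(params: SynthParams, site_ids) -> SynthParams:
    """Return params with p_on = 0 for the named sites (in-silico mutant)."""
    known = {s.site_id for s in params.sites}
    unknown = set(site_ids) - known
    if unknown:
        raise KeyError(f"unknown site ids: {sorted(unknown)}")
    new_sites = tuple(
        dataclasses.replace(s, p_on={k: 0.0 for k in s.p_on})
        if s.site_id in site_ids else s
        for s in params.sites)
    return dataclasses.replace(params, sites=new_sites)


# ---------------------------------------------------------------------------
# system construction
# ---------------------------------------------------------------------------

def _build_system(params: SynthParams):
    """Protein rim rings + anchor residues + one headgroup bead per lipid."""
    Lx, Ly = params.box
    Lz = 2.0 * params.leaflet_z + 2.0
    cx, cy = Lx / 2.0, Ly / 2.0
    R = params.protein_radius

    names, resids, resnames, species, roles, radii, pos = [], [], [], [], [], [], []
    resid = 0

    def add_protein_bead(x, y, z, resname):
        nonlocal resid
        resid += 1
        names.append("BB")
        resids.append(resid)
        resnames.append(resname)
        species.append("PROTEIN")
        roles.append(frozenset({"BACKBONE_CA"}))
        radii.append(2.3)
        pos.append((x, y, z))
        return resid

    for leaflet, zs in ((INNER, -params.leaflet_z), (OUTER, params.leaflet_z)):
        for k in range(params.n_ring):
            th = 2.0 * np.pi * (k + 0.5) / params.n_ring
            add_protein_bead(cx + R * np.cos(th), cy + R * np.sin(th), zs, "ALA")

    site_defs, anchor_xy = [], {}
    anchor_resnames = {"site1": ("ARG", "ARG"), "site2": ("LYS", "ARG"),
                       "site3": ("LYS", "TRP")}
    for s in params.sites:
        zs = params.leaflet_z if s.leaflet == OUTER else -params.leaflet_z
        Rs = R + s.anchor_radial_offset   # pocket centre may sit off the rim
        dth = s.anchor_half_separation / Rs
        rn = anchor_resnames.get(s.site_id, ("ARG", "ARG"))
        rids = []
        for j, th in enumerate((s.anchor_angle - dth, s.anchor_angle + dth)):
            rids.append(add_protein_bead(cx + Rs * np.cos(th),
                                         cy + Rs * np.sin(th), zs, rn[j]))
        site_defs.append(SiteDefinition(s.site_id, s.leaflet, tuple(rids)))
        anchor_xy[s.site_id] = (cx + Rs * np.cos(s.anchor_angle),
                                cy + Rs * np.sin(s.anchor_angle))

    n_prot = len(names)
    lipid_species, lipid_leaflet = [], []
    for sp in sorted(params.lipid_counts):
        n_in, n_out = params.lipid_counts[sp]
        lipid_species += [sp] * (n_in + n_out)
        lipid_leaflet += [INNER] * n_in + [OUTER] * n_out
    for i, sp in enumerate(lipid_species):
        resid += 1
        names.append("PO4")
        resids.append(resid)
        resnames.append(sp)
        species.append(sp)
        roles.append(frozenset({"HEADGROUP"}))
        radii.append(2.3)
        z = params.leaflet_z if lipid_leaflet[i] == OUTER else -params.leaflet_z
        pos.append((0.0, 0.0, z))  # xy filled in after placement

    n = len(names)
    system = MembraneSystem(
        bead_id=np.arange(1, n + 1), name=np.array(names, dtype=object),
        residue_id=np.array(resids), residue_name=np.array(resnames, dtype=object),
        molecule_id=np.concatenate([np.zeros(n_prot, dtype=int),
                                    np.arange(1, n - n_prot + 1)]),
        species=np.array(species, dtype=object), roles=roles,
        vdw_radius=np.array(radii),
        box=(Lx, Ly, Lz))
    system.validate()
    base_positions = np.array(pos, dtype=float)
    # shift z into [0, Lz): bilayer midplane at Lz/2
    base_positions[:, 2] += Lz / 2.0
    return (system, base_positions, n_prot, np.array(lipid_species, dtype=object),
            np.array(lipid_leaflet, dtype=object), site_defs, anchor_xy)


def annotation_table() -> pd.DataFrame:
    """Annotation CSV matching the structures this generator writes."""
    rows = [("ALA", "BB", "PROTEIN", "BACKBONE_CA", 2.3),
            ("ARG", "BB", "PROTEIN", "BACKBONE_CA", 2.3),
            ("LYS", "BB", "PROTEIN", "BACKBONE_CA", 2.3),
            ("TRP", "BB", "PROTEIN", "BACKBONE_CA", 2.3)]
    rows += [(sp, "PO4", sp, "HEADGROUP", 2.3)
             for sp in ("POPE", "POPG", "CL", "POPC")]
    return pd.DataFrame(rows, columns=["residue_name", "bead_name", "species",
                                       "roles", "vdw_radius_A"])


# ---------------------------------------------------------------------------
# placement and dynamics
# ---------------------------------------------------------------------------

def _place_lipids(rng, params, lipid_leaflet):
    """Equilibrium initial placement: uniform x exp(-u), outside the disc,
    with a minimum spacing per leaflet (dart throwing)."""
    Lx, Ly = params.box
    c = np.array([Lx / 2.0, Ly / 2.0])
    R2 = params.protein_radius ** 2
    w1, w2, eps = params.well
    n = len(lipid_leaflet)
    out = np.empty((n, 2))
    placed = {INNER: [], OUTER: []}
    max_tries = 2000
    for i in range(n):
        leaf = lipid_leaflet[i]
        others = placed[leaf]
        for _ in range(max_tries):
            p = rng.random(2) * (Lx, Ly)
            d = p - c
            r2 = d @ d
            if r2 < R2:
                continue
            in_well = w1 * w1 <= r2 <= w2 * w2
            if eps > 0 and not in_well and rng.random() >= np.exp(-eps):
                continue  # Boltzmann thinning relative to the in-well weight
            if others:
                dd = min_image(p - np.asarray(others), np.array([Lx, Ly]))
                if np.min((dd * dd).sum(axis=1)) < params.min_spacing ** 2:
                    continue
            break
        else:
            raise SystemError_(
                f"cannot place lipid {i + 1}/{n} without overlap "
                f"(min_spacing={params.min_spacing} nm); reduce the count")
        out[i] = p
        others.append(p)
    return out


def _cage_positions(rng, anchor, r_c, count, c, R2, box2):
    """Uniform points in the capture disc, rejected out of the protein disc."""
    out = np.empty((count, 2))
    done = 0
    while done < count:
        m = (count - done) * 2 + 4
        u = rng.random((m, 2))
        rad = r_c * np.sqrt(u[:, 0])
        th = 2.0 * np.pi * u[:, 1]
        cand = anchor + np.column_stack([rad * np.cos(th), rad * np.sin(th)])
        cand = wrap(cand, box2)
        d = cand - c
        ok = (d * d).sum(axis=1) >= R2
        take = min(int(ok.sum()), count - done)
        out[done:done + take] = cand[ok][:take]
        done += take
    return out


def generate(params: SynthParams):
    """Run the generator; returns (MembraneSystem, Trajectory, GroundTruth)."""
    rng = np.random.default_rng(params.seed)
    (system, base_pos, n_prot, lipid_species, lipid_leaflet,
     site_defs, anchor_xy) = _build_system(params)

    Lx, Ly = params.box
    box2 = np.array([Lx, Ly])
    c = np.array([Lx / 2.0, Ly / 2.0])
    R2 = params.protein_radius ** 2
    w1, w2, eps = params.well
    w1_2, w2_2 = w1 * w1, w2 * w2
    n_lip = len(lipid_species)

    species_names = sorted(set(lipid_species))
    sp_index = np.array([species_names.index(s) for s in lipid_species])
    sigma_by_sp = np.array([np.sqrt(2.0 * params.diffusion[s] * _CM2S_TO_NM2NS
                                    * params.dt) for s in species_names])
    sigma = sigma_by_sp[sp_index][:, None]

    pos = _place_lipids(rng, params, lipid_leaflet)
    r2_cur = ((pos - c) ** 2).sum(axis=1)

    sites = list(params.sites)
    n_sites = len(sites)
    site_anchor = np.array([anchor_xy[s.site_id] for s in sites])
    site_rc2 = np.array([s.capture_radius ** 2 for s in sites])
    site_leaf_mask = [np.asarray(lipid_leaflet == s.leaflet) for s in sites]
    # per-site per-species capture probability and escape probability
    p_on = np.array([[s.p_on.get(sp, 0.0) for sp in species_names] for s in sites])
    q_esc = np.array([[1.0 - np.exp(-params.dt / s.tau.get(sp, np.inf))
                       for sp in species_names] for s in sites])

    bound_site = np.full(n_lip, -1, dtype=int)
    occupant = np.full(n_sites, -1, dtype=int)

    n_rec = params.n_steps // params.record_stride + 1
    rec = np.empty((n_rec, n_lip, 2), dtype=np.float32)
    rec_times = np.empty(n_rec)
    rec[0] = pos
    rec_times[0] = 0.0
    i_rec = 1

    for step in range(1, params.n_steps + 1):
        unbound = bound_site < 0
        free_at_start = occupant < 0

        # Metropolis move for unbound lipids
        prop = wrap(pos + rng.normal(0.0, 1.0, (n_lip, 2)) * sigma, box2)
        d = prop - c
        r2_new = (d * d).sum(axis=1)
        ok = unbound & (r2_new >= R2)
        if eps > 0.0:
            in_old = (r2_cur >= w1_2) & (r2_cur <= w2_2)
            in_new = (r2_new >= w1_2) & (r2_new <= w2_2)
            uphill = ok & in_old & ~in_new
            rej = uphill & (rng.random(n_lip) >= np.exp(-eps))
            ok &= ~rej
        pos[ok] = prop[ok]
        r2_cur[ok] = r2_new[ok]

        # bound lipids rattle in their cage, then may escape
        for j in range(n_sites):
            li = occupant[j]
            if li < 0:
                continue
            pos[li] = _cage_positions(rng, site_anchor[j],
                                      sites[j].capture_radius, 1, c, R2, box2)[0]
            r2_cur[li] = ((pos[li] - c) ** 2).sum()
            if rng.random() < q_esc[j, sp_index[li]]:
                occupant[j] = -1
                bound_site[li] = -1

        # capture: only sites that were free at the start of the step
        for j in range(n_sites):
            if not free_at_start[j] or occupant[j] >= 0:
                continue
            dd = min_image(pos - site_anchor[j], box2)
            near = unbound & site_leaf_mask[j] & ((dd * dd).sum(axis=1) <= site_rc2[j])
            idx = np.nonzero(near)[0]
            if idx.size == 0:
                continue
            coins = rng.random(idx.size) < p_on[j, sp_index[idx]]
            winners = idx[coins]
            if winners.size:
                li = int(winners[0]) if winners.size == 1 else int(rng.choice(winners))
                occupant[j] = li
                bound_site[li] = j

        if step % params.record_stride == 0:
            rec[i_rec] = pos
            rec_times[i_rec] = step * params.dt
            i_rec += 1

    # assemble trajectory: static protein + recorded lipid xy, fixed z
    Lz = system.box[2]
    n_beads = system.n_beads
    positions = np.empty((i_rec, n_beads, 3), dtype=np.float32)
    positions[:, :n_prot, :] = base_pos[:n_prot]
    positions[:, n_prot:, 2] = base_pos[n_prot:, 2]
    positions[:, n_prot:, :2] = rec[:i_rec]
    traj = Trajectory(rec_times[:i_rec], positions,
                      np.tile(np.array([Lx, Ly, Lz]), (i_rec, 1)))

    leaflet_of_molecule = {int(m): str(lipid_leaflet[k])
                           for k, m in enumerate(range(1, n_lip + 1))}
    truth = GroundTruth(
        params=params, sites=site_defs, anchor_xy=anchor_xy,
        expected_density_ratio=float(np.exp(eps)),
        tau={s.site_id: dict(s.tau) for s in sites},
        diffusion=dict(params.diffusion),
        leaflet_of_molecule=leaflet_of_molecule)
    return system, traj, truth
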