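"""Contact occupancy and per-residue contact profiles.

The central object is the binary occupancy indicator zeta(t) of a binding
site with respect to one lipid species: zeta = 1 whenever the minimum
distance between any bead of the site's two anchor residues and any
headgroup bead of that species is at or below the species cutoff delta.
All distances are minimum-image; the trajectory is resampled to a fixed
interval (0.3 ns by default) by nearest-frame selection and never smoothed
or interpolated.

Cutoff defaults follow the two conventions used for the transporter study
this package targets: 0.7 nm for POPE/POPG throughout; for the bulky CL
headgroup 0.8 nm at residue level and 1.1 nm at site level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .system import (LIPID_SPECIES, MembraneSystem, SystemError_, Trajectory,
                     min_image)
from .synth import SiteDefinition

__all__ = ["ContactConfig", "SiteDefinition", "OccupancySeries", "ContactProfile",
           "occupancy_series", "residue_contact_profile", "lipids_in_contact"]


@dataclass(frozen=True)
class ContactConfig:
    """Contact cutoffs (nm) and the sampling interval (ns).

    ``delta`` applies to residue-level contacts, ``site_delta`` to site-level
    occupancy.  ``delta_ref`` is the reference cutoff for the cutoff-volume
    normalization of contact profiles (the POPE/POPG value, so their divisor
    is exactly 1).  Raw series are never smoothed.
    """

    delta: dict = field(default_factory=lambda: {
        "POPE": 0.7, "POPG": 0.7, "CL": 0.8, "POPC": 0.7})
    site_delta: dict = field(default_factory=lambda: {
        "POPE": 0.7, "POPG": 0.7, "CL": 1.1, "POPC": 0.7})
    sampling_interval: float = 0.3
    delta_ref: float = 0.7

    def __post_init__(self):
        for d in (self.delta, self.site_delta):
            if any(v <= 0 for v in d.values()):
                raise SystemError_("contact cutoffs must be positive")
        if self.sampling_interval <= 0:
            raise SystemError_("sampling interval must be positive")


@dataclass
class OccupancySeries:
    """Site-species occupancy: d(t), zeta(t) and the occupant molecule sets."""

    site: SiteDefinition
    species: str
    times: np.ndarray
    d: np.ndarray                 # min site<->headgroup distance per frame, nm
    zeta: np.ndarray              # 0/1 per frame
    occupants: list               # frozenset of molecule_ids per frame
    delta: float
    interval: float

    def occupancy_fraction(self) -> float:
        return float(np.mean(self.zeta)) if len(self.zeta) else float("nan")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(len(self.times)), "time_ns": self.times,
            "d_nm": self.d, "zeta": self.zeta,
            "occupants": [";".join(map(str, sorted(s))) for s in self.occupants]})


@dataclass
class ContactProfile:
    """Per (residue, species) contact counts under one normalization."""

    table: pd.DataFrame           # residue_id, residue_name, species, raw, normalized
    mode: str
    config: ContactConfig


def resample_indices(times: np.ndarray, interval: float) -> np.ndarray:
    """Frame indices nearest to a fixed-interval grid (never interpolates).

    When the trajectory is already sampled at the requested interval this is
    the identity.
    """
    times = np.asarray(times, dtype=float)
    if len(times) < 2:
        return np.arange(len(times))
    native = np.median(np.diff(times))
    if abs(native - interval) < 1e-9:
        return np.arange(len(times))
    targets = np.arange(times[0], times[-1] + 1e-9, interval)
    idx = np.searchsorted(times, targets)
    idx = np.clip(idx, 1, len(times) - 1)
    left = targets - times[idx - 1]
    right = times[idx] - targets
    return np.where(left <= right, idx - 1, idx)


def _molecule_compact(system: MembraneSystem, bead_idx: np.ndarray):
    """Map the given beads onto compact molecule indices."""
    mols = system.molecule_id[bead_idx]
    uniq, compact = np.unique(mols, return_inverse=True)
    return uniq, compact


def _min_dist_per_molecule(frame_pos, a_idx, hg_idx, hg_compact, n_mol, box):
    """Per-molecule minimum distance between molecule headgroup beads and the
    bead set ``a_idx`` (minimum-image), for one frame."""
    d = frame_pos[hg_idx][:, None, :] - frame_pos[a_idx][None, :, :]
    d = min_image(d, box)
    per_bead = np.sqrt((d * d).sum(axis=-1)).min(axis=1)
    out = np.full(n_mol, np.inf)
    np.minimum.at(out, hg_compact, per_bead)
    return out


def occupancy_series(traj: Trajectory, system: MembraneSystem,
                     site: SiteDefinition, species: str,
                     config: ContactConfig | None = None,
                     delta: float | None = None,
                     chunk: int = 5000) -> OccupancySeries:
    """Compute zeta(t) for one site and one lipid species.

    The site-to-lipid distance is the minimum over all beads of the two
    anchor residues times all HEADGROUP beads of the species.  ``delta``
    overrides the per-species site-level cutoff (used by the cutoff scan).
    """
    config = config or ContactConfig()
    if species not in LIPID_SPECIES:
        raise SystemError_(f"not a lipid species: {species!r}")
    hg_idx = system.headgroup_indices(species)
    if hg_idx.size == 0:
        raise SystemError_(f"species {species} absent from system")
    a_idx = np.concatenate([system.residue_beads(r) for r in site.anchor_residues])
    if a_idx.size == 0:
        raise SystemError_(f"site {site.site_id}: anchor residues "
                           f"{site.anchor_residues} not found among protein beads")
    if delta is None:
        delta = config.site_delta[species]

    mols, hg_compact = _molecule_compact(system, hg_idx)
    n_mol = len(mols)
    sel = resample_indices(traj.times, config.sampling_interval)

    d_min = np.empty(len(sel))
    occupants = []
    for lo in range(0, len(sel), chunk):
        block = sel[lo:lo + chunk]
        # (F, H, A) distances in one shot, then per-molecule reduction
        p = traj.positions[block]
        diff = p[:, hg_idx, None, :] - p[:, a_idx, :][:, None, :, :]
        diff = min_image(diff, np.asarray(traj.boxes[block[0]]))
        per_bead = np.sqrt((diff.astype(float) ** 2).sum(axis=-1)).min(axis=2)
        for f in range(per_bead.shape[0]):
            per_mol = np.full(n_mol, np.inf)
            np.minimum.at(per_mol, hg_compact, per_bead[f])
            d_min[lo + f] = per_mol.min()
            occupants.append(frozenset(int(m) for m in mols[per_mol <= delta]))
    zeta = (d_min <= delta).astype(np.int8)
    return OccupancySeries(site, species, traj.times[sel], d_min, zeta,
                           occupants, float(delta), config.sampling_interval)


def residue_contact_profile(traj: Trajectory, system: MembraneSystem,
                            config: ContactConfig | None = None,
                            mode: str = "per_lipid_frame_volume",
                            species: tuple | None = None) -> ContactProfile:
    """Per-residue contact counts between protein residues and lipid headgroups.

    Raw count for (residue, species) = number of (sampled frame, lipid) pairs
    with minimum bead distance (residue beads vs. lipid headgroup beads) at or
    below the species cutoff; each lipid counts at most once per residue per
    frame.  Normalizations:

    ``per_lipid_frame_volume``
        raw / (N_species * N_frames * (delta_species / delta_ref)**3)
    ``max_residue``
        raw / max over residues of raw for that species (top residue = 1).
    """
    config = config or ContactConfig()
    if mode not in ("per_lipid_frame_volume", "max_residue"):
        raise SystemError_(f"unknown normalization mode {mode!r}")
    sel = resample_indices(traj.times, config.sampling_interval)
    if len(sel) == 0:
        raise SystemError_("trajectory has zero frames")

    prot_idx = np.nonzero(system.protein_mask)[0]
    res_ids = system.residue_id[prot_idx]
    res_uniq, res_compact = np.unique(res_ids, return_inverse=True)
    n_res = len(res_uniq)
    res_names = {}
    for i, r in zip(prot_idx, res_ids):
        res_names.setdefault(int(r), system.residue_name[i])

    if species is None:
        species = tuple(sp for sp in LIPID_SPECIES
                        if system.headgroup_indices(sp).size)
    box = np.asarray(traj.boxes[0])

    rows = []
    for sp in species:
        hg_idx = system.headgroup_indices(sp)
        mols, hg_compact = _molecule_compact(system, hg_idx)
        n_mol = len(mols)
        delta = config.delta[sp]
        raw = np.zeros(n_res)
        for fi in sel:
            p = traj.positions[fi].astype(float)
            diff = p[prot_idx][:, None, :] - p[hg_idx][None, :, :]
            diff = min_image(diff, box)
            close = (diff * diff).sum(axis=-1) <= delta * delta  # (P, H)
            # OR-reduce beads -> (residue, molecule), count each lipid once
            rm = np.zeros((n_res, n_mol), dtype=bool)
            np.logical_or.at(rm, (res_compact[:, None].repeat(len(hg_idx), 1),
                                  hg_compact[None, :].repeat(len(prot_idx), 0)),
                             close)
            raw += rm.sum(axis=1)
        if mode == "per_lipid_frame_volume":
            denom = n_mol * len(sel) * (delta / config.delta_ref) ** 3
            norm = raw / denom if denom > 0 else np.zeros_like(raw)
        else:
            top = raw.max()
            norm = raw / top if top > 0 else np.zeros_like(raw)
        for k, rid in enumerate(res_uniq):
            rows.append((int(rid), res_names[int(rid)], sp, float(raw[k]),
                         float(norm[k])))
    table = pd.DataFrame(rows, columns=["residue_id", "residue_name", "species",
                                        "raw", "normalized"])
    return ContactProfile(table, mode, config)


def lipids_in_contact(traj: Trajectory, system: MembraneSystem,
                      config: ContactConfig | None = None,
                      species: tuple | None = None):
    """Per-frame number of lipids of each species in contact with the protein.

    A lipid is in contact when any of its HEADGROUP beads is within the
    species cutoff of any PROTEIN bead; each lipid counts once per frame.
    Returns (DataFrame with time_ns and one column per species, dict of time
    averages).
    """
    config = config or ContactConfig()
    sel = resample_indices(traj.times, config.sampling_interval)
    prot_idx = np.nonzero(system.protein_mask)[0]
    if species is None:
        species = tuple(sp for sp in LIPID_SPECIES
                        if system.headgroup_indices(sp).size)
    box = np.asarray(traj.boxes[0])
    data = {"time_ns": traj.times[sel]}
    means = {}
    for sp in species:
        hg_idx = system.headgroup_indices(sp)
        mols, hg_compact = _molecule_compact(system, hg_idx)
        counts = np.zeros(len(sel), dtype=int)
        if hg_idx.size and prot_idx.size:
            delta2 = config.delta[sp] ** 2
            for k, fi in enumerate(sel):
                p = traj.positions[fi].astype(float)
                diff = p[hg_idx][:, None, :] - p[prot_idx][None, :, :]
                diff = min_image(diff, box)
                close_b = (diff * diff).sum(axis=-1).min(axis=1) <= delta2
                in_contact = np.zeros(len(mols), dtype=bool)
                np.logical_or.at(in_contact, hg_compact, close_b)
                counts[k] = int(in_contact.sum())
        data[sp] = counts
        means[sp] = float(counts.mean()) if len(counts) else float("nan")
    return pd.DataFrame(data), means
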