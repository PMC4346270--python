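"""Run configuration and the staged analysis pipeline.

A run is described by a YAML config whose defaults are the study's printed
analysis constants (cutoffs 0.7/1.1 nm, 0.3 ns sampling, annuli 0-3 and
3.5-6 nm, pore bands 1.15/2.3 Angstrom).  Unknown keys are rejected before
any computation; every default in effect is logged at startup and echoed
into the machine-readable summary so each number in the summary is
reproducible from config + seed alone.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import contacts as contacts_mod
from . import density as density_mod
from . import io as io_mod
from . import motion as motion_mod
from . import pore as pore_mod
from . import residence as residence_mod
from .synth import SiteDefinition
from .system import INNER, OUTER, LIPID_SPECIES

log = logging.getLogger("memlip")


class ConfigError(ValueError):
    """Unknown or invalid run-configuration key."""


DEFAULTS = {
    "seed": 0,
    "output_dir": "memlip_out",
    "inputs": {"structure": None, "annotation": None, "trajectory": None},
    "sites": [],                       # list of {site_id, leaflet, anchor_residues}
    "species": None,                   # default: every lipid species present
    "contact": {"delta": None, "site_delta": None,
                "sampling_interval": 0.3, "delta_ref": 0.7},
    "annuli": {"near": [0.0, 3.0], "bulk": [3.5, 6.0]},
    "density": {"cell_size": 0.2, "masked": True,
                "leaflets": [INNER, OUTER], "write_maps": True},
    "residence": {"delta_grid": None, "top_k": 10},
    "msd": {"fit_window": [0.1, 0.5], "per_leaflet": False},
    "domains": {"fit_residues": None, "probe_residue": 350},
    "pore": {"enabled": False, "step": 0.5, "z_window": None},
    "stages": ["contacts", "residence", "density", "motion", "pore"],
}

# subtrees whose keys are free-form (per-species maps etc.)
_OPEN_PATHS = {"contact.delta", "contact.site_delta"}


def _merge(defaults, override, path=""):
    if override is None:
        return copy.deepcopy(defaults)
    if isinstance(defaults, dict):
        if not isinstance(override, dict):
            raise ConfigError(f"config key {path or '<root>'} must be a mapping")
        out = copy.deepcopy(defaults)
        for k, v in override.items():
            if k not in defaults:
                raise ConfigError(f"unknown config key {path + k!r}")
            child = path + k + "."
            if isinstance(defaults[k], dict) and (path + k) not in _OPEN_PATHS:
                out[k] = _merge(defaults[k], v, child)
            else:
                out[k] = copy.deepcopy(v)
        return out
    return copy.deepcopy(override)


def load_config(path=None, overrides=None) -> dict:
    """Resolve a config file against the defaults; rejects unknown keys."""
    user = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = _merge(DEFAULTS, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def sites_from_config(cfg) -> list:
    out = []
    for s in cfg["sites"]:
        extra = set(s) - {"site_id", "leaflet", "anchor_residues"}
        if extra:
            raise ConfigError(f"unknown site keys {sorted(extra)}")
        out.append(SiteDefinition(str(s["site_id"]), str(s["leaflet"]),
                                  tuple(int(r) for r in s["anchor_residues"])))
    return out


def contact_config(cfg) -> contacts_mod.ContactConfig:
    base = contacts_mod.ContactConfig(
        sampling_interval=cfg["contact"]["sampling_interval"],
        delta_ref=cfg["contact"]["delta_ref"])
    delta = dict(base.delta)
    site_delta = dict(base.site_delta)
    delta.update(cfg["contact"]["delta"] or {})
    site_delta.update(cfg["contact"]["site_delta"] or {})
    return contacts_mod.ContactConfig(delta=delta, site_delta=site_delta,
                                      sampling_interval=base.sampling_interval,
                                      delta_ref=base.delta_ref)


def run(cfg, outdir=None) -> dict:
    """Execute the configured stages in order; returns the summary dict.

    Stage order: contacts -> residence -> density/enrichment -> motion ->
    pore.  A stage failure aborts the run with the stage named.  All CSV /
    JSON / OpenDX outputs land in the output directory along with
    ``summary.json``.
    """
    outdir = Path(outdir or cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    for key, val in sorted(_flatten(cfg)):
        log.info("config %s = %r", key, val)

    paths = cfg["inputs"]
    if not paths["structure"] or not paths["annotation"] or not paths["trajectory"]:
        raise ConfigError("inputs.structure/annotation/trajectory are required")
    system = io_mod.load_system(paths["structure"], paths["annotation"])
    traj = io_mod.load_trajectory(paths["trajectory"], system)
    ccfg = contact_config(cfg)
    sites = sites_from_config(cfg)
    species = cfg["species"] or [sp for sp in LIPID_SPECIES
                                 if system.headgroup_indices(sp).size]

    summary = {"memlip_version": __version__,
               "numpy_version": np.__version__,
               "seed": cfg["seed"],
               "config": cfg,
               "n_frames": traj.n_frames, "n_beads": system.n_beads,
               "stages": {}}

    stage = None
    try:
        for stage in cfg["stages"]:
            if stage == "contacts":
                summary["stages"]["contacts"] = _stage_contacts(
                    traj, system, ccfg, species, outdir)
            elif stage == "residence":
                summary["stages"]["residence"] = _stage_residence(
                    traj, system, ccfg, sites, species, cfg, outdir)
            elif stage == "density":
                summary["stages"]["density"] = _stage_density(
                    traj, system, cfg, sites, species, outdir)
            elif stage == "motion":
                summary["stages"]["motion"] = _stage_motion(
                    traj, system, cfg, species, outdir)
            elif stage == "pore":
                if cfg["pore"]["enabled"]:
                    summary["stages"]["pore"] = _stage_pore(
                        traj, system, cfg, outdir)
            else:
                raise ConfigError(f"unknown stage {stage!r}")
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    return summary


def _flatten(d, prefix=""):
    for k, v in d.items():
        if isinstance(v, dict):
            yield from _flatten(v, prefix + str(k) + ".")
        else:
            yield prefix + str(k), v


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _stage_contacts(traj, system, ccfg, species, outdir):
    out = {}
    for mode in ("per_lipid_frame_volume", "max_residue"):
        prof = contacts_mod.residue_contact_profile(traj, system, ccfg, mode,
                                                    tuple(species))
        prof.table.to_csv(outdir / f"contact_profile_{mode}.csv", index=False)
    table, means = contacts_mod.lipids_in_contact(traj, system, ccfg,
                                                  tuple(species))
    table.to_csv(outdir / "lipids_in_contact.csv", index=False)
    out["lipids_in_contact_mean"] = means
    return out


def _stage_residence(traj, system, ccfg, sites, species, cfg, outdir):
    out = {}
    all_events = []
    for site in sites:
        for sp in species:
            series = contacts_mod.occupancy_series(traj, system, site, sp, ccfg)
            series.to_dataframe().to_csv(
                outdir / f"occupancy_{site.site_id}_{sp}.csv", index=False)
            events = residence_mod.extract_events(series)
            all_events.extend(events)
            key = f"{site.site_id}/{sp}"
            longest = residence_mod.longest_events(events, cfg["residence"]["top_k"]) \
                if events else []
            out[key] = {
                "occupancy_fraction": series.occupancy_fraction(),
                "n_events": len(events),
                "mean_residence_ns": residence_mod.mean_residence(events),
                "longest_ns": [ev.duration for ev in longest],
            }
    residence_mod.events_to_dataframe(all_events).to_csv(
        outdir / "binding_events.csv", index=False)
    return out


def _stage_density(traj, system, cfg, sites, species, outdir):
    out = {}
    annuli = (tuple(cfg["annuli"]["near"]), tuple(cfg["annuli"]["bulk"]))
    masked = cfg["density"]["masked"]
    for sp in species:
        for leaflet in cfg["density"]["leaflets"]:
            if cfg["density"]["write_maps"]:
                dmap = density_mod.density_map(
                    traj, system, sp, leaflet,
                    cell_size=cfg["density"]["cell_size"])
                density_mod.write_dx(dmap, outdir / f"density_{sp}_{leaflet}.dx")
                density_mod.density_map_to_dataframe(dmap).to_csv(
                    outdir / f"density_{sp}_{leaflet}.csv", index=False)
            res = density_mod.enrichment_ratio(traj, system, sp, leaflet,
                                               annuli=annuli, masked=masked)
            out[f"S/{sp}/{leaflet}"] = {"S": res.S, "se": res.se}
    if sites:
        for leaflet in cfg["density"]["leaflets"]:
            on_leaf = [s for s in sites if s.leaflet == leaflet]
            if not on_leaf:
                continue
            res = density_mod.site_local_enrichment(
                traj, system, on_leaf, "CL", capture_radius=1.1,
                leaflet=leaflet, annulus_bulk=annuli[1], masked=masked)
            out[f"S_site_local/CL/{leaflet}"] = {"S": res.S, "se": res.se}
    pd.DataFrame([
        {"key": k, **v} for k, v in out.items()
    ]).to_csv(outdir / "enrichment.csv", index=False)
    return out


def _stage_motion(traj, system, cfg, species, outdir):
    out = {}
    leaflets = [INNER, OUTER] if cfg["msd"]["per_leaflet"] else [None]
    msd_rows = []
    for sp in species:
        for leaflet in leaflets:
            try:
                res = motion_mod.msd_diffusion(
                    traj, system, sp, leaflet,
                    fit_window=tuple(cfg["msd"]["fit_window"]))
            except Exception as exc:
                log.warning("msd %s/%s skipped: %s", sp, leaflet, exc)
                continue
            key = f"D/{sp}" + (f"/{leaflet}" if leaflet else "")
            out[key] = {"D_cm2_s": res.D_cm2_s, "se": res.D_se,
                        "poor_fit": res.poor_fit}
            for lag, m in zip(res.lags, res.msd):
                msd_rows.append((sp, leaflet or "both", lag, m))
    pd.DataFrame(msd_rows, columns=["species", "leaflet", "lag_ns",
                                    "msd_nm2"]).to_csv(
        outdir / "msd.csv", index=False)

    ca = np.nonzero(system.ca_mask & system.protein_mask)[0]
    if ca.size >= 3 and traj.n_frames >= 2:
        rmsd = motion_mod.rmsd_series(traj, traj.positions[0].astype(float), ca)
        pd.DataFrame({"time_ns": traj.times, "rmsd_nm": rmsd}).to_csv(
            outdir / "rmsd.csv", index=False)
        res_ids, rmsf = motion_mod.rmsf(traj, system)
        pd.DataFrame({"residue_id": res_ids, "rmsf_nm": rmsf}).to_csv(
            outdir / "rmsf.csv", index=False)
        out["rmsd_final_nm"] = float(rmsd[-1])
        out["rmsf_mean_nm"] = float(np.mean(rmsf))
        fit_residues = cfg["domains"]["fit_residues"]
        if fit_residues:
            dist = motion_mod.domain_fit_distance(
                traj, traj.positions[0].astype(float), system, fit_residues,
                cfg["domains"]["probe_residue"])
            pd.DataFrame({"time_ns": traj.times, "distance_nm": dist}).to_csv(
                outdir / "domain_distance.csv", index=False)
            out["domain_distance_final_nm"] = float(dist[-1])
    return out


def _stage_pore(traj, system, cfg, outdir):
    profile = pore_mod.pore_profile(traj.frame(traj.n_frames - 1), system,
                                    step=cfg["pore"]["step"])
    profile.to_dataframe().to_csv(outdir / "pore_profile.csv", index=False)
    closed, min_r = pore_mod.is_closed(profile, cfg["pore"]["z_window"])
    return {"min_radius_A": min_r, "min_radius_z_A": profile.min_radius_z,
            "closed": closed}
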