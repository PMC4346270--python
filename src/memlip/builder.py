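"""Composition accounting: lipid-exchange plans and neutralizing ions.

A mixed bilayer is built from a pure-POPC one by randomly replacing one
POPC per new POPE or POPG and *two* POPC per cardiolipin (CL has two
diacylphosphatidic-acid moieties joined by a central glycerol, so it takes
the area of two single-tailed-pair lipids).  Ion counts follow the exact
charge balance n_Na - n_Cl = -(total system charge); when a target salt
concentration is given instead of a fixed Cl- count, the Cl- count comes
from molarity x waters / 55.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .system import SystemError_

_WATER_MOLARITY = 55.5  # mol/L, for salt-count conversion


@dataclass
class ExchangePlan:
    """Replacement plan per leaflet plus the resulting per-species counts."""

    replacements: dict           # leaflet -> list of (species, (popc_id, ...))
    leftover_popc: dict          # leaflet -> list of untouched POPC ids
    counts: dict                 # leaflet -> {species: n} incl. remaining POPC
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for leaflet, reps in self.replacements.items():
            for sp, ids in reps:
                for pid in ids:
                    rows.append((leaflet, sp, pid))
        return pd.DataFrame(rows, columns=["leaflet", "new_species", "popc_id"])


@dataclass
class IonCounts:
    n_na: int
    n_cl: int
    residual_charge: int = 0


def plan_lipid_exchange(popc_ids, targets, seed: int = 0) -> ExchangePlan:
    """Randomly assign POPC molecules for replacement, per leaflet.

    ``popc_ids`` maps leaflet -> available POPC molecule ids; ``targets``
    maps leaflet -> {species: count} for species in POPE/POPG/CL.  Each CL
    consumes exactly two POPC, POPE/POPG one each; leftover POPC is kept.
    Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    replacements, leftover, counts = {}, {}, {}
    for leaflet in popc_ids:
        ids = list(popc_ids[leaflet])
        want = dict(targets.get(leaflet, {}))
        unknown = set(want) - {"POPE", "POPG", "CL"}
        if unknown:
            raise SystemError_(f"cannot exchange into species {sorted(unknown)}")
        need = want.get("POPE", 0) + want.get("POPG", 0) + 2 * want.get("CL", 0)
        if need > len(ids):
            raise SystemError_(
                f"leaflet {leaflet}: need {need} POPC but only {len(ids)} "
                f"available (shortfall {need - len(ids)})")
        order = [ids[i] for i in rng.permutation(len(ids))]
        reps, k = [], 0
        for _ in range(want.get("CL", 0)):
            reps.append(("CL", tuple(order[k:k + 2])))
            k += 2
        for sp in ("POPE", "POPG"):
            for _ in range(want.get(sp, 0)):
                reps.append((sp, (order[k],)))
                k += 1
        replacements[leaflet] = reps
        leftover[leaflet] = sorted(order[k:])
        counts[leaflet] = {"POPE": want.get("POPE", 0),
                           "POPG": want.get("POPG", 0),
                           "CL": want.get("CL", 0),
                           "POPC": len(ids) - need}
    plan = ExchangePlan(replacements, leftover, counts, seed)
    _check_plan(plan, popc_ids)
    return plan


def _check_plan(plan: ExchangePlan, popc_ids) -> None:
    for leaflet, reps in plan.replacements.items():
        consumed = [pid for _, ids in reps for pid in ids]
        if len(consumed) != len(set(consumed)):
            raise SystemError_("a POPC molecule was consumed twice")
        for sp, ids in reps:
            if sp == "CL" and len(ids) != 2:
                raise SystemError_("CL replacement must consume exactly 2 POPC")
            if sp in ("POPE", "POPG") and len(ids) != 1:
                raise SystemError_(f"{sp} replacement must consume exactly 1 POPC")
        if set(consumed) | set(plan.leftover_popc[leaflet]) != set(popc_ids[leaflet]):
            raise SystemError_("plan does not account for every POPC")


def neutralizing_ions(charge_contributions, n_cl: int | None = None,
                      salt_molarity: float | None = None,
                      water_count: int | None = None) -> IonCounts:
    """Na+/Cl- counts that exactly neutralize the given charge contributions.

    ``charge_contributions`` are integer charges in e (e.g. -84 for the POPG
    lipids, -42 for the CL, +6 for the protein).  Either fix the Cl- count
    (n_Na then follows from n_Na - n_Cl = -total) or give a salt molarity
    plus water count.
    """
    contributions = [int(c) for c in charge_contributions]
    total = sum(contributions)
    if n_cl is None:
        if salt_molarity is None or water_count is None:
            n_cl = 0
        else:
            n_cl = int(round(salt_molarity * water_count / _WATER_MOLARITY))
    if n_cl < 0:
        raise SystemError_("Cl- count cannot be negative")
    n_na = n_cl - total
    if n_na < 0:
        raise SystemError_(
            f"cannot neutralize charge {total} e with {n_cl} Cl-: "
            "required Na+ count is negative")
    residual = total + n_na - n_cl
    assert residual == 0
    return IonCounts(n_na=n_na, n_cl=n_cl, residual_charge=residual)
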