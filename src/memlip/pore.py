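"""Sphere-fitting pore-radius profile along a transport axis.

At each position z along the axis the profiler finds the largest sphere
centred in that plane that fits without overlapping any protein bead:
maximize over the in-plane centre (x, y) the objective

    f(x, y) = min over beads ( |c - bead| - bead_radius )

with full 3D distances; only beads within +/-10 Angstrom of the plane
constrain it.  The search is a coarse 0.5 A grid around the previous
plane's optimum (channel continuity) followed by Nelder-Mead refinement to
better than 0.05 A.  All pore quantities are in Angstrom.

Radii are classified into the conventional colour bands: RED below 1.15 A
(too narrow even for a water molecule: closed), GREEN between 1.15 and
2.3 A, BLUE above 2.3 A (wide enough for bulk-like water).  The RED test
is a strict inequality, so a plane at exactly 1.15 A is not closed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .system import Frame, MembraneSystem, SystemError_

RED_THRESHOLD_A = 1.15
BLUE_THRESHOLD_A = 2.3

RED, GREEN, BLUE = "RED", "GREEN", "BLUE"


@dataclass
class PoreProfile:
    z: np.ndarray                # Angstrom along the transport axis
    radius: np.ndarray           # Angstrom; may be negative when occluded
    center_xy: np.ndarray        # (n, 2) optimized in-plane centres, Angstrom
    band: np.ndarray             # RED/GREEN/BLUE per z
    unbounded: np.ndarray        # True where no bead constrained the plane

    @property
    def radius_clamped(self) -> np.ndarray:
        return np.maximum(self.radius, 0.0)

    @property
    def min_radius(self) -> float:
        return float(np.min(self.radius))

    @property
    def min_radius_z(self) -> float:
        return float(self.z[int(np.argmin(self.radius))])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"z_A": self.z, "radius_A": self.radius,
                             "x_A": self.center_xy[:, 0],
                             "y_A": self.center_xy[:, 1],
                             "band": self.band,
                             "unbounded": self.unbounded})


def classify_band(radius_A: float) -> str:
    if radius_A < RED_THRESHOLD_A:
        return RED
    if radius_A > BLUE_THRESHOLD_A:
        return BLUE
    return GREEN


def _axis_rotation(axis_direction) -> np.ndarray:
    """Rotation matrix sending ``axis_direction`` to +z."""
    a = np.asarray(axis_direction, dtype=float)
    norm = np.linalg.norm(a)
    if norm == 0:
        raise SystemError_("axis direction must be nonzero")
    a = a / norm
    z = np.array([0.0, 0.0, 1.0])
    if np.allclose(a, z):
        return np.eye(3)
    if np.allclose(a, -z):
        return Rotation.from_rotvec([np.pi, 0, 0]).as_matrix()
    rot, _ = Rotation.align_vectors(z[None], a[None])
    return rot.as_matrix()


def pore_profile(frame: Frame, system: MembraneSystem,
                 axis_point=None, axis_direction=(0.0, 0.0, 1.0),
                 z_range=None, step: float = 0.5,
                 slab_half_width: float = 10.0, search_radius: float = 5.0,
                 coarse_step: float = 0.5, refine_tol: float = 0.01,
                 max_radius: float = 25.0) -> PoreProfile:
    """Pore-radius profile of a protein frame (all lengths in Angstrom,
    positions converted from the frame's nm internally).

    ``axis_point`` defaults to the protein CA centroid; ``z_range`` to the
    protein's extent along the axis.  Planes with no bead within the
    +/-``slab_half_width`` slab report ``max_radius`` and are flagged
    ``unbounded``.
    """
    prot = np.nonzero(system.protein_mask)[0]
    if prot.size == 0:
        raise SystemError_("no protein beads")
    beads = frame.positions[prot].astype(float) * 10.0  # nm -> Angstrom
    radii = system.vdw_radius[prot].astype(float)

    Rm = _axis_rotation(axis_direction)
    beads = beads @ Rm.T
    if axis_point is None:
        ca = system.ca_mask[prot]
        ref = beads[ca] if ca.any() else beads
        axis_point_r = ref.mean(axis=0)
    else:
        ap = np.asarray(axis_point, dtype=float)
        if ap.size == 2:            # (x, y) in the axis plane
            ap = np.array([ap[0], ap[1], 0.0])
        axis_point_r = (ap * 10.0) @ Rm.T
    if z_range is None:
        z_lo, z_hi = beads[:, 2].min(), beads[:, 2].max()
    else:
        z_lo, z_hi = z_range  # already in Angstrom along the axis

    zs = np.arange(z_lo, z_hi + step / 2, step)
    out_r = np.empty(len(zs))
    out_c = np.empty((len(zs), 2))
    out_u = np.zeros(len(zs), dtype=bool)
    seed = axis_point_r[:2].copy()

    for i, z in enumerate(zs):
        slab = np.abs(beads[:, 2] - z) <= slab_half_width
        if not slab.any():
            out_r[i] = max_radius
            out_c[i] = seed
            out_u[i] = True
            continue
        b = beads[slab]
        rb = radii[slab]

        def f(c):
            d = np.sqrt((b[:, 0] - c[0]) ** 2 + (b[:, 1] - c[1]) ** 2
                        + (b[:, 2] - z) ** 2)
            return float(np.min(d - rb))

        # coarse grid around the previous optimum
        g = np.arange(-search_radius, search_radius + coarse_step / 2, coarse_step)
        gx, gy = np.meshgrid(seed[0] + g, seed[1] + g)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        d = np.sqrt((pts[:, None, 0] - b[None, :, 0]) ** 2
                    + (pts[:, None, 1] - b[None, :, 1]) ** 2
                    + (z - b[None, :, 2]) ** 2)
        vals = (d - rb[None, :]).min(axis=1)
        best = pts[int(np.argmax(vals))]

        res = minimize(lambda c: -f(c), best, method="Nelder-Mead",
                       options={"xatol": refine_tol, "fatol": refine_tol / 10,
                                "maxiter": 200})
        cand = res.x
        if np.linalg.norm(cand - seed) > search_radius + coarse_step:
            cand = best  # refinement drifted out of the continuity region
        val = f(cand)
        if val < vals.max():   # never worse than the coarse optimum
            cand, val = best, float(vals.max())
        if val > max_radius:
            val = max_radius
            out_u[i] = True
        out_r[i] = val
        out_c[i] = cand
        seed = cand

    bands = np.array([classify_band(r) for r in out_r], dtype=object)
    return PoreProfile(zs, out_r, out_c, bands, out_u)


def is_closed(profile: PoreProfile, z_window=None):
    """Whether the pore is closed in a z window: min radius < 1.15 A.

    Returns (closed, min_radius_A).  ``z_window`` is (lo, hi) in Angstrom;
    default: the whole profile.
    """
    if z_window is None:
        sel = np.ones(len(profile.z), dtype=bool)
    else:
        lo, hi = z_window
        sel = (profile.z >= lo) & (profile.z <= hi)
    if not sel.any():
        raise SystemError_("empty z window")
    min_r = float(profile.radius[sel].min())
    return min_r < RED_THRESHOLD_A, min_r
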