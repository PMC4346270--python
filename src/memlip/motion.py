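"""Superposition metrics and lateral diffusion from MSD.

Superposition is the optimal proper rigid-body least-squares fit (Kabsch;
no reflection), here delegated to scipy's rotation machinery.  Lateral
diffusion is estimated from the time-origin-averaged mean squared
displacement of unwrapped headgroup xy coordinates: MSD(tau) = 4 D tau for
Brownian lateral motion, so D is the fitted slope over a lag window divided
by 4, reported in cm^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .system import (INNER, LIPID_SPECIES, MembraneSystem, SystemError_,
                     Trajectory, assign_leaflets, min_image)

_NM2_PER_NS_TO_CM2_PER_S = 1.0e-5


# ---------------------------------------------------------------------------
# rigid-body superposition
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, reference: np.ndarray, weights=None):
    """Optimal proper rotation + translation mapping mobile onto reference.

    Returns ``(R, t, rmsd)`` with ``R @ x + t`` the fitted coordinates.
    Requires >= 3 non-collinear points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise SystemError_("selection size mismatch between mobile and reference")
    if len(mobile) < 3:
        raise SystemError_("superposition needs at least 3 points")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    a, b = reference - rc, mobile - mc
    if np.linalg.matrix_rank(b - b.mean(axis=0), tol=1e-10) < 2:
        raise SystemError_("degenerate (collinear) selection")
    rot, _ = Rotation.align_vectors(a, b, weights=weights)
    R = rot.as_matrix()
    t = rc - R @ mc
    fitted = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return R, t, rmsd


def superpose_rmsd(mobile_frame, reference_frame, selection=None):
    """RMSD after optimal superposition of one frame onto another.

    ``selection`` is an index array into the bead roster (default: all).
    Returns ``((R, t), rmsd)``.
    """
    mob = np.asarray(getattr(mobile_frame, "positions", mobile_frame), dtype=float)
    ref = np.asarray(getattr(reference_frame, "positions", reference_frame), dtype=float)
    if selection is not None:
        mob, ref = mob[selection], ref[selection]
    R, t, rmsd = superpose(mob, ref)
    return (R, t), rmsd


def rmsd_series(traj: Trajectory, reference, selection=None) -> np.ndarray:
    """Per-frame RMSD (nm) versus a reference after superposition."""
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        _, out[i] = superpose_rmsd(traj.positions[i], reference, selection)
    return out


def rmsf(traj: Trajectory, system: MembraneSystem, selection=None):
    """Per-residue RMSF (nm) of backbone-CA beads about the trajectory mean.

    Each frame is superposed onto the mean structure over the selection
    (two fixed-point iterations starting from a frame-0 fit); RMSF is the
    root-mean-square deviation of each selected bead about its mean
    position.  Returns (residue_ids, rmsf_nm).
    """
    if traj.n_frames < 2:
        raise SystemError_("RMSF needs at least 2 frames")
    if selection is None:
        selection = np.nonzero(system.ca_mask & system.protein_mask)[0]
    selection = np.asarray(selection)
    coords = traj.positions[:, selection, :].astype(float)
    ref = coords[0]
    for _ in range(2):
        fitted = np.empty_like(coords)
        for i in range(len(coords)):
            R, t, _ = superpose(coords[i], ref)
            fitted[i] = coords[i] @ R.T + t
        ref = fitted.mean(axis=0)
    dev = fitted - ref
    out = np.sqrt(np.mean(np.sum(dev * dev, axis=2), axis=0))
    return system.residue_id[selection], out


def domain_fit_distance(traj: Trajectory, reference, system: MembraneSystem,
                        fit_residues, probe_residue: int = 350) -> np.ndarray:
    """Distance of a probe CA from its reference position after a core fit.

    Per frame, the CA beads of ``fit_residues`` (the rigid core domain) are
    superposed onto the reference; the reported series is the Euclidean
    distance between the transformed probe CA and the reference probe CA —
    a direct readout of gate-domain motion relative to the core.  The probe
    defaults to residue 350.
    """
    ref = np.asarray(getattr(reference, "positions", reference), dtype=float)
    ca = system.ca_mask & system.protein_mask
    fit_sel = np.nonzero(ca & np.isin(system.residue_id, np.asarray(fit_residues)))[0]
    probe_sel = np.nonzero(ca & (system.residue_id == probe_residue))[0]
    if probe_sel.size != 1:
        raise SystemError_(f"probe residue {probe_residue} not found (or ambiguous)")
    probe = int(probe_sel[0])
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        p = traj.positions[i].astype(float)
        R, t, _ = superpose(p[fit_sel], ref[fit_sel])
        out[i] = np.linalg.norm((R @ p[probe] + t) - ref[probe])
    return out


# ---------------------------------------------------------------------------
# MSD and lateral diffusion
# ---------------------------------------------------------------------------

@dataclass
class DiffusionResult:
    species: str
    leaflet: str | None
    lags: np.ndarray             # ns
    msd: np.ndarray              # nm^2
    D_cm2_s: float
    D_se: float                  # standard error of the fitted slope / 4
    fit_window: tuple            # fraction of max lag
    slope: float                 # nm^2/ns
    intercept: float
    poor_fit: bool               # curvature diagnostic tripped
    n_lipids: int


def _msd_fft(r: np.ndarray) -> np.ndarray:
    """Time-origin-averaged MSD of one walker, all lags, O(T log T).

    Standard decomposition MSD(m) = S1(m) - 2 S2(m) with S2 the positional
    autocorrelation computed by FFT.
    """
    T, dim = r.shape
    nfft = 1 << (2 * T - 1).bit_length()
    s2 = np.zeros(T)
    for k in range(dim):
        f = np.fft.rfft(r[:, k], nfft)
        ac = np.fft.irfft(f * f.conjugate(), nfft)[:T]
        s2 += ac
    s2 /= T - np.arange(T)
    d = (r * r).sum(axis=1)
    # S1(m) = mean over origins of |r(t+m)|^2 + |r(t)|^2
    csum = np.concatenate([[0.0], np.cumsum(d)])
    total = csum[-1]
    m = np.arange(T)
    head = csum[T - m] - csum[0]          # sum_{t=0}^{T-m-1} d[t]
    tail = total - csum[m]                # sum_{t=m}^{T-1} d[t]
    s1 = (head + tail) / (T - m)
    return s1 - 2.0 * s2


def unwrap_xy(traj: Trajectory, bead_indices) -> np.ndarray:
    """Unwrapped xy tracks (T, n, 2): minimum-image displacements between
    consecutive frames, accumulated."""
    box2 = np.asarray(traj.boxes[0][:2])
    p = traj.positions[:, bead_indices, :2].astype(float)
    steps = min_image(np.diff(p, axis=0), box2)
    out = np.empty_like(p)
    out[0] = p[0]
    np.cumsum(steps, axis=0, out=steps)
    out[1:] = p[0] + steps
    return out


def msd_diffusion(traj: Trajectory, system: MembraneSystem, species: str,
                  leaflet: str | None = None,
                  fit_window: tuple = (0.1, 0.5)) -> DiffusionResult:
    """Lateral diffusion coefficient of one lipid species from the MSD slope.

    The MSD is computed over xy only, averaged over lipids (one headgroup
    centroid track per molecule) and over time origins; D = slope / 4 over
    the fit window, a (lo, hi) fraction of the maximum lag.  The default
    window 10-50% skips both the shortest lags (where the discrete-step
    microdynamics dominates) and the poorly averaged tail.
    """
    if traj.n_frames < 2:
        raise SystemError_("MSD needs at least 2 frames")
    if species not in LIPID_SPECIES:
        raise SystemError_(f"not a lipid species: {species!r}")
    hg_idx = system.headgroup_indices(species)
    if hg_idx.size == 0:
        raise SystemError_(f"species {species} absent from system")
    if leaflet is not None:
        assignment = assign_leaflets(traj.frame(0), system)
        keep = np.array([assignment.leaflet_of[int(m)] == leaflet
                         for m in system.molecule_id[hg_idx]])
        hg_idx = hg_idx[keep]
        if hg_idx.size == 0:
            raise SystemError_(f"no {species} lipids in leaflet {leaflet}")

    tracks = unwrap_xy(traj, hg_idx)
    # molecule headgroup centroid (CL may carry several headgroup beads)
    mols = system.molecule_id[hg_idx]
    uniq, inverse = np.unique(mols, return_inverse=True)
    cent = np.zeros((tracks.shape[0], len(uniq), 2))
    np.add.at(cent, (slice(None), inverse), tracks)
    cent /= np.bincount(inverse)[None, :, None]

    T = cent.shape[0]
    msd = np.zeros(T)
    for j in range(cent.shape[1]):
        msd += _msd_fft(cent[:, j, :])
    msd /= cent.shape[1]
    msd[0] = 0.0

    dt = traj.sampling_interval
    lags = np.arange(T) * dt
    lo = max(1, int(round(fit_window[0] * (T - 1))))
    hi = min(T - 1, max(lo + 2, int(round(fit_window[1] * (T - 1)))))
    if lo >= T or hi - lo < 2:
        raise SystemError_("fit window outside available lags")
    sel = slice(lo, hi + 1)
    x, y = lags[sel], msd[sel]
    if np.allclose(y, 0.0):
        slope, intercept, slope_se = 0.0, 0.0, 0.0
        cov = None
    else:
        (slope, intercept), cov = np.polyfit(x, y, 1, cov=True)
        slope_se = float(np.sqrt(cov[0, 0]))

    # curvature diagnostic: quadratic term material over the window
    c2, c1, _ = np.polyfit(x, y, 2)
    poor = bool(abs(c2) * (x[-1] - x[0]) > 0.2 * max(abs(c1), 1e-300))

    return DiffusionResult(
        species=species, leaflet=leaflet, lags=lags, msd=msd,
        D_cm2_s=float(slope / 4.0 * _NM2_PER_NS_TO_CM2_PER_S),
        D_se=slope_se / 4.0 * _NM2_PER_NS_TO_CM2_PER_S,
        fit_window=tuple(fit_window), slope=float(slope),
        intercept=float(intercept), poor_fit=poor, n_lipids=len(uniq))
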