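"""Superposition, RMSF, domain-fit distance and MSD/diffusion."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from memlip.motion import (domain_fit_distance, msd_diffusion, rmsf,
                           superpose, superpose_rmsd, unwrap_xy, _msd_fft)
from memlip.synth import SynthParams, generate
from memlip.system import MembraneSystem, SystemError_, Trajectory

from test_contacts import make_system, make_traj


def brute_force_min_rmsd(mobile, reference, n_coarse=3000, seed=0):
    """Quaternion-search oracle: random orientations plus shrinking local
    perturbations; translation handled by centroid matching."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def rmsd_of(R):
        return np.sqrt(np.mean(np.sum((mob @ R.T - ref) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    best_R = np.eye(3)
    best = rmsd_of(best_R)
    for R in Rotation.random(n_coarse, random_state=seed).as_matrix():
        v = rmsd_of(R)
        if v < best:
            best, best_R = v, R
    for scale in (0.3, 0.1, 0.03, 0.01, 0.003, 0.001, 3e-4, 1e-4):
        for _ in range(120):
            pert = Rotation.from_rotvec(rng.normal(0, scale, 3)).as_matrix()
            R = pert @ best_R
            v = rmsd_of(R)
            if v < best:
                best, best_R = v, R
    return best


class TestSuperpose:
    def test_identity(self):
        x = np.random.default_rng(0).random((8, 3))
        _, _, rmsd = superpose(x, x)
        assert rmsd < 1e-12

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_rigid_copy_has_zero_rmsd(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random((12, 3))
        R = Rotation.random(random_state=seed).as_matrix()
        y = x @ R.T + rng.random(3) * 5
        _, _, rmsd = superpose(y, x)
        assert rmsd < 1e-9

    def test_matches_quaternion_grid_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.random((4, 3)) * 2.0          # asymmetric 4-point fixture
        y = x + rng.normal(0, 0.1, x.shape)   # perturbed copy
        _, _, rmsd = superpose(y, x)
        oracle = brute_force_min_rmsd(y, x)
        assert rmsd == pytest.approx(oracle, abs=1e-6)
        assert rmsd <= oracle + 1e-9          # fit is the true minimum

    def test_fitted_never_exceeds_unfitted(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            x = rng.random((6, 3))
            y = x + rng.normal(0, 0.2, x.shape)
            _, fitted = superpose_rmsd(y, x)
            unfitted = np.sqrt(np.mean(np.sum((y - x) ** 2, axis=1)))
            assert fitted <= unfitted + 1e-12

    def test_degenerate_selection_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(SystemError_):
            superpose(line, line + 1.0)
        with pytest.raises(SystemError_):
            superpose(line[:2], line[:2])


class TestRmsf:
    def _protein_traj(self, n_res=8, n_frames=400, jitter_res=None, sigma=0.05,
                      rotate=False, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.random((n_res, 3)) * 3.0
        frames = []
        for k in range(n_frames):
            f = base.copy()
            if jitter_res is not None:
                f[jitter_res] += rng.normal(0, sigma, 3)
            if rotate:
                R = Rotation.from_euler("z", 0.01 * k).as_matrix()
                f = f @ R.T
            frames.append(f)
        system = make_system([], n_prot_res=n_res)
        traj = make_traj(frames)
        return system, traj

    def test_static_trajectory_zero(self):
        system, traj = self._protein_traj()
        _, vals = rmsf(traj, system)
        assert np.all(vals < 1e-12)

    def test_jittered_residue_recovers_sigma_sqrt3(self):
        # enough static residues that the rigid fit cannot absorb the
        # single residue's jitter (absorption ~ sqrt(1 - 6/(3 n_res)))
        sigma = 0.05
        system, traj = self._protein_traj(n_res=40, n_frames=1500,
                                          jitter_res=4, sigma=sigma, seed=3)
        ids, vals = rmsf(traj, system)
        assert vals[4] == pytest.approx(sigma * np.sqrt(3), rel=0.08)
        assert np.all(np.delete(vals, 4) < 0.01)

    def test_global_rotation_removed_by_fit(self):
        system, traj = self._protein_traj(n_frames=100, rotate=True)
        _, vals = rmsf(traj, system)
        assert np.all(vals < 1e-9)


class TestDomainFit:
    def _system(self, n_res=12):
        system = make_system([], n_prot_res=n_res)
        # relabel the last residue as the probe (residue 350)
        rid = np.asarray(system.residue_id).copy()
        rid[n_res - 1] = 350
        system.residue_id = rid
        return system

    def test_reference_frame_gives_zero(self):
        system = self._system()
        rng = np.random.default_rng(0)
        pos = rng.random((12, 3)) * 3
        traj = make_traj([pos])
        d = domain_fit_distance(traj, pos, system, fit_residues=range(1, 9))
        assert d[0] < 1e-12

    def test_translated_gate_reads_one_nm(self):
        system = self._system()
        rng = np.random.default_rng(1)
        ref = rng.random((12, 3)) * 3
        moved = ref.copy()
        moved[8:] += np.array([0.0, 0.0, 1.0])   # gate beads incl. probe
        traj = make_traj([moved])
        d = domain_fit_distance(traj, ref, system, fit_residues=range(1, 9))
        assert d[0] == pytest.approx(1.0, abs=1e-9)

    def test_probe_default_is_350(self):
        system = self._system()
        pos = np.random.default_rng(2).random((12, 3))
        traj = make_traj([pos])
        assert domain_fit_distance(traj, pos, system,
                                   fit_residues=range(1, 9))[0] < 1e-12
        missing = make_system([], n_prot_res=5)
        with pytest.raises(SystemError_, match="350"):
            domain_fit_distance(traj, pos, missing, fit_residues=range(1, 4))


class TestMsd:
    def test_fft_equals_naive_oracle(self):
        rng = np.random.default_rng(5)
        r = np.cumsum(rng.normal(0, 0.3, (64, 2)), axis=0)
        fast = _msd_fft(r)
        naive = np.zeros(len(r))
        for m in range(1, len(r)):
            d = r[m:] - r[:-m]
            naive[m] = np.mean((d ** 2).sum(axis=1))
        np.testing.assert_allclose(fast[1:], naive[1:], rtol=1e-8, atol=1e-10)

    def test_unwrap_recovers_free_walk(self):
        rng = np.random.default_rng(6)
        steps = rng.normal(0, 0.4, (200, 3, 2))
        true = np.concatenate([np.zeros((1, 3, 2)), np.cumsum(steps, axis=0)])
        box = 5.0
        wrapped = np.mod(true, box)
        pos3 = np.concatenate([wrapped, np.zeros((201, 3, 1))], axis=2)
        traj = Trajectory(np.arange(201) * 0.3, pos3, [(box, box, box)] * 201)
        un = unwrap_xy(traj, np.arange(3))
        np.testing.assert_allclose(un - un[0], true - true[0], atol=1e-9)

    def test_diffusion_recovery_within_five_percent(self):
        # 512 lipids x 8000 steps keeps the fitted-slope noise near 2%
        D_in = 6.2e-7
        p = SynthParams(box=(30.0, 30.0), protein_radius=1.5,
                        lipid_counts={"POPE": (256, 256)},
                        diffusion={"POPE": D_in}, well=(0.0, 0.0, 0.0),
                        sites=(), n_steps=8000, seed=2)
        system, traj, _ = generate(p)
        res = msd_diffusion(traj, system, "POPE")
        assert res.D_cm2_s == pytest.approx(D_in, rel=0.05)
        assert not res.poor_fit

    def test_immobile_gives_zero(self):
        p = SynthParams(box=(20.0, 20.0), protein_radius=1.5,
                        lipid_counts={"POPE": (30, 30)},
                        diffusion={"POPE": 0.0}, well=(0.0, 0.0, 0.0),
                        sites=(), n_steps=100, seed=3)
        system, traj, _ = generate(p)
        assert msd_diffusion(traj, system, "POPE").D_cm2_s == 0.0

    def test_drift_flagged_as_poor_fit(self):
        v = 0.05  # nm per frame, constant velocity -> MSD quadratic in lag
        n = 400
        pos = np.zeros((n, 4, 3))
        for k in range(n):
            pos[k, 3, :2] = [7.0 + v * k % 14.0, 7.0]
        pos[:, :3] = np.random.default_rng(0).random((3, 3)) * 2
        system = make_system(["POPE"], box=(14.0, 14.0, 5.0), n_prot_res=3)
        traj = make_traj(np.mod(pos, 14.0), box=(14.0, 14.0, 5.0))
        res = msd_diffusion(traj, system, "POPE")
        assert res.poor_fit

    def test_time_origin_averaging_consistent_with_single_origin(self):
        """On a stationary walk both MSD estimators agree in expectation."""
        rng = np.random.default_rng(9)
        n_lip, T = 60, 300
        steps = rng.normal(0, 0.3, (T - 1, n_lip, 2))
        tracks = np.concatenate([np.zeros((1, n_lip, 2)),
                                 np.cumsum(steps, axis=0)])
        lag = T // 4
        multi = np.mean([_msd_fft(tracks[:, j])[lag] for j in range(n_lip)])
        single = np.mean(((tracks[lag] - tracks[0]) ** 2).sum(axis=1))
        # single-origin estimate is noisier; agree within its sampling error
        se = np.std(((tracks[lag] - tracks[0]) ** 2).sum(axis=1)) / np.sqrt(n_lip)
        assert abs(multi - single) <= 4 * se

    def test_leaflet_filtering(self, default_run):
        system, traj, _ = default_run
        inner = msd_diffusion(traj, system, "CL", "INNER")
        both = msd_diffusion(traj, system, "CL")
        assert inner.n_lipids * 2 == both.n_lipids
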