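"""Contact occupancy and profiles, checked against brute-force oracles."""

import numpy as np
import pytest

from memlip.contacts import (ContactConfig, SiteDefinition, lipids_in_contact,
                             occupancy_series, residue_contact_profile,
                             resample_indices)
from memlip.system import (Frame, MembraneSystem, SystemError_, Trajectory,
                           min_image)


def make_system(species_per_lipid, box=(5.0, 5.0, 5.0), n_prot_res=2):
    """Tiny system: n protein CA residues + one headgroup bead per lipid."""
    names, resids, resnames, species, roles, mols = [], [], [], [], [], []
    for r in range(1, n_prot_res + 1):
        names.append("BB"); resids.append(r); resnames.append("ALA")
        species.append("PROTEIN"); roles.append(frozenset({"BACKBONE_CA"}))
        mols.append(0)
    for i, sp in enumerate(species_per_lipid):
        names.append("PO4"); resids.append(n_prot_res + 1 + i); resnames.append(sp)
        species.append(sp); roles.append(frozenset({"HEADGROUP"}))
        mols.append(i + 1)
    n = len(names)
    return MembraneSystem(
        bead_id=np.arange(1, n + 1), name=np.array(names, dtype=object),
        residue_id=np.array(resids), residue_name=np.array(resnames, dtype=object),
        molecule_id=np.array(mols), species=np.array(species, dtype=object),
        roles=roles, vdw_radius=np.full(n, 2.3), box=box)


def make_traj(positions_per_frame, box=(5.0, 5.0, 5.0), dt=0.3):
    pos = np.asarray(positions_per_frame, dtype=float)
    times = np.arange(len(pos)) * dt
    return Trajectory(times, pos, [box] * len(pos))


SITE = SiteDefinition("s", "INNER", (1, 2))


class TestOccupancy:
    def test_boundary_convention_and_simple_values(self):
        system = make_system(["CL"])
        base = np.array([[1.0, 1.0, 1.0], [1.0, 1.6, 1.0], [0.0, 0.0, 0.0]])
        for d, expected in ((0.6, 1), (0.7, 1), (0.75, 0)):
            frame = base.copy()
            frame[2] = [1.0 + d, 1.0, 1.0]   # lipid exactly d from anchor 1
            traj = make_traj([frame])
            ser = occupancy_series(traj, system, SITE, "CL", delta=0.7)
            assert ser.zeta[0] == expected
            assert ser.d[0] == pytest.approx(d)

    def test_hand_built_five_frame_series(self):
        system = make_system(["CL"])
        dists = [0.5, 0.65, 0.72, 0.69, 1.0]
        frames = []
        for d in dists:
            f = np.array([[1.0, 1.0, 1.0], [1.0, 1.6, 1.0], [1.0 + d, 1.0, 1.0]])
            frames.append(f)
        ser = occupancy_series(make_traj(frames), system, SITE, "CL", delta=0.7)
        assert list(ser.zeta) == [1, 1, 0, 1, 0]

    def test_occupant_set_invariant(self):
        rng = np.random.default_rng(0)
        system = make_system(["CL"] * 5)
        frames = rng.random((10, 7, 3)) * 5.0
        ser = occupancy_series(make_traj(frames), system, SITE, "CL", delta=1.5)
        for z, occ, d in zip(ser.zeta, ser.occupants, ser.d):
            assert (z == 1) == (len(occ) > 0) == (d <= 1.5)

    def test_absent_species_errors(self):
        system = make_system(["CL"])
        traj = make_traj([np.zeros((3, 3))])
        with pytest.raises(SystemError_, match="POPG"):
            occupancy_series(traj, system, SITE, "POPG")

    def test_translation_and_wrap_invariance(self):
        rng = np.random.default_rng(1)
        system = make_system(["CL"] * 4)
        frames = rng.random((6, 6, 3)) * 5.0
        ser0 = occupancy_series(make_traj(frames), system, SITE, "CL", delta=1.2)
        shifted = np.mod(frames + np.array([3.7, -1.2, 0.9]), 5.0)
        ser1 = occupancy_series(make_traj(shifted), system, SITE, "CL", delta=1.2)
        assert np.array_equal(ser0.zeta, ser1.zeta)
        np.testing.assert_allclose(ser0.d, ser1.d, atol=1e-9)
        assert ser0.occupants == ser1.occupants


def brute_force_contacts(system, frame_pos, box, delta_by_species):
    """All-pairs python-loop oracle: per (residue, species) lipid contacts."""
    box = np.asarray(box)
    counts = {}
    prot = [i for i in range(system.n_beads) if system.species[i] == "PROTEIN"]
    for sp in set(system.species) - {"PROTEIN"}:
        delta = delta_by_species[sp]
        for mol in np.unique(system.molecule_id[system.species == sp]):
            hg = [i for i in range(system.n_beads)
                  if system.molecule_id[i] == mol and "HEADGROUP" in system.roles[i]]
            for res in np.unique(system.residue_id[system.protein_mask]):
                rb = [i for i in prot if system.residue_id[i] == res]
                dmin = np.inf
                for i in rb:
                    for j in hg:
                        d = min_image(frame_pos[j] - frame_pos[i], box)
                        dmin = min(dmin, float(np.sqrt((d * d).sum())))
                if dmin <= delta:
                    counts[(int(res), sp)] = counts.get((int(res), sp), 0) + 1
    return counts


class TestResidueProfile:
    def test_counts_match_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        system = make_system(["CL", "CL", "POPE", "POPG", "POPE"], n_prot_res=3)
        frames = rng.random((4, system.n_beads, 3)) * 5.0
        traj = make_traj(frames)
        cfg = ContactConfig()
        prof = residue_contact_profile(traj, system, cfg, "max_residue")
        expected = {}
        for f in frames:
            for k, v in brute_force_contacts(system, f, (5, 5, 5),
                                             cfg.delta).items():
                expected[k] = expected.get(k, 0) + v
        for _, row in prof.table.iterrows():
            assert row["raw"] == expected.get((row["residue_id"],
                                               row["species"]), 0)

    def test_max_residue_normalization_tops_at_one(self, default_run):
        system, traj, _ = default_run
        sub = Trajectory(traj.times[:30], traj.positions[:30], traj.boxes[:30])
        prof = residue_contact_profile(sub, system, mode="max_residue")
        for sp, grp in prof.table.groupby("species"):
            if grp["raw"].max() > 0:
                assert grp["normalized"].max() == pytest.approx(1.0)
            assert ((grp["normalized"] >= 0) & (grp["normalized"] <= 1)).all()
            # zero-contact residues normalize to zero
            assert (grp.loc[grp["raw"] == 0, "normalized"] == 0).all()

    def test_cutoff_volume_ratio_divisor(self):
        """CL at delta 0.8 vs reference 0.7 is divided by (8/7)^3 ~ 1.4927."""
        system = make_system(["CL"])
        frame = np.array([[1.0, 1.0, 1.0], [1.2, 1.0, 1.0], [1.5, 1.0, 1.0]])
        traj = make_traj([frame])
        prof = residue_contact_profile(traj, system, mode="per_lipid_frame_volume")
        row = prof.table[(prof.table.residue_id == 1)
                         & (prof.table.species == "CL")].iloc[0]
        assert row["raw"] == 1
        assert row["normalized"] == pytest.approx(1.0 / (0.8 / 0.7) ** 3)
        assert (0.8 / 0.7) ** 3 == pytest.approx(1.4927, abs=2e-4)

    def test_monotone_in_delta(self):
        rng = np.random.default_rng(9)
        system = make_system(["CL", "POPE", "POPG"] * 3, n_prot_res=4)
        traj = make_traj(rng.random((5, system.n_beads, 3)) * 5.0)
        prev = None
        for d in (0.5, 0.8, 1.1, 1.6):
            cfg = ContactConfig(delta={sp: d for sp in
                                       ("POPE", "POPG", "CL", "POPC")})
            raw = residue_contact_profile(traj, system, cfg,
                                          "max_residue").table["raw"].values
            if prev is not None:
                assert np.all(raw >= prev)
            prev = raw

    def test_zero_frames_rejected(self):
        system = make_system(["CL"])
        with pytest.raises(Exception):
            residue_contact_profile(
                Trajectory(np.empty(0), np.empty((0, 3, 3)), np.empty((0, 3))),
                system)


class TestLipidsInContact:
    def test_hand_enumerated_counts(self):
        system = make_system(["POPE"] * 5)
        # 2 lipids within 0.7 of a protein bead, 3 far away
        frame = np.array([[1.0, 1.0, 1.0], [1.5, 1.0, 1.0],
                          [1.0, 1.5, 1.0], [1.5, 1.6, 1.0],
                          [4.0, 4.0, 4.0], [3.5, 0.2, 2.0], [2.9, 2.9, 2.9]])
        table, means = lipids_in_contact(make_traj([frame]), system)
        assert table["POPE"].iloc[0] == 2
        assert means["POPE"] == 2.0

    def test_multibead_headgroup_counts_once(self):
        # a CL with both headgroup beads inside delta counts as one lipid
        system = make_system([])
        names = list(system.name) + ["PO41", "PO42"]
        resids = list(system.residue_id) + [3, 3]
        resnames = list(system.residue_name) + ["CL", "CL"]
        species = list(system.species) + ["CL", "CL"]
        roles = list(system.roles) + [frozenset({"HEADGROUP"})] * 2
        mols = list(system.molecule_id) + [1, 1]
        system = MembraneSystem(np.arange(1, 5), np.array(names, dtype=object),
                                np.array(resids), np.array(resnames, dtype=object),
                                np.array(mols), np.array(species, dtype=object),
                                roles, np.full(4, 2.3), (5.0, 5.0, 5.0))
        frame = np.array([[1.0, 1.0, 1.0], [1.5, 1.0, 1.0],
                          [1.2, 1.3, 1.0], [1.3, 1.2, 1.0]])
        table, _ = lipids_in_contact(make_traj([frame]), system)
        assert table["CL"].iloc[0] == 1

    def test_empty_bilayer_counts_zero(self):
        system = make_system([])
        table, means = lipids_in_contact(
            make_traj([np.zeros((2, 3))]), system, species=("POPE",))
        assert table["POPE"].iloc[0] == 0


def test_resampling_nearest_frame():
    times = np.arange(0, 3.0, 0.1)
    idx = resample_indices(times, 0.3)
    np.testing.assert_allclose(times[idx] % 0.3, 0, atol=1e-9)
    # native interval equal to requested -> identity
    times = np.arange(0, 3.0, 0.3)
    assert np.array_equal(resample_indices(times, 0.3), np.arange(len(times)))
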