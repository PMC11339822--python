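import numpy as np
import pandas as pd
import pytest

from bmcpore.solvent import (
    ContactParams,
    SASAParams,
    monomer_average,
    residence_times,
    sasa_per_residue,
    segment_monomers,
    split_by_monomer,
    water_contacts,
)
from bmcpore.structure_io import Structure, Trajectory
from bmcpore.synthetic_data import (
    WaterTrackSpec,
    expected_residence_events,
    make_water_trajectory,
    random_walk_tracks,
)
from conftest import make_atom, min_image_dist_27, residence_state_machine


def _water(resid, pos, serial):
    """A 3-site water at pos (O) with hydrogens offset by ~1 A."""
    out = []
    for i, (name, elem, off) in enumerate(
        [("OH2", "O", (0, 0, 0)), ("H1", "H", (0.96, 0, 0)), ("H2", "H", (0, 0.96, 0))]
    ):
        out.append(
            make_atom(
                serial=serial + i, name=name, element=elem, resname="TIP3",
                resid=resid, chain="W", position=np.add(pos, off),
                vdw=1.52 if elem == "O" else 1.2,
            )
        )
    return out


def _traj(topology, frames, box=40.0, dt=1.0):
    frames = np.asarray(frames, dtype=float)
    return Trajectory(
        topology=topology,
        coords=frames,
        boxes=np.full((len(frames), 3), box),
        times=dt * np.arange(len(frames)),
    )


# --------------------------------------------------------------------------
# SASA
# --------------------------------------------------------------------------


class TestSASA:
    def test_isolated_sphere_closed_form(self):
        s = Structure([make_atom(vdw=1.9)])
        area = sasa_per_residue(s, "all")["value"][0]
        exact = 4 * np.pi * (1.9 + 1.4) ** 2
        assert area == pytest.approx(exact, rel=0.02)

    def test_two_distant_atoms_additive(self):
        s = Structure(
            [make_atom(serial=1, resid=1, vdw=1.9),
             make_atom(serial=2, resid=2, vdw=1.9, position=(100, 0, 0))]
        )
        table = sasa_per_residue(s, "all")
        exact = 4 * np.pi * (3.3) ** 2
        np.testing.assert_allclose(table["value"], exact, rtol=0.02)

    @pytest.mark.parametrize("d", [2.0, 4.0, 6.0])
    def test_two_sphere_overlap_matches_cap_formula(self, d):
        """Each sphere loses a spherical cap cut by the radical plane."""
        r = 1.9 + 1.4  # equal inflated radii
        s = Structure(
            [make_atom(serial=1, resid=1, vdw=1.9),
             make_atom(serial=2, resid=2, vdw=1.9, position=(d, 0, 0))]
        )
        table = sasa_per_residue(s, "all")
        cap_h = r - d / 2.0
        exact = 4 * np.pi * r**2 - 2 * np.pi * r * cap_h
        np.testing.assert_allclose(table["value"], exact, rtol=0.02)

    def test_partition_sums_to_total(self, random_structure):
        table = sasa_per_residue(random_structure, "protein")
        total_table = sasa_per_residue(
            random_structure.subset(np.flatnonzero(~random_structure.is_water)), "all"
        )
        assert table["value"].sum() == pytest.approx(
            total_table["value"].sum(), abs=1e-6
        )

    def test_water_excluded_as_surface_and_occluder(self):
        protein = make_atom(vdw=1.9)
        atoms = [protein] + _water(1, (2.0, 0, 0), serial=2)
        s = Structure(atoms)
        table = sasa_per_residue(s, "all")
        assert list(table["resname"]) == ["ALA"]
        exact = 4 * np.pi * (3.3) ** 2
        assert table["value"][0] == pytest.approx(exact, rel=0.02)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SASAParams(probe_radius=0.0)
        with pytest.raises(ValueError):
            SASAParams(n_sphere_points=8)


# --------------------------------------------------------------------------
# Water contacts
# --------------------------------------------------------------------------


class TestWaterContacts:
    def _system(self, water_positions, box=40.0, n_frames=3):
        atoms = [make_atom()]  # probe residue at origin
        serial = 2
        for wi, pos in enumerate(water_positions):
            atoms += _water(wi + 1, pos, serial)
            serial += 3
        top = Structure(atoms)
        return _traj(top, [top.coords] * n_frames, box=box)

    def test_three_fixed_waters(self):
        traj = self._system([(3, 0, 0), (0, 3, 0), (0, 0, 3)])
        table = water_contacts(traj, "resname ALA")
        assert table["value"][0] == pytest.approx(3.0)

    def test_no_water_in_cutoff(self):
        traj = self._system([(20, 0, 0)])
        table = water_contacts(traj, "resname ALA")
        assert table["value"][0] == 0.0

    def test_contact_through_periodic_image(self):
        # water at x = 35.2 in a 40 A box is 4.8 A from the origin via the image
        traj = self._system([(35.2, 0, 0)], box=40.0)
        d27 = min_image_dist_27((0, 0, 0), (35.2, 0, 0), (40, 40, 40))
        assert d27 == pytest.approx(4.8)
        table = water_contacts(traj, "resname ALA")
        assert table["value"][0] == pytest.approx(1.0)

    def test_invariant_to_rigid_box_translation(self):
        traj = self._system([(3, 0, 0), (35.2, 0, 0), (18, 5, -2)])
        shifted = Trajectory(
            topology=traj.topology,
            coords=traj.coords + np.array([13.7, -8.2, 101.0]),
            boxes=traj.boxes,
            times=traj.times,
        )
        a = water_contacts(traj, "resname ALA")["value"]
        b = water_contacts(shifted, "resname ALA")["value"]
        np.testing.assert_allclose(a, b)

    def test_cumulative_mode_counts_distinct_waters(self):
        atoms = [make_atom()]
        atoms += _water(1, (3, 0, 0), serial=2)
        atoms += _water(2, (20, 0, 0), serial=5)
        top = Structure(atoms)
        frames = [top.coords.copy(), top.coords.copy()]
        frames[1][4:7] = frames[1][4:7] - np.array([16.0, 0, 0])  # water 2 moves in
        traj = _traj(top, frames)
        mean = water_contacts(traj, "resname ALA")["value"][0]
        distinct = water_contacts(traj, "resname ALA", cumulative=True)["value"][0]
        assert mean == pytest.approx(1.5)
        assert distinct == 2.0

    def test_empty_mask_rejected(self):
        traj = self._system([(3, 0, 0)])
        with pytest.raises(ValueError, match="mask"):
            water_contacts(traj, "resname ALA", mask=np.array([], dtype=int))


# --------------------------------------------------------------------------
# Residence times
# --------------------------------------------------------------------------


class TestResidenceTimes:
    def test_scripted_five_ns_event(self):
        track = np.concatenate([np.full(50, 3.0), np.full(30, 20.0)])
        traj, truth = make_water_trajectory(WaterTrackSpec(tracks=[track], dt=0.1))
        events, table = residence_times(traj, "resname GLY")
        assert len(events) == 1
        assert events[0].duration_ns == pytest.approx(5.0)
        assert table["value"][0] == pytest.approx(5.0)

    def test_between_threshold_oscillation_single_event(self):
        track = np.concatenate([[4.9], np.tile([6.0, 7.5], 40)[:79], np.full(20, 9.0)])
        traj, _ = make_water_trajectory(WaterTrackSpec(tracks=[track], dt=0.1))
        events, _ = residence_times(traj, "resname GLY")
        assert len(events) == 1
        assert (events[0].start, events[0].end) == (0, 79)

    def test_matches_independent_state_machine_on_random_walks(self):
        spec = random_walk_tracks(20, 200, dt=0.1, seed=11)
        traj, _ = make_water_trajectory(spec)
        events, _ = residence_times(traj, "resname GLY")
        got = {}
        for e in events:
            got.setdefault(e.water[1], []).append(
                (e.start, e.end, e.duration_ns, e.censored)
            )
        for wi, track in enumerate(spec.tracks):
            expected = residence_state_machine(track, 5.0, 8.0, 0.1)
            assert got.get(wi + 1, []) == expected

    def test_monotone_in_release_cutoff(self):
        spec = random_walk_tracks(10, 150, dt=0.1, seed=13)
        traj, _ = make_water_trajectory(spec)
        ev8, _ = residence_times(traj, "resname GLY", ContactParams(5.0, 8.0))
        ev10, _ = residence_times(traj, "resname GLY", ContactParams(5.0, 10.0))
        # per (water, start) the duration never decreases with a wider release
        starts8 = {(e.water, e.start): e.duration_ns for e in ev8}
        total8 = sum(e.duration_ns for e in ev8)
        total10_matched = sum(
            e.duration_ns for e in ev10 if (e.water, e.start) in starts8
        )
        for e in ev10:
            key = (e.water, e.start)
            if key in starts8:
                assert e.duration_ns >= starts8[key] - 1e-12

    def test_censored_flagged_at_final_frame(self):
        track = np.full(30, 2.0)
        traj, _ = make_water_trajectory(WaterTrackSpec(tracks=[track], dt=0.1))
        events, _ = residence_times(traj, "resname GLY")
        assert len(events) == 1 and events[0].censored


# --------------------------------------------------------------------------
# Segmentation and monomer averaging
# --------------------------------------------------------------------------


def _assembly():
    atoms = []
    serial = 1
    # trimer chain T at origin
    for i in range(3):
        atoms.append(
            make_atom(serial=serial, resid=i + 1, chain="T", position=(i * 2.0, 0, 0))
        )
        serial += 1
    # chain A abuts the trimer at 3 A, chain B is 30 A away
    for chain, offset in (("A", 3.0), ("B", 30.0)):
        for i in range(3):
            atoms.append(
                make_atom(
                    serial=serial, resid=i + 1, chain=chain,
                    position=(4.0 + offset + i, 0, 0),
                )
            )
            serial += 1
    return Structure(atoms)


class TestSegmentMonomers:
    def test_toy_classification(self):
        cm = segment_monomers(_assembly(), "chain T", contact_distance=5.0)
        assert cm == {"A": "buried-interface", "B": "exposed"}

    def test_tiny_cutoff_all_exposed(self):
        cm = segment_monomers(_assembly(), "chain T", contact_distance=0.1)
        assert set(cm.values()) == {"exposed"}

    def test_matches_all_pairs_oracle(self):
        asm = _assembly()
        for cutoff in (1.0, 3.5, 5.0, 28.0, 35.0):
            cm = segment_monomers(asm, "chain T", contact_distance=cutoff)
            trimer = asm.coords[np.flatnonzero(asm.chains == "T")]
            for chain in ("A", "B"):
                pts = asm.coords[np.flatnonzero(asm.chains == chain)]
                dmin = np.min(
                    np.linalg.norm(pts[:, None] - trimer[None, :], axis=2)
                )
                expected = "buried-interface" if dmin <= cutoff else "exposed"
                assert cm[chain] == expected, (chain, cutoff)

    def test_empty_trimer_selection_rejected(self):
        with pytest.raises(ValueError, match="no atoms"):
            segment_monomers(_assembly(), "chain Z")


class TestMonomerAverage:
    def test_identical_tables(self):
        s = pd.Series([1.0, 2.0], index=["ALA1", "GLY2"])
        out = monomer_average({"A": s, "B": s.copy()})
        np.testing.assert_allclose(out["mean"], [1.0, 2.0])
        np.testing.assert_allclose(out["sem"], 0.0)
        assert (out["n_monomers"] == 2).all()

    def test_two_monomer_sem_hand_computed(self):
        a = pd.Series([2.0], index=["ALA1"])
        b = pd.Series([4.0], index=["ALA1"])
        out = monomer_average({"A": a, "B": b})
        assert out["mean"][0] == pytest.approx(3.0)
        # sd = sqrt(((2-3)^2 + (4-3)^2)/1) = sqrt(2); sem = sqrt(2)/sqrt(2) = 1
        assert out["sem"][0] == pytest.approx(1.0)

    def test_class_filter_single_monomer(self):
        a = pd.Series([2.0], index=["ALA1"])
        b = pd.Series([4.0], index=["ALA1"])
        cm = {"A": "exposed", "B": "buried-interface"}
        out = monomer_average({"A": a, "B": b}, cm, "exposed")
        assert out["mean"][0] == 2.0 and out["sem"][0] == 0.0

    def test_empty_class_rejected(self):
        a = pd.Series([2.0], index=["ALA1"])
        with pytest.raises(ValueError, match="class"):
            monomer_average({"A": a}, {"A": "exposed"}, "buried-interface")

    def test_mismatched_residues_rejected(self):
        a = pd.Series([2.0], index=["ALA1"])
        b = pd.Series([4.0], index=["GLY9"])
        with pytest.raises(ValueError, match="different residue"):
            monomer_average({"A": a, "B": b})

    def test_split_by_monomer_roundtrip(self):
        df = pd.DataFrame(
            dict(chain=["A", "A", "B", "B"], resid=[1, 2, 1, 2],
                 resname=["ALA", "GLY", "ALA", "GLY"], value=[1.0, 2.0, 3.0, 4.0])
        )
        split = split_by_monomer(df)
        assert list(split) == ["A", "B"]
        assert list(split["A"].index) == ["ALA1", "GLY2"]
        np.testing.assert_allclose(split["B"].to_numpy(), [3.0, 4.0])
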