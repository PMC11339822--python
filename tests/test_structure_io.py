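import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bmcpore.structure_io import (
    PDBParseError,
    RadiusTable,
    Selection,
    SelectionError,
    Structure,
    Trajectory,
    read_structure,
    read_trajectory,
    select,
    write_dcd,
    write_structure,
    write_trajectory,
)
from conftest import brute_force_filter, make_atom

import functools


@functools.lru_cache(maxsize=1)
def _algebra_structure():
    rng = np.random.default_rng(7)
    atoms = []
    serial = 1
    for chain in "AB":
        for resid in range(1, 13):
            for name in ("N", "CA", "C"):
                atoms.append(
                    make_atom(
                        serial=serial, name=name, element=name[0], resname="GLY",
                        resid=resid, chain=chain, position=rng.normal(size=3) * 10,
                    )
                )
                serial += 1
    for w in range(1, 4):
        for name, elem in (("OH2", "O"), ("H1", "H"), ("H2", "H")):
            atoms.append(
                make_atom(
                    serial=serial, name=name, element=elem, resname="TIP3",
                    resid=w, chain="W", position=rng.normal(size=3) * 10,
                )
            )
            serial += 1
    return Structure(atoms)


PDB_TWO_ATOMS = (
    "ATOM      1  CA  ALA A   7       0.000   0.000   0.000  1.00  0.00           C\n"
    "ATOM      2  O   ALA A   7       1.000   0.000   0.000  1.00  0.00           O\n"
    "END\n"
)


class TestReadStructure:
    def test_identity_parse(self):
        s = read_structure(PDB_TWO_ATOMS)
        assert s.n_atoms == 2
        assert list(s.names) == ["CA", "O"]
        np.testing.assert_array_equal(s.coords[0], [0, 0, 0])
        np.testing.assert_array_equal(s.coords[1], [1, 0, 0])
        assert ("A", 7, "ALA") in s.residues

    def test_truncated_coordinate_is_parse_error(self):
        bad = "ATOM      1  CA  ALA A   7       0.000   0.0"
        with pytest.raises(PDBParseError, match="line 1"):
            read_structure(bad)

    def test_garbled_coordinate_names_line(self):
        bad = PDB_TWO_ATOMS.replace("   1.000", "   x.000")
        with pytest.raises(PDBParseError, match="line 2"):
            read_structure(bad)

    def test_unresolvable_radius_names_atom(self):
        with pytest.raises(PDBParseError, match="CA"):
            read_structure(PDB_TWO_ATOMS, radii=RadiusTable(name="empty"))

    def test_extra_models_warn_and_are_ignored(self):
        body = PDB_TWO_ATOMS.replace("END\n", "")
        text = f"MODEL 1\n{body}ENDMDL\nMODEL 2\n{body}ENDMDL\nEND\n"
        with pytest.warns(UserWarning, match="models"):
            s = read_structure(text)
        assert s.n_atoms == 2

    def test_altloc_b_dropped(self):
        # mark the second atom altloc 'B' (column 17)
        lines = PDB_TWO_ATOMS.splitlines()
        line = lines[1]
        lines[1] = line[:16] + "B" + line[17:]
        s = read_structure("\n".join(lines))
        assert s.n_atoms == 1 and s.names[0] == "CA"

    def test_hetatm_water_accepted(self):
        text = (
            "HETATM    1  OH2 TIP3W   1       2.000   0.000   0.000  1.00  0.00           O\n"
        )
        s = read_structure(text)
        assert s.is_water.all()


class TestRoundTrip:
    def test_structure_roundtrip_preserves_order_names_coords(self, random_structure):
        text = write_structure(random_structure)
        back = read_structure(text)
        assert list(back.names) == list(random_structure.names)
        assert list(back.resids) == list(random_structure.resids)
        assert list(back.chains) == list(random_structure.chains)
        np.testing.assert_allclose(back.coords, random_structure.coords, atol=5e-4)

    def test_trajectory_roundtrip(self, random_structure):
        rng = np.random.default_rng(0)
        coords = random_structure.coords[None] + rng.normal(
            size=(3, random_structure.n_atoms, 3)
        )
        traj = Trajectory(
            topology=random_structure,
            coords=coords,
            boxes=np.full((3, 3), 50.0),
            times=np.arange(3.0),
        )
        text = write_trajectory(traj)
        back = read_trajectory(random_structure, text)
        assert back.n_frames == 3
        np.testing.assert_allclose(back.coords, coords, atol=5e-4)
        np.testing.assert_allclose(back.boxes, 50.0)

    def test_mdanalysis_agrees_with_our_parser(self, tmp_path, random_structure):
        """Cross-check the fixed-column writer/reader against MDAnalysis."""
        import MDAnalysis as mda

        path = tmp_path / "s.pdb"
        write_structure(random_structure, path)
        u = mda.Universe(str(path))
        np.testing.assert_allclose(
            u.atoms.positions.astype(float), random_structure.coords, atol=5e-4
        )
        assert list(u.atoms.names) == list(random_structure.names)

    def test_dcd_roundtrip(self, tmp_path, random_structure):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(4, random_structure.n_atoms, 3)) * 5 + 25
        traj = Trajectory(
            topology=random_structure,
            coords=coords,
            boxes=np.full((4, 3), 50.0),
            times=np.arange(4.0),
        )
        path = tmp_path / "t.dcd"
        write_dcd(traj, path)
        back = read_trajectory(random_structure, path)
        assert back.n_frames == 4
        np.testing.assert_allclose(back.coords, coords, atol=1e-4)


class TestReadTrajectory:
    def test_three_model_pdb(self, two_atom_structure):
        frames = []
        for m in range(3):
            frames.append(f"MODEL {m + 1}")
            frames.append(
                f"ATOM      1  CA  ALA A   1    {m:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C"
            )
            frames.append(
                f"ATOM      2  O   ALA A   1    {m + 1.0:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           O"
            )
            frames.append("ENDMDL")
        text = "\n".join(frames)
        top = Structure(
            [make_atom(serial=1, name="CA"), make_atom(serial=2, name="O", element="O")]
        )
        traj = read_trajectory(top, text, box=[30, 30, 30])
        assert traj.n_frames == 3
        np.testing.assert_allclose(traj.coords[:, 0, 0], [0, 1, 2])

    def test_atom_count_mismatch_reports_frame(self, two_atom_structure):
        text = (
            "MODEL 1\n"
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
        )
        with pytest.raises(ValueError, match="frame 0"):
            read_trajectory(two_atom_structure, text, box=[30, 30, 30])

    def test_missing_box_is_error(self, two_atom_structure):
        text = write_trajectory(
            Trajectory(
                topology=two_atom_structure,
                coords=two_atom_structure.coords[None],
                boxes=np.full((1, 3), 9.0),
                times=np.zeros(1),
            )
        )
        text = "\n".join(l for l in text.splitlines() if not l.startswith("CRYST1"))
        with pytest.raises(ValueError, match="box"):
            read_trajectory(two_atom_structure, text)


class TestSelection:
    def test_name_ca(self, two_atom_structure):
        idx = select(two_atom_structure, "name CA")
        assert idx.tolist() == [0]

    def test_water_selects_all_water_atoms(self, random_structure):
        idx = select(random_structure, "water")
        expected = brute_force_filter(random_structure, lambda a: a.resname == "TIP3")
        np.testing.assert_array_equal(idx, expected)
        assert len(idx) == 9

    def test_chain_and_resid_range_matches_brute_force(self, random_structure):
        idx = select(random_structure, "chain A and resid 5 to 10")
        expected = brute_force_filter(
            random_structure, lambda a: a.chain == "A" and 5 <= a.resid <= 10
        )
        np.testing.assert_array_equal(idx, expected)

    def test_not_and_parentheses(self, random_structure):
        idx = select(random_structure, "not (water or chain B)")
        expected = brute_force_filter(
            random_structure, lambda a: a.resname != "TIP3" and a.chain != "B"
        )
        np.testing.assert_array_equal(idx, expected)

    def test_unknown_keyword_is_error(self, two_atom_structure):
        with pytest.raises(SelectionError, match="cuttoff"):
            select(two_atom_structure, "cuttoff 5")

    def test_idempotent_and_sorted(self, random_structure):
        sel = Selection("resid 3 5 3 or resid 5")
        idx = sel.evaluate(random_structure)
        assert np.all(np.diff(idx) > 0)
        np.testing.assert_array_equal(idx, sel.evaluate(random_structure))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        lhs=st.sampled_from(["name CA", "resid 2 to 6", "chain A", "water"]),
        rhs=st.sampled_from(["name N C", "resid 4 to 9", "chain B", "element O"]),
    )
    def test_set_algebra(self, lhs, rhs):
        """'or' is set union and 'and' is set intersection of the operands."""
        structure = _algebra_structure()
        a = set(select(structure, lhs).tolist())
        b = set(select(structure, rhs).tolist())
        union = set(select(structure, f"({lhs}) or ({rhs})").tolist())
        inter = set(select(structure, f"({lhs}) and ({rhs})").tolist())
        assert union == a | b
        assert inter == a & b


class TestRadiusTable:
    def test_from_text_and_lookup(self):
        table = RadiusTable.from_text("C 1.8\nOH2 1.6\n# comment\n", name="t")
        assert table.lookup("CB", "C") == 1.8
        assert table.lookup("OH2", "O") == 1.6  # atom name beats element

    def test_out_of_range_radius_rejected(self):
        with pytest.raises(ValueError, match="range"):
            RadiusTable(name="bad", by_element={"C": 3.5})

    def test_bondi_resolves_biological_elements(self):
        t = RadiusTable.bondi()
        for elem in "CNOSH":
            assert 0.5 < t.lookup("X", elem) < 3.0
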