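import numpy as np
import pytest

from domdyn.structure_io import (
    AtomRecord,
    DomainSpec,
    EmptySelectionError,
    Frame,
    StructureParseError,
    Topology,
    Trajectory,
    read_structure,
    read_trajectory,
    residue_sequence,
    select_domain,
    write_trajectory,
)

from conftest import make_ca_topology, make_trajectory


def _atom_line(serial, name, resname, chain, resnum, x, y, z,
               altloc=" ", occ=1.0, record="ATOM  ", element=" C"):
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (f"{record}{serial:>5d} {name_field}{altloc}{resname:<3s} {chain}"
            f"{resnum:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00"
            f"          {element}\n")


def write_pdb(path, lines):
    path.write_text("".join(lines))
    return path


class TestReadStructure:
    def test_unit_conversion(self, tmp_path):
        # CA at (10, 0, 0) A -> (1.0, 0, 0) nm
        p = write_pdb(tmp_path / "one.pdb",
                      [_atom_line(1, "CA", "GLY", "A", 1, 10.0, 0.0, 0.0)])
        top, frame = read_structure(p)
        assert top.n_atoms == 1
        np.testing.assert_allclose(frame.coordinates[0], [1.0, 0.0, 0.0])

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        p = write_pdb(tmp_path / "alt.pdb", [
            _atom_line(1, "CA", "GLY", "A", 1, 1.0, 0.0, 0.0, altloc="A", occ=0.6),
            _atom_line(2, "CA", "GLY", "A", 1, 2.0, 0.0, 0.0, altloc="B", occ=0.4),
        ])
        top, frame = read_structure(p)
        assert top.n_atoms == 1
        np.testing.assert_allclose(frame.coordinates[0], [0.1, 0.0, 0.0])

    def test_altloc_tie_keeps_first(self, tmp_path):
        p = write_pdb(tmp_path / "alt.pdb", [
            _atom_line(1, "CA", "GLY", "A", 1, 1.0, 0.0, 0.0, altloc="A", occ=0.5),
            _atom_line(2, "CA", "GLY", "A", 1, 2.0, 0.0, 0.0, altloc="B", occ=0.5),
        ])
        _, frame = read_structure(p)
        np.testing.assert_allclose(frame.coordinates[0], [0.1, 0.0, 0.0])

    def test_hetatm_water_excluded(self, tmp_path):
        p = write_pdb(tmp_path / "wat.pdb", [
            _atom_line(1, "CA", "GLY", "A", 1, 1.0, 0.0, 0.0),
            _atom_line(2, "O", "HOH", "A", 100, 5.0, 5.0, 5.0, record="HETATM",
                       element=" O"),
        ])
        top, _ = read_structure(p)
        assert top.n_atoms == 1

    def test_malformed_record_names_line(self, tmp_path):
        p = write_pdb(tmp_path / "bad.pdb", [
            _atom_line(1, "CA", "GLY", "A", 1, 1.0, 0.0, 0.0),
            "ATOM      2  CA  GLY A   2      xxxxxxx   0.000   0.000\n",
        ])
        with pytest.raises(StructureParseError, match="line 2"):
            read_structure(p)

    def test_empty_file_errors(self, tmp_path):
        p = write_pdb(tmp_path / "empty.pdb", ["REMARK nothing here\n"])
        with pytest.raises(StructureParseError):
            read_structure(p)


class TestSelectDomain:
    def test_single_interval(self):
        top = make_ca_topology(10)
        spec = DomainSpec("d", "A", ((2, 4),))
        idx = select_domain(top, spec)
        assert list(idx) == [1, 2, 3]

    def test_two_intervals(self):
        top = make_ca_topology(10)
        spec = DomainSpec("d", "A", ((1, 2), (9, 10)))
        idx = select_domain(top, spec)
        assert list(idx) == [0, 1, 8, 9]

    def test_empty_selection_errors(self):
        top = make_ca_topology(10)
        with pytest.raises(EmptySelectionError):
            select_domain(top, DomainSpec("d", "A", ((50, 60),)))

    def test_missing_chain_errors(self):
        top = make_ca_topology(10)
        with pytest.raises(EmptySelectionError, match="chain"):
            select_domain(top, DomainSpec("d", "Z", ((1, 5),)))

    def test_idempotent_and_order_stable(self):
        top = make_ca_topology(20)
        spec = DomainSpec("d", "A", ((3, 8),))
        i1 = select_domain(top, spec)
        i2 = select_domain(top, spec)
        assert list(i1) == list(i2) == sorted(i1)

    def test_union_of_disjoint_specs(self):
        top = make_ca_topology(20)
        a = select_domain(top, DomainSpec("a", "A", ((1, 5),)))
        b = select_domain(top, DomainSpec("b", "A", ((10, 15),)))
        u = select_domain(top, DomainSpec("u", "A", ((1, 5), (10, 15))))
        assert list(u) == list(a) + list(b)

    def test_missing_residue_skipped_with_warning(self, caplog):
        atoms = [AtomRecord("A", n, "GLY", "CA") for n in (1, 2, 4)]  # 3 missing
        top = Topology(tuple(atoms))
        with caplog.at_level("WARNING"):
            idx = select_domain(top, DomainSpec("d", "A", ((1, 4),)))
        assert len(idx) == 3
        assert any("skipped" in r.message for r in caplog.records)

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            DomainSpec("d", "A", ((1, 5), (4, 8)))


class TestTrajectoryIO:
    def test_multi_model_identical(self, tmp_path, rng):
        coords = rng.normal(size=(5, 3))
        traj = make_trajectory([coords, coords, coords])
        path = write_trajectory(traj, tmp_path / "t.pdb")
        back = read_trajectory(path, traj.topology)
        assert back.n_frames == 3
        for fr in back.frames:
            np.testing.assert_allclose(fr.coordinates, back.frames[0].coordinates)

    def test_round_trip_precision(self, tmp_path, rng):
        # 100 atoms, 10 frames; PDB stores 3 decimals in A -> 5e-5 nm bound
        frames = [rng.uniform(-5, 5, size=(100, 3)) for _ in range(10)]
        traj = make_trajectory(frames)
        path = write_trajectory(traj, tmp_path / "t.pdb")
        back = read_trajectory(path, traj.topology)
        diff = np.abs(back.coordinate_array() - traj.coordinate_array())
        assert diff.max() <= 5e-5

    def test_round_trip_preserves_metadata_and_times(self, tmp_path, rng):
        traj = make_trajectory([rng.normal(size=(4, 3)) for _ in range(3)])
        path = write_trajectory(traj, tmp_path / "t.pdb")
        back = read_trajectory(path, traj.topology)
        assert back.topology == traj.topology
        np.testing.assert_allclose(back.times, traj.times)

    def test_two_files_concatenate_in_order(self, tmp_path, rng):
        t1 = make_trajectory([rng.normal(size=(4, 3)) for _ in range(5)])
        t2 = make_trajectory([rng.normal(size=(4, 3)) for _ in range(5)],
                             dt=0.04)
        p1 = write_trajectory(t1, tmp_path / "a.pdb")
        # strip times from the second file so they get assigned sequentially
        text = p1.read_text()
        p2 = tmp_path / "b.pdb"
        p2.write_text("\n".join(
            ln for ln in write_trajectory(t2, tmp_path / "b_raw.pdb")
            .read_text().splitlines() if "TIME_NS" not in ln) + "\n")
        p1b = tmp_path / "a_notime.pdb"
        p1b.write_text("\n".join(
            ln for ln in text.splitlines() if "TIME_NS" not in ln) + "\n")
        back = read_trajectory([p1b, p2], t1.topology, dt=0.1)
        assert back.n_frames == 10
        np.testing.assert_allclose(back.times, 0.1 * np.arange(1, 11))

    def test_single_frame_single_model(self, tmp_path, rng):
        traj = make_trajectory([rng.normal(size=(3, 3))])
        path = write_trajectory(traj, tmp_path / "one.pdb")
        text = path.read_text()
        assert text.count("MODEL") == 1 + text.count("ENDMDL") - 1
        assert text.count("ENDMDL") == 1

    def test_atom_count_mismatch_names_frame(self, tmp_path, rng):
        traj = make_trajectory([rng.normal(size=(4, 3))])
        path = write_trajectory(traj, tmp_path / "t.pdb")
        wrong_top = make_ca_topology(5)
        with pytest.raises(ValueError, match="frame 0"):
            read_trajectory(path, wrong_top)

    def test_empty_frames_rejected(self):
        top = make_ca_topology(3)
        with pytest.raises(ValueError):
            Trajectory(top, ())


class TestExternalReader:
    def test_agrees_with_native_pdb_reader(self, tmp_path, rng):
        pytest.importorskip("MDAnalysis")
        from domdyn.structure_io import read_trajectory_external

        traj = make_trajectory([rng.uniform(-3, 3, size=(8, 3))
                                for _ in range(4)], dt=0.1)
        path = write_trajectory(traj, tmp_path / "t.pdb")
        native = read_trajectory(path, traj.topology)
        external = read_trajectory_external(path, path, dt=0.1)
        assert external.n_frames == native.n_frames
        # MDAnalysis stores float32 positions
        diff = np.abs(external.coordinate_array() - native.coordinate_array())
        assert diff.max() <= 1e-6
        assert [a.chain_id for a in external.topology.atoms] == \
            [a.chain_id for a in native.topology.atoms]


class TestInvariants:
    def test_times_strictly_increasing_enforced(self, rng):
        top = make_ca_topology(2)
        f1 = Frame(1.0, rng.normal(size=(2, 3)))
        f2 = Frame(0.5, rng.normal(size=(2, 3)))
        with pytest.raises(ValueError, match="increasing"):
            Trajectory(top, (f1, f2))

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            Frame(0.0, np.array([[np.nan, 0.0, 0.0]]))

    def test_residue_sequence(self):
        atoms = [AtomRecord("P", i + 1, rn, "CA")
                 for i, rn in enumerate(["GLU", "GLU", "TYR"])]
        assert residue_sequence(Topology(tuple(atoms)), "P") == \
            ["GLU", "GLU", "TYR"]
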