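import io
import textwrap

import numpy as np
import pandas as pd
import pytest

from hingescope import (
    RegionSet,
    StructureFrame,
    Trajectory,
    load_preset,
    read_pdb,
    read_trajectory,
    select_ca,
    write_pdb,
    write_timeseries,
)
from hingescope.errors import (
    EmptySelectionError,
    EmptyStructureError,
    PDBParseError,
)
from hingescope.structure_io import available_presets, read_timeseries

from conftest import make_frame

TWO_ATOM_PDB = textwrap.dedent(
    """\
    ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
    ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
    END
    """
)

TWO_MODEL_PDB = textwrap.dedent(
    """\
    MODEL        1
    ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
    ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
    ENDMDL
    MODEL        2
    ATOM      1  CA  ALA A   1       0.000   0.000   1.000  1.00  0.00           C
    ATOM      2  CA  ALA A   2       3.800   0.000   1.000  1.00  0.00           C
    ENDMDL
    END
    """
)

ALTLOC_PDB = textwrap.dedent(
    """\
    ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.60  0.00           C
    ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.40  0.00           C
    ATOM      3  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
    END
    """
)


class TestReadPDB:
    def test_two_atom_single_model(self):
        frame = read_pdb(io.StringIO(TWO_ATOM_PDB))
        assert isinstance(frame, StructureFrame)
        assert frame.n_atoms == 2
        np.testing.assert_allclose(
            frame.coords[0], [11.104, 6.134, -6.504], atol=1e-9
        )
        assert frame.atoms[1].atom_name == "CA"
        assert frame.atoms[0].element == "N"
        assert frame.atoms[0].residue_number == 1

    def test_multi_model_as_trajectory(self):
        traj = read_pdb(io.StringIO(TWO_MODEL_PDB), model_policy="all")
        assert isinstance(traj, Trajectory)
        assert traj.n_frames == 2
        assert traj.frames[1, 0, 2] == pytest.approx(1.0)

    def test_altloc_keeps_highest_occupancy(self):
        frame = read_pdb(io.StringIO(ALTLOC_PDB))
        # brute-force expectation: among duplicated (residue, name) records,
        # the occupancy-0.6 copy survives
        assert frame.n_atoms == 2
        res1 = [a for a in frame.atoms if a.residue_number == 1]
        assert len(res1) == 1
        assert res1[0].occupancy == pytest.approx(0.6)
        assert frame.coords[0, 0] == pytest.approx(1.0)

    def test_no_altloc_is_identity(self):
        frame = read_pdb(io.StringIO(TWO_ATOM_PDB))
        assert [a.altloc for a in frame.atoms] == ["", ""]
        assert frame.n_atoms == 2

    def test_zero_atoms_raises(self):
        with pytest.raises(EmptyStructureError):
            read_pdb(io.StringIO("HEADER    EMPTY\nEND\n"))

    def test_malformed_line_reports_line_number(self):
        bad = TWO_ATOM_PDB.replace("11.639", "xx.xxx")
        with pytest.raises(PDBParseError) as err:
            read_pdb(io.StringIO(bad))
        assert err.value.line_number == 2

    def test_hetatm_flagged(self):
        text = TWO_ATOM_PDB.replace(
            "END",
            "HETATM    3 ZN    ZN A 701      10.000  10.000  10.000  1.00  0.00          ZN\nEND",
        )
        frame = read_pdb(io.StringIO(text))
        assert frame.atoms[2].het is True
        assert frame.atoms[0].het is False

    def test_roundtrip_preserves_fields(self, tmp_path):
        frame = read_pdb(io.StringIO(TWO_ATOM_PDB))
        path = tmp_path / "out.pdb"
        write_pdb(frame, path)
        back = read_pdb(path)
        assert back.n_atoms == frame.n_atoms
        assert [a.atom_name for a in back.atoms] == [
            a.atom_name for a in frame.atoms
        ]
        assert [a.residue_number for a in back.atoms] == [
            a.residue_number for a in frame.atoms
        ]
        np.testing.assert_allclose(back.coords, frame.coords, atol=1e-3)

    def test_trajectory_roundtrip(self, tmp_path):
        traj = read_pdb(io.StringIO(TWO_MODEL_PDB), model_policy="all")
        path = tmp_path / "traj.pdb"
        write_pdb(traj, path)
        back = read_pdb(path, model_policy="all")
        np.testing.assert_allclose(back.frames, traj.frames, atol=1e-3)

    def test_topology_plus_coordinate_stream(self, tmp_path):
        topo = tmp_path / "topo.pdb"
        topo.write_text(TWO_ATOM_PDB)
        coords = tmp_path / "frames.txt"
        data = np.arange(18, dtype=float).reshape(6, 3)
        np.savetxt(coords, data)
        traj = read_trajectory(topo, coords, timestep=0.5)
        assert traj.n_frames == 3
        np.testing.assert_allclose(traj.times, [0.0, 0.5, 1.0])
        np.testing.assert_allclose(traj.frames[2, 1], data[5])


class TestSelectCA:
    def test_single_range(self, ca_ladder):
        sel = select_ca(ca_ladder, [[3, 5]], "A")
        assert len(sel) == 3
        assert [ca_ladder.atoms[i].residue_number for i in sel] == [3, 4, 5]

    def test_multiple_ranges(self, ca_ladder):
        sel = select_ca(ca_ladder, [[3, 5], [8, 8]], "A")
        assert len(sel) == 4

    def test_missing_residue_reported(self):
        frame = make_frame(
            [
                ("CA", "C", "ALA", r, "A", (3.8 * r, 0.0, 0.0))
                for r in (1, 2, 3, 5, 6)
            ]
        )
        with pytest.warns(UserWarning):
            sel = select_ca(frame, [[3, 5]], "A")
        assert len(sel) == 2
        assert sel.missing_residues == [4]

    def test_range_order_irrelevant(self, ca_ladder):
        a = select_ca(ca_ladder, [[3, 5], [8, 8]], "A")
        b = select_ca(ca_ladder, [[8, 8], [3, 5]], "A")
        assert list(a.indices) == list(b.indices)

    def test_empty_region_raises(self, ca_ladder):
        with pytest.raises(EmptySelectionError):
            select_ca(ca_ladder, [], "A")

    def test_no_match_raises(self, ca_ladder):
        with pytest.raises(EmptySelectionError):
            select_ca(ca_ladder, [[50, 60]], "A")

    def test_hetatm_calcium_excluded(self):
        frame = make_frame(
            [
                ("CA", "C", "ALA", 1, "A", (0.0, 0.0, 0.0)),
                ("CA", "Ca", "CA", 2, "A", (5.0, 0.0, 0.0), True),
            ]
        )
        sel = select_ca(frame, [[1, 2]], "A")
        assert list(sel.indices) == [0]
        assert sel.missing_residues == [2]


class TestRegionSet:
    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            RegionSet("A", [[1, 5], [4, 8]], [[20, 25]], [[1, 10]], [[20, 30]])

    def test_lip_must_lie_in_subdomain(self):
        with pytest.raises(ValueError, match="lip1"):
            RegionSet("A", [[1, 5]], [[20, 25]], [[6, 10]], [[20, 30]])

    def test_presets_load_and_validate(self):
        assert set(available_presets()) >= {"sace_cdomain", "ace2"}
        for name in ("sace_cdomain", "ace2"):
            regions = load_preset(name)
            assert regions.chain_id == "A"
            assert len(regions.lip1) == 4
            assert len(regions.lip2) == 3

    def test_yaml_roundtrip(self, tmp_path):
        regions = load_preset("sace_cdomain")
        path = tmp_path / "r.yaml"
        regions.to_yaml(path)
        back = RegionSet.from_yaml(path)
        assert back == regions


class TestTimeseries:
    def test_three_frames_four_lines(self, tmp_path):
        path = tmp_path / "d.csv"
        write_timeseries(
            [{"time_ns": t, "distance_A": 10.0 + t} for t in range(3)], path
        )
        assert len(path.read_text().splitlines()) == 4

    def test_empty_series_header_only(self, tmp_path):
        path = tmp_path / "d.csv"
        write_timeseries(pd.DataFrame(columns=["time_ns", "distance_A"]), path)
        lines = path.read_text().splitlines()
        assert lines == ["time_ns,distance_A"]

    def test_roundtrip_six_significant_digits(self, tmp_path, rng):
        path = tmp_path / "d.csv"
        table = pd.DataFrame(
            {
                "time_ns": np.arange(100) * 0.2,
                "distance_A": rng.uniform(8, 25, size=100),
            }
        )
        write_timeseries(table, path)
        back = read_timeseries(path)
        np.testing.assert_allclose(
            back["distance_A"], table["distance_A"], rtol=1e-5
        )
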