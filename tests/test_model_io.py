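"""Model/trajectory I/O, author-numbered selection, round trips."""

import warnings

import numpy as np
import pytest

from pentagate.model_io import (DomainScheme, FormatError, SelectionError,
                                StructureModel, Trajectory, load_scheme,
                                read_structure, read_trajectory, select,
                                write_structure, write_trajectory)
from pentagate.synth import PentamerSpec, build_pentamer, build_trajectory

THREE_ATOM_PDB = """\
ATOM      1  N   ALA A  10       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A  10       2.500   2.000   3.000  1.00  0.00           C
ATOM      3  CA  GLY A  11       4.000   2.500   3.500  1.00  0.00           C
END
"""


@pytest.fixture()
def three_atom_model(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(THREE_ATOM_PDB)
    return read_structure(p)


class TestReadStructure:
    def test_identity_parse_of_minimal_pdb(self, three_atom_model):
        m = three_atom_model
        assert m.n_atoms == 3
        assert list(m.chain_ids) == ["A", "A", "A"]
        assert list(m.res_seq) == [10, 10, 11]
        np.testing.assert_allclose(m.xyz[0], [1, 2, 3])
        assert not m.is_hetero.any()

    def test_pdb_and_mmcif_give_same_model(self, pentamer, tmp_path):
        write_structure(pentamer, tmp_path / "m.pdb")
        write_structure(pentamer, tmp_path / "m.cif")
        from_pdb = read_structure(tmp_path / "m.pdb")
        from_cif = read_structure(tmp_path / "m.cif")
        assert from_pdb.n_atoms == from_cif.n_atoms
        assert list(from_pdb.atom_name) == list(from_cif.atom_name)
        assert list(from_pdb.res_seq) == list(from_cif.res_seq)
        # both formats carry ≥1e-3 Å precision
        np.testing.assert_allclose(from_pdb.xyz, from_cif.xyz, atol=2e-3)

    def test_roundtrip_preserves_atoms_to_format_precision(self, pentamer, tmp_path):
        write_structure(pentamer, tmp_path / "m.pdb")
        back = read_structure(tmp_path / "m.pdb")
        assert back.n_atoms == pentamer.n_atoms
        assert list(back.atom_name) == list(pentamer.atom_name)
        assert (back.is_hetero == pentamer.is_hetero).all()
        np.testing.assert_allclose(back.xyz, pentamer.xyz, atol=1e-3)

    def test_hetero_cations_retained(self, pentamer, tmp_path):
        write_structure(pentamer, tmp_path / "m.pdb")
        back = read_structure(tmp_path / "m.pdb")
        ca = (np.char.upper(back.element.astype(str)) == "CA") & back.is_hetero
        assert ca.sum() == 20  # 4 sites x 5 chains

    def test_garbage_file_raises_format_error(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text("this is not a structure\n")
        with pytest.raises(FormatError):
            read_structure(bad)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_structure(tmp_path / "nope.pdb")


class TestSelect:
    def test_beta1_range_yields_one_ca_per_residue(self, pentamer):
        sel = select(pentamer, "A", (340, 345), "ca_only")
        assert len(sel) == 6
        assert sel.coverage == 1.0 and not sel.flagged

    def test_unbuilt_loop_returns_empty_flagged_selection(self, pentamer):
        # mirrors a disordered stretch absent from a deposited model
        with pytest.warns(UserWarning, match="coverage 0"):
            sel = select(pentamer, "A", (291, 296), "ca_only")
        assert len(sel) == 0 and sel.coverage == 0.0 and sel.flagged

    def test_heavy_filter_excludes_hydrogens(self):
        m = StructureModel(
            chain_ids=np.array(["A"] * 3), res_seq=np.array([1, 1, 1]),
            res_name=np.array(["ALA"] * 3), atom_name=np.array(["CA", "HA", "CB"]),
            element=np.array(["C", "H", "C"]), xyz=np.zeros((3, 3)),
            is_hetero=np.zeros(3, dtype=bool))
        sel = select(m, "A", (1, 1), "heavy")
        assert list(m.atom_name[sel.indices]) == ["CA", "CB"]

    def test_selection_invariant_to_record_order(self, pentamer, rng):
        perm = rng.permutation(pentamer.n_atoms)
        shuffled = StructureModel(
            chain_ids=pentamer.chain_ids[perm], res_seq=pentamer.res_seq[perm],
            res_name=pentamer.res_name[perm], atom_name=pentamer.atom_name[perm],
            element=pentamer.element[perm], xyz=pentamer.xyz[perm],
            is_hetero=pentamer.is_hetero[perm],
            assembly_chains=pentamer.assembly_chains)
        a = select(pentamer, "B", (328, 513), "ca_only")
        b = select(shuffled, "B", (328, 513), "ca_only")
        np.testing.assert_allclose(
            np.sort(pentamer.xyz[a.indices], axis=0),
            np.sort(shuffled.xyz[b.indices], axis=0), atol=0)

    def test_full_scheme_coverage_on_generator(self, pentamer, scheme):
        for role in ("ntd_track", "ecd_twist", "tmd_twist", "tmd_align",
                     "beta1", "beta10", "ntd1", "ntd2"):
            sel = select(pentamer, "C", scheme.range_for(role), "ca_only")
            assert sel.coverage == 1.0, role

    def test_unknown_chain_raises(self, pentamer):
        with pytest.raises(SelectionError):
            select(pentamer, "Z", (328, 513))


class TestTrajectoryIO:
    def test_single_frame_equals_topology(self, pentamer, tmp_path):
        write_structure(pentamer, tmp_path / "top.pdb")
        traj = Trajectory(topology=pentamer, frames=pentamer.xyz[None],
                          times=np.array([0.0]))
        write_trajectory(traj, tmp_path / "one.pdb")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            back = read_trajectory(tmp_path / "top.pdb", tmp_path / "one.pdb")
        assert back.n_frames == 1
        np.testing.assert_allclose(back.frames[0], pentamer.xyz, atol=1e-3)

    def test_ten_frame_roundtrip(self, default_spec, tmp_path):
        traj, _ = build_trajectory(default_spec, 10)
        write_structure(traj.topology, tmp_path / "top.pdb")
        write_trajectory(traj, tmp_path / "tr.pdb")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            back = read_trajectory(tmp_path / "top.pdb", tmp_path / "tr.pdb")
        assert back.n_frames == 10
        np.testing.assert_allclose(back.frames, traj.frames, atol=1e-3)

    def test_atom_count_mismatch_is_hard_error(self, pentamer, default_spec, tmp_path):
        traj, _ = build_trajectory(default_spec, 2)
        write_trajectory(traj, tmp_path / "tr.pdb")
        truncated = StructureModel(
            chain_ids=pentamer.chain_ids[:100], res_seq=pentamer.res_seq[:100],
            res_name=pentamer.res_name[:100], atom_name=pentamer.atom_name[:100],
            element=pentamer.element[:100], xyz=pentamer.xyz[:100],
            is_hetero=pentamer.is_hetero[:100])
        write_structure(truncated, tmp_path / "small.pdb")
        with pytest.raises(ValueError, match="100"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                read_trajectory(tmp_path / "small.pdb", tmp_path / "tr.pdb")

    def test_shuffled_times_rejected(self, pentamer):
        with pytest.raises(ValueError, match="increasing"):
            Trajectory(topology=pentamer,
                       frames=np.repeat(pentamer.xyz[None], 3, axis=0),
                       times=np.array([0.0, 2.0, 1.0]))


class TestDomainScheme:
    def test_defaults_match_convention(self):
        s = DomainScheme()
        assert s.tmd_align == (328, 639)
        assert s.ecd_twist == (328, 513)
        assert s.beta1 == (340, 345) and s.beta10 == (511, 515)

    def test_overlapping_beta_ranges_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            DomainScheme(beta1=(340, 512), beta10=(511, 515))

    def test_prime_outside_tmd_rejected(self):
        with pytest.raises(ValueError, match="prime"):
            DomainScheme(prime_map={"2'": 100})

    def test_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "scheme.yaml"
        p.write_text(
            "ntd1: [35, 115]\nntd2: [116, 195]\n"
            "prime_map:\n  \"2'\": 637\n")
        s = load_scheme(p)
        assert s.ntd1 == (35, 115)
        assert s.prime_map["2'"] == 637
        assert s.tmd_align == (328, 639)  # defaults kept
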