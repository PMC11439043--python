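"""Structure parsing, numbering transfer, channel distances, superposition."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from mitosel.simulate import toy_structure
from mitosel.structure import (
    ChannelAnnotation,
    ResidueMapping,
    Residue,
    StructureModel,
    StructureError,
    classify_proximity,
    map_residue_coordinates,
    min_channel_distance,
    project_channel,
    read_structure,
    superpose_rmsd,
    write_structure,
)


class TestReadStructure:
    def test_no_atom_records_is_an_error(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("HEADER    EMPTY\nEND\n")
        with pytest.raises(StructureError):
            read_structure(p)

    def test_synthetic_roundtrip_preserves_atoms(self, tmp_path):
        model, _, _ = toy_structure(3, seed=1)
        p = tmp_path / "toy.pdb"
        write_structure(model, p)
        back = read_structure(p)
        assert back.n_residues() == 3
        for num in (1, 2, 3):
            a, b = model.residue("A", num), back.residue("A", num)
            assert set(a.atoms) == set(b.atoms) == {"CA", "CB"}
            for name in a.atoms:
                assert np.allclose(a.atoms[name], b.atoms[name], atol=2e-3)

    def test_highest_occupancy_altloc_kept(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60  0.00           C\n"
            "ATOM      2  CA BALA A   1       9.000   9.000   9.000  0.40  0.00           C\n"
            "END\n"
        )
        model = read_structure(p)
        assert np.allclose(model.residue("A", 1).atoms["CA"], [0, 0, 0])

    def test_hydrogens_excluded(self, tmp_path):
        p = tmp_path / "h.pdb"
        p.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  H   ALA A   1       1.000   0.000   0.000  1.00  0.00           H\n"
            "END\n"
        )
        assert set(read_structure(p).residue("A", 1).atoms) == {"CA"}

    def test_malformed_coordinate_reports_line(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(
            "ATOM      1  CA  ALA A   1       0.000   xxx.000   0.000  1.00  0.00           C\n"
        )
        with pytest.raises(StructureError, match="line 1"):
            read_structure(p)


class TestResidueMapping:
    def test_identity(self):
        seq = "MKTAYIAKQR"
        assert map_residue_coordinates(seq, seq, 7) == 7

    def test_insertion_shifts_downstream_positions(self):
        a = "MKTAYIAKQRQISFVKSHFSRQ"
        b = a[:5] + "GG" + a[5:]
        assert map_residue_coordinates(a, b, 10) == 12
        assert map_residue_coordinates(a, b, 3) == 3

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            map_residue_coordinates("MKT", "MKT", 9)

    def test_composition_roundtrip(self):
        a = "MKTAYIAKQRQISFVKSHFSRQ"
        b = "MKTAIAKQRQWWISFVKSHF"
        m_ab = ResidueMapping.from_sequences(a, b)
        m_ba = ResidueMapping.from_sequences(b, a)
        for pos_a, pos_b in m_ab.pairs:
            assert m_ba.a2b.get(pos_b) == pos_a

    def test_mapping_validates_monotonicity(self):
        with pytest.raises(ValueError):
            ResidueMapping([(1, 2), (2, 1)])


class TestChannelDistance:
    def test_member_residue_is_at_zero(self):
        model, channels, _ = toy_structure(8, seed=2,
                                           channel_residues={"H": [3, 6]})
        d, nearest = min_channel_distance(model, ("A", 3), channels["H"])
        assert d == 0.0 and nearest == ("A", 3)

    def test_euclidean_identity(self):
        res = {
            1: Residue(1, "A", {"CA": np.zeros(3)}),
            2: Residue(2, "G", {"CA": np.array([3.0, 4.0, 0.0])}),
        }
        model = StructureModel({"A": list(res.values())})
        ch = ChannelAnnotation("H", [("A", 2)])
        d, _ = min_channel_distance(model, ("A", 1), ch)
        assert d == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, seed):
        model, channels, truth = toy_structure(
            12, geometry="coil", seed=seed, channel_residues={"H": [2, 7], "K": [11]}
        )
        for num in (1, 4, 9, 12):
            for name, ch in channels.items():
                d, _ = min_channel_distance(model, ("A", num), ch)
                assert d == pytest.approx(truth[num][name], abs=1e-9)

    def test_missing_member_listed(self):
        model, _, _ = toy_structure(4, seed=3)
        ch = ChannelAnnotation("H", [("A", 99)])
        with pytest.raises(KeyError, match="99"):
            min_channel_distance(model, ("A", 1), ch)


class TestProximity:
    @pytest.mark.parametrize(
        "dist,expected",
        [(3.9, "within4"), (4.0, "within4"), (4.1, "within13"),
         (12.9, "within13"), (13.0, "within13"), (13.1, "distal")],
    )
    def test_inclusive_thresholds(self, dist, expected):
        assert classify_proximity({"H": dist}).proximity_class == expected

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            classify_proximity({"H": -1.0})

    def test_minimum_over_pathways(self):
        rec = classify_proximity({"H": 20.0, "K": 3.0})
        assert rec.proximity_class == "within4"

    def test_template_frame_projection(self):
        mapping = ResidueMapping([(i, i + 2) for i in range(1, 10)])
        ch = ChannelAnnotation("H", [("A", 3), ("A", 8)], frame="template")
        proj = project_channel(ch, mapping)
        assert proj.members == [("A", 5), ("A", 10)] and proj.frame == "query"


class TestSuperposition:
    def test_identical_and_rigidly_moved(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(10, 3))
        assert superpose_rmsd(A, A) == pytest.approx(0.0, abs=1e-12)
        R = Rotation.from_euler("xyz", [0.3, -1.0, 2.2]).as_matrix()
        B = A @ R.T + np.array([5.0, -2.0, 7.0])
        assert superpose_rmsd(A, B) <= 1e-9

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(10, 3))
        B = A + rng.normal(scale=0.3, size=(10, 3))
        assert superpose_rmsd(A, B) == pytest.approx(superpose_rmsd(B, A), abs=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_rotation_search_oracle(self, seed):
        # independent oracle: minimize RMSD over Euler angles numerically
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(10, 3))
        B = A + rng.normal(scale=0.2, size=(10, 3))
        Ac, Bc = A - A.mean(0), B - B.mean(0)

        def rmsd_at(angles):
            R = Rotation.from_euler("xyz", angles).as_matrix()
            return float(np.sqrt(((Ac - Bc @ R.T) ** 2).sum() / len(A)))

        best = np.inf
        for g in np.ndindex(6, 6, 6):  # coarse grid then local refinement
            x0 = (np.array(g) / 6) * 2 * np.pi
            res = minimize(rmsd_at, x0, method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-12})
            best = min(best, res.fun)
        assert superpose_rmsd(B, A) == pytest.approx(best, abs=1e-3)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            superpose_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        with pytest.raises(ValueError):
            superpose_rmsd(line, line)
        with pytest.raises(ValueError):
            superpose_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))
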