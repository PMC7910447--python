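import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from accref.structures import (ProteinModel, Residue, cb_coords, gdt_ts,
                               kabsch_superpose, read_pdb, s_score, write_pdb)


class TestReadPdb:
    def test_parses_three_residues(self, tiny_pdb):
        model = read_pdb(tiny_pdb)
        assert len(model) == 3
        assert model.sequence == "AGS"
        assert model.residues[0].pdb_number == 1

    def test_gly_uses_ca_for_cb(self, tiny_pdb):
        model = read_pdb(tiny_pdb)
        cb = cb_coords(model)
        np.testing.assert_allclose(cb[1], model.residues[1].atoms["CA"])
        # non-GLY residues use their stored CB
        np.testing.assert_allclose(cb[0], model.residues[0].atoms["CB"])

    def test_altloc_highest_occupancy_wins(self, tiny_pdb):
        model = read_pdb(tiny_pdb)
        np.testing.assert_allclose(model.residues[2].atoms["CA"],
                                   [7.6, 3.9, 0.1], atol=1e-3)

    def test_residue_missing_backbone_dropped(self, tmp_path):
        # second residue lacks CA entirely
        src = tmp_path / "broken.pdb"
        lines = [
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N",
            "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C",
            "ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C",
            "ATOM      4  N   ALA A   2       3.332   1.536   0.000  1.00  0.00           N",
            "ATOM      5  C   ALA A   2       5.480   2.705   0.100  1.00  0.00           C",
            "ATOM      6  N   ALA A   3       6.150   3.850   0.050  1.00  0.00           N",
            "ATOM      7  CA  ALA A   3       7.600   3.900   0.100  1.00  0.00           C",
            "ATOM      8  C   ALA A   3       8.200   5.290   0.150  1.00  0.00           C",
            "END",
        ]
        src.write_text("\n".join(lines) + "\n")
        model = read_pdb(str(src))
        assert len(model) == 2

    def test_round_trip_preserves_coordinates(self, tiny_pdb, tmp_path):
        model = read_pdb(tiny_pdb)
        out = tmp_path / "out.pdb"
        write_pdb(model, str(out))
        back = read_pdb(str(out))
        for r1, r2 in zip(model.residues, back.residues):
            for name in r1.atoms:
                np.testing.assert_allclose(r1.atoms[name], r2.atoms[name],
                                           atol=1.5e-3)


class TestKabsch:
    def test_identical_sets(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        sup = kabsch_superpose(pts, pts)
        assert sup.rmsd < 1e-9
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_mirror_gives_proper_rotation(self):
        pts = np.random.default_rng(1).normal(size=(10, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        sup = kabsch_superpose(pts, mirrored)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)
        assert sup.rmsd > 0.1

    def test_recovers_random_rigid_transform(self, rigid_factory):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(20, 3))
        rot, trans = rigid_factory(rng)
        sup = kabsch_superpose(pts, pts @ rot.T + trans)
        assert sup.rmsd < 1e-6

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


def _brute_force_gdt(mob, tgt):
    """Independent GDT oracle: scipy superpositions over all seed windows."""
    n = len(mob)
    seeds = [list(range(n))]
    for w in (3, 5, 7):
        seeds += [list(range(s, s + w)) for s in range(n - w + 1)]
    best = {c: 0.0 for c in (1.0, 2.0, 4.0, 8.0)}
    for seed in seeds:
        for c in best:
            idx = list(seed)
            for _ in range(10):
                rot, _ = Rotation.align_vectors(
                    tgt[idx] - tgt[idx].mean(0), mob[idx] - mob[idx].mean(0))
                moved = (mob - mob[idx].mean(0)) @ rot.as_matrix().T + tgt[idx].mean(0)
                d = np.linalg.norm(moved - tgt, axis=1)
                new = list(np.flatnonzero(d <= c))
                best[c] = max(best[c], len(new) / n)
                if new == idx or len(new) < 3:
                    break
                idx = new
    return 100.0 * np.mean([best[c] for c in sorted(best)])


class TestGdtTs:
    def test_identical_is_100(self, native30):
        assert gdt_ts(native30, native30) == pytest.approx(100.0)

    def test_rigid_invariance(self, native30, rigid_factory):
        rot, trans = rigid_factory(np.random.default_rng(3))
        moved = native30.transformed(rot, trans)
        assert gdt_ts(moved, native30) == pytest.approx(100.0, abs=1e-6)

    def test_matches_brute_force_oracle(self, native30, decoys30):
        decoy = decoys30[3][0]
        ours = gdt_ts(decoy, native30)
        oracle = _brute_force_gdt(decoy.ca_coords(), native30.ca_coords())
        assert ours == pytest.approx(oracle, abs=1e-6)

    def test_length_mismatch_rejected(self, native30):
        short = ProteinModel("A", native30.residues[:10])
        with pytest.raises(ValueError):
            gdt_ts(short, native30)


class TestSScore:
    def test_identical_is_one(self, native30):
        assert s_score(native30, native30) == pytest.approx(1.0)

    def test_decreases_as_single_residue_deviates(self, native30):
        # displacing one CA further and further strictly lowers the score
        scores = []
        for shift in (1.0, 3.0, 8.0, 20.0):
            moved = native30.copy()
            moved.residues[15].atoms["CA"] = (
                native30.residues[15].atoms["CA"] + np.array([shift, 0, 0]))
            scores.append(s_score(moved, native30))
        assert all(a > b for a, b in zip(scores, scores[1:]))
        assert all(0.0 < s < 1.0 for s in scores)

    def test_limit_large_deviations(self, native30):
        far = native30.copy()
        rng = np.random.default_rng(5)
        for r in far.residues:
            shift = rng.normal(scale=80.0, size=3)
            for k in r.atoms:
                r.atoms[k] = r.atoms[k] + shift
        assert s_score(far, native30) < 0.1

    def test_formula_midpoint(self, pair_model_factory):
        # direct formula check: d_i = d0 = 5 gives exactly 0.5 per residue
        d = np.array([5.0, 5.0])
        assert float(np.mean(1 / (1 + (d / 5.0) ** 2))) == pytest.approx(0.5)
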