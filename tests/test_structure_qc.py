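import numpy as np
import pytest

from lipscreen import structure_qc, synthetic_data
from lipscreen.seqio import Residue, Structure
from lipscreen.structure_qc import RamachandranMap


@pytest.fixture(scope="module")
def rama_map():
    return RamachandranMap.default()


def helix(n=20, phi=-57.0, psi=-47.0, plan=None):
    structure, _ = synthetic_data.generate_helix_pdb(n, phi, psi, confidence_plan=plan)
    return structure


def transform(structure, rotation, translation):
    out = Structure()
    for res in structure.residues:
        out.residues.append(
            Residue(
                chain=res.chain, number=res.number, name=res.name,
                n=rotation @ res.n + translation,
                ca=rotation @ res.ca + translation,
                c=rotation @ res.c + translation,
                confidence=res.confidence,
            )
        )
    return out


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


class TestBackboneDihedrals:
    def test_build_measure_round_trip(self):
        dihedrals = structure_qc.backbone_dihedrals(helix(20))
        for rec in dihedrals[1:-1]:
            assert rec.phi == pytest.approx(-57.0, abs=1e-4)
            assert rec.psi == pytest.approx(-47.0, abs=1e-4)

    @pytest.mark.parametrize("phi,psi", [(-57.0, -47.0), (-120.0, 130.0), (60.0, 40.0)])
    def test_round_trip_various_angles(self, phi, psi):
        dihedrals = structure_qc.backbone_dihedrals(helix(10, phi, psi))
        interior = dihedrals[1:-1]
        assert all(d.phi == pytest.approx(phi, abs=1e-4) for d in interior)
        assert all(d.psi == pytest.approx(psi, abs=1e-4) for d in interior)

    def test_termini_undefined(self):
        dihedrals = structure_qc.backbone_dihedrals(helix(5))
        assert dihedrals[0].phi is None
        assert dihedrals[-1].psi is None

    def test_incomplete_residue_flagged(self):
        structure = helix(5)
        structure.residues[2].ca = None
        dihedrals = structure_qc.backbone_dihedrals(structure)
        assert dihedrals[2].phi is None and dihedrals[2].psi is None
        assert not dihedrals[2].complete
        # neighbours lose the angle that needs the broken residue
        assert dihedrals[1].psi is None
        assert dihedrals[3].phi is None

    def test_rigid_motion_invariance(self, rng):
        structure = helix(12, -100.0, 120.0)
        base = structure_qc.backbone_dihedrals(structure)
        for _ in range(5):
            moved = transform(structure, random_rotation(rng), rng.normal(size=3) * 50)
            got = structure_qc.backbone_dihedrals(moved)
            for a, b in zip(base, got):
                if a.phi is not None:
                    assert b.phi == pytest.approx(a.phi, abs=1e-6)
                if a.psi is not None:
                    assert b.psi == pytest.approx(a.psi, abs=1e-6)

    def test_mirror_negates_angles(self):
        structure = helix(10, -57.0, -47.0)
        mirror = Structure()
        flip = np.diag([1.0, 1.0, -1.0])
        for res in structure.residues:
            mirror.residues.append(
                Residue(chain=res.chain, number=res.number, name=res.name,
                        n=flip @ res.n, ca=flip @ res.ca, c=flip @ res.c,
                        confidence=res.confidence)
            )
        base = structure_qc.backbone_dihedrals(structure)
        got = structure_qc.backbone_dihedrals(mirror)
        for a, b in zip(base, got):
            if a.phi is not None:
                assert b.phi == pytest.approx(-a.phi, abs=1e-6)
            if a.psi is not None:
                assert b.psi == pytest.approx(-a.psi, abs=1e-6)

    def test_short_chain_all_undefined(self):
        structure = helix(3)
        structure.residues = structure.residues[:1]
        dihedrals = structure_qc.backbone_dihedrals(structure)
        assert dihedrals[0].phi is None and dihedrals[0].psi is None


class TestRamachandran:
    def test_all_helical_highly_favored(self, rama_map):
        dihedrals = structure_qc.backbone_dihedrals(helix(30))
        summary = structure_qc.ramachandran_classify(dihedrals, rama_map)
        assert summary.fractions["highly_favored"] == 1.0
        assert summary.counted == 28

    def test_fractions_sum_to_one(self, rng, rama_map):
        dihedrals = [
            structure_qc.DihedralRecord(i, float(rng.uniform(-180, 180)),
                                        float(rng.uniform(-180, 180)))
            for i in range(100)
        ]
        summary = structure_qc.ramachandran_classify(dihedrals, rama_map)
        assert sum(summary.fractions.values()) == pytest.approx(1.0)

    def test_planted_questionable_fraction(self, rama_map):
        # 8 of 95 counted residues planted in a questionable cell -> 8.4%
        good = [structure_qc.DihedralRecord(i, -57.0, -47.0) for i in range(87)]
        bad = [structure_qc.DihedralRecord(87 + i, 120.0, -90.0) for i in range(8)]
        assert rama_map.classify(120.0, -90.0) == "questionable"
        summary = structure_qc.ramachandran_classify(good + bad, rama_map)
        assert summary.counted == 95
        assert round(100 * summary.fractions["questionable"], 1) == 8.4

    def test_undefined_angles_not_counted(self, rama_map):
        dihedrals = [
            structure_qc.DihedralRecord(0, None, -47.0),
            structure_qc.DihedralRecord(1, -57.0, -47.0),
        ]
        summary = structure_qc.ramachandran_classify(dihedrals, rama_map)
        assert summary.counted == 1

    def test_trimming_low_confidence_reduces_questionable(self, rama_map):
        # low-confidence residues planted in questionable cells, as in models
        # whose disordered terminal strands carry the bad geometry
        n_good, n_bad = 40, 10
        dihedrals = [structure_qc.DihedralRecord(i, -57.0, -47.0) for i in range(n_good)]
        dihedrals += [structure_qc.DihedralRecord(n_good + i, 120.0, -90.0) for i in range(n_bad)]
        confidences = [90.0] * n_good + [30.0] * n_bad
        full = structure_qc.ramachandran_classify(dihedrals, rama_map)
        kept = [d for d, c in zip(dihedrals, confidences) if c >= 50]
        trimmed = structure_qc.ramachandran_classify(kept, rama_map)
        assert full.fractions["questionable"] > 0
        assert trimmed.fractions["questionable"] == 0.0

    def test_custom_map_loadable(self, tmp_path):
        path = tmp_path / "map.tsv"
        lines = ["phi_min\tpsi_min\tregion"]
        for p in range(-180, 180, 10):
            for s in range(-180, 180, 10):
                lines.append(f"{p}\t{s}\tfavored")
        path.write_text("\n".join(lines) + "\n")
        custom = RamachandranMap.load(path)
        assert custom.classify(12.0, -155.0) == "favored"

    def test_wrap_at_180(self, rama_map):
        assert rama_map.classify(180.0, 0.0) == rama_map.classify(-180.0, 0.0)


class TestPlddt:
    def test_mean(self):
        structure = helix(2 + 1, plan=[70.0, 90.0, 80.0])
        summary = structure_qc.plddt_summary(structure)
        assert summary.mean == pytest.approx(80.0)

    def test_all_very_confident(self):
        summary = structure_qc.plddt_summary(helix(5, plan=[95.0] * 5))
        assert summary.band_fractions[">90"] == 1.0

    def test_planted_band_counts(self):
        plan = [40.0] * 2 + [60.0] * 3 + [80.0] * 4 + [95.0] * 1
        summary = structure_qc.plddt_summary(helix(10, plan=plan))
        assert summary.band_fractions["<50"] == pytest.approx(0.2)
        assert summary.band_fractions["50-70"] == pytest.approx(0.3)
        assert summary.band_fractions["70-90"] == pytest.approx(0.4)
        assert summary.band_fractions[">90"] == pytest.approx(0.1)

    def test_band_fractions_sum_to_one(self, rng):
        plan = list(rng.uniform(0, 100, size=37))
        summary = structure_qc.plddt_summary(helix(37, plan=plan))
        assert sum(summary.band_fractions.values()) == pytest.approx(1.0)

    def test_out_of_range_named(self):
        structure = helix(4, plan=[90.0, 120.0, 90.0, 90.0])
        with pytest.raises(ValueError, match="residue 1"):
            structure_qc.plddt_summary(structure)


class TestRollingMean:
    def test_constant_series(self):
        out = structure_qc.rolling_mean([3.0] * 50, window=7)
        assert np.allclose(out, 3.0)

    def test_window_one_identity(self, rng):
        series = rng.normal(size=30)
        assert np.allclose(structure_qc.rolling_mean(series, 1), series)

    def test_linear_ramp_interior_unchanged(self):
        series = np.arange(100, dtype=float)
        out = structure_qc.rolling_mean(series, window=5)
        assert np.allclose(out[2:-2], series[2:-2])

    def test_output_length(self, rng):
        series = rng.normal(size=80)
        assert len(structure_qc.rolling_mean(series, 40)) == 80

    def test_window_too_large(self):
        with pytest.raises(ValueError):
            structure_qc.rolling_mean([1.0, 2.0], window=3)

    def test_edges_use_shrunken_windows(self):
        out = structure_qc.rolling_mean([0.0, 1.0, 2.0, 3.0], window=3)
        assert out[0] == pytest.approx(0.5)  # mean of first two
        assert out[-1] == pytest.approx(2.5)
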