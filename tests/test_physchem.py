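"""Descriptor-panel tests.

Independent oracles: Biopython's ProteinAnalysis for MW/GRAVY/instability
(same published constant tables, independent code path), scipy's Brent root
finder for the isoelectric point, and closed forms for homopolymers.
"""

import numpy as np
import pytest
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from hypothesis import given, strategies as st
from scipy.optimize import brentq

from lipscreen import physchem
from lipscreen.seqio import STANDARD_AA, ProteinRecord

from conftest import make_record

KD = {  # Kyte-Doolittle hydropathy, frozen for the homopolymer closed form
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def random_sequence(rng, n=None) -> str:
    n = n or int(rng.integers(10, 200))
    return "".join(rng.choice(list(STANDARD_AA), size=n))


class TestMolecularWeight:
    def test_glycine(self):
        assert physchem.molecular_weight("G") == pytest.approx(75.07, abs=0.01)

    def test_diglycine(self):
        assert physchem.molecular_weight("GG") == pytest.approx(132.12, abs=0.01)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            physchem.molecular_weight("")

    def test_additivity(self, rng):
        a, b = random_sequence(rng), random_sequence(rng)
        assert physchem.molecular_weight(a + b) == pytest.approx(
            physchem.molecular_weight(a) + physchem.molecular_weight(b) - 18.0153,
            abs=1e-6,
        )

    def test_against_biopython(self, rng):
        for _ in range(20):
            seq = random_sequence(rng)
            assert physchem.molecular_weight(seq) == pytest.approx(
                ProteinAnalysis(seq).molecular_weight(), abs=0.05
            )

    def test_strict_mode_rejects_ambiguity(self):
        with pytest.raises(physchem.AmbiguousResidueError):
            physchem.molecular_weight("GXG", mode="strict")


class TestChargeCounts:
    def test_dekr(self):
        assert physchem.charge_counts("DEKR") == (2, 2)

    def test_histidine_not_counted(self):
        assert physchem.charge_counts("HHHH") == (0, 0)

    def test_neutral(self):
        assert physchem.charge_counts("GGGG") == (0, 0)


class TestExtinction:
    def test_tryptophan(self):
        assert physchem.extinction_coefficient_280("W") == (5500, 5500)

    def test_tyrosines(self):
        assert physchem.extinction_coefficient_280("YY") == (2980, 2980)

    def test_cystine_pair(self):
        assert physchem.extinction_coefficient_280("CC") == (0, 125)

    def test_odd_cysteine_not_counted(self):
        assert physchem.extinction_coefficient_280("CCC") == (0, 125)


class TestIsoelectricPoint:
    def test_zero_net_charge_property(self, rng):
        for _ in range(20):
            seq = random_sequence(rng)
            pi = physchem.isoelectric_point(seq)
            assert abs(physchem.net_charge(seq, pi)) < 1e-2

    def test_acidic_homopolymer(self):
        # oracle: Brent root finder on the same charge model
        pi = physchem.isoelectric_point("DDDDDD")
        oracle = brentq(lambda ph: physchem.net_charge("DDDDDD", ph), 0, 14, xtol=1e-6)
        assert pi == pytest.approx(oracle, abs=2e-3)
        assert pi < 4.5

    def test_basic_homopolymer(self):
        pi = physchem.isoelectric_point("KKKKKK")
        oracle = brentq(lambda ph: physchem.net_charge("KKKKKK", ph), 0, 14, xtol=1e-6)
        assert pi == pytest.approx(oracle, abs=2e-3)
        assert pi > 9.5

    def test_appending_lysine_never_decreases_pi(self, rng):
        seq = random_sequence(rng, 50)
        assert physchem.isoelectric_point(seq + "K") >= physchem.isoelectric_point(seq) - 1e-3

    def test_appending_aspartate_never_increases_pi(self, rng):
        seq = random_sequence(rng, 50)
        assert physchem.isoelectric_point(seq + "D") <= physchem.isoelectric_point(seq) + 1e-3

    def test_in_open_interval(self, rng):
        for _ in range(10):
            pi = physchem.isoelectric_point(random_sequence(rng))
            assert 0 < pi < 14


class TestInstabilityIndex:
    def test_diglycine_from_table(self):
        # DIWV(G,G) = 13.34; II = (10/2) * 13.34 = 66.7
        value, label = physchem.instability_index("GG")
        assert value == pytest.approx(66.7, abs=1e-6)
        assert label == "unstable"

    def test_threshold_classification(self):
        value, label = physchem.instability_index("AAAA")
        assert (label == "unstable") == (value > 40)

    def test_against_biopython(self, rng):
        for _ in range(20):
            seq = random_sequence(rng)
            mine, _ = physchem.instability_index(seq)
            assert mine == pytest.approx(ProteinAnalysis(seq).instability_index(), abs=0.02)

    def test_length_one_errors(self):
        with pytest.raises(ValueError):
            physchem.instability_index("G")

    def test_depends_only_on_dipeptide_multiset(self):
        # ABAB and the dipeptide multiset {AB, BA, AB} give the same sum
        v1, _ = physchem.instability_index("GAGA")
        total = physchem._DIWV["G"]["A"] * 2 + physchem._DIWV["A"]["G"]
        assert v1 == pytest.approx(10 / 4 * total)


class TestAliphaticIndex:
    def test_all_alanine(self):
        value, flag = physchem.aliphatic_index("AAAA")
        assert value == pytest.approx(100.0)
        assert flag

    def test_all_valine(self):
        value, _ = physchem.aliphatic_index("VVVV")
        assert value == pytest.approx(290.0)

    def test_no_aliphatics(self):
        value, flag = physchem.aliphatic_index("GGGG")
        assert value == 0.0
        assert not flag

    def test_leucine_isoleucine_weight(self):
        value, _ = physchem.aliphatic_index("IL")
        assert value == pytest.approx(390.0)

    def test_permutation_invariant(self, rng):
        seq = random_sequence(rng)
        shuffled = "".join(rng.permutation(list(seq)))
        assert physchem.aliphatic_index(seq)[0] == pytest.approx(
            physchem.aliphatic_index(shuffled)[0]
        )


class TestGravy:
    @pytest.mark.parametrize("aa", sorted(STANDARD_AA))
    def test_homopolymer_closed_form(self, aa):
        assert physchem.gravy(aa * 5) == pytest.approx(KD[aa])

    def test_against_biopython(self, rng):
        for _ in range(20):
            seq = random_sequence(rng)
            assert physchem.gravy(seq) == pytest.approx(
                ProteinAnalysis(seq).gravy(), abs=1e-9
            )

    def test_lenient_mode_excludes_x(self):
        with pytest.warns(UserWarning):
            assert physchem.gravy("AXA") == pytest.approx(1.8)

    def test_range_bound(self, rng):
        for _ in range(10):
            assert -4.5 <= physchem.gravy(random_sequence(rng)) <= 4.5


class TestHalfLife:
    def test_methionine_mammalian(self):
        assert physchem.half_life_class("MAAA", "mammalian") == "30 h"

    def test_arginine_yeast(self):
        assert physchem.half_life_class("RAAA", "yeast") == "2 min"

    def test_organism_keyed(self):
        assert physchem.half_life_class("LAAA", "mammalian") != physchem.half_life_class(
            "LAAA", "bacterial"
        )

    def test_unknown_organism(self):
        with pytest.raises(ValueError):
            physchem.half_life_class("MAAA", "martian")


class TestProfile:
    def test_composition(self, rng):
        seq = random_sequence(rng)
        record = ProteinRecord(id="p1", sequence=seq)
        prof = physchem.profile(record)
        assert prof.molecular_weight == pytest.approx(physchem.molecular_weight(seq))
        assert prof.gravy == pytest.approx(physchem.gravy(seq))
        assert (prof.n_negative, prof.n_positive) == physchem.charge_counts(seq)
        assert prof.aliphatic_index == pytest.approx(physchem.aliphatic_index(seq)[0])
        assert prof.isoelectric_point == pytest.approx(
            physchem.isoelectric_point(seq), abs=1e-9
        )

    def test_length_one_instability_undefined(self):
        prof = physchem.profile(make_record("G"))
        assert prof.instability_index is None
        assert prof.instability_class == "undefined"

    def test_stable_iff_below_40(self, rng):
        for _ in range(10):
            prof = physchem.profile(make_record(random_sequence(rng)))
            assert (prof.instability_class == "stable") == (prof.instability_index < 40)

    def test_planted_unstable_fraction(self):
        # 75%-unstable panel: 3 poly-P (DIWV(P,P)=20.26 -> II 202.6) + 1 poly-A (II 10.7)
        panel = [make_record("PPPPPPPP", f"u{i}") for i in range(3)]
        panel.append(make_record("AAAAAAAA", "s0"))
        profiles = [physchem.profile(r) for r in panel]
        unstable = sum(p.instability_class == "unstable" for p in profiles)
        assert unstable / len(profiles) == 0.75

    def test_report_rounding(self):
        rows = physchem.profile_rows([physchem.profile(make_record("GHSLGAAKDE"))])
        row = rows[0]
        assert row["gravy"] == round(physchem.gravy("GHSLGAAKDE"), 3)
        assert row["pI"] == round(physchem.isoelectric_point("GHSLGAAKDE"), 2)


@given(st.text(alphabet=STANDARD_AA, min_size=2, max_size=60))
def test_descriptors_permutation_invariant_except_order_dependent(seq):
    reversed_seq = seq[::-1]
    assert physchem.gravy(seq) == pytest.approx(physchem.gravy(reversed_seq))
    assert physchem.molecular_weight(seq) == pytest.approx(
        physchem.molecular_weight(reversed_seq)
    )
    assert physchem.charge_counts(seq) == physchem.charge_counts(reversed_seq)
    assert physchem.aliphatic_index(seq)[0] == pytest.approx(
        physchem.aliphatic_index(reversed_seq)[0]
    )
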