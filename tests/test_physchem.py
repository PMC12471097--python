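import math

import pytest
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from hypothesis import given
from hypothesis import strategies as st

import ampdigest as ad
from ampdigest.physchem import (
    DipeptideInstabilityMatrix,
    boman_scale,
    kyte_doolittle_scale,
    pka_set,
)
from ampdigest.records import CANONICAL_RESIDUES

seqs = st.text(alphabet=sorted(CANONICAL_RESIDUES), min_size=2, max_size=30)


class TestScales:
    def test_hydropathy_scale_bounds(self):
        scale = kyte_doolittle_scale()
        assert len(scale) == 20
        assert all(-4.5 <= v <= 4.5 for v in scale.values())

    def test_boman_scale_covers_alphabet(self):
        scale = boman_scale()
        assert set(scale) == set(CANONICAL_RESIDUES)

    def test_pka_sets_differ_only_in_histidine(self):
        pi, charge = pka_set("pi"), pka_set("charge")
        assert pi.values["H"] == 6.5 and charge.values["H"] == 6.0
        assert {k: v for k, v in pi.values.items() if k != "H"} == {
            k: v for k, v in charge.values.items() if k != "H"
        }

    def test_unknown_pka_set_rejected(self):
        with pytest.raises(KeyError):
            pka_set("mystery")

    def test_instability_matrix_default_fill(self):
        m = DipeptideInstabilityMatrix({"A": {"R": 2.0}})
        assert m.weight("A", "R") == 2.0
        assert m.weight("G", "G") == 1.0


class TestGravy:
    @pytest.mark.parametrize(
        "seq, expected", [("AR", -1.35), ("G", -0.40), ("IL", 4.15), ("AA", 1.80)]
    )
    def test_known_values(self, seq, expected):
        assert round(ad.gravy(seq), 2) == expected

    @given(seqs)
    def test_permutation_invariant(self, seq):
        assert ad.gravy(seq) == pytest.approx(ad.gravy(seq[::-1]))

    @given(seqs)
    def test_matches_independent_reference_implementation(self, seq):
        assert ad.gravy(seq) == pytest.approx(ProteinAnalysis(seq).gravy())


class TestAliphaticIndex:
    @pytest.mark.parametrize(
        "seq, expected",
        [("IL", 390.00), ("GG", 0.00), ("VF", 145.00), ("AA", 100.00), ("PGL", 130.00)],
    )
    def test_known_values(self, seq, expected):
        assert round(ad.aliphatic_index(seq), 2) == expected


class TestBomanIndex:
    @pytest.mark.parametrize("seq, expected", [("IL", -4.92), ("ER", 10.865)])
    def test_known_values(self, seq, expected):
        assert ad.boman_index(seq) == pytest.approx(expected, abs=1e-9)

    def test_homopolymer_equals_scale_value(self):
        assert ad.boman_index("RR") == pytest.approx(boman_scale()["R"])

    @given(seqs)
    def test_permutation_invariant(self, seq):
        assert ad.boman_index(seq) == pytest.approx(ad.boman_index(seq[::-1]))


class TestNetChargeAndPI:
    def test_ar_charge_rounds_to_plus_one(self):
        assert round(ad.net_charge("AR", 7.0)) == 1

    def test_qh_charge_is_slightly_positive(self):
        assert round(ad.net_charge("QH", 7.0), 1) == 0.1

    def test_termini_only_peptide_is_near_neutral(self):
        assert abs(ad.net_charge("GG", 7.0)) < 0.05

    @pytest.mark.parametrize(
        "seq, expected", [("AR", 10.55), ("EK", 6.41), ("GL", 6.10)]
    )
    def test_known_isoelectric_points(self, seq, expected):
        assert round(ad.isoelectric_point(seq), 2) == expected

    def test_neutral_peptide_pi_is_terminal_midpoint(self):
        pkas = pka_set("pi")
        midpoint = (pkas.values["nterm"] + pkas.values["cterm"]) / 2
        assert ad.isoelectric_point("GL") == pytest.approx(midpoint, abs=1e-6)

    @given(seqs)
    def test_charge_strictly_decreasing_in_ph(self, seq):
        charges = [ad.net_charge(seq, ph) for ph in range(15)]
        assert all(a > b for a, b in zip(charges, charges[1:]))

    @given(seqs)
    def test_charge_vanishes_at_pi(self, seq):
        pi = ad.isoelectric_point(seq)
        assert abs(ad.net_charge(seq, pi, pka_set("pi"))) < 1e-4

    @given(seqs)
    def test_basic_residues_raise_pi_acidic_lower_it(self, seq):
        pi = ad.isoelectric_point(seq)
        assert ad.isoelectric_point(seq + "K") >= pi - 1e-9
        assert ad.isoelectric_point(seq + "R") >= pi - 1e-9
        assert ad.isoelectric_point(seq + "D") <= pi + 1e-9
        assert ad.isoelectric_point(seq + "E") <= pi + 1e-9


class TestInstabilityIndex:
    @pytest.mark.parametrize(
        "seq, expected", [("IL", 101.30), ("TF", 66.70), ("PGL", 6.67), ("PW", -9.40)]
    )
    def test_known_values(self, seq, expected):
        assert round(ad.instability_index(seq), 2) == expected

    def test_order_matters(self):
        assert ad.instability_index("TF") != ad.instability_index("FT")

    def test_single_residue_rejected(self):
        with pytest.raises(ValueError):
            ad.instability_index("G")

    @given(seqs)
    def test_matches_independent_reference_implementation(self, seq):
        assert ad.instability_index(seq) == pytest.approx(
            ProteinAnalysis(seq).instability_index(), abs=1e-6
        )


class TestSolubilityAndFlags:
    @pytest.mark.parametrize(
        "seq, expected", [("SK", "good"), ("CF", "poor"), ("DD", "good")]
    )
    def test_solubility_rule(self, seq, expected):
        assert ad.solubility_class(seq) == expected

    def test_flags_from_thresholds(self):
        flags = ad.classify_profile(boman=10.86, instability=5.0, aliphatic=0.0, length=2)
        assert flags["high_binding"] and not flags["unstable"]
        assert not flags["thermostable"] and flags["pept_transportable"]
        flags = ad.classify_profile(boman=-0.2, instability=66.7, aliphatic=195.0, length=4)
        assert not flags["high_binding"] and flags["unstable"]
        assert flags["thermostable"] and not flags["pept_transportable"]


class TestProfileAssembly:
    def test_aw_profile_matches_reference_row(self):
        row = ad.physchem_profile("AW").as_report_row()
        assert row == {
            "sequence": "AW",
            "boman": -2.07,
            "net_charge": 0.0,
            "pI": 6.10,
            "instability": 5.0,
            "aliphatic": 50.0,
            "gravy": 0.45,
            "solubility": "poor",
        }

    def test_boman_display_truncates_toward_zero(self):
        # mean of A and R is 6.555; the display convention truncates
        row = ad.physchem_profile("AR").as_report_row()
        assert row["boman"] == 6.55
        assert math.copysign(1, row["boman"]) == 1.0

    def test_er_profile_flags(self):
        p = ad.physchem_profile("ER")
        assert p.high_binding and not p.unstable and not p.thermostable
        assert p.pept_transportable

    def test_gl_is_thermostable(self):
        assert ad.physchem_profile("GL").thermostable
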