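"""Featurization unit and property tests.

Expected descriptor values asserted here were re-typed independently from the
published scale tables rather than read back from the bundled TSVs.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neodl.descriptors import FAMILY_SIZES, load_class_table, load_descriptor_table
from neodl.peptide_features import (
    FeatureVocabulary,
    PeptidePair,
    aa_class_flags,
    aggregate_patient,
    build_feature_vector,
    patient_feature_matrix,
    physchem_properties,
    residue_frequency_matrix,
    shannon_entropy,
    unit_descriptor,
    unit_molecular_weight,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
seq9 = st.text(alphabet=AA, min_size=9, max_size=9)


# ---------------------------------------------------------------------------
# descriptor tables
# ---------------------------------------------------------------------------

class TestDescriptorTables:
    def test_structure(self):
        table = load_descriptor_table()
        assert len(table.components) == 66
        assert sum(FAMILY_SIZES.values()) == 66
        mat = table.matrix()
        assert mat.shape == (20, 66)
        assert np.isfinite(mat).all()

    @pytest.mark.parametrize(
        "residue,component,expected",
        [
            # Kidera factors
            ("A", "KF1", -1.56), ("A", "KF10", -0.48), ("R", "KF4", 1.87),
            ("W", "KF2", 2.10), ("V", "KF3", 2.04), ("G", "KF8", 2.36),
            # Z-scales
            ("A", "Z1", 0.24), ("R", "Z1", 3.52), ("W", "Z2", 3.94),
            ("L", "Z1", -4.28), ("D", "Z1", 3.98),
            # VHSE
            ("A", "VHSE1", 0.15), ("P", "VHSE8", 3.56), ("R", "VHSE6", 1.47),
            ("G", "VHSE3", -2.63),
            # Cruciani
            ("D", "PP1", 1.00), ("W", "PP2", 1.00), ("K", "PP3", 1.00),
            ("A", "PP1", -0.96),
            # MS-WHIM
            ("W", "MSWHIM1", 1.00), ("R", "MSWHIM3", 1.00), ("D", "MSWHIM2", -1.00),
        ],
    )
    def test_published_reference_values(self, residue, component, expected):
        assert load_descriptor_table().lookup(residue, component) == pytest.approx(expected)

    def test_unknown_component_rejected(self):
        with pytest.raises(KeyError):
            load_descriptor_table().lookup("A", "KF11")

    def test_class_table_membership(self):
        classes = load_class_table()
        assert set(classes.index) == set(AA)
        assert classes.loc["A", ["Tiny", "Small", "Aliphatic", "NonPolar"]].all()
        assert classes.loc["A", ["Aromatic", "Polar", "Charged", "Basic", "Acidic"]].sum() == 0
        assert classes.loc["R", ["Polar", "Charged", "Basic"]].all()
        # aliphatic and aromatic are disjoint classes
        assert not (classes["Aliphatic"] & classes["Aromatic"]).any()


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

class TestEntropy:
    def test_homopolymer_is_zero(self):
        assert shannon_entropy("AAAAAAAAA") == 0.0

    def test_all_distinct_reaches_log2_9(self):
        assert shannon_entropy("ACDEFGHIK") == pytest.approx(math.log2(9))

    def test_two_symbol_mixture(self):
        # -(5/9)log2(5/9) - (4/9)log2(4/9)
        expected = -(5 / 9) * math.log2(5 / 9) - (4 / 9) * math.log2(4 / 9)
        assert shannon_entropy("AAAAACCCC") == pytest.approx(expected)
        assert expected == pytest.approx(0.9911, abs=1e-4)

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ValueError, match="non-standard"):
            shannon_entropy("AAAAAAAAX")

    @given(seq9)
    @settings(max_examples=50, deadline=None)
    def test_bounds(self, seq):
        h = shannon_entropy(seq)
        assert 0.0 <= h <= math.log2(9) + 1e-12
        assert (h == 0.0) == (len(set(seq)) == 1)


class TestUnits:
    def test_homo_dipeptide_equals_single(self):
        for comp in ("KF1", "VHSE6", "PP1"):
            assert unit_descriptor("AA", comp) == unit_descriptor("A", comp)

    def test_dipeptide_is_mean(self):
        v = unit_descriptor("AC", "Z1")
        single = (unit_descriptor("A", "Z1") + unit_descriptor("C", "Z1")) / 2
        assert v == pytest.approx(single)

    def test_molecular_weight_glycine(self):
        assert unit_molecular_weight("G") == pytest.approx(75.07, abs=0.01)
        assert unit_molecular_weight("GG") == pytest.approx(132.12, abs=0.01)

    @given(st.text(alphabet=AA, min_size=1, max_size=8), st.sampled_from(AA))
    @settings(max_examples=30, deadline=None)
    def test_appending_residue_increases_mass(self, s, extra):
        assert unit_molecular_weight(s + extra) > unit_molecular_weight(s)

    def test_class_flags(self):
        a = aa_class_flags("A")
        assert (a["Tiny"], a["Small"], a["Aliphatic"], a["NonPolar"]) == (1, 1, 1, 1)
        assert sum(a.values()) == 4
        r = aa_class_flags("R")
        assert (r["Polar"], r["Charged"], r["Basic"]) == (1, 1, 1)
        assert (r["Acidic"], r["Aliphatic"], r["Aromatic"]) == (0, 0, 0)


class TestPhyschem:
    def test_molecular_weight_matches_unit_mw(self):
        seq = "ACDEFGHIK"
        assert physchem_properties(seq)["MW"] == pytest.approx(unit_molecular_weight(seq))

    def test_charge_signs(self):
        assert physchem_properties("KKKKKKKKK")["charge_pH7"] > 0
        assert physchem_properties("DDDDDDDDD")["charge_pH7"] < 0

    def test_gravy_ordering(self):
        assert (physchem_properties("IIIIIIIII")["gravy"]
                > physchem_properties("RRRRRRRRR")["gravy"])

    def test_aliphatic_index_homopolymers(self):
        assert physchem_properties("IIIIIIIII")["aliphatic_index"] == pytest.approx(390.0)
        assert physchem_properties("DDDDDDDDD")["aliphatic_index"] == 0.0


# ---------------------------------------------------------------------------
# pair validation and full vectors
# ---------------------------------------------------------------------------

class TestPeptidePair:
    def test_rejects_multiple_differences(self):
        with pytest.raises(ValueError, match="differ exactly"):
            PeptidePair("P", "ACDEFGHIK", "ACDEFGHIW", 4, 100, 900)

    def test_rejects_wrong_length(self):
        with pytest.raises(ValueError, match="9-mer"):
            PeptidePair("P", "ACDEFGHI", "ACDQFGHI", 4, 100, 900)

    def test_rejects_nonpositive_ic50(self):
        with pytest.raises(ValueError, match="positive"):
            PeptidePair("P", "ACDEFGHIK", "ACDQFGHIK", 4, 0.0, 900)

    def test_rejects_nonstandard_residue(self):
        with pytest.raises(ValueError, match="non-standard"):
            PeptidePair("P", "ACDEFGHIX", "ACDQFGHIX", 4, 100, 900)


class TestVocabulary:
    def test_size_and_composition(self, vocab):
        # per role: 9*(66+9) + 8*67 + 7*67 + (66+8+9+1) + (75 + 5*67)
        per_role = 675 + 536 + 469 + 84 + 410
        assert per_role == 2174
        assert len(vocab) == 2 * per_role
        assert len(set(vocab.names)) == len(vocab)

    def test_reported_feature_names_resolvable(self, vocab):
        # the 12 protective dipeptide/tripeptide features + named positional hits
        for name in [
            "MT.peptide.3-4.MW", "MT.peptide.3-4.KF2", "MT.peptide.3-4.Z2",
            "MT.peptide.3-4.T1", "MT.peptide.3-4.ProtFP2", "MT.peptide.3-4.VHSE2",
            "MT.peptide.3-4.VHSE3", "MT.peptide.3-4.VHSE6", "MT.peptide.3-4.ST1",
            "MT.peptide.2-4.BLOSUM2", "MT.peptide.2-4.MSWHIM1",
            "MT.peptide.4.Aliphatic", "MT.peptide.3-4.ST4", "MT.peptide.4.VHSE6",
            "MT.peptide.4.PP1", "MT.peptide.5.Basic", "MT.peptide.7.VHSE6",
        ]:
            assert name in vocab

    def test_order_is_stable(self, vocab):
        assert FeatureVocabulary().names == vocab.names


class TestBuildFeatureVector:
    def test_deterministic(self, pair, vocab):
        v1 = build_feature_vector(pair, vocab)
        v2 = build_feature_vector(pair, vocab)
        np.testing.assert_array_equal(v1.values, v2.values)
        np.testing.assert_array_equal(v1.mask, v2.mask)

    def test_identical_sequences_give_symmetric_roles(self, vocab):
        forced = PeptidePair.unchecked("P", "ACDEFGHIK", "ACDEFGHIK", 4, 100.0, 900.0)
        v = build_feature_vector(forced, vocab)
        half = len(vocab) // 2
        np.testing.assert_allclose(v.values[:half], v.values[half:], rtol=0, atol=0)

    def test_position_locality(self, vocab):
        """A difference at position 9 leaves positions 1..8 untouched."""
        p = PeptidePair("P", "ACDEFGHIK", "ACDEFGHIW", 9, 100.0, 900.0)
        v = build_feature_vector(p, vocab)
        for pos in range(1, 9):
            for comp in ("KF1", "VHSE6", "PP1", "Tiny"):
                mt = v[f"MT.peptide.{pos}.{comp}"]
                wt = v[f"WT.peptide.{pos}.{comp}"]
                assert mt == wt

    def test_mutation_anchored_values_and_masks(self, vocab):
        p = PeptidePair("P", "WCDEFGHIK", "ACDEFGHIK", 1, 100.0, 900.0)
        v = build_feature_vector(p, vocab)
        # position-1 mutation: no left dipeptide / left+center tripeptides
        assert np.isnan(v["MT.mutsite.di.left.KF1"])
        assert np.isnan(v["MT.mutsite.tri.left.KF1"])
        assert np.isnan(v["MT.mutsite.tri.center.KF1"])
        assert v["MT.mutsite.pos.KF1"] == v["MT.peptide.1.KF1"]
        assert v["MT.mutsite.di.right.MW"] == v["MT.peptide.1-2.MW"]

    def test_named_unit_against_manual_mean(self, pair, vocab):
        v = build_feature_vector(pair, vocab)
        manual = unit_descriptor(pair.mt_seq[2:4], "ST4")
        assert v["MT.peptide.3-4.ST4"] == pytest.approx(manual, abs=1e-12)
        assert v["MT.peptide.3-4.MW"] == pytest.approx(
            unit_molecular_weight(pair.mt_seq[2:4]), abs=1e-9)


class TestAggregation:
    def test_single_vector_is_identity(self, pair, vocab):
        v = build_feature_vector(pair, vocab)
        agg = aggregate_patient([v])
        np.testing.assert_allclose(agg.values[~agg.mask], v.values[~v.mask])

    def test_mean_and_permutation_invariance(self, vocab):
        p1 = PeptidePair("P", "ACDEFGHIK", "ACDQFGHIK", 4, 100.0, 900.0)
        p2 = PeptidePair("P", "WCDEFGHIK", "ACDEFGHIK", 1, 100.0, 900.0)
        v1, v2 = build_feature_vector(p1, vocab), build_feature_vector(p2, vocab)
        a12 = aggregate_patient([v1, v2])
        a21 = aggregate_patient([v2, v1])
        np.testing.assert_array_equal(a12.values[~a12.mask], a21.values[~a21.mask])
        both = ~(v1.mask | v2.mask)
        np.testing.assert_allclose(
            a12.values[both], (v1.values[both] + v2.values[both]) / 2, atol=1e-12)
        # entry masked in one input only -> value of the other input
        only_v1 = v2.mask & ~v1.mask
        if only_v1.any():
            np.testing.assert_allclose(a12.values[only_v1], v1.values[only_v1])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_patient([])


class TestResidueFrequencyMatrix:
    def test_point_mass_for_constant_input(self):
        pairs = [PeptidePair(f"P{i}", "ACDEFGHIK", "ACDQFGHIK", 4, 100.0, 900.0)
                 for i in range(5)]
        freq = residue_frequency_matrix(pairs, role="MT")
        assert freq.shape == (9, 20)
        for pos, aa in enumerate("ACDEFGHIK", start=1):
            assert freq.loc[pos, aa] == 1.0
        np.testing.assert_allclose(freq.sum(axis=1), 1.0)

    def test_uniform_residues_within_binomial_bound(self):
        rng = np.random.default_rng(0)
        pairs = []
        n = 10_000
        for i in range(n):
            wt = "".join(rng.choice(list(AA), size=9))
            pos = int(rng.integers(1, 10))
            mt = list(wt)
            while mt[pos - 1] == wt[pos - 1]:
                mt[pos - 1] = rng.choice(list(AA))
            pairs.append(PeptidePair(f"P{i}", "".join(mt), wt, pos, 100.0, 900.0))
        freq = residue_frequency_matrix(pairs, role="WT")
        sigma = np.sqrt(0.05 * 0.95 / n)
        assert (np.abs(freq.to_numpy() - 0.05) < 3.1 * sigma + 1e-12).mean() > 0.97
        np.testing.assert_allclose(freq.sum(axis=1), 1.0)


def test_patient_matrix_shape_and_order(small_sim, vocab):
    from neodl.cohort_io import call_neoantigens

    called = call_neoantigens(small_sim.cohort.pairs)
    mat = patient_feature_matrix(called, vocab)
    assert mat.shape[1] == len(vocab)
    assert set(mat.index) <= {c.patient_id for c in small_sim.cohort.clinical}
    assert isinstance(mat, pd.DataFrame)
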