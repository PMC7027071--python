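"""Alignment filtering, 7-class entropy and conserved-residue selection."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conscluster.conservation import (
    CLASS_OF,
    MAX_ENTROPY,
    SEVEN_CLASSES,
    ConservationProfile,
    Msa,
    chain_mean_entropy,
    column_entropy,
    filter_msa,
    read_fasta_msa,
    select_conserved,
    sequence_identity,
)
from conscluster.structure import RegionLabel, RegionTable, SasaRecord

from _oracles import tally_entropy, twenty_type_entropy


def make_msa(rows, ids=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    ids[0] = "query"
    return Msa(query_id="query", ids=ids, rows=rows)


class TestClassMap:
    def test_partition_of_twenty_amino_acids(self):
        all_aas = "".join(SEVEN_CLASSES.values())
        assert len(all_aas) == 20 and len(set(all_aas)) == 20
        assert SEVEN_CLASSES[1] == "TGS"
        assert SEVEN_CLASSES[2] == "VAICML"
        assert SEVEN_CLASSES[6] == "H"
        assert SEVEN_CLASSES[7] == "KR"


class TestFilterMsa:
    def test_identical_homolog_retained(self):
        msa = make_msa(["ACDEF", "ACDEF"])
        res = filter_msa(msa)
        assert len(res.msa.ids) == 2
        assert sequence_identity(msa.query_row, msa.rows[1]) == 1.0

    def test_six_missing_residues_removed(self):
        q = "ACDEFGHIKLMNPQRSTVWY"
        hom = q[:14] + "------"  # identity 0.7 but 6 gaps at query columns
        res = filter_msa(make_msa([q, hom]))
        assert res.n_removed_missing == 1
        assert len(res.msa.ids) == 1

    def test_five_missing_residues_kept(self):
        q = "ACDEFGHIKL"
        hom = "ACDEF-----"  # exactly 5 gaps: at the limit, kept
        res = filter_msa(make_msa([q, hom]))
        assert res.n_removed_missing == 0

    def test_identity_threshold_against_hand_computation(self):
        # query of length 20; homologs straddling 45% identity
        q = "ACDEFGHIKLMNPQRSTVWY"
        homs = {}
        for n_match in (6, 8, 9, 10, 14, 20):
            row = q[:n_match] + "".join(
                "G" if c != "G" else "A" for c in q[n_match:])
            homs[n_match] = row
        msa = make_msa([q] + list(homs.values()),
                       ids=["query"] + [f"m{k}" for k in homs])
        res = filter_msa(msa)
        kept = set(res.msa.ids) - {"query"}
        # oracle: identity = n_match / 20, keep when >= 0.45
        assert kept == {f"m{k}" for k in homs if k / 20 >= 0.45}

    def test_usable_requires_more_than_five_homologs(self):
        q = "ACDEFGHIKL"
        assert not filter_msa(make_msa([q] * 6)).usable   # exactly 5 homologs
        assert filter_msa(make_msa([q] * 7)).usable       # 6 homologs

    def test_missing_query_raises(self):
        with pytest.raises(ValueError, match="query"):
            Msa(query_id="nope", ids=["a"], rows=["ACD"])


class TestColumnEntropy:
    def test_single_class_column_is_zero(self):
        msa = make_msa(["L"] * 8)
        assert column_entropy(msa, 0) == 0.0

    def test_seven_equiprobable_classes_hit_the_maximum(self):
        msa = make_msa(["T", "V", "Q", "E", "W", "H", "K"])
        s = column_entropy(msa, 0)
        assert s == pytest.approx(MAX_ENTROPY)
        assert round(s, 2) == 2.81

    def test_two_equiprobable_classes_give_one_bit(self):
        msa = make_msa(["T", "T", "K", "K"])
        assert column_entropy(msa, 0) == pytest.approx(1.0)

    def test_mixed_counts_match_direct_tally(self):
        col = ["T", "G", "V", "E"]  # class counts {1:2, 2:1, 4:1}
        msa = make_msa(col)
        expected = -(0.5 * math.log2(0.5) + 2 * 0.25 * math.log2(0.25))
        assert column_entropy(msa, 0) == pytest.approx(expected)
        assert column_entropy(msa, 0) == pytest.approx(tally_entropy(col, CLASS_OF))

    def test_gaps_and_unknowns_excluded(self):
        msa = make_msa(["L", "-", "X", "L"])
        assert column_entropy(msa, 0) == 0.0

    def test_empty_column_is_undefined_not_zero(self):
        msa = make_msa(["-", "-", "X"])
        assert math.isnan(column_entropy(msa, 0))

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.sampled_from(sorted(CLASS_OF) + ["-", "X"]),
                    min_size=1, max_size=40))
    def test_bounds_and_coarsening(self, column):
        msa = make_msa(["".join(column)] * 1)  # one row per symbol instead:
        msa = make_msa(list(column))
        s7 = column_entropy(msa, 0)
        if math.isnan(s7):
            assert all(c in "-X" for c in column)
            return
        assert -1e-12 <= s7 <= MAX_ENTROPY + 1e-12
        # grouping into 7 classes can only lose information
        s20 = twenty_type_entropy([c for c in column if c in CLASS_OF])
        assert s7 <= s20 + 1e-12


def region_table_for(ids, labels):
    recs = {rid: SasaRecord(rid, "ALA", 10.0, 10.0, 10.0, 0.0) for rid in ids}
    return RegionTable(records=recs, labels=dict(zip(ids, labels)))


class TestSelection:
    def test_chain_mean_entropy_examples(self):
        prof = ConservationProfile(np.array([0.0, 0.0]), [("A", 1, ""), ("A", 2, "")])
        assert chain_mean_entropy(prof) == 0.0
        prof = ConservationProfile(np.array([0.5, 1.5]), [("A", 1, ""), ("A", 2, "")])
        assert chain_mean_entropy(prof) == pytest.approx(1.0)

    def test_empty_profile_raises(self):
        with pytest.raises(ValueError):
            chain_mean_entropy(ConservationProfile(np.array([math.nan]), [("A", 1, "")]))

    def test_three_residue_interface_hand_oracle(self):
        ids = [("A", i, "") for i in (1, 2, 3)]
        prof = ConservationProfile(np.array([0.2, 0.6, 1.0]), ids)
        table = region_table_for(ids, [RegionLabel.INTERFACE] * 3)
        sel = select_conserved(prof, table)
        assert sel.mean_entropy_int == pytest.approx(0.6)
        assert sel.c1 == [("A", 1, "")]       # 0.2 < 0.6
        assert sel.c2 == [("A", 1, "")]       # 0.2 < 0.3
        assert sel.c3 == []

    def test_all_equal_entropies_give_empty_c1(self):
        ids = [("A", i, "") for i in (1, 2)]
        prof = ConservationProfile(np.array([0.7, 0.7]), ids)
        sel = select_conserved(prof, region_table_for(ids, [RegionLabel.INTERFACE] * 2))
        assert sel.c1 == [] and sel.c2 == [] and sel.c3 == []

    def test_zero_entropy_residue_lands_in_c3(self):
        ids = [("A", i, "") for i in (1, 2, 3)]
        prof = ConservationProfile(np.array([0.0, 1.0, 2.0]), ids)
        sel = select_conserved(prof, region_table_for(ids, [RegionLabel.INTERFACE] * 3))
        assert sel.c3 == [("A", 1, "")]

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=2.807), min_size=2, max_size=25))
    def test_criteria_are_nested(self, entropies):
        ids = [("A", i, "") for i in range(len(entropies))]
        prof = ConservationProfile(np.array(entropies), ids)
        sel = select_conserved(prof, region_table_for(
            ids, [RegionLabel.INTERFACE] * len(ids)))
        assert set(sel.c3) <= set(sel.c2) <= set(sel.c1) <= set(ids)

    def test_empty_interface_raises(self):
        ids = [("A", 1, "")]
        prof = ConservationProfile(np.array([0.5]), ids)
        with pytest.raises(ValueError, match="[Ee]mpty interface"):
            select_conserved(prof, region_table_for(ids, [RegionLabel.SURFACE]))


class TestSyntheticRecovery:
    def test_planted_conservation_recovered(self, clustered_complex, clustered_msa):
        # conserved columns: s == 0 exactly; variable columns: near log2(7)
        syn = clustered_complex
        msa = clustered_msa
        for i in range(msa.n_columns):
            s = column_entropy(msa, i)
            if i in syn.conserved_positions:
                assert s == 0.0
            else:
                assert s > 1.5  # far from conserved at 50 rows

    def test_variable_columns_near_max_at_500_rows(self):
        from conscluster.synthetic import generate_msa
        seq = "ACDEFGHIKLMNPQRSTVWY" * 2
        text = generate_msa(seq, set(range(20)), 500, seed=3)
        msa = read_fasta_msa(io.StringIO(text))
        variable = [column_entropy(msa, i) for i in range(20, 40)]
        assert np.all(np.abs(np.array(variable) - MAX_ENTROPY) < 0.1)

    def test_generator_mean_entropy_matches_expectation(self, clustered_complex,
                                                        clustered_msa):
        # dichotomous planting: <s> ~ (1 - f_cons) * E[s_variable]
        syn = clustered_complex
        msa = clustered_msa
        svals = np.array([column_entropy(msa, i) for i in range(msa.n_columns)])
        f = len(syn.conserved_positions) / len(syn.sequence)
        expected = (1 - f) * np.mean(svals[svals > 0])
        assert np.mean(svals) == pytest.approx(expected, abs=0.05)
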