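"""Specificity-residue extraction, Hamming comparison, and summaries."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spo0scan import (
    extract_signature,
    group_distance_summary,
    hamming,
    position_frequency_matrix,
)
from spo0scan.model import SpecificitySignature
from spo0scan.references import (
    construct_expected_signatures,
    default_hiska_profile,
    default_rec_profile,
    construct_panel,
)


def sig(residues: str, role: str = "HISKA_LIKE", gene_id: str = "x") -> SpecificitySignature:
    return SpecificitySignature(gene_id=gene_id, role=role, residues=residues)


class TestHamming:
    def test_one_position_difference(self):
        assert hamming("TAGFQL", "TTGFQL") == 1

    def test_identity(self):
        assert hamming("QGILEVD", "QGILEVD") == 0

    def test_three_position_difference(self):
        assert hamming("NELLEYD", "NEFIDYD") == 3

    def test_gap_mismatches_residue_but_matches_gap(self):
        assert hamming("TA-FQL", "TAGFQL") == 1
        assert hamming("TA-FQL", "TA-FQL") == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hamming("TAGFQL", "QGILEVD")

    def test_role_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hamming(sig("TAGFQL"), sig("QGILEVD"[:6] + "D", role="REC"))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.tuples(
            st.text("ACDEFG", min_size=6, max_size=6),
            st.text("ACDEFG", min_size=6, max_size=6),
            st.text("ACDEFG", min_size=6, max_size=6),
        )
    )
    def test_metric_properties(self, abc):
        a, b, c = abc
        assert hamming(a, a) == 0
        assert hamming(a, b) == hamming(b, a)
        assert hamming(a, c) <= hamming(a, b) + hamming(b, c)


class TestExtraction:
    def test_planted_residues_recovered_from_spliced_sequence(self):
        profile = default_hiska_profile()
        ref = profile.references[0]
        anchor0 = ref.anchor_pos - 1
        seq = list(ref.sequence)
        for off, aa in zip(profile.offsets, "WYWYWY"):
            seq[anchor0 + off] = aa
        out = extract_signature("".join(seq), profile, "spliced")
        assert out.residues == "WYWYWY"
        assert out.anchor_position == ref.anchor_pos

    def test_reference_self_extraction_anchors_on_itself(self):
        profile = default_rec_profile()
        ref = profile.references[0]
        out = extract_signature(ref.sequence, profile, ref.name)
        assert out.anchor_position == ref.anchor_pos
        expected = "".join(ref.sequence[ref.anchor_pos - 1 + o] for o in profile.offsets)
        assert out.residues == expected

    def test_unalignable_sequence_gets_no_anchor_flag(self):
        profile = default_hiska_profile()
        out = extract_signature("PG" * 40, profile, "junk")
        assert out.residues == "-" * 6
        assert "no_anchor" in out.flags

    def test_signature_lengths_match_roles(self):
        cons = construct_panel()
        k = extract_signature(cons["BsKinA"], default_hiska_profile(), "BsKinA")
        r = extract_signature(cons["Bs0F"], default_rec_profile(), "Bs0F")
        assert len(k.residues) == 6
        assert len(r.residues) == 7

    def test_calibration_reproduces_all_published_construct_signatures(self):
        """Anchored extraction recovers the residue strings planted in the
        synthetic stand-ins for all 11 tagged construct proteins."""
        cons = construct_panel()
        hp, rp = default_hiska_profile(), default_rec_profile()
        for row in construct_expected_signatures().itertuples(index=False):
            prof = hp if row.role == "HISKA_LIKE" else rp
            out = extract_signature(cons[row.construct], prof, row.construct)
            assert out.residues == row.residues, row.construct

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            extract_signature("", default_hiska_profile())


class TestFrequencyMatrix:
    def test_identical_signatures_concentrate_counts(self):
        m = position_frequency_matrix([sig("TAGFQL")] * 3)
        assert m.loc[1, "T"] == 3
        assert (m.sum(axis=1) == 3).all()
        assert (m.to_numpy().sum(axis=1) == 3).all()

    def test_split_column(self):
        m = position_frequency_matrix([sig("TAGFQL"), sig("TTGFQL")])
        assert m.loc[2, "A"] == 1 and m.loc[2, "T"] == 1
        assert (m.sum(axis=1) == 2).all()

    def test_gaps_excluded_from_column_sums(self):
        m = position_frequency_matrix([sig("TAGFQL"), sig("T-GFQL")])
        assert m.loc[2].sum() == 1
        assert m.loc[1].sum() == 2

    def test_empty_input_warns_and_returns_zero_matrix(self):
        with pytest.warns(UserWarning):
            m = position_frequency_matrix([], role="HISKA_LIKE")
        assert m.shape == (6, 20) and not m.to_numpy().any()

    def test_mixed_roles_rejected(self):
        with pytest.raises(ValueError):
            position_frequency_matrix([sig("TAGFQL"), sig("QGILEVD", role="REC")])


class TestGroupDistances:
    def test_singletons_between_only(self):
        m = group_distance_summary({"X": [sig("AAAAAA")], "Y": [sig("AAATTT")]})
        assert m.loc["X", "Y"] == 3
        assert np.isnan(m.loc["X", "X"])

    def test_identical_pair_within_zero(self):
        m = group_distance_summary({"X": [sig("TAGFQL"), sig("TAGFQL")]})
        assert m.loc["X", "X"] == 0

    def test_brute_force_mean_over_pairs(self):
        groups = {
            "X": [sig("AAAAAA"), sig("AAAAAT")],
            "Y": [sig("TTTTTT")],
        }
        m = group_distance_summary(groups)
        assert m.loc["X", "X"] == 1
        assert m.loc["X", "Y"] == pytest.approx((6 + 5) / 2)
        assert m.loc["Y", "X"] == m.loc["X", "Y"]

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            group_distance_summary({"X": [sig("TAGFQL"), sig("QGILEVD", role="REC")]})
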