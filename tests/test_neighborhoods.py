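"""Marker-gene windows, neighborhood merging, and marker-domain ranking."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings, strategies as st

from spo0scan import (
    choose_marker_neighborhood,
    find_marker_genes,
    merge_neighborhoods,
    select_marker_domains,
    window,
)
from spo0scan.model import MarkerSpec, SPO0F_MARKERS
from spo0scan.neighborhoods import discover_neighborhoods

from conftest import build_genome

FBA = ("F_bp_aldolase", "PFAM", 2, 90)
TAL = ("Transaldolase", "PFAM", 2, 90)
CTP = ("CTP_Synth_N", "PFAM", 2, 90)


class TestFindMarkerGenes:
    def test_single_marker_found(self):
        ann = build_genome(n=20, domains={5: [FBA]})
        genes = find_marker_genes(ann, SPO0F_MARKERS)
        assert [g.orf_index for g in genes] == [5]

    def test_no_markers_empty(self):
        ann = build_genome(n=20)
        assert find_marker_genes(ann, SPO0F_MARKERS) == []

    def test_gene_with_two_marker_domains_listed_once(self):
        ann = build_genome(n=20, domains={5: [TAL, CTP]})
        assert len(find_marker_genes(ann, SPO0F_MARKERS)) == 1


class TestWindow:
    def test_interior_window(self):
        ann = build_genome(n=100, domains={10: [FBA]})
        nb = window(ann, ann.genes[10], radius=4)
        assert nb.member_orf_indices == tuple(range(6, 15))

    def test_boundary_clip_on_linear_replicon(self):
        ann = build_genome(n=100, domains={1: [FBA]})
        nb = window(ann, ann.genes[1], radius=4)
        assert nb.member_orf_indices == tuple(range(0, 6))

    def test_wrap_on_circular_replicon(self):
        ann = build_genome(n=10, circular=True, domains={0: [FBA]})
        nb = window(ann, ann.genes[0], radius=4)
        assert set(nb.member_orf_indices) == {6, 7, 8, 9, 0, 1, 2, 3, 4}


class TestMerge:
    def test_markers_three_apart_merge(self):
        ann = build_genome(n=100, domains={10: [FBA], 14: [TAL]})
        merged = discover_neighborhoods(ann, SPO0F_MARKERS)
        assert len(merged) == 1
        assert merged[0].marker_gene_ids == {ann.genes[10].gene_id, ann.genes[14].gene_id}

    def test_five_intervening_orfs_with_disjoint_windows_stay_separate(self):
        spec = MarkerSpec("SPO0F", SPO0F_MARKERS.marker_domains, radius=2, merge_gap=4)
        ann = build_genome(n=100, domains={10: [FBA], 16: [TAL]})
        assert len(discover_neighborhoods(ann, spec)) == 2

    def test_shared_member_merges_even_beyond_marker_gap(self):
        ann = build_genome(n=100, domains={10: [FBA], 17: [TAL]})
        wins = [window(ann, ann.genes[i], 4) for i in (10, 17)]
        merged = merge_neighborhoods(wins, ann, merge_gap=4)
        assert len(merged) == 1
        assert merged[0].member_orf_indices == tuple(range(6, 22))

    def test_different_genome_rejected(self):
        ann_a = build_genome(n=20, genome_id="a", domains={5: [FBA]})
        ann_b = build_genome(n=20, genome_id="b", domains={5: [FBA]})
        wa = window(ann_a, ann_a.genes[5], 4)
        wb = window(ann_b, ann_b.genes[5], 4)
        with pytest.raises(ValueError, match="genome"):
            merge_neighborhoods([wa, wb], ann_a)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        markers=st.lists(st.integers(0, 79), min_size=1, max_size=8, unique=True),
        circular=st.booleans(),
    )
    def test_idempotent_order_invariant_and_markers_partitioned(self, markers, circular):
        ann = build_genome(
            n=80, circular=circular, domains={i: [FBA] for i in markers}
        )
        wins = [window(ann, ann.genes[i], 4) for i in markers]
        merged = merge_neighborhoods(wins, ann, 4)
        again = merge_neighborhoods(merged, ann, 4)
        assert [m.member_orf_indices for m in again] == [m.member_orf_indices for m in merged]
        reversed_merge = merge_neighborhoods(list(reversed(wins)), ann, 4)
        assert [m.member_orf_indices for m in reversed_merge] == [
            m.member_orf_indices for m in merged
        ]
        # every marker gene appears in exactly one merged neighborhood
        for i in markers:
            gid = ann.genes[i].gene_id
            assert sum(gid in m.marker_gene_ids for m in merged) == 1


class TestSelectMarkerDomains:
    def _guide_setup(self):
        # one guide genome: neighborhood around orf 10; domain A on all members
        # near the anchor, domain B only outside
        domains = {
            10: [FBA],
            11: [("domA", "PFAM", 1, 50)],
            40: [("domB", "PFAM", 1, 50)],
        }
        ann = build_genome(n=100, domains=domains)
        nb = window(ann, ann.genes[10], 4)
        return ann, nb

    def test_domain_in_all_neighborhoods_ranks_first(self):
        ann, nb = self._guide_setup()
        ranked = select_marker_domains([nb], [ann], top_k=5)
        assert ranked[0][0] in ("domA", "F_bp_aldolase")
        names = [d for d, _ in ranked]
        assert names.index("domA") < names.index("domB")

    def test_common_outside_only_domain_scores_negative(self):
        domains = {10: [FBA], 11: [("domA", "PFAM", 1, 50)]}
        for i in range(30, 80):
            domains[i] = [("domB", "PFAM", 1, 50)]
        ann = build_genome(n=100, domains=domains)
        nb = window(ann, ann.genes[10], 4)
        ranked = dict(select_marker_domains([nb], [ann], top_k=5))
        assert ranked["domB"] < 0  # frequent outside, absent inside
        assert ranked["domA"] > ranked["domB"]

    def test_score_matches_hand_evaluated_formula(self):
        # 5 guide neighborhoods: domain A in 5/5, domain B in 3/5, none outside
        domains = {}
        anchors = [10, 30, 50, 70, 90]
        for k, a in enumerate(anchors):
            domains[a] = [FBA]
            domains[a + 1] = [("domA", "PFAM", 1, 50)]
            if k < 3:
                domains[a + 2] = [("domB", "PFAM", 1, 50)]
        ann = build_genome(n=120, domains=domains)
        nbs = [window(ann, ann.genes[a], 4) for a in anchors]
        ranked = dict(select_marker_domains(nbs, [ann], top_k=10))
        n_outside = 120 - len({i for nb in nbs for i in nb.member_orf_indices})
        expect_a = math.log(6 / 7) - math.log(1 / (n_outside + 2))
        expect_b = math.log(4 / 7) - math.log(1 / (n_outside + 2))
        assert ranked["domA"] == pytest.approx(expect_a)
        assert ranked["domB"] == pytest.approx(expect_b)
        assert ranked["domA"] > ranked["domB"]

    def test_empty_guide_set_rejected(self):
        ann = build_genome(n=10)
        with pytest.raises(ValueError):
            select_marker_domains([], [ann])


class TestChooseMarkerNeighborhood:
    def _two_sets(self, candidate_at=None):
        domains = {10: [FBA], 50: [TAL], 51: [CTP]}
        ann = build_genome(n=100, domains=domains)
        merged = discover_neighborhoods(ann, SPO0F_MARKERS)
        assert len(merged) == 2
        return ann, merged

    def test_set_with_candidate_wins(self):
        ann, merged = self._two_sets()
        target = ann.genes[11].gene_id

        def pred(a, g):
            return g.gene_id == target

        chosen = choose_marker_neighborhood(merged, ann, pred)
        assert 11 in chosen.member_orf_indices

    def test_most_markers_wins_without_candidates(self):
        ann, merged = self._two_sets()
        chosen = choose_marker_neighborhood(merged, ann, lambda a, g: False)
        assert len(chosen.marker_gene_ids) == 2  # the two-marker 50/51 set

    def test_lowest_index_breaks_full_ties(self):
        domains = {10: [FBA], 50: [TAL]}
        ann = build_genome(n=100, domains=domains)
        merged = discover_neighborhoods(ann, SPO0F_MARKERS)
        chosen = choose_marker_neighborhood(merged, ann, lambda a, g: False)
        assert chosen.min_index == 6

    def test_empty_list_rejected(self):
        ann = build_genome(n=10)
        with pytest.raises(ValueError):
            choose_marker_neighborhood([], ann, lambda a, g: False)
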