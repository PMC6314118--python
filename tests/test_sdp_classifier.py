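from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fadtools.family_io import GroupedAlignment
from fadtools.sdp_classifier import (
    Category,
    ColumnProfile,
    ConsensusError,
    classify_column,
    column_profile,
    divergent_sites,
    group_consensus,
    scan_candidates,
)
from fadtools.synthetic_data import FamilySimSpec, PlantedSite, simulate_family

residue = st.sampled_from("ACDEFGHIKLMNPQRSTVWY")


class TestGroupConsensus:
    def test_unanimity(self):
        assert group_consensus(["W", "W", "W"], threshold=1.0) == "W"

    def test_majority_vs_strict(self):
        assert group_consensus(["W", "W", "F"], threshold=1.0) is None
        assert group_consensus(["W", "W", "F"], threshold=0.66) == "W"

    def test_empty_group_is_error(self):
        with pytest.raises(ConsensusError):
            group_consensus([])

    def test_all_gap_column_gives_none(self):
        assert group_consensus(["-", "-", "-"]) is None

    def test_gappy_column_beyond_cap_gives_none(self):
        # 2/4 gaps > default 25% cap, even though non-gaps are unanimous
        assert group_consensus(["W", "W", "-", "-"]) is None
        assert group_consensus(["W", "W", "-", "-"], gap_max=0.5) == "W"

    @given(
        st.lists(st.sampled_from("ACDEFG-"), min_size=1, max_size=12),
        st.sampled_from([0.6, 0.75, 1.0]),
    )
    @settings(derandomize=True, max_examples=200)
    def test_matches_brute_force_frequency_count(self, col, threshold):
        got = group_consensus(col, threshold=threshold)
        non_gap = [r for r in col if r != "-"]
        expected = None
        if non_gap and (len(col) - len(non_gap)) / len(col) <= 0.25:
            res, count = Counter(non_gap).most_common(1)[0]
            if count / len(non_gap) >= threshold:
                expected = res
        assert got == expected

    @given(st.lists(st.sampled_from("ACDEFG"), min_size=2, max_size=12))
    @settings(derandomize=True, max_examples=100)
    def test_raising_threshold_never_adds_consensus(self, col):
        has_consensus = [
            group_consensus(col, threshold=t) is not None
            for t in (0.55, 0.7, 0.85, 1.0)
        ]
        # once lost at some threshold, consensus never reappears higher up
        assert has_consensus == sorted(has_consensus, reverse=True)


class TestClassifyColumn:
    def _profile(self, d12, w3, q, **kw):
        return ColumnProfile(
            column=1,
            delta12=tuple(d12),
            omega3=tuple(w3),
            query_residue=q,
            delta12_consensus=group_consensus(d12, **kw),
            omega3_consensus=group_consensus(w3, **kw),
        )

    def test_query_shares_omega3_against_conserved_delta12(self):
        # both groups conserved at different residues: both sides fire
        cats = classify_column(self._profile("VVVV", "IIII", "I"))
        assert Category.QUERY_WITH_OMEGA3 in cats
        assert cats == {Category.QUERY_WITH_OMEGA3, Category.DELTA12_ONLY}

    def test_query_shares_delta12_against_mixed_omega3(self):
        cats = classify_column(self._profile("VVVV", "ISTN", "V"))
        assert cats == {Category.QUERY_WITH_DELTA12}

    def test_uniform_column_has_no_category(self):
        assert classify_column(self._profile("VVVV", "VVVV", "V")) == frozenset()

    def test_query_gap_skipped(self):
        assert classify_column(self._profile("VVVV", "IIII", "-")) == frozenset()

    def test_property_mode_ignores_within_class_difference(self):
        # L vs I are both hydrophobic: no between-group difference in class
        profile = self._profile("LLLL", "IIII", "L", mode="property")
        assert classify_column(profile, mode="property") == frozenset()
        # K vs D is positive vs negative: both sides fire
        profile = self._profile("KKKK", "DDDD", "K", mode="property")
        cats = classify_column(profile, mode="property")
        assert Category.QUERY_WITH_DELTA12 in cats


class TestScanCandidates:
    def test_identical_columns_yield_no_candidates(self):
        ga = GroupedAlignment(
            rows=[(i, "MKTAYIAK") for i in ("a", "b", "c", "d", "q")],
            groups={"a": "delta12", "b": "delta12", "c": "omega3",
                    "d": "omega3", "q": "query"},
        )
        assert scan_candidates(ga) == []

    def test_planted_sites_recovered_exactly(self, planted_family):
        """Planted-truth oracle: 12 sites, perfect precision and recall."""
        _, ga, truth = planted_family
        sites = scan_candidates(ga, threshold=1.0)
        assert sites == truth.sites

    def test_missing_group_is_configuration_error(self):
        ga = GroupedAlignment(
            rows=[("a", "ACDE"), ("q", "ACDF")],
            groups={"a": "delta12", "q": "query"},
        )
        with pytest.raises(Exception):
            scan_candidates(ga)

    def test_invariant_to_row_order(self, planted_family):
        _, ga, _ = planted_family
        reordered = GroupedAlignment(
            rows=list(reversed(ga.rows)), groups=ga.groups, reference_id="query"
        )
        assert scan_candidates(reordered) == scan_candidates(ga)

    def test_invariant_to_gap_only_column_insertion(self, planted_family):
        _, ga, _ = planted_family
        k = ga.length // 2
        rows = [(sid, aligned[:k] + "-" + aligned[k:]) for sid, aligned in ga.rows]
        padded = GroupedAlignment(rows=rows, groups=ga.groups, reference_id="query")
        assert scan_candidates(padded) == scan_candidates(ga)

    def test_positions_reported_in_query_numbering(self):
        # query gap before the planted column shifts its residue number by 1
        spec = FamilySimSpec(
            seed=5,
            length=60,
            planted=(PlantedSite(column=30, category=Category.OMEGA3_ONLY,
                                 omega3="W", query="F"),),
            indel_rate=0.3,
        )
        ga, truth = simulate_family(spec)
        sites = scan_candidates(ga)
        assert [s.ref_position for s in sites] == [s.ref_position for s in truth.sites]
        n_query_gaps = ga.aligned("query")[:29].count("-")
        assert sites[0].ref_position == 30 - n_query_gaps


class TestDivergentSites:
    def test_identical_query_ids_rejected(self, planted_family):
        _, ga, _ = planted_family
        with pytest.raises(ValueError):
            divergent_sites(ga, "query", "query")

    def test_planted_divergent_columns_recovered(self):
        spec = FamilySimSpec(
            seed=9,
            length=200,
            divergent=tuple((c, "L", "R") for c in (20, 80, 150)),
        )
        ga, truth = simulate_family(spec)
        sites = divergent_sites(ga, "query", "query2")
        assert [s.ref_position for s in sites] == truth.divergent_positions
        assert all(s.query1_residue == "L" and s.query2_residue == "R" for s in sites)

    def test_conserved_group_columns_excluded(self):
        # paralogs differ, but the ω3 group is conserved: not divergent
        spec = FamilySimSpec(
            seed=11,
            length=50,
            planted=(PlantedSite(column=25, category=Category.OMEGA3_ONLY,
                                 omega3="W", query="F"),),
            include_paralog=True,
        )
        ga, _ = simulate_family(spec)
        rows = []
        for sid, aligned in ga.rows:  # make the paralog differ at column 25
            if sid == "query2":
                aligned = aligned[:24] + "Y" + aligned[25:]
            rows.append((sid, aligned))
        ga2 = GroupedAlignment(rows=rows, groups=ga.groups, reference_id="query")
        assert divergent_sites(ga2, "query", "query2") == []

    def test_matches_brute_force_rescan(self):
        spec = FamilySimSpec(
            seed=13, length=150, include_paralog=True,
            divergent=tuple((c, "K", "E") for c in (10, 60, 110)),
        )
        ga, _ = simulate_family(spec)
        got = {(s.ref_position, s.query1_residue, s.query2_residue)
               for s in divergent_sites(ga, "query", "query2")}
        # independent brute-force: walk columns, recount everything
        expected = set()
        a1, a2 = ga.aligned("query"), ga.aligned("query2")
        refpos = 0
        for col in range(1, ga.length + 1):
            r1, r2 = a1[col - 1], a2[col - 1]
            if r1 != "-":
                refpos += 1
            if "-" in (r1, r2) or r1 == r2:
                continue
            col_res = ga.column(col)
            conserved = False
            for group in ("delta12", "omega3"):
                vals = [col_res[i] for i in ga.group_ids(group)]
                non_gap = [v for v in vals if v != "-"]
                if (
                    non_gap
                    and (len(vals) - len(non_gap)) / len(vals) <= 0.25
                    and len(set(non_gap)) == 1
                ):
                    conserved = True
            if not conserved:
                expected.add((refpos, r1, r2))
        assert got == expected
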