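"""Diagnostic sites, exact DP segmentation, breakpoints, chimera flags."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phagemosaic import (
    find_diagnostic_sites,
    localize_breakpoints,
    segment_cds_aware,
    segment_extents,
    segment_minimal_switches,
    simulate_mosaic_progeny,
)
from phagemosaic.segmentation import DiagnosticSite, SegmentationParams


def make_sites(support_sets, labels="ABC", spacing=10):
    """Diagnostic sites at fixed spacing with prescribed support sets."""
    sites = []
    for i, support in enumerate(support_sets):
        support = frozenset(support)
        alleles = {lab: ("A" if lab in support else "C") for lab in labels}
        sites.append(
            DiagnosticSite(
                position=i * spacing,
                alleles=alleles,
                progeny_allele="A" if support else "G",
                support_set=support,
            )
        )
    return sites


def brute_force_minimum(sites, labels, switch_penalty, mismatch_cost=1.0):
    """Exhaustive enumeration over all label paths (the DP oracle)."""
    best = float("inf")
    for path in itertools.product(range(len(labels)), repeat=len(sites)):
        cost = sum(
            mismatch_cost
            for site, j in zip(sites, path)
            if labels[j] not in site.support_set
        )
        cost += switch_penalty * sum(a != b for a, b in zip(path, path[1:]))
        best = min(best, cost)
    return best


def random_instance(rng, n_sites, labels="ABC"):
    supports = []
    for _ in range(n_sites):
        k = rng.integers(0, len(labels) + 1)
        supports.append(rng.choice(list(labels), size=k, replace=False))
    return make_sites(supports, labels)


class TestDiagnosticSites:
    def test_identical_ancestors_yield_no_sites(self):
        seqs = {"A": "ACGTACGT", "B": "ACGTACGT"}
        assert find_diagnostic_sites("ACGTACGT", seqs) == []

    def test_k_differences_yield_k_sites(self):
        seqs = {"A": "ACGTACGT", "B": "ACGAACGA"}
        sites = find_diagnostic_sites("ACGTACGT", seqs)
        assert [s.position for s in sites] == [3, 7]
        assert all(s.support_set == {"A"} for s in sites)

    def test_site_count_matches_column_scan_oracle(self, small_panel):
        seqs = small_panel.sequences()
        progeny = small_panel.get("A").sequence
        sites = find_diagnostic_sites(progeny, seqs)
        expected = sum(
            1
            for cols in zip(*seqs.values())
            if len(set(cols)) > 1
        )
        assert len(sites) == expected

    def test_support_set_empty_when_progeny_matches_nobody(self):
        seqs = {"A": "AAAA", "B": "AACA"}
        sites = find_diagnostic_sites("AAGA", seqs)
        assert len(sites) == 1 and sites[0].support_set == frozenset()

    def test_offset_shifts_reported_positions(self):
        seqs = {"A": "ACGT", "B": "ACCT"}
        sites = find_diagnostic_sites("ACGT", seqs, offset=100)
        assert sites[0].position == 102

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            find_diagnostic_sites("ACGT", {"A": "ACG"})


class TestMinimalSwitchDp:
    def test_uniform_support_is_single_segment(self):
        sites = make_sites([{"A"}] * 6)
        seg = segment_minimal_switches(sites, "ABC")
        assert seg.n_switches == 0
        assert len(seg.segments) == 1
        assert seg.segments[0].label_set == {"A"}
        assert seg.breakpoints == ()
        assert seg.objective_value == 0.0

    def test_empty_site_list_is_empty_segmentation(self):
        seg = segment_minimal_switches([], "ABC")
        assert seg.segments == () and seg.n_switches == 0

    def test_clean_two_block_instance(self):
        sites = make_sites([{"A"}] * 4 + [{"B"}] * 4)
        seg = segment_minimal_switches(sites, "ABC", switch_penalty=2.0)
        assert seg.n_switches == 1
        assert [set(s.label_set) for s in seg.segments] == [{"A"}, {"B"}]
        assert seg.objective_value == pytest.approx(2.0)

    def test_single_discordant_site_cheaper_than_switching(self):
        # one B site inside an A run costs 1 mismatch < 2 switches * 2.0
        sites = make_sites([{"A"}, {"A"}, {"B"}, {"A"}, {"A"}])
        seg = segment_minimal_switches(sites, "ABC", switch_penalty=2.0)
        assert seg.n_switches == 0
        assert seg.objective_value == pytest.approx(1.0)

    def test_empty_support_sites_never_force_a_switch(self):
        sites = make_sites([{"A"}] * 3 + [set()] * 4 + [{"A"}] * 3)
        seg = segment_minimal_switches(sites, "ABC")
        assert seg.n_switches == 0
        assert seg.objective_value == pytest.approx(4.0)

    def test_jointly_supported_stretch_labelled_with_both(self):
        # 5 joint sites: switching in and out (2 * 2.0) beats 5 mismatches
        sites = make_sites([{"C"}] * 4 + [{"A", "B"}] * 5 + [{"C"}] * 4)
        seg = segment_minimal_switches(sites, "ABC")
        assert [set(s.label_set) for s in seg.segments] == [{"C"}, {"A", "B"}, {"C"}]

    def test_dp_equals_brute_force_on_random_small_instances(self, rng):
        # the acceptance-scale check (200 instances) lives in the
        # acceptance suite; this is a quick smoke version
        for _ in range(30):
            sites = random_instance(rng, int(rng.integers(1, 9)))
            seg = segment_minimal_switches(sites, "ABC", switch_penalty=1.5)
            assert seg.objective_value == pytest.approx(
                brute_force_minimum(sites, "ABC", 1.5)
            )

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_dp_optimality_property(self, data):
        n = data.draw(st.integers(1, 7))
        supports = data.draw(
            st.lists(
                st.sets(st.sampled_from("ABC"), max_size=3), min_size=n, max_size=n
            )
        )
        penalty = data.draw(st.sampled_from([0.5, 1.0, 2.0, 3.5]))
        sites = make_sites(supports)
        seg = segment_minimal_switches(sites, "ABC", switch_penalty=penalty)
        assert seg.objective_value == pytest.approx(
            brute_force_minimum(sites, "ABC", penalty)
        )

    def test_switch_count_non_increasing_in_penalty(self, rng):
        sites = random_instance(rng, 40)
        counts = [
            segment_minimal_switches(sites, "ABC", switch_penalty=lam).n_switches
            for lam in (0.5, 1.0, 2.0, 4.0, 8.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_segment_label_sets_have_maximal_support(self, rng):
        # independent re-derivation of the merge rule: within each
        # segment's core (boundary sites also explained for free by the
        # neighbouring segment are ambiguous and excluded), the label
        # set is exactly the argmin of the site-cost totals
        sites = random_instance(rng, 60)
        seg = segment_minimal_switches(sites, "ABC")

        def cost(site, label_set_or_lab):
            if not site.support_set:
                return 1
            labs = label_set_or_lab
            return 0 if any(l in site.support_set for l in labs) else 1

        for i, segment in enumerate(seg.segments):
            lo, hi = segment.first_site_index, segment.last_site_index
            if i > 0:
                prev = seg.segments[i - 1].label_set
                while lo < hi and sites[lo].support_set and prev & sites[lo].support_set:
                    lo += 1
            if i < len(seg.segments) - 1:
                nxt = seg.segments[i + 1].label_set
                while hi > lo and sites[hi].support_set and nxt & sites[hi].support_set:
                    hi -= 1
            core = sites[lo : hi + 1]
            costs = {
                lab: sum(1 for s in core if s.support_set and lab not in s.support_set)
                for lab in "ABC"
            }
            best = min(costs.values())
            undominated = {lab for lab, c in costs.items() if c == best}
            # no dominated label survives in the recorded set
            assert segment.label_set <= undominated

    def test_low_confidence_flag_for_single_site_segments(self):
        sites = make_sites([{"A"}] * 5 + [{"B"}] + [{"A"}] * 5)
        seg = segment_minimal_switches(sites, "ABC", switch_penalty=0.4)
        flags = [s.low_confidence for s in seg.segments]
        assert flags == [False, True, False]


class TestBreakpoints:
    def test_single_segment_has_empty_report(self):
        sites = make_sites([{"A"}] * 4)
        seg = segment_minimal_switches(sites, "ABC")
        assert localize_breakpoints(seg) == []

    def test_breakpoint_interval_spans_the_flanking_firm_sites(self):
        # A-sites at 0..30, ambiguous {A,B} at 40, B-sites at 50..80:
        # the switch window is the open interval (30, 50)
        sites = make_sites([{"A"}] * 4 + [{"A", "B"}] + [{"B"}] * 4)
        seg = segment_minimal_switches(sites, "ABC")
        (bp,) = seg.breakpoints
        assert (bp.left_bound, bp.right_bound) == (30, 50)
        assert bp.midpoint == pytest.approx(40.0)

    def test_planted_crossovers_recovered_and_contained(self, small_panel):
        # >=3 exclusive diagnostic sites per planted segment, no noise:
        # exact switch count and containment of every planted crossover
        L = small_panel.genome_length
        crossovers = [(1500, "C"), (3000, "A"), (4500, "C")]
        progeny, truth = simulate_mosaic_progeny(small_panel, crossovers, initial_label="A")
        sites = find_diagnostic_sites(progeny, small_panel.sequences())
        seg = segment_minimal_switches(sites, small_panel.labels)
        assert seg.n_switches == len(truth.crossover_positions)
        rows = localize_breakpoints(seg, truth.crossover_positions)
        assert all(row["contains_planted"] for row in rows)

    def test_segment_extents_partition_the_region(self):
        sites = make_sites([{"C"}] * 5 + [{"A"}] * 5)
        seg = segment_minimal_switches(sites, "ABC")
        extents = segment_extents(seg, 0, 200)
        assert extents[0][0] == 0 and extents[-1][1] == 200
        for (s1, e1), (s2, e2) in zip(extents, extents[1:]):
            assert e1 == s2


class TestCdsAware:
    def test_intergenic_crossovers_flag_no_cds(self, small_panel):
        cds_list = small_panel.ancestors[0].cds_list
        # crossovers exactly at gene starts fall in the preceding spacer
        crossovers = [(cds_list[1].start, "C"), (cds_list[3].start, "A")]
        progeny, _ = simulate_mosaic_progeny(small_panel, crossovers, initial_label="A")
        result = segment_cds_aware(progeny, small_panel, cds_list)
        assert result.chimeric_cds == frozenset()
        assert result.n_switches == 2

    def test_within_cds_crossover_flagged(self, small_panel):
        cds_list = small_panel.ancestors[0].cds_list
        target = cds_list[2]
        mid = (target.start + target.end) // 2
        progeny, _ = simulate_mosaic_progeny(small_panel, [(mid, "C")], initial_label="A")
        result = segment_cds_aware(progeny, small_panel, cds_list)
        assert result.chimeric_cds == {target.cds_id}

    def test_mosaic_region_chimera_flags(self, mosaic_region_scenario):
        """Only the internally chimeric tail-fiber gene is flagged; the
        gene carrying the de novo mutation is not."""
        scn = mosaic_region_scenario
        result = segment_cds_aware(scn.progeny, scn.panel, scn.cds_list)
        assert "CDS_131" in result.chimeric_cds
        assert "CDS_130" not in result.chimeric_cds
        assert result.chimeric_cds == {"CDS_131"}
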