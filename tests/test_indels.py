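import pytest
from hypothesis import given, settings, strategies as st

from plastevol import indels, structure
from plastevol.formats_io import (
    FormatError,
    GAP_CHARS,
    GenomeInterval,
    PlastevolError,
    ValidationError,
    dated_tree_from_string,
)


def toy_partition():
    # LSC 0-8000, IRb 8000-10500, SSC 10500-12000, IRa 12000-14500
    return structure.QuadripartitePartition(
        lsc=GenomeInterval(0, 8000),
        irb=GenomeInterval(8000, 10500),
        ssc=GenomeInterval(10500, 12000),
        ira=GenomeInterval(12000, 14500),
    )


class TestCallIndels:
    def test_simple_insertion(self):
        events = indels.call_indels(
            [("REF", "AC--GT"), ("s1", "ACTTGT")], "REF"
        )
        assert [(e.kind, e.ref_pos, e.length) for e in events] == [
            ("insertion", 1, 2)
        ]

    def test_simple_deletion(self):
        events = indels.call_indels(
            [("REF", "ACGTGT"), ("s1", "AC--GT")], "REF"
        )
        assert [(e.kind, e.ref_pos, e.length) for e in events] == [
            ("deletion", 1, 2)
        ]

    def test_identical_sequences_no_events(self):
        assert indels.call_indels([("REF", "ACGT"), ("s1", "ACGT")], "REF") == []

    def test_sample_equal_to_reference_row_is_skipped(self):
        events = indels.call_indels([("REF", "AC-GT"), ("s1", "ACTGT")], "REF")
        assert len(events) == 1 and events[0].sample_id == "s1"

    def test_terminal_gap_runs_discarded(self):
        # leading/trailing sample gaps are alignment-end artifacts, not deletions
        events = indels.call_indels(
            [("REF", "AAACGTAAA"), ("s1", "--ACG-A--")], "REF"
        )
        assert [(e.kind, e.ref_pos, e.length) for e in events] == [
            ("deletion", 4, 1)
        ]

    def test_both_gap_columns_are_transparent(self):
        # another sample's insertion column must not split this pair's runs
        alignment = [
            ("REF", "AAA--CCC"),
            ("s1", "AAATTCCC"),
            ("s2", "A----CCC"),  # deletion whose run spans the both-gap columns
        ]
        events = indels.call_indels(alignment, "REF")
        s2 = [(e.kind, e.ref_pos, e.length) for e in events if e.sample_id == "s2"]
        assert s2 == [("deletion", 0, 2)]

    def test_insertion_at_reference_start_gets_flank_minus_one(self):
        events = indels.call_indels([("REF", "--ACGT"), ("s1", "TTACGT")], "REF")
        assert [(e.kind, e.ref_pos, e.length) for e in events] == [
            ("insertion", -1, 2)
        ]

    def test_missing_reference_and_ragged_rows_error(self):
        with pytest.raises(PlastevolError):
            indels.call_indels([("a", "ACGT")], "REF")
        with pytest.raises(FormatError):
            indels.call_indels([("REF", "ACGT"), ("s1", "ACG")], "REF")

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.sampled_from(["MM", "M-", "-M", "--"]), min_size=1, max_size=60))
    def test_called_bp_reconstructs_sample_length(self, columns):
        """Sum of insertion bp minus deletion bp equals the length difference
        between the aligned sample and reference windows (conservation)."""
        ref = "".join("A" if c[0] == "M" else "-" for c in columns)
        sample = "".join("A" if c[1] == "M" else "-" for c in columns)
        if "A" not in ref or "A" not in sample:
            return
        events = indels.call_indels([("REF", ref), ("s1", sample)], "REF")
        lo = min(i for i, ch in enumerate(sample) if ch not in GAP_CHARS)
        hi = max(i for i, ch in enumerate(sample) if ch not in GAP_CHARS) + 1
        ref_len = sum(1 for ch in ref[lo:hi] if ch not in GAP_CHARS)
        sample_len = sum(1 for ch in sample[lo:hi] if ch not in GAP_CHARS)
        ins = sum(e.length for e in events if e.kind == "insertion")
        dels = sum(e.length for e in events if e.kind == "deletion")
        assert ref_len + ins - dels == sample_len


class TestRegions:
    def test_left_flank_rule(self):
        part = toy_partition()
        ev = indels.IndelEvent("s", "deletion", ref_pos=7999, length=50)
        assert indels.assign_region(ev, part).region == "LSC"
        ev = indels.IndelEvent("s", "insertion", ref_pos=8000, length=5)
        assert indels.assign_region(ev, part).region == "IR"

    def test_both_ir_copies_map_to_ir(self):
        part = toy_partition()
        for pos in (9000, 13000):
            ev = indels.IndelEvent("s", "insertion", ref_pos=pos, length=1)
            assert indels.assign_region(ev, part).region == "IR"

    def test_flank_before_reference_start_uses_base_zero(self):
        part = toy_partition()
        ev = indels.IndelEvent("s", "insertion", ref_pos=-1, length=3)
        assert indels.assign_region(ev, part).region == "LSC"

    def test_simulated_events_agree_with_ground_truth_regions(self, toy_simulation):
        called = indels.assign_regions(
            indels.call_indels(
                toy_simulation.alignment, toy_simulation.config.reference_id
            ),
            toy_simulation.partition,
        )
        by_tip = {}
        for e in called:
            by_tip.setdefault(e.sample_id, []).append(e)
        for tip, truth in toy_simulation.events_by_tip.items():
            got = sorted(
                (e.kind, e.ref_pos, e.length, e.region) for e in by_tip.get(tip, [])
            )
            expected = sorted((e.kind, e.ref_pos, e.length, e.region) for e in truth)
            assert got == expected


class TestDensityAndRates:
    def test_density_is_bp_per_kbp(self):
        part = toy_partition()
        events = [
            indels.assign_region(
                indels.IndelEvent("s1", "insertion", ref_pos=100, length=400), part
            )
        ]
        summary = indels.summarize_indels(events)
        density = indels.indel_density(summary, part)
        assert density.loc[0, "density_bp_per_kbp"] == pytest.approx(50.0)

    def test_zero_events_zero_density(self):
        density = indels.indel_density(indels.summarize_indels([]), toy_partition())
        assert density.empty

    def test_branch_rate_is_bp_over_duration(self):
        tree = dated_tree_from_string("(A:5.0,B:5.0);")
        events = {"A": [indels.IndelEvent("A", "deletion", 10, 500)]}
        (rate,) = indels.branch_rates(events, tree)
        assert rate.deletion_rate == pytest.approx(100.0)
        assert rate.insertion_rate == 0.0
        # rate times duration reproduces the assigned bp exactly
        assert rate.deletion_rate * rate.duration_myr == rate.deletion_bp

    def test_sample_missing_from_tree_errors(self):
        tree = dated_tree_from_string("(A:5.0,B:5.0);")
        events = {"Z": [indels.IndelEvent("Z", "deletion", 10, 5)]}
        with pytest.raises(ValidationError):
            indels.branch_rates(events, tree)

    def test_unsupported_attribution_rejected(self):
        tree = dated_tree_from_string("(A:5.0,B:5.0);")
        with pytest.raises(ValidationError):
            indels.branch_rates({}, tree, attribution="parsimony")

    def test_summary_region_bp_sums_to_sample_totals(self, toy_simulation):
        called = indels.assign_regions(
            indels.call_indels(
                toy_simulation.alignment, toy_simulation.config.reference_id
            ),
            toy_simulation.partition,
        )
        summary = indels.summarize_indels(called)
        per_sample_from_regions = summary.groupby("sample_id")["bp"].sum()
        for tip in toy_simulation.tip_records:
            direct = sum(e.length for e in called if e.sample_id == tip)
            assert per_sample_from_regions.get(tip, 0) == direct
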