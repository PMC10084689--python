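import numpy as np
import pandas as pd
import pytest

from plastevol import indels, structure, synthetic_data as sd
from plastevol.formats_io import ValidationError, revcomp


class TestConfig:
    def test_zero_length_ssc_rejected(self):
        with pytest.raises(ValidationError):
            sd.SimulationConfig(ssc_len=0)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValidationError):
            sd.SimulationConfig(deletion_rates={"C3": -1.0, "CAM": 1, "C3-CAM": 1})

    def test_fragment_must_fit_inside_ir(self):
        with pytest.raises(ValidationError):
            sd.SimulationConfig(psi_ycf1=3000, ir_len=2500)


class TestAncestor:
    def test_partition_tiles_and_ir_is_revcomp(self, toy_config):
        ancestor, partition = sd.make_ancestor(toy_config)
        assert partition.genome_length == len(ancestor.sequence)
        partition.validate_sequence(ancestor.sequence)
        irb = ancestor.sequence[partition.irb.start : partition.irb.end]
        ira = ancestor.sequence[partition.ira.start : partition.ira.end]
        assert irb == revcomp(ira)

    def test_configured_junction_geometry_measured_back(self):
        config = sd.toy_config(seed=42, psi_ycf1=315, psi_rpl22=37, ndhf_jsb_offset=18)
        ancestor, _ = sd.make_ancestor(config)
        part = structure.detect_inverted_repeat(ancestor.sequence)
        profile = structure.profile_junctions(ancestor, part)
        assert profile.psi_ycf1_len == 315
        assert profile.psi_rpl22_len == 37
        assert profile.ndhf_jsb_offset == 18
        assert profile.jsb_type == "type_a_overlap"


class TestEvolution:
    def test_zero_rates_give_identical_tips_and_empty_log(self):
        zero = {"C3": 0.0, "CAM": 0.0, "C3-CAM": 0.0}
        config = sd.toy_config(
            seed=1, insertion_rates=zero, deletion_rates=zero, substitution_rates=zero
        )
        result = sd.evolve_along_tree(config)
        for tip, record in result.tip_records.items():
            assert record.sequence == result.ancestor.sequence
            assert result.events_by_tip[tip] == []

    def test_alignment_consistent_with_event_log(self, toy_simulation):
        """Per-tip insertion/deletion bp read off the alignment equal the
        logged totals (ground-truth consistency)."""
        ref_row = dict(toy_simulation.alignment)[toy_simulation.config.reference_id]
        for tip, row in toy_simulation.alignment:
            if tip == toy_simulation.config.reference_id:
                continue
            ins_bp = sum(
                1 for r, s in zip(ref_row, row) if r == "-" and s != "-"
            )
            del_bp = sum(
                1 for r, s in zip(ref_row, row) if r != "-" and s == "-"
            )
            log = toy_simulation.events_by_tip[tip]
            assert ins_bp == sum(e.length for e in log if e.kind == "insertion")
            assert del_bp == sum(e.length for e in log if e.kind == "deletion")

    def test_deletion_bp_matches_poisson_expectation(self):
        """Mean deletion bp per branch over replicates is close to
        rate * duration (3 sigma of the replicate mean)."""
        rate, duration, reps = 90.0, 10.0, 15
        config_rates = {"C3": rate, "CAM": rate, "C3-CAM": rate}
        totals = []
        for seed in range(reps):
            config = sd.toy_config(seed=seed, deletion_rates=config_rates)
            result = sd.evolve_along_tree(config)
            for tip, events in result.events_by_tip.items():
                totals.append(sum(e.length for e in events if e.kind == "deletion"))
        totals = np.asarray(totals, dtype=float)
        se = totals.std(ddof=1) / np.sqrt(len(totals))
        assert abs(totals.mean() - rate * duration) < 3 * se + 1e-9

    def test_internal_branch_events_shared_by_descendants(self):
        newick = "((A:5.0,B:5.0):5.0,C:10.0);"
        config = sd.toy_config(
            seed=2,
            tree_newick=newick,
            categories={"A": "CAM", "B": "CAM", "C": "C3"},
        )
        result = sd.evolve_along_tree(config)
        internal = [
            e for branch, events in result.events_by_branch.items()
            if branch.startswith("node") for e in events
        ]
        assert internal, "internal branch should accumulate events at these rates"
        for event in internal:
            for tip in ("A", "B"):
                assert (event.kind, event.ref_pos, event.length) in {
                    (e.kind, e.ref_pos, e.length) for e in result.events_by_tip[tip]
                }


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self):
        a = sd.generate_bundle(sd.toy_config(seed=33))
        b = sd.generate_bundle(sd.toy_config(seed=33))
        assert a.simulation.alignment == b.simulation.alignment
        assert a.simulation.ancestor.sequence == b.simulation.ancestor.sequence
        pd.testing.assert_frame_equal(a.pn_traces, b.pn_traces)
        pd.testing.assert_frame_equal(a.climate, b.climate)
        assert a.codon_alignments == b.codon_alignments

    def test_different_seeds_differ(self):
        a = sd.make_ancestor(sd.toy_config(seed=1))[0].sequence
        b = sd.make_ancestor(sd.toy_config(seed=2))[0].sequence
        assert a != b


class TestTraceAndClimateShapes:
    def test_climate_row_count_is_localities_times_species(self, toy_bundle):
        assert len(toy_bundle.climate) == 13 * 11 == 143

    def test_pn_trace_has_both_phases_per_species(self, toy_bundle):
        per_species = toy_bundle.pn_traces.groupby("species")["phase"].nunique()
        assert (per_species == 2).all()

    def test_codon_alignments_cover_all_taxa_and_reference(
        self, toy_bundle, toy_config
    ):
        assert len(toy_bundle.codon_alignments) == 68
        for pairs in toy_bundle.codon_alignments.values():
            ids = [name for name, _ in pairs]
            assert ids[0] == toy_config.reference_id
            assert set(ids[1:]) == set(toy_config.categories)
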