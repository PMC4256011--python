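"""The iterative partition pipeline: passes, thresholds, optimization."""

import pytest

from ecod.hierarchy import Classification, Domain, SpecialCategory, add_lineage
from ecod.partition import (
    PartitionError,
    PartitionState,
    PipelineConfig,
    QueryChain,
    chain_pass,
    domain_pass,
    optimize_boundaries,
    profile_pass,
    run_pipeline,
    structure_pass,
    triage_special,
)
from ecod.ranges import SegmentSet
from ecod.search_io import Hit


def make_reference_two_domain_chain() -> Classification:
    """One reference chain (pdb 'ref0', chain A, 100 residues, 2 domains)."""
    c = Classification(label="ref")
    add_lineage(c, "beta barrels", "2001.1.1.1")
    add_lineage(c, "beta barrels", "2001.1.1.2")
    c.add_domain(
        Domain(
            uid="rd1",
            pdb_id="ref0",
            segset=SegmentSet.single("A", 1, 50),
            f_node="2001.1.1.1",
        )
    )
    c.add_domain(
        Domain(
            uid="rd2",
            pdb_id="ref0",
            segset=SegmentSet.single("A", 51, 100),
            f_node="2001.1.1.2",
        )
    )
    return c


def query(n: int = 100, chain_id: str = "q1") -> QueryChain:
    return QueryChain(chain_id=chain_id, sequence="A" * n)


def state_for(chain: QueryChain, **config_kwargs) -> PartitionState:
    return PartitionState(chain=chain, config=PipelineConfig(**config_kwargs))


def chain_hit(evalue: float, qstart: int, qend: int, chain_id="q1", target="ref0_A"):
    return Hit(
        query_id=chain_id,
        query_range=SegmentSet.single(chain_id, qstart, qend),
        target_id=target,
        target_kind="chain",
        method="chain_blast",
        evalue=evalue,
        aligned_pairs=tuple((q, q) for q in range(qstart, qend + 1)),
    )


def domain_hit(evalue, qstart, qend, target, tlen=None, chain_id="q1"):
    n = qend - qstart + 1 if tlen is None else tlen
    return Hit(
        query_id=chain_id,
        query_range=SegmentSet.single(chain_id, qstart, qend),
        target_id=target,
        target_kind="domain",
        method="domain_blast",
        evalue=evalue,
        aligned_pairs=tuple((qstart + i, 1 + i) for i in range(min(n, qend - qstart + 1))),
    )


class TestTriage:
    def test_short_chain_without_hits_is_peptide(self):
        assert triage_special(query(25)) is SpecialCategory.PEPTIDE

    def test_short_chain_with_hits_is_not_peptide(self):
        assert triage_special(query(25), has_hits=True) is None

    def test_annotated_coiled_coil_over_most_of_extent(self):
        chain = query(300)
        annotation = {"coiled_coil": SegmentSet.single("q1", 1, 280)}
        assert triage_special(chain, annotation) is SpecialCategory.COILED_COIL

    def test_coiled_coil_annotation_on_small_region_ignored(self):
        chain = query(300)
        annotation = {"coiled_coil": SegmentSet.single("q1", 1, 100)}
        assert triage_special(chain, annotation) is None

    def test_unannotated_mid_size_chain_is_none(self):
        assert triage_special(query(150)) is None

    def test_low_resolution_flag(self):
        assert (
            triage_special(query(150), {"low_resolution": True})
            is SpecialCategory.LOW_RESOLUTION
        )


class TestChainPass:
    def test_architecture_transfer_partitions_all_domains(self):
        reference = make_reference_two_domain_chain()
        state = state_for(query(100))
        chain_pass(state, [chain_hit(1e-20, 1, 97)], reference)  # 3 uncovered
        assert len(state.domains) == 2
        assert state.domains[0].segset == SegmentSet.single("q1", 1, 50)
        assert state.domains[1].segset == SegmentSet.single("q1", 51, 97)
        assert {d.proposed_f_node for d in state.domains} == {
            "2001.1.1.1",
            "2001.1.1.2",
        }
        assert all(d.source_method == "chain_blast" for d in state.domains)

    def test_evalue_exactly_at_gate_rejected(self):
        reference = make_reference_two_domain_chain()
        state = state_for(query(100))
        chain_pass(state, [chain_hit(2e-3, 1, 100)], reference)
        assert state.domains == []
        assert any(not r.accepted and "not <" in r.reason for r in state.log)

    def test_ten_uncovered_exactly_rejected(self):
        reference = make_reference_two_domain_chain()
        state = state_for(query(100))
        chain_pass(state, [chain_hit(1e-9, 1, 90)], reference)  # 10 uncovered
        assert state.domains == []

    def test_unknown_reference_chain_is_an_error(self):
        reference = make_reference_two_domain_chain()
        state = state_for(query(100))
        with pytest.raises(PartitionError, match="unknown reference chain"):
            chain_pass(state, [chain_hit(1e-9, 1, 100, target="zz_A")], reference)


class TestDomainPass:
    def test_two_clean_hits_accepted(self):
        reference = make_reference_two_domain_chain()
        state = state_for(query(100))
        hits = [
            domain_hit(1e-10, 1, 50, "rd1"),
            domain_hit(1e-8, 53, 100, "rd2"),
        ]
        domain_pass(state, hits, reference)
        assert len(state.domains) == 2

    def test_coverage_exactly_eighty_percent_rejected(self):
        reference = make_reference_two_domain_chain()
        state = state_for(query(100))
        domain_pass(state, [domain_hit(1e-10, 1, 40, "rd1")], reference)  # 40/50
        assert state.domains == []
        assert any("coverage 0.800" in r.reason for r in state.log)

    def test_overlapping_second_hit_skipped_and_logged(self):
        reference = make_reference_two_domain_chain()
        state = state_for(query(100))
        hits = [
            domain_hit(1e-10, 1, 50, "rd1"),
            domain_hit(1e-8, 41, 90, "rd2"),  # overlaps 10 > tolerance 5
        ]
        domain_pass(state, hits, reference)
        assert len(state.domains) == 1
        assert any("overlap" in r.reason and not r.accepted for r in state.log)

    def test_small_overlap_trimmed(self):
        reference = make_reference_two_domain_chain()
        state = state_for(query(100))
        hits = [
            domain_hit(1e-10, 1, 50, "rd1"),
            domain_hit(1e-8, 48, 100, "rd2"),  # overlaps 3 <= tolerance
        ]
        domain_pass(state, hits, reference)
        assert len(state.domains) == 2
        assert state.domains[1].segset == SegmentSet.single("q1", 51, 100)


def profile_hit(prob, qstart, qend, target, chain_id="q1"):
    return Hit(
        query_id=chain_id,
        query_range=SegmentSet.single(chain_id, qstart, qend),
        target_id=target,
        target_kind="profile",
        method="hhsearch",
        probability=prob,
        evalue=1e-10,
        aligned_pairs=tuple((qstart + i, 1 + i) for i in range(qend - qstart + 1)),
    )


class TestProfilePass:
    def test_confident_hit_accepted(self):
        reference = make_reference_two_domain_chain()
        state = state_for(query(100))
        profile_pass(state, [profile_hit(97.3, 1, 47, "rd1")], reference)
        assert len(state.domains) == 1

    @pytest.mark.parametrize("probability", [89.9, 90.0])
    def test_at_or_below_gate_rejected(self, probability):
        reference = make_reference_two_domain_chain()
        state = state_for(query(100))
        profile_pass(state, [profile_hit(probability, 1, 47, "rd1")], reference)
        assert state.domains == []

    def test_empty_hit_list_leaves_state_unchanged(self):
        reference = make_reference_two_domain_chain()
        state = state_for(query(100))
        profile_pass(state, [], reference)
        assert state.domains == [] and state.log == []


def dali_hit(z, qstart, qend, target, chain_id="q1"):
    return Hit(
        query_id=chain_id,
        query_range=SegmentSet.single(chain_id, qstart, qend),
        target_id=target,
        target_kind="structure",
        method="dali",
        z_score=z,
        aligned_pairs=tuple((qstart + i, 1 + i) for i in range(qend - qstart + 1)),
    )


class TestStructurePass:
    def _sequences(self, qseq="A" * 100):
        # rd1 similar to query (As), rd2 maximally dissimilar (Ws vs Ps)
        return {"q1": qseq, "rd1": "A" * 50, "rd2": "W" * 50}

    def test_good_z_and_blosum_accepted(self):
        reference = make_reference_two_domain_chain()
        state = state_for(query(100))
        structure_pass(state, [dali_hit(10.2, 1, 50, "rd1")], self._sequences(), reference)
        assert len(state.domains) == 1
        assert state.domains[0].source_method == "dali"

    def test_negative_mean_blosum_rejected(self):
        reference = make_reference_two_domain_chain()
        state = state_for(query(100))
        # A aligned to W scores -3: mean well below 0
        structure_pass(state, [dali_hit(10.2, 1, 50, "rd2")], self._sequences(), reference)
        assert state.domains == []
        assert any("BLOSUM" in r.reason for r in state.log)

    def test_low_z_rejected(self):
        reference = make_reference_two_domain_chain()
        state = state_for(query(100))
        structure_pass(state, [dali_hit(3.0, 1, 50, "rd1")], self._sequences(), reference)
        assert state.domains == []

    def test_pair_outside_sequence_is_an_error(self):
        reference = make_reference_two_domain_chain()
        state = state_for(query(100))
        bad = dali_hit(10.0, 60, 120, "rd1")  # target side exceeds rd1 length
        with pytest.raises(PartitionError, match="outside"):
            structure_pass(state, [bad], self._sequences(), reference)


class TestOptimizeBoundaries:
    def _state_with(self, segsets, n=200):
        state = state_for(query(n))
        for seg in segsets:
            state.domains.append(
                __import__("ecod.partition", fromlist=["ProvisionalDomain"]).ProvisionalDomain(
                    segset=SegmentSet.from_string(seg),
                    source_method="domain_blast",
                    source_hit=None,
                )
            )
        return state

    def test_interstitial_gap_split_at_nearest_boundary(self):
        state = self._state_with(["q1:1-100", "q1:113-200"], n=200)
        optimize_boundaries(state)
        assert state.domains[0].segset == SegmentSet.from_string("q1:1-106")
        assert state.domains[1].segset == SegmentSet.from_string("q1:107-200")

    def test_odd_gap_tie_goes_to_n_terminal_neighbor(self):
        state = self._state_with(["q1:1-100", "q1:112-200"], n=200)
        optimize_boundaries(state)
        # gap 101-111 (11 residues): 6 to the left, 5 to the right
        assert state.domains[0].segset == SegmentSet.from_string("q1:1-106")
        assert state.domains[1].segset == SegmentSet.from_string("q1:107-200")

    def test_terminal_run_merges_into_terminal_domain(self):
        state = self._state_with(["q1:15-200"], n=200)
        optimize_boundaries(state)
        assert state.domains[0].segset == SegmentSet.from_string("q1:1-200")

    def test_gap_beyond_threshold_left_unassigned(self):
        state = self._state_with(["q1:1-100", "q1:132-200"], n=200)
        optimize_boundaries(state)  # gap of 31 > 30
        assert state.domains[0].segset == SegmentSet.from_string("q1:1-100")
        assert state.domains[1].segset == SegmentSet.from_string("q1:132-200")

    def test_domains_remain_disjoint(self):
        state = self._state_with(["q1:1-80", "q1:90-140", "q1:160-200"], n=200)
        optimize_boundaries(state)
        total = SegmentSet()
        count = 0
        for dom in state.domains:
            count += dom.segset.size
            total = total.union(dom.segset)
        assert total.size == count  # no overlap introduced


class TestRunPipeline:
    def test_provider_failure_flags_manual_not_crash(self):
        reference = make_reference_two_domain_chain()

        def exploding():
            raise RuntimeError("search backend down")

        result = run_pipeline(
            query(100), {"domain_blast": exploding}, reference
        )
        assert result.status == "flagged_manual"
        assert any("provider failure" in r.reason for r in result.log)

    def test_unmatched_region_flags_manual(self):
        reference = make_reference_two_domain_chain()
        hits = [domain_hit(1e-10, 1, 50, "rd1", chain_id="q1")]
        chain = QueryChain(chain_id="q1", sequence="A" * 110)
        result = run_pipeline(chain, {"domain_blast": hits}, reference)
        # 60 residues at the C-terminus match nothing
        assert result.status == "flagged_manual"

    def test_completeness_soundness(self):
        """status complete_automatic <=> zero uncovered residues."""
        from ecod.ranges import uncovered_count

        reference = make_reference_two_domain_chain()
        for hits, n in [
            ([domain_hit(1e-10, 1, 50, "rd1"), domain_hit(1e-9, 51, 100, "rd2")], 100),
            ([domain_hit(1e-10, 1, 50, "rd1")], 110),
            ([], 150),
        ]:
            chain = QueryChain(chain_id="q1", sequence="A" * n)
            result = run_pipeline(chain, {"domain_blast": hits}, reference)
            assigned = SegmentSet()
            for dom in result.domains:
                assigned = assigned.union(dom.segset)
            uncovered = uncovered_count(chain.extent, assigned)
            assert (result.status == "complete_automatic") == (
                uncovered == 0 and bool(result.domains)
            )

    def test_peptide_chain_is_nondomain(self):
        reference = make_reference_two_domain_chain()
        result = run_pipeline(query(20), {}, reference)
        assert result.status == "nondomain"
        assert result.special is SpecialCategory.PEPTIDE

    def test_mixed_blast_and_dali_sources_reach_completion(self):
        reference = make_reference_two_domain_chain()
        chain = QueryChain(chain_id="q1", sequence="A" * 100)
        hits_blast = [domain_hit(1e-12, 1, 50, "rd1")]
        hits_dali = [dali_hit(11.0, 51, 100, "rd1")]
        sequences = {"q1": "A" * 100, "rd1": "A" * 50, "rd2": "W" * 50}
        result = run_pipeline(
            chain,
            {"domain_blast": hits_blast, "dali": hits_dali},
            reference,
            sequences=sequences,
        )
        assert result.status == "complete_automatic"
        assert {d.source_method for d in result.domains} == {"domain_blast", "dali"}
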