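"""The iterative domain-partition pipeline.

Unclassified chains are partitioned by evidence of decreasing specificity:

1. **triage** — peptides, annotated coiled-coils, disordered and
   low-resolution chains are diverted to special categories before any
   assignment is attempted;
2. **chain pass** — BLAST against a library of known full-length chains;
   one significant, near-complete hit transfers the entire series of
   domains of the reference chain onto the query in a single pass;
3. **domain pass** — BLAST against the domain library; domains are accepted
   individually by E-value and coverage of the known target domain;
4. **profile pass** — HHsearch against representative domain profiles, for
   homologs beyond the reach of pairwise sequence comparison;
5. **boundary optimization** — small interstitial gaps between assigned
   domains and short terminal tails are absorbed into the flanking domains;
6. **structure pass** (only when sequence evidence leaves an unassigned
   region at least one domain long) — DALI hits gated by Z-score and by a
   BLOSUM column-score filter on the structure alignment.

A chain whose extent is 100% covered afterwards is complete and enters the
classification automatically; anything else is flagged for manual curation.
Thresholds printed in the method description (E-value < 2e-3, < 10 residues
uncovered, coverage > 80%) are strict inequalities, and the unpublished
gates (HHsearch probability, DALI Z, BLOSUM mean, gap size) are configurable
with conservative defaults — the probability gate is likewise strict, by
symmetry with the printed thresholds.

Every accept/reject decision is logged with the governing threshold so runs
are auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

from .hierarchy import Classification, Domain, SpecialCategory
from .ranges import SegmentSet, coverage_fraction, uncovered_count
from .search_io import Hit
from .structmetrics import blosum_column_score

__all__ = [
    "PipelineConfig",
    "QueryChain",
    "ProvisionalDomain",
    "PartitionResult",
    "PartitionError",
    "PartitionState",
    "triage_special",
    "chain_pass",
    "domain_pass",
    "profile_pass",
    "structure_pass",
    "optimize_boundaries",
    "run_pipeline",
    "reference_chain_index",
]


class PartitionError(ValueError):
    """Inconsistent pipeline input (unknown reference, bad alignment)."""


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds governing the pipeline, each on its documented scale.

    evalue_max:              BLAST E-value gate, strict ``<`` (2e-3 as printed).
    chain_pass_uncovered_max: query residues the chain-pass hit may leave
                             uncovered, strict ``<`` (10 as printed).
    domain_pass_coverage_min: fraction of the known target domain that must be
                             aligned, strict ``>`` (0.80 as printed).
    hh_prob_min:             HHsearch probability gate, percent scale, strict ``>``.
    dali_z_min:              DALI Z-score gate, ``>=``.
    blosum_score_min:        mean per-column BLOSUM62 score gate, ``>=``.
    gap_merge_max:           largest unassigned gap (residues) absorbed by
                             boundary optimization.
    min_domain_len:          smallest unassigned region worth a structure search.
    peptide_len_max:         chains shorter than this with no hit evidence are
                             triaged as peptides.
    overlap_tolerance:       residues by which an incoming hit may overlap
                             already-assigned regions (the overlap is trimmed).
    """

    evalue_max: float = 2e-3
    chain_pass_uncovered_max: int = 10
    domain_pass_coverage_min: float = 0.80
    hh_prob_min: float = 90.0
    dali_z_min: float = 8.0
    blosum_score_min: float = 0.0
    gap_merge_max: int = 30
    min_domain_len: int = 25
    peptide_len_max: int = 40
    overlap_tolerance: int = 5


@dataclass(frozen=True)
class QueryChain:
    chain_id: str
    sequence: str
    extent: Optional[SegmentSet] = None

    def __post_init__(self):
        if self.extent is None:
            object.__setattr__(
                self, "extent", SegmentSet.single(self.chain_id, 1, len(self.sequence))
            )
        for chain, start, end in self.extent.segments:
            if chain != self.chain_id or end > len(self.sequence):
                raise PartitionError(
                    f"extent segment {chain}:{start}-{end} outside sequence "
                    f"of chain {self.chain_id!r}"
                )


@dataclass
class ProvisionalDomain:
    segset: SegmentSet
    source_method: str
    source_hit: Optional[Hit]
    proposed_f_node: Optional[str] = None


@dataclass(frozen=True)
class DecisionRecord:
    step: str
    target_id: str
    accepted: bool
    reason: str


@dataclass
class PartitionResult:
    chain_id: str
    status: str  # complete_automatic | flagged_manual | nondomain
    domains: list[ProvisionalDomain]
    special: Optional[SpecialCategory]
    log: list[DecisionRecord]


@dataclass
class PartitionState:
    """Mutable per-chain pipeline state; domains stay pairwise disjoint."""

    chain: QueryChain
    config: PipelineConfig
    domains: list[ProvisionalDomain] = field(default_factory=list)
    log: list[DecisionRecord] = field(default_factory=list)

    @property
    def assigned(self) -> SegmentSet:
        out = SegmentSet()
        for dom in self.domains:
            out = out.union(dom.segset)
        return out

    @property
    def uncovered(self) -> int:
        return uncovered_count(self.chain.extent, self.assigned)

    def record(self, step: str, target: str, accepted: bool, reason: str) -> None:
        self.log.append(DecisionRecord(step, target, accepted, reason))


def reference_chain_index(reference: Classification) -> dict[str, list[Domain]]:
    """Map reference chain keys ``"<pdb>_<chain>"`` to their domains.

    A multi-chain domain contributes to every chain it spans.
    """
    index: dict[str, list[Domain]] = {}
    for uid in sorted(reference.domains):
        domain = reference.domains[uid]
        for chain in domain.segset.chains():
            index.setdefault(f"{domain.pdb_id}_{chain}", []).append(domain)
    return index


# ---------------------------------------------------------------------------
# Triage


def triage_special(
    chain: QueryChain,
    annotations: Optional[Mapping] = None,
    config: PipelineConfig = PipelineConfig(),
    has_hits: bool = False,
) -> Optional[SpecialCategory]:
    """Divert unclassifiable chains before any assignment is attempted.

    Coiled-coil and disorder calls come only from externally supplied
    annotations (a SegmentSet covering > 80% of the extent); low resolution
    is a boolean flag.  The peptide rule is internal: a chain shorter than
    ``peptide_len_max`` with no hit evidence cannot be meaningfully
    classified and is binned as a peptide.
    """
    annotations = annotations or {}
    extent = chain.extent
    for key, category in (
        ("coiled_coil", SpecialCategory.COILED_COIL),
        ("disordered", SpecialCategory.DISORDERED),
    ):
        region = annotations.get(key)
        if isinstance(region, SegmentSet) and region:
            if coverage_fraction(extent, region) > 0.8:
                return category
        elif region is True:
            return category
    if annotations.get("low_resolution"):
        return SpecialCategory.LOW_RESOLUTION
    if annotations.get("fragment"):
        return SpecialCategory.FRAGMENT
    if extent.size < config.peptide_len_max and not has_hits:
        return SpecialCategory.PEPTIDE
    return None


# ---------------------------------------------------------------------------
# Hit ordering and conflict handling


def _sort_by_evalue(hits: Iterable[Hit]) -> list[Hit]:
    # Deterministic: E-value, then longer query range, then target id.
    return sorted(
        hits,
        key=lambda h: (
            h.evalue if h.evalue is not None else float("inf"),
            -h.query_range.size,
            h.target_id,
        ),
    )


def _sort_by_probability(hits: Iterable[Hit]) -> list[Hit]:
    return sorted(
        hits,
        key=lambda h: (
            -(h.probability if h.probability is not None else -1.0),
            h.evalue if h.evalue is not None else float("inf"),
            -h.query_range.size,
            h.target_id,
        ),
    )


def _admit_range(state: PartitionState, step: str, hit: Hit) -> Optional[SegmentSet]:
    """Apply the overlap rule: small overlaps are trimmed, large ones reject."""
    assigned = state.assigned
    overlap = hit.query_range.intersection(assigned).size
    if overlap > state.config.overlap_tolerance:
        state.record(
            step,
            hit.target_id,
            False,
            f"overlap {overlap} residues with assigned regions exceeds "
            f"tolerance {state.config.overlap_tolerance}",
        )
        return None
    segset = hit.query_range.subtract(assigned)
    if segset.size == 0:
        state.record(step, hit.target_id, False, "hit entirely inside assigned regions")
        return None
    return segset


def _target_domain(reference: Classification, target_id: str) -> Optional[Domain]:
    return reference.domains.get(target_id)


# ---------------------------------------------------------------------------
# Passes


def chain_pass(
    state: PartitionState, hits: Sequence[Hit], reference: Classification
) -> PartitionState:
    """Whole-chain BLAST: transfer a complete reference architecture at once.

    The best hit with E-value below the gate that leaves fewer than
    ``chain_pass_uncovered_max`` query residues uncovered maps *every* domain
    of the reference chain onto the query through the alignment.
    """
    config = state.config
    index = reference_chain_index(reference)
    for hit in _sort_by_evalue(hits):
        if hit.evalue is None or not (hit.evalue < config.evalue_max):
            state.record(
                "chain_pass",
                hit.target_id,
                False,
                f"E-value {hit.evalue} not < {config.evalue_max}",
            )
            continue
        left_uncovered = uncovered_count(state.chain.extent, hit.query_range)
        if not (left_uncovered < config.chain_pass_uncovered_max):
            state.record(
                "chain_pass",
                hit.target_id,
                False,
                f"{left_uncovered} residues uncovered, not < "
                f"{config.chain_pass_uncovered_max}",
            )
            continue
        ref_domains = index.get(hit.target_id)
        if ref_domains is None:
            raise PartitionError(f"hit references unknown reference chain {hit.target_id!r}")
        ref_chain = hit.target_id.rsplit("_", 1)[1]
        for domain in ref_domains:
            mapped = SegmentSet.from_positions(
                (state.chain.chain_id, q)
                for q, t in hit.aligned_pairs
                if (ref_chain, t) in domain.segset
            )
            mapped = mapped.subtract(state.assigned)
            if mapped.size == 0:
                state.record(
                    "chain_pass",
                    domain.uid,
                    False,
                    "reference domain maps to no unassigned query residues",
                )
                continue
            state.domains.append(
                ProvisionalDomain(
                    segset=mapped,
                    source_method="chain_blast",
                    source_hit=hit,
                    proposed_f_node=domain.f_node,
                )
            )
            state.record(
                "chain_pass",
                domain.uid,
                True,
                f"architecture transfer, E-value {hit.evalue:g} < {config.evalue_max}, "
                f"{left_uncovered} uncovered < {config.chain_pass_uncovered_max}",
            )
        break  # only the best accepted chain hit partitions the query
    return state


def _iterative_hit_pass(
    state: PartitionState,
    hits: Sequence[Hit],
    reference: Classification,
    step: str,
    accept: Callable[[Hit], tuple[bool, str]],
) -> PartitionState:
    for hit in hits:
        ok, reason = accept(hit)
        if not ok:
            state.record(step, hit.target_id, False, reason)
            continue
        segset = _admit_range(state, step, hit)
        if segset is None:
            continue
        target = _target_domain(reference, hit.target_id)
        state.domains.append(
            ProvisionalDomain(
                segset=segset,
                source_method=hit.method,
                source_hit=hit,
                proposed_f_node=target.f_node if target is not None else None,
            )
        )
        state.record(step, hit.target_id, True, reason)
    return state


def _target_coverage(hit: Hit, reference: Classification) -> Optional[float]:
    """Aligned fraction of the known target domain's full length."""
    target = _target_domain(reference, hit.target_id)
    if target is None:
        return None
    aligned = len(hit.aligned_pairs)
    if aligned == 0:
        # Tabular hits without explicit pairs: use the query-range length.
        aligned = hit.query_range.size
    return min(aligned / target.segset.size, 1.0)


def domain_pass(
    state: PartitionState, hits: Sequence[Hit], reference: Classification
) -> PartitionState:
    """Per-domain BLAST: accept best non-conflicting hits one at a time."""
    config = state.config

    def accept(hit: Hit) -> tuple[bool, str]:
        if hit.evalue is None or not (hit.evalue < config.evalue_max):
            return False, f"E-value {hit.evalue} not < {config.evalue_max}"
        cov = _target_coverage(hit, reference)
        if cov is None:
            return False, f"unknown target domain {hit.target_id!r}"
        if not (cov > config.domain_pass_coverage_min):
            return False, (
                f"target coverage {cov:.3f} not > {config.domain_pass_coverage_min}"
            )
        return True, (
            f"E-value {hit.evalue:g} < {config.evalue_max}, coverage {cov:.3f} > "
            f"{config.domain_pass_coverage_min}"
        )

    return _iterative_hit_pass(state, _sort_by_evalue(hits), reference, "domain_pass", accept)


def profile_pass(
    state: PartitionState, hits: Sequence[Hit], reference: Classification
) -> PartitionState:
    """HHsearch profile hits, descending probability; same conflict rule."""
    config = state.config

    def accept(hit: Hit) -> tuple[bool, str]:
        if hit.probability is None or not (hit.probability > config.hh_prob_min):
            return False, (
                f"probability {hit.probability} not > {config.hh_prob_min}"
            )
        cov = _target_coverage(hit, reference)
        if cov is None:
            return False, f"unknown target domain {hit.target_id!r}"
        if not (cov > config.domain_pass_coverage_min):
            return False, (
                f"target coverage {cov:.3f} not > {config.domain_pass_coverage_min}"
            )
        return True, (
            f"probability {hit.probability:.2f} > {config.hh_prob_min}, "
            f"coverage {cov:.3f} > {config.domain_pass_coverage_min}"
        )

    return _iterative_hit_pass(
        state, _sort_by_probability(hits), reference, "profile_pass", accept
    )


def structure_pass(
    state: PartitionState,
    hits: Sequence[Hit],
    sequences: Mapping[str, str],
    reference: Classification,
) -> PartitionState:
    """DALI structure hits, gated by Z-score and a BLOSUM sequence filter.

    ``sequences`` must resolve both the query chain id and the reference
    target ids to amino-acid sequences so the alignment can be re-scored.
    """
    config = state.config
    qseq = sequences[state.chain.chain_id]

    def accept(hit: Hit) -> tuple[bool, str]:
        if hit.z_score is None or hit.z_score < config.dali_z_min:
            return False, f"Z-score {hit.z_score} below {config.dali_z_min}"
        tseq = sequences.get(hit.target_id)
        if tseq is None:
            return False, f"no sequence for target {hit.target_id!r}"
        for q, t in hit.aligned_pairs:
            if q > len(qseq) or t > len(tseq):
                raise PartitionError(
                    f"aligned pair ({q},{t}) outside sequences for "
                    f"{state.chain.chain_id}->{hit.target_id}"
                )
        mean_blosum = blosum_column_score(hit.aligned_pairs, qseq, tseq)
        if mean_blosum < config.blosum_score_min:
            return False, (
                f"mean BLOSUM {mean_blosum:.2f} below {config.blosum_score_min}"
            )
        return True, (
            f"Z {hit.z_score:.1f} >= {config.dali_z_min}, "
            f"mean BLOSUM {mean_blosum:.2f} >= {config.blosum_score_min}"
        )

    ordered = sorted(
        hits,
        key=lambda h: (
            -(h.z_score if h.z_score is not None else -1e9),
            -h.query_range.size,
            h.target_id,
        ),
    )
    return _iterative_hit_pass(state, ordered, reference, "structure_pass", accept)


# ---------------------------------------------------------------------------
# Boundary optimization


def _largest_gap(state: PartitionState) -> int:
    gaps = state.chain.extent.subtract(state.assigned)
    return max((end - start + 1 for _, start, end in gaps.segments), default=0)


def optimize_boundaries(state: PartitionState) -> PartitionState:
    """Absorb small unassigned gaps into the flanking domains.

    Each unassigned run of at most ``gap_merge_max`` residues strictly
    between two assigned regions is split residue-by-residue to the domain
    whose flanking boundary is nearer (ties go to the N-terminal neighbor);
    terminal runs of at most ``gap_merge_max`` join the terminal domain.
    Larger gaps are left untouched.  Domains remain pairwise disjoint.
    """
    if not state.domains:
        return state
    config = state.config
    for chain_id in state.chain.extent.chains():
        # Boundaries of assigned regions on this chain, owner-indexed.
        owners: list[tuple[int, int, ProvisionalDomain]] = []
        for dom in state.domains:
            for c, s, e in dom.segset.segments:
                if c == chain_id:
                    owners.append((s, e, dom))
        if not owners:
            continue
        owners.sort(key=lambda t: t[0])
        extent_span = state.chain.extent.span(chain_id)
        assert extent_span is not None
        lo, hi = extent_span
        additions: list[tuple[ProvisionalDomain, int, int]] = []
        # Terminal run before the first assigned region.
        first_s, _, first_dom = owners[0]
        if lo < first_s and (first_s - lo) <= config.gap_merge_max:
            additions.append((first_dom, lo, first_s - 1))
        # Terminal run after the last assigned region.
        _, last_e, last_dom = owners[-1]
        if hi > last_e and (hi - last_e) <= config.gap_merge_max:
            additions.append((last_dom, last_e + 1, hi))
        # Interstitial gaps.
        for (s1, e1, dom1), (s2, e2, dom2) in zip(owners, owners[1:]):
            gap_start, gap_end = e1 + 1, s2 - 1
            gap_len = gap_end - gap_start + 1
            if gap_len <= 0 or gap_len > config.gap_merge_max:
                continue
            if dom1 is dom2:
                additions.append((dom1, gap_start, gap_end))
                continue
            # Nearest flanking boundary wins; tie -> N-terminal neighbor.
            split = None
            for r in range(gap_start, gap_end + 1):
                if (r - e1) > (s2 - r):
                    split = r
                    break
            if split is None:
                additions.append((dom1, gap_start, gap_end))
            else:
                if split > gap_start:
                    additions.append((dom1, gap_start, split - 1))
                additions.append((dom2, split, gap_end))
        for dom, s, e in additions:
            dom.segset = dom.segset.union(SegmentSet.single(chain_id, s, e))
    return state


# ---------------------------------------------------------------------------
# Orchestration

HitProvider = Union[Sequence[Hit], Callable[[], Sequence[Hit]]]


def _resolve_provider(
    providers: Mapping[str, HitProvider], key: str, state: PartitionState
) -> Optional[list[Hit]]:
    provider = providers.get(key)
    if provider is None:
        return []
    if callable(provider):
        try:
            return list(provider())
        except Exception as exc:  # provider failure must never crash the run
            state.record(key, "<provider>", False, f"provider failure: {exc}")
            return None
    return list(provider)


def run_pipeline(
    chain: QueryChain,
    providers: Mapping[str, HitProvider],
    reference: Classification,
    config: Optional[PipelineConfig] = None,
    sequences: Optional[Mapping[str, str]] = None,
    annotations: Optional[Mapping] = None,
) -> PartitionResult:
    """Run the full triage/sequence/structure pipeline on one chain.

    ``providers`` maps method names (``chain_blast``, ``domain_blast``,
    ``hhsearch``, ``dali``) to hit lists or zero-argument callables; a
    callable that raises flags the chain for manual curation rather than
    crashing the run.  ``sequences`` (query chain id and reference target
    ids to sequences) is required only when the structure pass runs.
    """
    config = config or PipelineConfig()
    state = PartitionState(chain=chain, config=config)
    provider_failed = False

    resolved: dict[str, Optional[list[Hit]]] = {}
    for key in ("chain_blast", "domain_blast", "hhsearch", "dali"):
        resolved[key] = _resolve_provider(providers, key, state)
        if resolved[key] is None:
            provider_failed = True
    has_hits = any(resolved[k] for k in resolved)

    special = triage_special(chain, annotations, config, has_hits=has_hits)
    if special is not None:
        state.record("triage", chain.chain_id, True, f"special category {special.value}")
        return PartitionResult(
            chain_id=chain.chain_id,
            status="nondomain",
            domains=[],
            special=special,
            log=state.log,
        )

    if resolved["chain_blast"]:
        chain_pass(state, resolved["chain_blast"], reference)
    if state.uncovered > 0:
        if resolved["domain_blast"]:
            domain_pass(state, resolved["domain_blast"], reference)
        if resolved["hhsearch"]:
            profile_pass(state, resolved["hhsearch"], reference)
    optimize_boundaries(state)

    if (
        state.uncovered > 0
        and _largest_gap(state) >= config.min_domain_len
        and resolved["dali"]
    ):
        if sequences is None:
            state.record(
                "structure_pass", "<config>", False, "no sequence store supplied"
            )
        else:
            structure_pass(state, resolved["dali"], sequences, reference)
            optimize_boundaries(state)

    if provider_failed:
        status = "flagged_manual"
    elif state.uncovered == 0 and state.domains:
        status = "complete_automatic"
    else:
        status = "flagged_manual"
    state.record(
        "completeness",
        chain.chain_id,
        status == "complete_automatic",
        f"{state.uncovered} residues uncovered",
    )
    return PartitionResult(
        chain_id=chain.chain_id,
        status=status,
        domains=list(state.domains),
        special=None,
        log=state.log,
    )
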