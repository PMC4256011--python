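"""Synthetic fixture generator: a reference classification, query chains,
and internally consistent hit tables with ground truth.

The generator emulates the inputs of the partition pipeline so every stage
is testable offline: a reference hierarchy whose F-groups share a sequence
motif (within-family identity high, cross-family identity background), query
chains built by concatenating mutated copies of reference domains, and hit
files — chain/domain BLAST tabular, HHR, the DALI dialect, domtblout — whose
true hits pass the default pipeline thresholds by construction and whose
decoys are guaranteed to fail at least one.

Decoys are sampled *exactly at* the printed thresholds (E-value 2e-3,
coverage 0.80, 10 residues uncovered, probability 90.0) so that a
strict-versus-non-strict inequality bug anywhere in the pipeline surfaces as
a lineage error in recovery scoring rather than passing silently.

Sequences use the plain 20-letter alphabet with per-domain substitution
mutation and no indels (the pipeline consumes scores, not raw profile
searches, so realistic profile statistics are not attempted).  Coordinates
are not generated; structure-kernel tests use hand-built geometric toys.

Everything is deterministic: the same :class:`FixtureSpec` (including seed)
reproduces byte-identical fixture files.
"""

from __future__ import annotations

import datetime as _dt
import io
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

from .hierarchy import (
    Classification,
    Domain,
    SpecialCategory,
    add_lineage,
    classification_to_string,
)
from .fgroups import PairProbTable
from .ranges import SegmentSet
from .search_io import (
    Hit,
    write_blast_tabular,
    write_dali_rows,
    write_fasta,
    write_hhr,
    write_hmmer_domtblout,
)
from .partition import PartitionResult

__all__ = [
    "FixtureSpec",
    "Reference",
    "TrueDomain",
    "ChainTruth",
    "GroundTruth",
    "QueryFixture",
    "PartitionScore",
    "make_reference",
    "make_queries",
    "make_fixture",
    "partition_fixture",
    "score_partition",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

ARCHITECTURE_NAMES = (
    "beta barrels",
    "alpha bundles",
    "a+b two layers",
    "alpha arrays",
    "beta sandwiches",
    "a/b three-layered sandwiches",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic dataset.

    The defaults describe the standard recovery experiment: a reference of
    4x2x2x2x2 = 64 domains in 32 families, 100 query chains of 1-4 domains
    each, a tenth of chains carrying an at-threshold decoy hit and a tenth
    of true domains findable only by structure search.
    """

    seed: int = 0
    n_xgroups: int = 4
    h_per_x: int = 2
    t_per_h: int = 2
    f_per_t: int = 2
    domains_per_f: int = 2
    domain_len_range: tuple[int, int] = (40, 120)
    n_query_chains: int = 100
    domains_per_chain_range: tuple[int, int] = (1, 4)
    decoy_rate: float = 0.1
    dali_only_rate: float = 0.1
    hh_only_rate: float = 0.15
    peptide_rate: float = 0.0

    def __post_init__(self):
        for name in ("n_xgroups", "h_per_x", "t_per_h", "f_per_t",
                     "domains_per_f", "n_query_chains"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("decoy_rate", "dali_only_rate", "hh_only_rate", "peptide_rate"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.domain_len_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid domain_len_range")
        lo, hi = self.domains_per_chain_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid domains_per_chain_range")


@dataclass
class Reference:
    classification: Classification
    sequences: dict[str, str]  # domain uid AND "<pdb>_<chain>" key -> sequence
    prob_table: PairProbTable
    pfam_of_fgroup: dict[str, Optional[str]]  # f_id -> Pfam accession or None


@dataclass(frozen=True)
class TrueDomain:
    start: int
    end: int
    source_uid: str
    f_node: str
    route: str  # chain_blast | domain_blast | hhsearch | dali


@dataclass
class ChainTruth:
    chain_id: str
    sequence: str
    domains: list[TrueDomain]
    special: Optional[SpecialCategory] = None
    has_decoy: bool = False

    @property
    def expected_status(self) -> str:
        return "nondomain" if self.special is not None else "complete_automatic"


@dataclass
class GroundTruth:
    spec: FixtureSpec
    chains: dict[str, ChainTruth]


@dataclass
class QueryFixture:
    fasta: str
    chain_blast: str
    domain_blast: str
    hhr: dict[str, str]  # chain_id -> HHR text
    dali: str
    domtblout: str
    truth: GroundTruth
    hits: dict[str, dict[str, list[Hit]]]  # chain_id -> method -> hits

    def write_to(self, directory) -> dict[str, Path]:
        """Write all fixture files under ``directory``; returns the paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, text in (
            ("queries.fasta", self.fasta),
            ("chain_blast.tsv", self.chain_blast),
            ("domain_blast.tsv", self.domain_blast),
            ("dali.tsv", self.dali),
            ("pfam.domtbl", self.domtblout),
        ):
            path = directory / name
            path.write_text(text)
            paths[name] = path
        hh_dir = directory / "hh"
        hh_dir.mkdir(exist_ok=True)
        for chain_id, text in self.hhr.items():
            path = hh_dir / f"{chain_id}.hhr"
            path.write_text(text)
            paths[f"hh/{chain_id}.hhr"] = path
        return paths


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


def _mutate(rng: random.Random, seq: str, rate: float) -> str:
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append(rng.choice([a for a in AMINO_ACIDS if a != ch]))
        else:
            out.append(ch)
    return "".join(out)


def make_reference(spec: FixtureSpec) -> Reference:
    """Build the reference classification, sequence store and HH table.

    One domain per reference chain; the first domain of every family is its
    manual representative.  Within-family HHsearch probabilities are drawn
    in [92, 99.5] (above the clustering cutoff), cross-family pairs inside
    the same T-group in [10, 60] (safely below it).
    """
    rng = random.Random(spec.seed)
    classification = Classification(label="reference")
    sequences: dict[str, str] = {}
    prob = PairProbTable()
    pfam_of_fgroup: dict[str, Optional[str]] = {}
    uid_counter = 0
    pdb_counter = 0
    fgroup_members: dict[str, list[str]] = {}
    tgroup_fgroups: dict[str, list[str]] = {}

    for xi in range(spec.n_xgroups):
        a_name = ARCHITECTURE_NAMES[xi % len(ARCHITECTURE_NAMES)]
        for hi in range(spec.h_per_x):
            for ti in range(spec.t_per_h):
                t_id = f"{2001 + xi}.{hi + 1}.{ti + 1}"
                tgroup_fgroups[t_id] = []
                for fi in range(spec.f_per_t):
                    f_id = f"{t_id}.{fi + 1}"
                    add_lineage(classification, a_name, f_id)
                    tgroup_fgroups[t_id].append(f_id)
                    motif = _random_seq(
                        rng, rng.randint(*spec.domain_len_range)
                    )
                    pfam_of_fgroup[f_id] = (
                        f"PF{rng.randint(10000, 99999):05d}"
                        if rng.random() < 0.75
                        else None
                    )
                    members = []
                    for di in range(spec.domains_per_f):
                        uid = f"e{uid_counter:05d}"
                        uid_counter += 1
                        pdb = f"r{pdb_counter:03d}"
                        pdb_counter += 1
                        seq = _mutate(rng, motif, rng.uniform(0.01, 0.05))
                        date = _dt.date(2000, 1, 1) + _dt.timedelta(
                            days=rng.randint(0, 4900)
                        )
                        classification.add_domain(
                            Domain(
                                uid=uid,
                                pdb_id=pdb,
                                segset=SegmentSet.single("A", 1, len(seq)),
                                f_node=f_id,
                                rep_status="manual" if di == 0 else "auto",
                                deposition_date=date,
                            )
                        )
                        sequences[uid] = seq
                        sequences[f"{pdb}_A"] = seq
                        members.append(uid)
                    fgroup_members[f_id] = members
    # HH probabilities: dense within families, sparse background within T.
    for f_id, members in fgroup_members.items():
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                prob.set(a, b, round(rng.uniform(92.0, 99.5), 2))
    for t_id, f_ids in tgroup_fgroups.items():
        for i, fa in enumerate(f_ids):
            for fb in f_ids[i + 1 :]:
                for a in fgroup_members[fa]:
                    for b in fgroup_members[fb]:
                        prob.set(a, b, round(rng.uniform(10.0, 60.0), 2))
    return Reference(
        classification=classification,
        sequences=sequences,
        prob_table=prob,
        pfam_of_fgroup=pfam_of_fgroup,
    )


def _identity_percent(a: str, b: str) -> float:
    same = sum(1 for x, y in zip(a, b) if x == y)
    return 100.0 * same / max(len(a), 1)


def make_queries(reference: Reference, spec: FixtureSpec) -> QueryFixture:
    """Generate query chains and all hit files, with ground truth.

    Per true domain a route is drawn: structure-only (DALI table only, at
    ``dali_only_rate``), profile-only (HHR only, at ``hh_only_rate``), or
    sequence (domain BLAST plus a redundant HHR hit).  Single-domain
    sequence-route chains additionally receive a whole-chain BLAST hit.
    With probability ``decoy_rate`` a chain carries one decoy sampled
    exactly at a pipeline threshold (see module docstring).
    """
    rng = random.Random(spec.seed + 1)
    classification = reference.classification
    uids = sorted(classification.domains)
    nonspecial_uids = [u for u in uids if classification.domains[u].f_node]

    fasta: dict[str, str] = {}
    chain_blast_hits: list[Hit] = []
    domain_blast_hits: list[Hit] = []
    dali_hits: list[Hit] = []
    hmmer_hits: list[Hit] = []
    hhr_texts: dict[str, str] = {}
    per_chain_hits: dict[str, dict[str, list[Hit]]] = {}
    truth_chains: dict[str, ChainTruth] = {}

    def wrong_family_uid(avoid_f: str) -> str:
        candidates = [
            u for u in nonspecial_uids
            if classification.domains[u].f_node != avoid_f
        ]
        return rng.choice(candidates)

    for qi in range(spec.n_query_chains):
        chain_id = f"q{qi:03d}_A"
        if rng.random() < spec.peptide_rate:
            seq = _random_seq(rng, rng.randint(8, 35))
            fasta[chain_id] = seq
            truth_chains[chain_id] = ChainTruth(
                chain_id=chain_id,
                sequence=seq,
                domains=[],
                special=SpecialCategory.PEPTIDE,
            )
            per_chain_hits[chain_id] = {
                "chain_blast": [], "domain_blast": [], "hhsearch": [], "dali": []
            }
            hhr_texts[chain_id] = _render_hhr(chain_id, seq, [], reference)
            continue

        n_dom = rng.randint(*spec.domains_per_chain_range)
        sources = [rng.choice(nonspecial_uids) for _ in range(n_dom)]
        pieces: list[str] = []
        true_domains: list[TrueDomain] = []
        routes: list[str] = []
        pos = 1
        for uid in sources:
            source_seq = reference.sequences[uid]
            piece = _mutate(rng, source_seq, rng.uniform(0.02, 0.08))
            start, end = pos, pos + len(piece) - 1
            draw = rng.random()
            if draw < spec.dali_only_rate:
                route = "dali"
            elif draw < spec.dali_only_rate + spec.hh_only_rate:
                route = "hhsearch"
            else:
                route = "domain_blast"
            if n_dom == 1 and route == "domain_blast":
                route = "chain_blast"
            routes.append(route)
            true_domains.append(
                TrueDomain(
                    start=start,
                    end=end,
                    source_uid=uid,
                    f_node=classification.domains[uid].f_node,
                    route=route,
                )
            )
            pieces.append(piece)
            pos = end + 1
        sequence = "".join(pieces)
        fasta[chain_id] = sequence

        chain_hits: dict[str, list[Hit]] = {
            "chain_blast": [], "domain_blast": [], "hhsearch": [], "dali": []
        }
        for td, route in zip(true_domains, routes):
            source = classification.domains[td.source_uid]
            tlen = source.segset.size
            pairs = tuple((td.start + i, 1 + i) for i in range(tlen))
            identity = _identity_percent(
                sequence[td.start - 1 : td.end], reference.sequences[td.source_uid]
            )
            if route == "chain_blast":
                hit = Hit(
                    query_id=chain_id,
                    query_range=SegmentSet.single(chain_id, td.start, td.end),
                    target_id=f"{source.pdb_id}_A",
                    target_kind="chain",
                    method="chain_blast",
                    evalue=10 ** rng.uniform(-40.0, -10.0),
                    identity=identity,
                    aligned_pairs=pairs,
                )
                chain_hits["chain_blast"].append(hit)
            elif route == "dali":
                hit = Hit(
                    query_id=chain_id,
                    query_range=SegmentSet.single(chain_id, td.start, td.end),
                    target_id=td.source_uid,
                    target_kind="structure",
                    method="dali",
                    z_score=round(rng.uniform(8.5, 30.0), 1),
                    aligned_pairs=pairs,
                )
                chain_hits["dali"].append(hit)
            else:
                if route == "domain_blast":
                    hit = Hit(
                        query_id=chain_id,
                        query_range=SegmentSet.single(chain_id, td.start, td.end),
                        target_id=td.source_uid,
                        target_kind="domain",
                        method="domain_blast",
                        # strictly inside the printed gate (< 2e-3)
                        evalue=10 ** rng.uniform(-30.0, -3.0),
                        identity=identity,
                        aligned_pairs=pairs,
                    )
                    chain_hits["domain_blast"].append(hit)
                hh_hit = Hit(
                    query_id=chain_id,
                    query_range=SegmentSet.single(chain_id, td.start, td.end),
                    target_id=td.source_uid,
                    target_kind="profile",
                    method="hhsearch",
                    probability=round(rng.uniform(90.5, 99.9), 2),
                    evalue=10 ** rng.uniform(-30.0, -5.0),
                    identity=identity,
                    aligned_pairs=pairs,
                )
                chain_hits["hhsearch"].append(hh_hit)
            # Pfam evidence for the family, when it has an accession.
            accession = reference.pfam_of_fgroup.get(td.f_node)
            if accession is not None:
                hmmer_hits.append(
                    Hit(
                        query_id=chain_id,
                        query_range=SegmentSet.single(chain_id, td.start, td.end),
                        target_id=accession,
                        target_kind="profile",
                        method="hmmer",
                        evalue=10 ** rng.uniform(-40.0, -10.0),
                    )
                )

        has_decoy = False
        if rng.random() < spec.decoy_rate:
            has_decoy = _add_decoy(
                rng, chain_id, sequence, true_domains, routes, chain_hits,
                reference, wrong_family_uid,
            )

        chain_blast_hits.extend(chain_hits["chain_blast"])
        domain_blast_hits.extend(chain_hits["domain_blast"])
        dali_hits.extend(chain_hits["dali"])
        hhr_texts[chain_id] = _render_hhr(
            chain_id, sequence, chain_hits["hhsearch"], reference
        )
        per_chain_hits[chain_id] = chain_hits
        truth_chains[chain_id] = ChainTruth(
            chain_id=chain_id,
            sequence=sequence,
            domains=true_domains,
            has_decoy=has_decoy,
        )

    def _text(writer, hits):
        buf = io.StringIO()
        writer(hits, buf)
        return buf.getvalue()

    fasta_buf = io.StringIO()
    write_fasta(fasta, fasta_buf)
    return QueryFixture(
        fasta=fasta_buf.getvalue(),
        chain_blast=_text(write_blast_tabular, chain_blast_hits),
        domain_blast=_text(write_blast_tabular, domain_blast_hits),
        hhr=hhr_texts,
        dali=_text(write_dali_rows, dali_hits),
        domtblout=_text(write_hmmer_domtblout, hmmer_hits),
        truth=GroundTruth(spec=spec, chains=truth_chains),
        hits=per_chain_hits,
    )


def _render_hhr(chain_id: str, sequence: str, hits, reference: Reference) -> str:
    buf = io.StringIO()
    write_hhr(buf, chain_id, sequence, hits, reference.sequences)
    return buf.getvalue()


def _add_decoy(
    rng, chain_id, sequence, true_domains, routes, chain_hits, reference,
    wrong_family_uid,
) -> bool:
    """Attach one at-threshold decoy to this chain; returns True if added.

    Modes (all fail a strict default threshold *exactly at* the boundary):

    * ``evalue_exact`` — BLAST decoy at E = 2e-3 over a profile-only
      domain's span (a non-strict E gate would claim the region first);
    * ``prob_exact`` — HHR decoy at probability 90.0 over a structure-only
      domain's span (a non-strict probability gate claims it before DALI);
    * ``coverage_exact`` — BLAST decoy with E far below every true hit but
      target coverage exactly 0.80 (a non-strict coverage gate accepts it
      ahead of the true hit);
    * ``uncovered_exact`` — whole-chain BLAST decoy with the best E-value
      that leaves exactly 10 query residues uncovered.
    """
    classification = reference.classification
    modes = ["coverage_exact"]
    hh_doms = [td for td, r in zip(true_domains, routes) if r == "hhsearch"]
    dali_doms = [td for td, r in zip(true_domains, routes) if r == "dali"]
    if hh_doms:
        modes.append("evalue_exact")
    if dali_doms:
        modes.append("prob_exact")
    if chain_hits["chain_blast"]:
        modes.append("uncovered_exact")
    mode = rng.choice(modes)

    if mode == "coverage_exact":
        td = rng.choice(true_domains)
        available = len(sequence) - td.start + 1
        # need a wrong-family target whose length is divisible by 5 so that
        # an alignment of 4/5 of it gives coverage == 0.80 exactly
        viable = [
            u for u in sorted(classification.domains)
            if classification.domains[u].f_node
            and classification.domains[u].f_node != td.f_node
            and classification.domains[u].segset.size % 5 == 0
            and (classification.domains[u].segset.size * 4) // 5 <= available
        ]
        if not viable:
            return False
        wrong = rng.choice(viable)
        tlen = classification.domains[wrong].segset.size
        aligned = (tlen * 4) // 5  # coverage exactly 0.80
        pairs = tuple((td.start + i, 1 + i) for i in range(aligned))
        chain_hits["domain_blast"].append(
            Hit(
                query_id=chain_id,
                query_range=SegmentSet.single(chain_id, td.start, td.start + aligned - 1),
                target_id=wrong,
                target_kind="domain",
                method="domain_blast",
                evalue=1e-60,  # sorts ahead of every true hit
                identity=30.0,
                aligned_pairs=pairs,
            )
        )
        return True

    if mode == "evalue_exact":
        td = rng.choice(hh_doms)
        wrong = wrong_family_uid(td.f_node)
        tlen = classification.domains[wrong].segset.size
        aligned = min(tlen, td.end - td.start + 1)
        pairs = tuple((td.start + i, 1 + i) for i in range(aligned))
        chain_hits["domain_blast"].append(
            Hit(
                query_id=chain_id,
                query_range=SegmentSet.single(chain_id, td.start, td.start + aligned - 1),
                target_id=wrong,
                target_kind="domain",
                method="domain_blast",
                evalue=2e-3,  # exactly at the printed gate -> must be rejected
                identity=25.0,
                aligned_pairs=pairs,
            )
        )
        return True

    if mode == "prob_exact":
        td = rng.choice(dali_doms)
        wrong = wrong_family_uid(td.f_node)
        tlen = classification.domains[wrong].segset.size
        aligned = min(tlen, td.end - td.start + 1)
        pairs = tuple((td.start + i, 1 + i) for i in range(aligned))
        chain_hits["hhsearch"].append(
            Hit(
                query_id=chain_id,
                query_range=SegmentSet.single(chain_id, td.start, td.start + aligned - 1),
                target_id=wrong,
                target_kind="profile",
                method="hhsearch",
                probability=90.0,  # exactly at the gate -> must be rejected
                evalue=1e-10,
                identity=20.0,
                aligned_pairs=pairs,
            )
        )
        return True

    # uncovered_exact: chain decoy leaving exactly 10 residues uncovered
    td = true_domains[0]
    if len(sequence) <= 11:
        return False
    wrong = wrong_family_uid(td.f_node)
    wrong_dom = classification.domains[wrong]
    span = len(sequence) - 10
    aligned = min(span, wrong_dom.segset.size)
    if len(sequence) - aligned != 10:
        return False
    pairs = tuple((1 + i, 1 + i) for i in range(aligned))
    chain_hits["chain_blast"].append(
        Hit(
            query_id=chain_id,
            query_range=SegmentSet.single(chain_id, 1, aligned),
            target_id=f"{wrong_dom.pdb_id}_A",
            target_kind="chain",
            method="chain_blast",
            evalue=1e-70,  # best E-value, but 10 uncovered -> rejected
            identity=28.0,
            aligned_pairs=pairs,
        )
    )
    return True


def make_fixture(spec: FixtureSpec) -> tuple[Reference, QueryFixture]:
    reference = make_reference(spec)
    return reference, make_queries(reference, spec)


# ---------------------------------------------------------------------------
# Recovery scoring


@dataclass
class PartitionScore:
    boundary_exactness: float
    lineage_accuracy: float
    status_accuracy: float
    status_confusion: dict[tuple[str, str], int]
    n_chains: int
    n_true_boundaries: int
    n_scored_domains: int


def score_partition(
    results: Mapping[str, PartitionResult],
    truth: GroundTruth,
    boundary_tolerance: int = 0,
) -> PartitionScore:
    """Compare pipeline output against generator ground truth.

    Boundary exactness is the fraction of true domain boundaries reproduced
    by some predicted boundary within ±``boundary_tolerance`` residues;
    lineage accuracy is the fraction of predicted domains whose proposed
    family matches the overlapping true domain's family.
    """
    n_boundaries = 0
    matched_boundaries = 0
    n_scored = 0
    correct_lineage = 0
    confusion: dict[tuple[str, str], int] = {}
    correct_status = 0

    for chain_id, chain_truth in truth.chains.items():
        result = results.get(chain_id)
        expected = chain_truth.expected_status
        got = result.status if result is not None else "<missing>"
        confusion[(expected, got)] = confusion.get((expected, got), 0) + 1
        if expected == got:
            correct_status += 1
        if result is None:
            n_boundaries += 2 * len(chain_truth.domains)
            continue
        predicted_boundaries: set[int] = set()
        for dom in result.domains:
            for _, s, e in dom.segset.segments:
                predicted_boundaries.update((s, e))
        for td in chain_truth.domains:
            for boundary in (td.start, td.end):
                n_boundaries += 1
                if any(
                    abs(boundary - p) <= boundary_tolerance
                    for p in predicted_boundaries
                ):
                    matched_boundaries += 1
        for dom in result.domains:
            if dom.proposed_f_node is None:
                continue
            best_td, best_overlap = None, 0
            for td in chain_truth.domains:
                overlap = dom.segset.intersection(
                    SegmentSet.single(chain_id, td.start, td.end)
                ).size
                if overlap > best_overlap:
                    best_td, best_overlap = td, overlap
            if best_td is None:
                continue
            n_scored += 1
            if dom.proposed_f_node == best_td.f_node:
                correct_lineage += 1

    return PartitionScore(
        boundary_exactness=(
            matched_boundaries / n_boundaries if n_boundaries else 1.0
        ),
        lineage_accuracy=correct_lineage / n_scored if n_scored else 1.0,
        status_accuracy=correct_status / len(truth.chains) if truth.chains else 1.0,
        status_confusion=confusion,
        n_chains=len(truth.chains),
        n_true_boundaries=n_boundaries,
        n_scored_domains=n_scored,
    )


def reference_to_tsv(reference: Reference) -> str:
    """The reference classification in the domain-table dialect."""
    return classification_to_string(reference.classification)


def partition_fixture(
    reference: Reference,
    queries: QueryFixture,
    config=None,
    parse_files: bool = True,
) -> dict[str, PartitionResult]:
    """Run the partition pipeline over every chain of a query fixture.

    With ``parse_files=True`` (the default) the hit evidence is re-read from
    the rendered fixture *files* — exercising every parser on every run —
    rather than taken from the in-memory hit lists.
    """
    from .partition import QueryChain, run_pipeline
    from .search_io import parse_blast_tabular, parse_dali_rows, parse_hhr

    if parse_files:
        def group(hits):
            grouped: dict[str, list[Hit]] = {}
            for hit in hits:
                grouped.setdefault(hit.query_id, []).append(hit)
            return grouped

        chain_hits = group(parse_blast_tabular(queries.chain_blast, method="chain_blast"))
        domain_hits = group(parse_blast_tabular(queries.domain_blast, method="domain_blast"))
        hh_hits = {cid: parse_hhr(text) for cid, text in queries.hhr.items()}
        dali_hits = group(parse_dali_rows(queries.dali))
    else:
        chain_hits = {c: h["chain_blast"] for c, h in queries.hits.items()}
        domain_hits = {c: h["domain_blast"] for c, h in queries.hits.items()}
        hh_hits = {c: h["hhsearch"] for c, h in queries.hits.items()}
        dali_hits = {c: h["dali"] for c, h in queries.hits.items()}

    sequences = dict(reference.sequences)
    results: dict[str, PartitionResult] = {}
    for chain_id, chain_truth in queries.truth.chains.items():
        sequences[chain_id] = chain_truth.sequence
        results[chain_id] = run_pipeline(
            QueryChain(chain_id=chain_id, sequence=chain_truth.sequence),
            {
                "chain_blast": chain_hits.get(chain_id, []),
                "domain_blast": domain_hits.get(chain_id, []),
                "hhsearch": hh_hits.get(chain_id, []),
                "dali": dali_hits.get(chain_id, []),
            },
            reference.classification,
            config=config,
            sequences=sequences,
        )
    return results
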