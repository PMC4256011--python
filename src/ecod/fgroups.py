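"""Family (F-group) assignment and redundancy filtering.

Families are the sequence-similarity level of the hierarchy.  Assignment is
two-tiered: domains with a confident Pfam match (HMMER3 i-Evalue below the
gate, envelope covering at least half the domain) take the Pfam accession as
their family; the remainder are clustered by all-versus-all HHsearch
probability with *complete linkage* — a family is a set of domains in which
every pair shares at least the probability cutoff (90% by default).

Each family carries exactly one representative: a manually curated member
when one exists, otherwise a *provisional* representative — the member with
the highest mean within-group probability — is designated for later manual
examination.

The redundancy filter emulates BLASTCLUST-style clustering: greedy
single-linkage over pairs meeting BOTH a sequence-identity threshold (95%)
and a length-coverage threshold (90%, required of both sequences), keeping
the longest member of each cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .hierarchy import Domain
from .ranges import coverage_fraction
from .search_io import Hit

__all__ = [
    "FGroupError",
    "PairProbTable",
    "FGroupRecord",
    "assign_pfam",
    "hh_complete_linkage",
    "designate_representatives",
    "assign_fgroups",
    "redundancy_filter",
]


class FGroupError(ValueError):
    """Asymmetric probability table or inconsistent clustering input."""


class PairProbTable:
    """Symmetric (uid, uid) -> HHsearch probability (percent) mapping."""

    def __init__(self, pairs: Optional[Mapping[tuple[str, str], float]] = None):
        self._probs: dict[tuple[str, str], float] = {}
        if pairs:
            for (a, b), p in pairs.items():
                self.set(a, b, p)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, prob: float) -> None:
        if a == b:
            if prob != 100.0:
                raise FGroupError(f"diagonal entry for {a!r} must be 100, got {prob}")
            return
        key = self._key(a, b)
        existing = self._probs.get(key)
        if existing is not None and existing != prob:
            raise FGroupError(
                f"asymmetric table: ({a},{b}) given as both {existing} and {prob}"
            )
        self._probs[key] = float(prob)

    def get(self, a: str, b: str, default: float = 0.0) -> float:
        if a == b:
            return 100.0
        return self._probs.get(self._key(a, b), default)

    def items(self):
        return self._probs.items()

    def __len__(self) -> int:
        return len(self._probs)


@dataclass
class FGroupRecord:
    f_label: str
    origin: str  # pfam | hh_cluster | unclustered
    representative_uid: Optional[str] = None
    rep_kind: Optional[str] = None  # manual | provisional


def assign_pfam(
    domains: Mapping[str, Domain],
    hmmer_hits: Sequence[Hit],
    evalue_max: float = 1e-3,
    coverage_min: float = 0.5,
) -> dict[str, FGroupRecord]:
    """Confident Pfam assignments: best i-Evalue wins, ties by accession.

    A hit counts only if its envelope covers at least ``coverage_min`` of
    the domain and its i-Evalue is at most ``evalue_max``.  Domains without
    such a hit are left out of the returned mapping.
    """
    best: dict[str, tuple[float, str]] = {}
    for hit in hmmer_hits:
        domain = domains.get(hit.query_id)
        if domain is None or hit.evalue is None or hit.evalue > evalue_max:
            continue
        # Envelope coordinates live on the domain's chain(s).
        envelope = hit.query_range
        cov = 0.0
        for chain in domain.segset.chains():
            remapped = type(envelope)(
                [(chain, s, e) for _, s, e in envelope.segments]
            )
            cov = max(cov, coverage_fraction(domain.segset, remapped))
        if cov < coverage_min:
            continue
        key = (hit.evalue, hit.target_id)
        if hit.query_id not in best or key < best[hit.query_id]:
            best[hit.query_id] = key
    return {
        uid: FGroupRecord(f_label=acc, origin="pfam") for uid, (_, acc) in best.items()
    }


def hh_complete_linkage(
    uids: Iterable[str], probs: PairProbTable, cutoff: float = 90.0
) -> list[tuple[str, ...]]:
    """Complete-linkage clusters: every within-cluster pair >= cutoff.

    Deterministic greedy agglomeration: candidate pairs are processed by
    descending probability (ties broken lexicographically) and two clusters
    merge only if the union remains a >=cutoff clique.  Output clusters are
    sorted internally and by first member.
    """
    uids = sorted(set(uids))
    cluster_of: dict[str, int] = {u: i for i, u in enumerate(uids)}
    members: dict[int, list[str]] = {i: [u] for i, u in enumerate(uids)}
    candidates = [
        (p, a, b)
        for (a, b), p in probs.items()
        if p >= cutoff and a in cluster_of and b in cluster_of
    ]
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    for _p, a, b in candidates:
        ca, cb = cluster_of[a], cluster_of[b]
        if ca == cb:
            continue
        if all(
            probs.get(x, y) >= cutoff for x in members[ca] for y in members[cb]
        ):
            for member in members[cb]:
                cluster_of[member] = ca
            members[ca].extend(members.pop(cb))
    clusters = [tuple(sorted(group)) for group in members.values()]
    clusters.sort()
    return clusters


def designate_representatives(
    assignment: Mapping[str, FGroupRecord],
    manual_reps: Iterable[str],
    probs: Optional[PairProbTable] = None,
) -> dict[str, FGroupRecord]:
    """Choose one representative per F-group.

    Groups containing a manually curated representative use it (the
    lexicographically first if several qualify); in groups with none, the
    member with the highest mean within-group probability becomes the
    provisional representative (ties lexicographic; singletons represent
    themselves).
    """
    manual = set(manual_reps)
    probs = probs or PairProbTable()
    groups: dict[str, list[str]] = {}
    for uid, record in assignment.items():
        groups.setdefault(record.f_label, []).append(uid)
    out: dict[str, FGroupRecord] = {}
    for f_label, group in groups.items():
        group = sorted(group)
        manual_members = [u for u in group if u in manual]
        if manual_members:
            rep, kind = manual_members[0], "manual"
        elif len(group) == 1:
            rep, kind = group[0], "provisional"
        else:
            def mean_prob(u: str) -> float:
                return sum(probs.get(u, v) for v in group if v != u) / (len(group) - 1)

            rep = min(group, key=lambda u: (-mean_prob(u), u))
            kind = "provisional"
        for uid in group:
            old = assignment[uid]
            out[uid] = FGroupRecord(
                f_label=old.f_label,
                origin=old.origin,
                representative_uid=rep,
                rep_kind=kind,
            )
    return out


def assign_fgroups(
    domains: Mapping[str, Domain],
    hmmer_hits: Sequence[Hit],
    probs: PairProbTable,
    manual_reps: Iterable[str] = (),
    pfam_evalue_max: float = 1e-3,
    hh_cutoff: float = 90.0,
) -> dict[str, FGroupRecord]:
    """Full family assignment: Pfam first, HH clustering for the rest."""
    assignment = assign_pfam(domains, hmmer_hits, evalue_max=pfam_evalue_max)
    leftover = [uid for uid in sorted(domains) if uid not in assignment]
    clusters = hh_complete_linkage(leftover, probs, cutoff=hh_cutoff)
    cluster_idx = 0
    for cluster in clusters:
        if len(cluster) == 1:
            uid = cluster[0]
            has_link = any(probs.get(uid, other) > 0.0 for other in domains if other != uid)
            origin = "hh_cluster" if has_link else "unclustered"
            label = f"HH.{cluster_idx + 1}" if origin == "hh_cluster" else f"UC.{uid}"
        else:
            origin = "hh_cluster"
            label = f"HH.{cluster_idx + 1}"
        if origin == "hh_cluster":
            cluster_idx += 1
        for uid in cluster:
            assignment[uid] = FGroupRecord(f_label=label, origin=origin)
    return designate_representatives(assignment, manual_reps, probs)


@dataclass(frozen=True)
class PairSimilarity:
    """Pairwise identity (percent) and per-sequence length coverage (percent)."""

    identity: float
    coverage_a: float
    coverage_b: float


def redundancy_filter(
    domains: Mapping[str, Domain],
    similarities: Mapping[tuple[str, str], PairSimilarity],
    id_min: float = 95.0,
    len_cov_min: float = 90.0,
) -> tuple[list[str], list[tuple[str, ...]]]:
    """Greedy single-linkage redundancy clustering (BLASTCLUST emulation).

    A pair is linked iff identity >= ``id_min`` AND the alignment covers at
    least ``len_cov_min`` percent of *both* sequences.  Clusters are the
    connected components; the longest member (ties lexicographic) represents
    each.  The result is invariant to input order (canonical sort first).

    Returns (sorted representative uids, clusters sorted by first member).
    """
    graph = nx.Graph()
    graph.add_nodes_from(sorted(domains))
    for (a, b), sim in sorted(similarities.items()):
        if a not in domains or b not in domains or a == b:
            continue
        if (
            sim.identity >= id_min
            and sim.coverage_a >= len_cov_min
            and sim.coverage_b >= len_cov_min
        ):
            graph.add_edge(a, b)
    clusters = []
    reps = []
    for component in nx.connected_components(graph):
        group = tuple(sorted(component))
        rep = min(group, key=lambda u: (-domains[u].segset.size, u))
        clusters.append(group)
        reps.append(rep)
    order = sorted(range(len(clusters)), key=lambda i: clusters[i])
    return sorted(reps), [clusters[i] for i in order]
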