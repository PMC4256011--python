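"""Placement of accepted domains into the hierarchy.

Two distinct mechanisms live here:

* the **four-case placement rule** used after manual homology assessment:
  a homologous hit with the same topology pulls the query into the hit's
  T-group; a homologous hit with a different topology opens a new T-group
  inside the hit's H-group; a merely *possible* homolog opens a new H-group
  inside the hit's X-group; and with no possible homolog at all the query
  founds a new X-group of its own;
* **alignment transfer**, which maps a non-representative sequence onto an
  already-classified representative domain and copies its lineage, with the
  boundaries carried through the alignment.

The homology verdict itself (homolog vs possible homolog vs none, and
whether topologies match) is an *input*: it rests on score inspection,
functional similarity, shared unusual structural features and literature —
judgment, not computation — so this module only mechanizes what follows
from the verdict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .hierarchy import Classification, Domain, GroupNode, Level, add_lineage
from .ranges import SegmentSet
from .search_io import Hit

__all__ = [
    "PlacementError",
    "PlacementEvidence",
    "PlacementDecision",
    "decide_placement",
    "allocate_node_id",
    "transfer_by_alignment",
    "VERDICTS",
]

VERDICTS = (
    "homolog_same_topology",
    "homolog_diff_topology",
    "possible_homolog",
    "none",
)


class PlacementError(ValueError):
    """Inconsistent placement evidence or a failed alignment transfer."""


@dataclass(frozen=True)
class PlacementEvidence:
    """Curated verdict about the best hit of a query domain."""

    homology_verdict: str
    best_hit: Optional[Hit] = None
    hit_lineage: Optional[tuple[str, str, str, str]] = None  # (X, H, T, F) node ids
    notes: str = ""  # free-text evidence (cofactors, disulfides, literature)

    def __post_init__(self):
        if self.homology_verdict not in VERDICTS:
            raise PlacementError(f"unknown verdict {self.homology_verdict!r}")
        if self.homology_verdict != "none" and (
            self.best_hit is None or self.hit_lineage is None
        ):
            raise PlacementError(
                f"verdict {self.homology_verdict!r} requires a hit and its lineage"
            )


@dataclass(frozen=True)
class PlacementDecision:
    action: str  # join_T | new_T_in_H | new_H_in_X | new_X
    target_node: Optional[str]


def decide_placement(evidence: PlacementEvidence) -> PlacementDecision:
    """The four-case rule; total over the verdict domain."""
    verdict = evidence.homology_verdict
    if verdict == "none":
        return PlacementDecision(action="new_X", target_node=None)
    x_id, h_id, t_id, _f_id = evidence.hit_lineage
    if verdict == "homolog_same_topology":
        return PlacementDecision(action="join_T", target_node=t_id)
    if verdict == "homolog_diff_topology":
        return PlacementDecision(action="new_T_in_H", target_node=h_id)
    if verdict == "possible_homolog":
        return PlacementDecision(action="new_H_in_X", target_node=x_id)
    raise AssertionError(f"unhandled verdict {verdict!r}")  # pragma: no cover


def allocate_node_id(classification: Classification, parent_id: Optional[str]) -> str:
    """Next free integer child id under ``parent_id`` (top-level X if None)."""
    if parent_id is None:
        existing = [
            int(n.node_id)
            for n in classification.nodes.values()
            if n.level is Level.X and n.node_id.isdigit()
        ]
        return str(max(existing, default=2000) + 1)
    prefix = parent_id + "."
    existing = [
        int(n.node_id[len(prefix) :])
        for n in classification.nodes.values()
        if n.node_id.startswith(prefix)
        and n.node_id[len(prefix) :].isdigit()
        and classification.nodes[parent_id].level.depth + 1 == n.level.depth
    ]
    return prefix + str(max(existing, default=0) + 1)


def transfer_by_alignment(
    nonrep_chain_id: str,
    nonrep_seq: str,
    rep_domain: Domain,
    alignment: Sequence[tuple[int, int]],
    uid: str,
    pdb_id: str,
    min_coverage: float = 0.70,
) -> Domain:
    """Map a close relative onto a representative and copy its lineage.

    ``alignment`` pairs (nonrep_pos, rep_pos) must cover at least
    ``min_coverage`` of the representative domain, otherwise the candidate
    is rejected for manual handling.  The mapped boundary is the contiguous
    span of non-representative positions aligned inside the domain, so
    insertions in the new sequence lengthen the domain and unmapped
    representative edges are truncated.
    """
    rep_positions = [
        (q, t)
        for q, t in alignment
        if any((c, t) in rep_domain.segset for c in rep_domain.segset.chains())
    ]
    covered = len({t for _, t in rep_positions})
    coverage = covered / rep_domain.segset.size
    if coverage < min_coverage:
        raise PlacementError(
            f"alignment covers {coverage:.2f} of representative "
            f"{rep_domain.uid}, below floor {min_coverage:.2f}"
        )
    qpos = [q for q, _ in rep_positions]
    lo, hi = min(qpos), max(qpos)
    if hi > len(nonrep_seq):
        raise PlacementError("alignment extends past the new sequence")
    return Domain(
        uid=uid,
        pdb_id=pdb_id,
        segset=SegmentSet.single(nonrep_chain_id, lo, hi),
        f_node=rep_domain.f_node,
        special=rep_domain.special,
        rep_status="auto",
        assembly="none",
        deposition_date=None,
    )
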