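"""The five-level evolutionary hierarchy (A/X/H/T/F) and its on-disk table.

Domains are grouped, from the top down, by architecture (A: secondary-structure
composition and shape), possible homology (X: structural similarity where
homology cannot be excluded), homology (H: common ancestry), topology (T:
connectivity within a homologous set), and family (F: significant sequence
similarity).  Entries for which evolutionary classification is not currently
meaningful — peptides, coiled-coils, fragments, largely disordered or
low-resolution structures, and non-peptide polymers — live in *special
architectures* and carry no X/H/T/F lineage.

Group nodes are identified by dotted-integer paths under their architecture
label: X ``"2001"``, H ``"2001.1"``, T ``"2001.1.1"``, F ``"2001.1.1.4"``.
Architecture nodes are identified by their name.  Architecture membership is
input data, never inferred (the boundary between architectures is partly
subjective); the ordering of X-groups inside an architecture by structural
similarity is likewise stored as an optional rank, not computed.

The on-disk representation is a TSV with one row per domain::

    uid  pdb  range  a_name  x_id  h_id  t_id  f_id  rep_status  assembly  deposition_date  special

Group nodes are implied by the domain rows, which makes write -> load a
bit-exact round trip on canonical tables.
"""

from __future__ import annotations

import datetime as _dt
import enum
import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, TextIO, Union

from .ranges import SegmentSet, SegmentError

__all__ = [
    "Level",
    "SpecialCategory",
    "GroupNode",
    "Domain",
    "Classification",
    "ClassificationError",
    "load_classification",
    "write_classification",
    "lineage",
    "level_populations",
    "validate_classification",
]

TSV_COLUMNS = (
    "uid",
    "pdb",
    "range",
    "a_name",
    "x_id",
    "h_id",
    "t_id",
    "f_id",
    "rep_status",
    "assembly",
    "deposition_date",
    "special",
)


class ClassificationError(ValueError):
    """Violation of a hierarchy invariant or a malformed domain table."""


class Level(enum.Enum):
    """Hierarchy levels, strictly ordered A > X > H > T > F.

    SPECIAL is a pseudo-level for the unclassifiable bins; it has no children.
    """

    A = "A"
    X = "X"
    H = "H"
    T = "T"
    F = "F"
    SPECIAL = "SPECIAL"

    @property
    def depth(self) -> int:
        return {"A": 0, "X": 1, "H": 2, "T": 3, "F": 4}.get(self.value, -1)


# Number of dotted components in a node_id for each sub-architecture level.
_DEPTH_TO_LEVEL = {1: Level.X, 2: Level.H, 3: Level.T, 4: Level.F}


class SpecialCategory(enum.Enum):
    PEPTIDE = "peptide"
    COILED_COIL = "coiled_coil"
    FRAGMENT = "fragment"
    DISORDERED = "disordered"
    LOW_RESOLUTION = "low_resolution"
    NONPEPTIDE_POLYMER = "nonpeptide_polymer"


@dataclass(frozen=True)
class GroupNode:
    node_id: str
    level: Level
    name: str = ""
    parent: Optional[str] = None  # None only for architecture roots
    rank: Optional[int] = None  # optional within-architecture ordering

    def __post_init__(self):
        if self.level is Level.A:
            if self.parent is not None:
                raise ClassificationError(
                    f"architecture node {self.node_id!r} cannot have a parent"
                )
        elif self.level in _DEPTH_TO_LEVEL.values():
            depth = len(self.node_id.split("."))
            if _DEPTH_TO_LEVEL.get(depth) is not self.level:
                raise ClassificationError(
                    f"node {self.node_id!r} has depth {depth}, "
                    f"inconsistent with level {self.level.value}"
                )


@dataclass(frozen=True)
class Domain:
    """A classified domain: residue segments plus a leaf position.

    A non-special domain points at its F-node; a special domain carries a
    :class:`SpecialCategory` instead and has no lineage.
    """

    uid: str
    pdb_id: str
    segset: SegmentSet
    f_node: Optional[str] = None
    special: Optional[SpecialCategory] = None
    rep_status: str = "auto"  # manual | provisional | auto
    assembly: str = "none"  # none | order_dependent | order_independent
    deposition_date: Optional[_dt.date] = None

    def __post_init__(self):
        if self.segset.size == 0:
            raise ClassificationError(f"domain {self.uid!r} has an empty segment set")
        if (self.f_node is None) == (self.special is None):
            raise ClassificationError(
                f"domain {self.uid!r} must have exactly one of f_node / special"
            )
        if self.rep_status not in ("manual", "provisional", "auto"):
            raise ClassificationError(
                f"domain {self.uid!r}: unknown rep_status {self.rep_status!r}"
            )
        if self.assembly not in ("none", "order_dependent", "order_independent"):
            raise ClassificationError(
                f"domain {self.uid!r}: unknown assembly {self.assembly!r}"
            )


@dataclass
class Classification:
    """A set of group nodes plus domain leaves, with all invariants enforced."""

    label: str = ""
    nodes: dict[str, GroupNode] = field(default_factory=dict)
    domains: dict[str, Domain] = field(default_factory=dict)

    def add_node(self, node: GroupNode) -> None:
        existing = self.nodes.get(node.node_id)
        if existing is not None:
            if existing.level is not node.level:
                raise ClassificationError(
                    f"node {node.node_id!r} redefined at a different level"
                )
            return
        if node.parent is not None and node.parent not in self.nodes:
            raise ClassificationError(
                f"node {node.node_id!r} references missing parent {node.parent!r}"
            )
        if node.parent is not None:
            parent = self.nodes[node.parent]
            if parent.level.depth != node.level.depth - 1:
                raise ClassificationError(
                    f"node {node.node_id!r} ({node.level.value}) under "
                    f"{node.parent!r} ({parent.level.value}): levels not adjacent"
                )
        self.nodes[node.node_id] = node

    def add_domain(self, domain: Domain) -> None:
        if domain.uid in self.domains:
            raise ClassificationError(f"duplicate domain uid {domain.uid!r}")
        if domain.f_node is not None:
            node = self.nodes.get(domain.f_node)
            if node is None:
                raise ClassificationError(
                    f"domain {domain.uid!r} references missing F-node {domain.f_node!r}"
                )
            if node.level is not Level.F:
                raise ClassificationError(
                    f"domain {domain.uid!r} attached to non-F node {domain.f_node!r}"
                )
        self.domains[domain.uid] = domain

    def node(self, node_id: str) -> GroupNode:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise ClassificationError(f"unknown node {node_id!r}") from None

    def ancestor_at(self, uid: str, level: Level) -> Optional[str]:
        """node_id of the domain's ancestor at ``level`` (None for specials)."""
        domain = self.domains.get(uid)
        if domain is None:
            raise ClassificationError(f"unknown domain uid {uid!r}")
        if domain.f_node is None:
            return None
        node = self.node(domain.f_node)
        while node.level is not level:
            if node.parent is None:
                return None
            node = self.node(node.parent)
        return node.node_id


def add_lineage(
    classification: Classification,
    a_name: str,
    f_id: str,
    names: Mapping[str, str] | None = None,
    rank: Optional[int] = None,
) -> None:
    """Create the A->X->H->T->F node chain for one F-node id (idempotent)."""
    names = names or {}
    classification.add_node(
        GroupNode(a_name, Level.A, name=names.get(a_name, a_name))
    )
    parts = f_id.split(".")
    if len(parts) != 4:
        raise ClassificationError(f"F-node id {f_id!r} must have 4 components")
    parent = a_name
    for depth in range(1, 5):
        node_id = ".".join(parts[:depth])
        classification.add_node(
            GroupNode(
                node_id,
                _DEPTH_TO_LEVEL[depth],
                name=names.get(node_id, node_id),
                parent=parent,
                rank=rank if depth == 1 else None,
            )
        )
        parent = node_id


# ---------------------------------------------------------------------------
# On-disk table


def load_classification(
    stream: Union[TextIO, str], label: str = ""
) -> Classification:
    """Read the domain-table TSV dialect into a :class:`Classification`.

    Errors (duplicate uid, dangling lineage, malformed range, bad header)
    are reported with the 1-based line number of the offending row.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    header = stream.readline().rstrip("\n")
    if tuple(header.split("\t")) != TSV_COLUMNS:
        raise ClassificationError(
            f"line 1: header does not match dialect {TSV_COLUMNS}"
        )
    classification = Classification(label=label)
    for lineno, raw in enumerate(stream, start=2):
        line = raw.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != len(TSV_COLUMNS):
            raise ClassificationError(
                f"line {lineno}: expected {len(TSV_COLUMNS)} columns, got {len(fields)}"
            )
        row = dict(zip(TSV_COLUMNS, fields))
        try:
            segset = SegmentSet.from_string(row["range"])
        except SegmentError as exc:
            raise ClassificationError(f"line {lineno}: {exc}") from exc
        date = None
        if row["deposition_date"]:
            try:
                date = _dt.date.fromisoformat(row["deposition_date"])
            except ValueError as exc:
                raise ClassificationError(f"line {lineno}: {exc}") from exc
        special = SpecialCategory(row["special"]) if row["special"] else None
        f_id = row["f_id"] or None
        try:
            if f_id is not None:
                expected = (row["x_id"], row["h_id"], row["t_id"])
                parts = f_id.split(".")
                implied = (parts[0], ".".join(parts[:2]), ".".join(parts[:3]))
                if expected != implied:
                    raise ClassificationError(
                        f"x/h/t ids {expected} disagree with f_id {f_id!r}"
                    )
                add_lineage(classification, row["a_name"], f_id)
            domain = Domain(
                uid=row["uid"],
                pdb_id=row["pdb"],
                segset=segset,
                f_node=f_id,
                special=special,
                rep_status=row["rep_status"] or "auto",
                assembly=row["assembly"] or "none",
                deposition_date=date,
            )
            classification.add_domain(domain)
        except ClassificationError as exc:
            raise ClassificationError(f"line {lineno}: {exc}") from exc
    return classification


def write_classification(classification: Classification, stream: TextIO) -> None:
    """Write the canonical TSV: header plus one row per domain, sorted by uid."""
    stream.write("\t".join(TSV_COLUMNS) + "\n")
    for uid in sorted(classification.domains):
        d = classification.domains[uid]
        if d.f_node is not None:
            parts = d.f_node.split(".")
            x_id, h_id, t_id, f_id = (
                parts[0],
                ".".join(parts[:2]),
                ".".join(parts[:3]),
                d.f_node,
            )
            a_name = classification.ancestor_at(uid, Level.A) or ""
        else:
            x_id = h_id = t_id = f_id = ""
            a_name = ""
        stream.write(
            "\t".join(
                (
                    d.uid,
                    d.pdb_id,
                    d.segset.to_string(),
                    a_name,
                    x_id,
                    h_id,
                    t_id,
                    f_id,
                    d.rep_status,
                    d.assembly,
                    d.deposition_date.isoformat() if d.deposition_date else "",
                    d.special.value if d.special else "",
                )
            )
            + "\n"
        )


def classification_to_string(classification: Classification) -> str:
    buf = io.StringIO()
    write_classification(classification, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Queries


def lineage(classification: Classification, uid: str):
    """Root-to-leaf path for a domain.

    Returns an ordered tuple of ``(Level, node_id, name)`` triples for
    classified domains, or ``(Level.SPECIAL, category)`` for special-bin
    members.
    """
    domain = classification.domains.get(uid)
    if domain is None:
        raise ClassificationError(f"unknown domain uid {uid!r}")
    if domain.special is not None:
        return (Level.SPECIAL, domain.special)
    path = []
    node = classification.node(domain.f_node)
    while node is not None:
        path.append((node.level, node.node_id, node.name))
        node = classification.node(node.parent) if node.parent else None
    return tuple(reversed(path))


def level_populations(classification: Classification) -> dict:
    """Population counts per level plus domain and representative tallies.

    Node counts are distinct group nodes per level; ``manual_reps`` counts
    domain leaves flagged as manual representatives.
    """
    counts = {level: 0 for level in (Level.A, Level.X, Level.H, Level.T, Level.F)}
    for node in classification.nodes.values():
        if node.level in counts:
            counts[node.level] += 1
    out = {level.value: n for level, n in counts.items()}
    out["domains"] = len(classification.domains)
    out["manual_reps"] = sum(
        1 for d in classification.domains.values() if d.rep_status == "manual"
    )
    out["special"] = sum(
        1 for d in classification.domains.values() if d.special is not None
    )
    return out


def validate_classification(classification: Classification) -> list[str]:
    """Return a list of human-readable invariant violations (empty iff valid)."""
    violations: list[str] = []
    for node_id, node in classification.nodes.items():
        if node.parent is not None:
            parent = classification.nodes.get(node.parent)
            if parent is None:
                violations.append(f"node {node_id}: dangling parent {node.parent}")
            elif parent.level.depth != node.level.depth - 1:
                violations.append(
                    f"node {node_id} ({node.level.value}) has parent at level "
                    f"{parent.level.value}"
                )
        elif node.level is not Level.A:
            violations.append(f"node {node_id}: non-architecture node without parent")
    f_with_domains = {
        d.f_node for d in classification.domains.values() if d.f_node is not None
    }
    for node_id, node in classification.nodes.items():
        if node.level is Level.F and node_id not in f_with_domains:
            violations.append(f"orphan F-node {node_id}: no member domains")
    for uid, domain in classification.domains.items():
        if domain.segset.size == 0:
            violations.append(f"domain {uid}: empty segment set")
        if domain.f_node is not None:
            node = classification.nodes.get(domain.f_node)
            if node is None:
                violations.append(f"domain {uid}: dangling F-node {domain.f_node}")
            elif node.level is not Level.F:
                violations.append(
                    f"domain {uid}: leaf attached at level {node.level.value}"
                )
    return violations
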