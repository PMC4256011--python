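"""Exact residue-interval algebra on SEQRES coordinates.

Every coverage rule in the classification pipeline — "fewer than 10 residues
uncovered", "hit coverage above 80%", "100% residue coverage" — reduces to
arithmetic on sets of residue positions.  A :class:`SegmentSet` is the exact
representation of such a set: an ordered list of chain-qualified, 1-based,
inclusive intervals on the SEQRES numbering of one or more chains.  SEQRES
indexing is gap-free, so no insertion-code arithmetic is needed; author (PDB)
numbering, when relevant, is carried elsewhere as an annotation.

Canonical form: segments are sorted by (chain, start), segments on the same
chain never overlap, and segments that abut (end + 1 == next start) are stored
merged.  All constructors and operations return canonical sets, so structural
equality is set equality.

The string dialect used in all on-disk tables is chain-qualified and
comma-joined: ``"A:1-100,A:120-180"``.  A domain spanning several chains is an
ordinary SegmentSet whose segments carry more than one chain id.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Tuple

__all__ = [
    "SegmentError",
    "Segment",
    "SegmentSet",
    "coverage_fraction",
    "uncovered_count",
]

Segment = Tuple[str, int, int]


class SegmentError(ValueError):
    """A malformed segment or an operation on an invalid region."""


def _canonicalize(segments: Iterable[Segment]) -> tuple[Segment, ...]:
    validated: list[Segment] = []
    for seg in segments:
        chain, start, end = seg
        chain = str(chain)
        start = int(start)
        end = int(end)
        if start > end or start < 1:
            raise SegmentError(f"malformed segment {chain}:{start}-{end}")
        validated.append((chain, start, end))
    validated.sort(key=lambda s: (s[0], s[1], s[2]))
    merged: list[Segment] = []
    for chain, start, end in validated:
        if merged:
            pchain, pstart, pend = merged[-1]
            if chain == pchain and start <= pend + 1:
                merged[-1] = (pchain, pstart, max(pend, end))
                continue
        merged.append((chain, start, end))
    return tuple(merged)


class SegmentSet:
    """An immutable set of residue positions stored as merged intervals.

    Overlapping or adjacent input segments are merged on construction
    (union semantics); a segment with ``start > end`` is rejected.
    """

    __slots__ = ("_segments", "_size")

    def __init__(self, segments: Iterable[Segment] = ()):
        self._segments = _canonicalize(segments)
        self._size = sum(end - start + 1 for _, start, end in self._segments)

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_string(cls, text: str) -> "SegmentSet":
        """Parse the ``"A:1-100,A:120-180"`` dialect; empty string -> empty set."""
        text = text.strip()
        if not text:
            return cls()
        segments = []
        for piece in text.split(","):
            piece = piece.strip()
            try:
                chain, span = piece.rsplit(":", 1)
                if "-" in span[1:]:  # permit negative-free spans only
                    start_s, end_s = span.split("-", 1)
                else:
                    start_s = end_s = span
                segments.append((chain, int(start_s), int(end_s)))
            except (ValueError, AttributeError) as exc:
                raise SegmentError(f"cannot parse range piece {piece!r}") from exc
        return cls(segments)

    @classmethod
    def from_positions(cls, positions: Iterable[Tuple[str, int]]) -> "SegmentSet":
        """Build from explicit (chain, position) pairs."""
        by_chain: dict[str, list[int]] = {}
        for chain, pos in positions:
            by_chain.setdefault(chain, []).append(int(pos))
        segments: list[Segment] = []
        for chain, poss in by_chain.items():
            poss = sorted(set(poss))
            if not poss:
                continue
            run_start = prev = poss[0]
            for p in poss[1:]:
                if p == prev + 1:
                    prev = p
                    continue
                segments.append((chain, run_start, prev))
                run_start = prev = p
            segments.append((chain, run_start, prev))
        return cls(segments)

    @classmethod
    def single(cls, chain: str, start: int, end: int) -> "SegmentSet":
        return cls([(chain, start, end)])

    # -- basic protocol --------------------------------------------------

    @property
    def segments(self) -> tuple[Segment, ...]:
        return self._segments

    @property
    def size(self) -> int:
        """Number of residue positions covered."""
        return self._size

    def __len__(self) -> int:
        return self._size

    def __bool__(self) -> bool:
        return bool(self._segments)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SegmentSet):
            return NotImplemented
        return self._segments == other._segments

    def __hash__(self) -> int:
        return hash(self._segments)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SegmentSet({self.to_string()!r})"

    def to_string(self) -> str:
        return ",".join(f"{c}:{s}-{e}" for c, s, e in self._segments)

    def chains(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for chain, _, _ in self._segments:
            seen.setdefault(chain)
        return tuple(seen)

    def positions(self) -> Iterator[Tuple[str, int]]:
        for chain, start, end in self._segments:
            for pos in range(start, end + 1):
                yield chain, pos

    def __contains__(self, item: Tuple[str, int]) -> bool:
        chain, pos = item
        for c, s, e in self._segments:
            if c == chain and s <= pos <= e:
                return True
        return False

    # -- set algebra -----------------------------------------------------

    def union(self, other: "SegmentSet") -> "SegmentSet":
        return SegmentSet(self._segments + other._segments)

    __or__ = union

    def intersection(self, other: "SegmentSet") -> "SegmentSet":
        out: list[Segment] = []
        for chain, s1, e1 in self._segments:
            for c2, s2, e2 in other._segments:
                if c2 != chain:
                    continue
                lo, hi = max(s1, s2), min(e1, e2)
                if lo <= hi:
                    out.append((chain, lo, hi))
        return SegmentSet(out)

    __and__ = intersection

    def subtract(self, other: "SegmentSet") -> "SegmentSet":
        out: list[Segment] = []
        for chain, start, end in self._segments:
            pieces = [(start, end)]
            for c2, s2, e2 in other._segments:
                if c2 != chain:
                    continue
                next_pieces: list[tuple[int, int]] = []
                for lo, hi in pieces:
                    if e2 < lo or s2 > hi:
                        next_pieces.append((lo, hi))
                        continue
                    if s2 > lo:
                        next_pieces.append((lo, s2 - 1))
                    if e2 < hi:
                        next_pieces.append((e2 + 1, hi))
                pieces = next_pieces
            out.extend((chain, lo, hi) for lo, hi in pieces)
        return SegmentSet(out)

    __sub__ = subtract

    def span(self, chain: str) -> tuple[int, int] | None:
        """(min, max) covered position on one chain, or None."""
        lo = hi = None
        for c, s, e in self._segments:
            if c != chain:
                continue
            lo = s if lo is None else min(lo, s)
            hi = e if hi is None else max(hi, e)
        if lo is None:
            return None
        return lo, hi


def coverage_fraction(region: SegmentSet, covered: SegmentSet) -> float:
    """Fraction of ``region`` positions also present in ``covered``.

    This is the quantity behind the ">80% hit coverage" acceptance rule: the
    denominator is always the region of interest (e.g. the full length of the
    known target domain), never the alignment alone.
    """
    if region.size == 0:
        raise SegmentError("coverage_fraction of an empty region is undefined")
    return region.intersection(covered).size / region.size


def uncovered_count(chain_extent: SegmentSet, assigned: SegmentSet) -> int:
    """Residues of the chain extent left without an assignment."""
    return chain_extent.subtract(assigned).size
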