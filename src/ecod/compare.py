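"""Cross-classification analytics.

Two domain classifications built over the same set of protein chains can
disagree in two orthogonal ways: in how chains are *partitioned* into
domains, and in how similarly partitioned domains are *grouped* into
homology-level units.  This module separates the two:

* :func:`equivalent_domains` matches domains across classifications by
  mutual residue coverage (>= 80% in both directions by default), yielding
  the subset on which grouping can be compared at all;
* :func:`homologous_pairs` turns a grouping into a set of unordered domain
  pairs sharing a node at a chosen level (the homology level, normally),
  and :func:`venn_fractions` intersects up to three such pair sets —
  the classical three-classification agreement figure;
* :func:`merge_histogram` asks, per homology group of one classification,
  how many distinct homology units of the other it absorbs;
* :func:`partition_distributions`, :func:`growth_curves` and
  :func:`similarity_distribution` are the corresponding summary statistics
  (domains per chain and domain lengths; cumulative group counts dated by
  each group's oldest deposition; and TM-score histograms banded by
  HHsearch probability).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .hierarchy import Classification, Level
from .ranges import SegmentSet, coverage_fraction

__all__ = [
    "CompareError",
    "EquivalenceMap",
    "VennReport",
    "equivalent_domains",
    "homologous_pairs",
    "venn_fractions",
    "merge_histogram",
    "partition_distributions",
    "growth_curves",
    "similarity_distribution",
    "PROBABILITY_BANDS",
]

logger = logging.getLogger(__name__)


class CompareError(ValueError):
    pass


@dataclass
class EquivalenceMap:
    """One-to-one matching of domains across two classifications.

    Each entry is (uid_a, uid_b, coverage_a_by_b, coverage_b_by_a), with
    both coverages at or above the threshold used to build the map.
    """

    threshold: float
    pairs: list[tuple[str, str, float, float]] = field(default_factory=list)

    def a_to_b(self) -> dict[str, str]:
        return {a: b for a, b, _, _ in self.pairs}

    def b_to_a(self) -> dict[str, str]:
        return {b: a for a, b, _, _ in self.pairs}

    def transpose(self) -> "EquivalenceMap":
        return EquivalenceMap(
            threshold=self.threshold,
            pairs=[(b, a, cb, ca) for a, b, ca, cb in self.pairs],
        )


def equivalent_domains(
    a: Classification,
    b: Classification,
    cov_min: float = 0.8,
) -> EquivalenceMap:
    """Match domains of ``a`` and ``b`` sharing mutual residue coverage.

    Candidates are domain pairs on the same PDB entry with coverage at least
    ``cov_min`` in *both* directions; matching is greedy best-first on total
    mutual coverage, deterministic, and one-to-one.
    """
    by_pdb_b: dict[str, list[str]] = {}
    for uid in sorted(b.domains):
        by_pdb_b.setdefault(b.domains[uid].pdb_id, []).append(uid)
    candidates: list[tuple[float, str, str, float, float]] = []
    for uid_a in sorted(a.domains):
        dom_a = a.domains[uid_a]
        for uid_b in by_pdb_b.get(dom_a.pdb_id, ()):
            dom_b = b.domains[uid_b]
            cov_a = coverage_fraction(dom_a.segset, dom_b.segset)
            cov_b = coverage_fraction(dom_b.segset, dom_a.segset)
            if cov_a >= cov_min and cov_b >= cov_min:
                candidates.append((cov_a + cov_b, uid_a, uid_b, cov_a, cov_b))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    matched_a: set[str] = set()
    matched_b: set[str] = set()
    result = EquivalenceMap(threshold=cov_min)
    for _total, uid_a, uid_b, cov_a, cov_b in candidates:
        if uid_a in matched_a or uid_b in matched_b:
            continue
        matched_a.add(uid_a)
        matched_b.add(uid_b)
        result.pairs.append((uid_a, uid_b, cov_a, cov_b))
    return result


def homologous_pairs(
    classification: Classification,
    uids: Iterable[str],
    level: Level = Level.H,
) -> set[tuple[str, str]]:
    """Unordered pairs of the given domains sharing a node at ``level``."""
    if level not in (Level.X, Level.H, Level.T, Level.F, Level.A):
        raise CompareError(f"cannot group by level {level!r}")
    groups: dict[str, list[str]] = {}
    for uid in sorted(set(uids)):
        node = classification.ancestor_at(uid, level)
        if node is None:
            continue  # special-category domains carry no lineage
        groups.setdefault(node, []).append(uid)
    pairs: set[tuple[str, str]] = set()
    for members in groups.values():
        for i, u in enumerate(members):
            for v in members[i + 1 :]:
                pairs.add((u, v) if u <= v else (v, u))
    return pairs


_REGIONS = ("p1_only", "p2_only", "p3_only", "p1_p2", "p1_p3", "p2_p3", "all")


@dataclass
class VennReport:
    """Exact counts and union-fractions for the 7 regions of a 3-set Venn."""

    counts: dict[str, int]
    fractions: dict[str, float]
    union_size: int

    def __post_init__(self):
        if sum(self.counts.values()) != self.union_size:
            raise CompareError("Venn region counts do not sum to the union size")


def venn_fractions(
    p1: set, p2: set, p3: Optional[set] = None
) -> VennReport:
    """Region counts by exact set algebra; fractions over the union."""
    p3 = p3 if p3 is not None else set()
    union = p1 | p2 | p3
    counts = {
        "all": len(p1 & p2 & p3),
        "p1_p2": len((p1 & p2) - p3),
        "p1_p3": len((p1 & p3) - p2),
        "p2_p3": len((p2 & p3) - p1),
        "p1_only": len(p1 - p2 - p3),
        "p2_only": len(p2 - p1 - p3),
        "p3_only": len(p3 - p1 - p2),
    }
    total = len(union)
    fractions = {
        region: (count / total if total else 0.0) for region, count in counts.items()
    }
    return VennReport(counts=counts, fractions=fractions, union_size=total)


def merge_histogram(
    ecod: Classification,
    other: Classification,
    equivalence: EquivalenceMap,
    level_a: Level = Level.H,
    level_b: Level = Level.H,
) -> dict[int, int]:
    """How many homology groups of one classification merge units of another.

    For each ``level_a`` group of ``ecod`` with at least one equivalent
    domain, count the distinct ``level_b`` units of ``other`` its domains
    map to; return the histogram over that count k.
    """
    foreign_units: dict[str, set[str]] = {}
    for uid_a, uid_b, _, _ in equivalence.pairs:
        group_a = ecod.ancestor_at(uid_a, level_a)
        group_b = other.ancestor_at(uid_b, level_b)
        if group_a is None or group_b is None:
            continue
        foreign_units.setdefault(group_a, set()).add(group_b)
    histogram: dict[int, int] = {}
    for units in foreign_units.values():
        k = len(units)
        histogram[k] = histogram.get(k, 0) + 1
    return dict(sorted(histogram.items()))


def partition_distributions(
    classification: Classification, length_bin: int = 25
) -> dict:
    """Domains-per-chain and domain-length histograms.

    A domain spanning several chains is counted once, in the ``"MC"``
    bucket, and excluded from the per-chain counts of its chains.  Length
    bins are half-open ``[k*length_bin, (k+1)*length_bin)`` keyed by their
    lower edge.
    """
    per_chain: dict[tuple[str, str], int] = {}
    mc_count = 0
    lengths: dict[int, int] = {}
    for uid in sorted(classification.domains):
        domain = classification.domains[uid]
        chains = domain.segset.chains()
        if len(chains) > 1:
            mc_count += 1
        else:
            key = (domain.pdb_id, chains[0])
            per_chain[key] = per_chain.get(key, 0) + 1
        bin_lo = (domain.segset.size // length_bin) * length_bin
        lengths[bin_lo] = lengths.get(bin_lo, 0) + 1
    domains_per_chain: dict = {}
    for count in per_chain.values():
        domains_per_chain[count] = domains_per_chain.get(count, 0) + 1
    out = {k: v for k, v in sorted(domains_per_chain.items())}
    if mc_count:
        out["MC"] = mc_count
    return {
        "domains_per_chain": out,
        "domain_length": dict(sorted(lengths.items())),
        "length_bin": length_bin,
    }


def growth_curves(classification: Classification) -> dict[str, list[tuple]]:
    """Cumulative group counts per level, each group dated by its oldest
    member deposition; groups with no dated member are excluded (warned)."""
    curves: dict[str, list[tuple]] = {}
    for level in (Level.X, Level.H, Level.T, Level.F):
        group_date: dict[str, object] = {}
        undated: set[str] = set()
        for uid in sorted(classification.domains):
            domain = classification.domains[uid]
            node = classification.ancestor_at(uid, level)
            if node is None:
                continue
            if domain.deposition_date is None:
                undated.add(node)
                continue
            current = group_date.get(node)
            if current is None or domain.deposition_date < current:
                group_date[node] = domain.deposition_date
        for node in undated - set(group_date):
            logger.warning(
                "%s-group %s has no dated member; excluded from growth curve",
                level.value,
                node,
            )
        steps: dict[object, int] = {}
        for date in group_date.values():
            steps[date] = steps.get(date, 0) + 1
        cumulative = 0
        curve = []
        for date in sorted(steps):
            cumulative += steps[date]
            curve.append((date, cumulative))
        curves[level.value] = curve
    return curves


PROBABILITY_BANDS = ("low", "medium", "high")


def similarity_distribution(
    pairs: Sequence[tuple[float, float]], n_bins: int = 20
) -> dict[str, list[float]]:
    """Banded, frequency-normalized TM-score histograms.

    Bands by HHsearch probability: low (<= 20%), medium (between 20% and
    90%, both exclusive), high (>= 90%).  TM-scores are binned into
    ``n_bins`` equal bins on [0, 1], a score of exactly 1.0 falling in the
    last bin; each band is normalized to sum to 1 (all-zero if empty).
    """
    counts = {band: [0] * n_bins for band in PROBABILITY_BANDS}
    for probability, tm in pairs:
        if not (0.0 <= tm <= 1.0):
            raise CompareError(f"tm_score {tm} outside [0, 1]")
        if probability <= 20.0:
            band = "low"
        elif probability < 90.0:
            band = "medium"
        else:
            band = "high"
        bin_idx = min(int(tm * n_bins), n_bins - 1)
        counts[band][bin_idx] += 1
    out: dict[str, list[float]] = {}
    for band, bins in counts.items():
        total = sum(bins)
        out[band] = [c / total if total else 0.0 for c in bins]
    return out
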