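"""Cross-classification analytics: equivalence, Venn, histograms, curves."""

import datetime
import random

import pytest

from ecod.compare import (
    CompareError,
    equivalent_domains,
    growth_curves,
    homologous_pairs,
    merge_histogram,
    partition_distributions,
    similarity_distribution,
    venn_fractions,
)
from ecod.hierarchy import Classification, Domain, Level, add_lineage
from ecod.ranges import SegmentSet


def classification_from(spec: dict, label: str = "") -> Classification:
    """spec: uid -> (pdb, range string, f_id[, date])"""
    c = Classification(label=label)
    for uid, item in spec.items():
        pdb, rng, f_id = item[:3]
        date = item[3] if len(item) > 3 else None
        add_lineage(c, "arch", f_id)
        c.add_domain(
            Domain(
                uid=uid,
                pdb_id=pdb,
                segset=SegmentSet.from_string(rng),
                f_node=f_id,
                deposition_date=date,
            )
        )
    return c


class TestEquivalentDomains:
    def test_identical_partitions_fully_matched(self):
        spec = {
            "a1": ("1xyz", "A:1-100", "2001.1.1.1"),
            "a2": ("1xyz", "A:101-200", "2001.1.1.2"),
        }
        spec_b = {
            "b1": ("1xyz", "A:1-100", "3001.1.1.1"),
            "b2": ("1xyz", "A:101-200", "3001.1.1.2"),
        }
        eq = equivalent_domains(classification_from(spec), classification_from(spec_b))
        assert sorted(eq.a_to_b().items()) == [("a1", "b1"), ("a2", "b2")]
        assert all(ca == 1.0 and cb == 1.0 for _, _, ca, cb in eq.pairs)

    def test_split_domain_has_no_equivalent(self):
        whole = classification_from({"b1": ("1xyz", "A:1-100", "2001.1.1.1")})
        halves = classification_from(
            {
                "a1": ("1xyz", "A:1-50", "2001.1.1.1"),
                "a2": ("1xyz", "A:51-100", "2001.1.1.2"),
            }
        )
        assert equivalent_domains(halves, whole).pairs == []

    def test_ten_percent_boundary_shift_still_matches(self):
        a = classification_from({"a1": ("1xyz", "A:1-100", "2001.1.1.1")})
        b = classification_from({"b1": ("1xyz", "A:11-110", "2001.1.1.1")})
        eq = equivalent_domains(a, b)
        assert eq.a_to_b() == {"a1": "b1"}
        assert eq.pairs[0][2] == pytest.approx(0.9)

    def test_symmetry_under_transposition(self):
        a = classification_from(
            {
                "a1": ("1xyz", "A:1-95", "2001.1.1.1"),
                "a2": ("1xyz", "A:96-200", "2001.1.1.2"),
            }
        )
        b = classification_from(
            {
                "b1": ("1xyz", "A:1-100", "2001.1.1.1"),
                "b2": ("1xyz", "A:101-200", "2001.1.1.2"),
            }
        )
        forward = equivalent_domains(a, b)
        backward = equivalent_domains(b, a)
        assert sorted(forward.transpose().pairs) == sorted(backward.pairs)


class TestHomologousPairs:
    def _classification(self):
        spec = {
            "a": ("1a", "A:1-50", "2001.1.1.1"),
            "b": ("1b", "A:1-50", "2001.1.1.2"),
            "c": ("1c", "A:1-50", "2001.1.2.1"),
            "d": ("1d", "A:1-50", "2002.1.1.1"),
            "e": ("1e", "A:1-50", "2002.1.1.1"),
        }
        return classification_from(spec)

    def test_h_group_of_three_gives_three_pairs(self):
        c = self._classification()
        pairs = homologous_pairs(c, ["a", "b", "c"], Level.H)
        assert pairs == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_two_groups_sizes_two_and_three(self):
        c = self._classification()
        pairs = homologous_pairs(c, ["a", "b", "c", "d", "e"], Level.H)
        assert len(pairs) == 3 + 1

    def test_all_singletons_empty(self):
        c = self._classification()
        assert homologous_pairs(c, ["a", "d"], Level.H) == set()

    def test_hierarchy_nesting_h_contains_t(self):
        c = self._classification()
        uids = ["a", "b", "c", "d", "e"]
        assert homologous_pairs(c, uids, Level.T) <= homologous_pairs(
            c, uids, Level.H
        )


class TestVenn:
    def test_hand_enumerated_toy(self):
        p1 = {("a", "b"), ("a", "c"), ("b", "c")}
        p2 = {("a", "b"), ("a", "c")}
        p3 = {("a", "b")}
        report = venn_fractions(p1, p2, p3)
        assert report.counts == {
            "all": 1, "p1_p2": 1, "p1_p3": 0, "p2_p3": 0,
            "p1_only": 1, "p2_only": 0, "p3_only": 0,
        }
        assert report.union_size == 3

    def test_identical_sets_all_triple(self):
        p = {("a", "b"), ("c", "d")}
        report = venn_fractions(p, set(p), set(p))
        assert report.counts["all"] == 2
        assert report.fractions["all"] == 1.0

    def test_disjoint_singletons_split_equally(self):
        report = venn_fractions({("a", "b")}, {("c", "d")}, {("e", "f")})
        assert report.fractions["p1_only"] == pytest.approx(1 / 3)
        assert report.fractions["p2_only"] == pytest.approx(1 / 3)
        assert report.fractions["p3_only"] == pytest.approx(1 / 3)

    def test_regions_sum_to_union_randomized(self):
        rng = random.Random(11)
        universe = [(f"u{i}", f"u{j}") for i in range(12) for j in range(i + 1, 12)]
        for _ in range(300):
            sets = [
                {p for p in universe if rng.random() < rng.uniform(0.1, 0.6)}
                for _ in range(3)
            ]
            report = venn_fractions(*sets)
            assert sum(report.counts.values()) == len(sets[0] | sets[1] | sets[2])
            if report.union_size:
                assert sum(report.fractions.values()) == pytest.approx(1.0)


class TestMergeHistogram:
    def test_one_group_merging_two_foreign_superfamilies(self):
        ecod = classification_from(
            {
                "a1": ("1a", "A:1-100", "2001.1.1.1"),
                "a2": ("1b", "A:1-100", "2001.1.1.1"),
                "a3": ("1c", "A:1-100", "2002.1.1.1"),
            }
        )
        other = classification_from(
            {
                "b1": ("1a", "A:1-100", "9001.1.1.1"),
                "b2": ("1b", "A:1-100", "9002.1.1.1"),  # different H than b1
                "b3": ("1c", "A:1-100", "9003.1.1.1"),
            }
        )
        eq = equivalent_domains(ecod, other)
        histogram = merge_histogram(ecod, other, eq)
        assert histogram == {1: 1, 2: 1}

    def test_no_equivalences_empty_histogram(self):
        ecod = classification_from({"a1": ("1a", "A:1-100", "2001.1.1.1")})
        other = classification_from({"b1": ("2b", "A:1-100", "9001.1.1.1")})
        eq = equivalent_domains(ecod, other)
        assert merge_histogram(ecod, other, eq) == {}


class TestPartitionDistributions:
    def test_domains_per_chain_counting(self):
        spec = {
            "a": ("1a", "A:1-90", "2001.1.1.1"),
            "b": ("1b", "A:1-150", "2001.1.1.1"),
            "c": ("1c", "A:1-70", "2001.1.1.1"),
            "d": ("1c", "A:71-220", "2001.1.1.1"),
        }
        dist = partition_distributions(classification_from(spec))
        assert dist["domains_per_chain"] == {1: 2, 2: 1}

    def test_multi_chain_domain_goes_to_mc_bucket(self):
        spec = {"mc": ("1a", "A:1-40,B:1-40", "2001.1.1.1")}
        dist = partition_distributions(classification_from(spec))
        assert dist["domains_per_chain"] == {"MC": 1}

    def test_length_histogram_bins_of_25(self):
        spec = {
            "a": ("1a", "A:1-90", "2001.1.1.1"),    # 90 -> bin 75
            "b": ("1b", "A:1-150", "2001.1.1.1"),   # 150 -> bin 150
            "c": ("1c", "A:1-150", "2001.1.1.1"),
        }
        dist = partition_distributions(classification_from(spec))
        assert dist["domain_length"] == {75: 1, 150: 2}


class TestGrowthCurves:
    def test_group_dated_by_oldest_member(self):
        spec = {
            "a": ("1a", "A:1-50", "2001.1.1.1", datetime.date(2010, 1, 1)),
            "b": ("1b", "A:1-50", "2001.1.1.1", datetime.date(2005, 6, 1)),
        }
        curves = growth_curves(classification_from(spec))
        assert curves["H"] == [(datetime.date(2005, 6, 1), 1)]

    def test_two_groups_same_date_step_of_two(self):
        spec = {
            "a": ("1a", "A:1-50", "2001.1.1.1", datetime.date(2005, 6, 1)),
            "b": ("1b", "A:1-50", "2002.1.1.1", datetime.date(2005, 6, 1)),
        }
        curves = growth_curves(classification_from(spec))
        assert curves["X"] == [(datetime.date(2005, 6, 1), 2)]

    def test_empty_classification_flat_zero(self):
        curves = growth_curves(Classification())
        assert all(curve == [] for curve in curves.values())

    def test_undated_group_excluded(self):
        spec = {"a": ("1a", "A:1-50", "2001.1.1.1")}
        curves = growth_curves(classification_from(spec))
        assert curves["H"] == []


class TestSimilarityDistribution:
    def test_high_probability_identical_structures(self):
        dist = similarity_distribution([(95.0, 1.0)] * 10)
        assert dist["high"][-1] == 1.0
        assert sum(dist["high"]) == 1.0
        assert sum(dist["low"]) == 0.0

    def test_probability_twenty_exactly_is_low_band(self):
        dist = similarity_distribution([(20.0, 0.5)])
        assert sum(dist["low"]) == 1.0
        assert sum(dist["medium"]) == 0.0

    def test_probability_ninety_exactly_is_high_band(self):
        dist = similarity_distribution([(90.0, 0.5)])
        assert sum(dist["high"]) == 1.0

    def test_uniform_scores_give_roughly_flat_histogram(self):
        rng = random.Random(5)
        pairs = [(50.0, rng.random()) for _ in range(20000)]
        dist = similarity_distribution(pairs)
        from scipy.stats import chisquare

        observed = [f * 20000 for f in dist["medium"]]
        assert chisquare(observed).pvalue > 1e-4

    def test_tm_score_outside_unit_interval_rejected(self):
        with pytest.raises(CompareError, match="outside"):
            similarity_distribution([(50.0, 1.2)])
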