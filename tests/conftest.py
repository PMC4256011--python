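"""Shared test fixtures: tiny hand-built classifications and hit tables."""

import io

import pytest

from ecod.hierarchy import (
    Classification,
    Domain,
    SpecialCategory,
    add_lineage,
)
from ecod.ranges import SegmentSet


def build_toy_classification() -> Classification:
    """Two X-groups under one architecture; 3 F-nodes, 5 domains.

    Layout:
      beta barrels / 2001.1.1.1 -> d1 (pdb 1aaa A:1-100, manual), d2 (1aab)
      beta barrels / 2001.1.1.2 -> d3 (1aac)
      beta barrels / 2002.1.1.1 -> d4 (1aad), d5 special peptide (1aae)
    """
    c = Classification(label="toy")
    add_lineage(c, "beta barrels", "2001.1.1.1")
    add_lineage(c, "beta barrels", "2001.1.1.2")
    add_lineage(c, "beta barrels", "2002.1.1.1")
    c.add_domain(
        Domain(
            uid="d1",
            pdb_id="1aaa",
            segset=SegmentSet.single("A", 1, 100),
            f_node="2001.1.1.1",
            rep_status="manual",
        )
    )
    c.add_domain(
        Domain(
            uid="d2",
            pdb_id="1aab",
            segset=SegmentSet.single("A", 1, 80),
            f_node="2001.1.1.1",
        )
    )
    c.add_domain(
        Domain(
            uid="d3",
            pdb_id="1aac",
            segset=SegmentSet.single("A", 5, 120),
            f_node="2001.1.1.2",
        )
    )
    c.add_domain(
        Domain(
            uid="d4",
            pdb_id="1aad",
            segset=SegmentSet.single("A", 1, 60),
            f_node="2002.1.1.1",
        )
    )
    c.add_domain(
        Domain(
            uid="d5",
            pdb_id="1aae",
            segset=SegmentSet.single("A", 1, 20),
            special=SpecialCategory.PEPTIDE,
        )
    )
    return c


@pytest.fixture
def toy_classification() -> Classification:
    return build_toy_classification()


@pytest.fixture
def toy_table(toy_classification) -> str:
    from ecod.hierarchy import classification_to_string

    return classification_to_string(toy_classification)
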