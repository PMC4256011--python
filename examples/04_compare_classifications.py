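"""Compare two classifications of the same chains.

Two toy classifications partition three PDB entries identically but group
them differently at the homology level.  Equivalent domains are matched by
mutual 80% residue coverage; homologous pairs (same H-group) are then
intersected to quantify agreement.
"""

from ecod.compare import (
    equivalent_domains,
    homologous_pairs,
    merge_histogram,
    venn_fractions,
)
from ecod.hierarchy import Classification, Domain, Level, add_lineage
from ecod.ranges import SegmentSet


def build(label, groupings):
    c = Classification(label=label)
    for uid, (pdb, f_id) in groupings.items():
        add_lineage(c, "arch", f_id)
        c.add_domain(Domain(uid=uid, pdb_id=pdb,
                            segset=SegmentSet.single("A", 1, 100), f_node=f_id))
    return c


# classification A unites all three domains in one H-group;
# classification B splits the third into its own.
a = build("A", {"a1": ("1aaa", "2001.1.1.1"),
                "a2": ("1aab", "2001.1.1.2"),
                "a3": ("1aac", "2001.1.2.1")})
b = build("B", {"b1": ("1aaa", "9001.1.1.1"),
                "b2": ("1aab", "9001.1.1.1"),
                "b3": ("1aac", "9002.1.1.1")})

eq = equivalent_domains(a, b)
print(f"equivalent domains: {len(eq.pairs)} of {len(a.domains)}")

pairs_a = homologous_pairs(a, eq.a_to_b(), Level.H)
mapped = eq.a_to_b()
back = {v: k for k, v in mapped.items()}
pairs_b = {
    tuple(sorted((back[u], back[v])))
    for u, v in homologous_pairs(b, mapped.values(), Level.H)
}
venn = venn_fractions(pairs_a, pairs_b)
print("homologous pairs A:", sorted(pairs_a))
print("homologous pairs B (remapped):", sorted(pairs_b))
print("venn counts:", {k: v for k, v in venn.counts.items() if v})
print("merge histogram (A H-groups x B H-units):",
      merge_histogram(a, b, eq))

# A records three homologous pairs, B only one: the shared pair lands in the
# intersection region and the two A-only pairs measure how much more
# homology classification A asserts.  The merge histogram shows one A
# H-group absorbing two distinct B homology units.
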