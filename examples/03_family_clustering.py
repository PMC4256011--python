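"""Family assignment: Pfam where confident, complete linkage elsewhere.

Four domains: one has a confident Pfam hit and becomes a Pfam family; two
share 95% HHsearch probability and form a complete-linkage family with a
provisional representative; the last is similar to neither and stays alone.
"""

from ecod.fgroups import PairProbTable, assign_fgroups
from ecod.hierarchy import Classification, Domain, add_lineage
from ecod.ranges import SegmentSet
from ecod.search_io import Hit

c = Classification()
add_lineage(c, "beta barrels", "2001.1.1.1")
domains = {
    uid: Domain(uid=uid, pdb_id=f"p{i}", segset=SegmentSet.single("A", 1, 100),
                f_node="2001.1.1.1")
    for i, uid in enumerate(["d_pfam", "d_hh1", "d_hh2", "d_alone"])
}

pfam_hit = Hit(query_id="d_pfam", query_range=SegmentSet.single("d_pfam", 1, 95),
               target_id="PF00042", target_kind="profile", method="hmmer",
               evalue=1e-30)
probs = PairProbTable({("d_hh1", "d_hh2"): 95.0,
                       ("d_hh1", "d_alone"): 35.0,
                       ("d_hh2", "d_alone"): 28.0})

assignment = assign_fgroups(domains, [pfam_hit], probs, manual_reps=["d_pfam"])
for uid in sorted(assignment):
    record = assignment[uid]
    print(f"{uid}: family {record.f_label} ({record.origin}), "
          f"representative {record.representative_uid} [{record.rep_kind}]")

# d_pfam keeps its Pfam accession with itself as manual representative;
# d_hh1/d_hh2 share an HH-cluster family whose representative is provisional
# (no curated member); d_alone forms a singleton awaiting evidence.
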