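"""Generate a synthetic dataset and measure pipeline recovery.

The generator builds a reference hierarchy, 100 query chains concatenated
from mutated reference domains, and internally consistent hit files (10% of
chains carry a decoy sampled exactly at a pipeline threshold; 10% of domains
are findable only by structure search).  The pipeline is then run from the
rendered files and scored against ground truth.
"""

from collections import Counter

from ecod.fixtures import FixtureSpec, make_fixture, partition_fixture, score_partition

spec = FixtureSpec(seed=1)
reference, queries = make_fixture(spec)
results = partition_fixture(reference, queries)
score = score_partition(results, queries.truth)

print(f"chains: {score.n_chains}")
print("status counts:", dict(Counter(r.status for r in results.values())))
print(f"boundary exactness (±0 residues): {score.boundary_exactness:.3f}")
print(f"lineage accuracy: {score.lineage_accuracy:.3f}")
print(f"status accuracy: {score.status_accuracy:.3f}")

routes = Counter(
    td.route for chain in queries.truth.chains.values() for td in chain.domains
)
print("evidence routes of true domains:", dict(routes))

# Exact boundaries and lineages (all three metrics 1.0) mean every chain was
# rebuilt residue-for-residue from its hit evidence and every at-threshold
# decoy was correctly rejected by the strict gates.
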