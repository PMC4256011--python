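# ecod — evolutionary classification of protein structural domains

A library and command-line toolkit for building and maintaining an
evolutionary classification of protein structural domains: a five-level
hierarchy, an automatic domain-partition pipeline driven by sequence and
structure homology searches, family clustering, and analytics for comparing
domain classifications against each other.

## Who this is for

Structural bioinformaticians who need to (1) partition protein chains into
evolutionary domain units from pre-computed homology search results,
(2) maintain a hierarchical classification of those units that emphasizes
*homology* over fold geometry, or (3) quantify how two or three domain
classifications of the same structures agree.

## The model

Domains are organized in a strict five-level hierarchy:

- **A** (architecture): secondary-structure composition and shape — input
  metadata, never inferred;
- **X** (possible homology): strong structural similarity where common
  ancestry cannot be excluded;
- **H** (homology): groups asserted to share common ancestry;
- **T** (topology): connectivity variants within a homologous group —
  homologs *can* differ in topology, which is why T sits below H;
- **F** (family): significant sequence similarity (Pfam accession where a
  confident HMMER3 hit exists, otherwise all-versus-all HHsearch
  complete-linkage clusters in which every pair shares ≥ 90% probability).

Peptides, coiled-coils, fragments, disordered and low-resolution entries are
held in *special architectures* with no X/H/T/F lineage.

Unclassified chains are partitioned by an iterative pipeline of evidence of
decreasing specificity, with strict printed thresholds:

1. whole-chain BLAST (accept iff E-value < 2·10⁻³ and < 10 query residues
   uncovered; the hit transfers the reference chain's whole domain
   architecture in one pass);
2. per-domain BLAST (E-value < 2·10⁻³ and > 80% coverage of the known
   target domain);
3. HHsearch profile search (probability > 90% by default, same coverage
   rule);
4. boundary optimization (unassigned gaps ≤ 30 residues are absorbed into
   the nearer flanking domain, ties to the N-terminal neighbor);
5. a DALI structure pass (Z ≥ 8 plus a non-negative mean per-column
   BLOSUM62 score over the structure alignment), only where sequence left a
   region at least one domain long.

A chain is classified automatically iff 100% of its residues end up
covered; anything else is flagged for manual curation. Placement of a new
domain follows the four-case rule: homolog with same topology → join the
hit's T-group; homolog with different topology → new T-group in the hit's
H-group; possible homolog → new H-group in the hit's X-group; no possible
homolog → a new X-group.

## Worked example

`examples/02_simulate_and_recover.py` generates a synthetic reference
hierarchy (64 domains in 32 families), 100 query chains concatenated from
mutated reference domains, and consistent hit files — then runs the pipeline
from those files and scores it against ground truth:

```
chains: 100
status counts: {'complete_automatic': 100}
boundary exactness (±0 residues): 1.000
lineage accuracy: 1.000
status accuracy: 1.000
evidence routes of true domains: {'chain_blast': 18, 'domain_blast': 176, 'dali': 28, 'hhsearch': 31}
```

Every chain is rebuilt residue-for-residue: all 100 chains reach automatic
completion, every true boundary is reproduced exactly, and every assigned
family matches ground truth — including chains whose only evidence is a
structure hit, and despite decoy hits planted *exactly at* the acceptance
thresholds (which the strict gates must reject). The other examples cover
single-chain partition with a decision log, family clustering,
classification comparison, and the structure kernels.

The same machinery is scriptable from the shell:

```
ecod simulate --seed 1 --out fixture/
ecod validate fixture/reference.tsv
ecod partition --fasta fixture/queries.fasta --domain-blast fixture/domain_blast.tsv \
    --ref fixture/reference.tsv --out partition.tsv
ecod cluster --domains fixture/reference.tsv --domtbl fixture/pfam.domtbl --out fgroups.tsv
ecod compare --a ecod.tsv --b scop.tsv --c cath.tsv --out report.json
ecod superpose --pdb 3cbn.pdb --chain A --split 77
```

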