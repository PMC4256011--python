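# Methods

## Scope and data model

The package implements a hierarchical, homology-centric classification of
protein structural domains and the automatic pipeline that feeds it. A
domain is a set of residue segments (a `SegmentSet`) on one or more chains,
indexed 1-based and inclusive on SEQRES numbering. SEQRES indexing is
gap-free, which keeps all coverage arithmetic exact; author (PDB) numbering
and insertion codes are deliberately out of scope. Multi-chain domains are
ordinary segment sets spanning several chain ids.

The hierarchy has five levels — architecture (A), possible homology (X),
homology (H), topology (T), family (F) — plus special architectures
(peptide, coiled-coil, fragment, disordered, low-resolution, non-peptide
polymer) whose members carry no lineage. Two judgments are treated as
*input data*, never computed: architecture membership (partly subjective by
its nature) and the homology/topology verdict behind the placement rule
(it rests on score inspection, function, unusual shared features and
literature — curator judgment). The code mechanizes only what follows
deterministically from those inputs.

## The partition pipeline

Passes run in fixed order: triage → chain BLAST → domain BLAST → HHsearch →
boundary optimization → (conditionally) DALI structure search → boundary
optimization. Assigned regions only ever grow, and provisional domains stay
pairwise residue-disjoint; a chain is `complete_automatic` iff its extent is
100% covered, `nondomain` iff triaged into a special category, else
`flagged_manual`. Every accept/reject decision is logged with the governing
threshold.

Thresholds (all overridable in `PipelineConfig`, each on its documented
scale):

| gate | default | comparison | origin |
|---|---|---|---|
| BLAST E-value | 2e-3 | strict `<` | published |
| chain-pass uncovered residues | 10 | strict `<` | published |
| target-domain coverage | 0.80 | strict `>` | published |
| HHsearch probability (partition) | 90.0% | strict `>` | chosen default |
| DALI Z-score | 8.0 | `>=` | chosen default |
| mean BLOSUM62 column score | 0.0 | `>=` | chosen default |
| gap merge limit | 30 residues | `<=` | chosen default |
| minimum domain length | 25 residues | — | chosen default |
| peptide length | < 40 residues | strict `<` | chosen default |
| hit/assigned overlap tolerance | 5 residues | `<=` | chosen default |

The published thresholds are printed as strict inequalities and are
implemented exactly so; the partition-time HHsearch gate is made strict by
symmetry. The *family clustering* cutoff is inclusive (`>= 90%`) — families
are sets in which every pair *shares* at least that probability — so the
two uses of 90% deliberately differ in boundary semantics.

Design choices where the procedure was genuinely open:

- **Coverage denominator.** "Hit coverage" is measured against the known
  target domain's full length (from the reference classification), not the
  HSP alone; a target-length table therefore rides along with every
  reference. The chain-pass "residues uncovered" count is taken over the
  *query* extent — the quantity completeness is later judged on.
- **Conflict rule.** An incoming hit may overlap already-assigned residues
  by at most 5; the overlap is trimmed from the incoming hit, larger
  overlaps reject it. The optimization step implies small-overlap tolerance
  but no published number exists.
- **Boundary optimization.** The published procedure builds on a structural
  domain parser whose gap-elimination details are unpublished; the stand-in
  here assigns each residue of an interstitial gap (≤ 30 residues) to the
  domain whose flanking boundary is nearer, ties to the N-terminal
  neighbor, and merges terminal runs of ≤ 30 into the terminal domain.
  It is deterministic and leaves domains disjoint.
- **Tie-breaking.** Hits are ordered by (E-value, longer query range,
  lexicographic target id) or (probability descending, then the same);
  all downstream clustering ties break lexicographically. Reruns are
  byte-reproducible.
- **Structure pass gating.** DALI evidence is consulted only when sequence
  passes leave an unassigned region at least `min_domain_len` long,
  mirroring the decreasing need for structure search as coverage grows.

## Family assignment and redundancy

Pfam assignment accepts the best HMMER3 hit with independent E-value
≤ 1e-3 whose envelope covers ≥ 50% of the domain ("confident" is undefined
in the source description; these are common Pfam practice and overridable).
Domains without a confident Pfam hit are clustered by all-versus-all
HHsearch probability under *complete linkage*: candidate pairs are processed
by descending probability and two clusters merge only if the union remains a
≥ cutoff clique, which makes the greedy agglomeration deterministic and
directly checkable against a brute-force clique/maximality oracle.
Representatives: a family containing a manually curated member uses it;
otherwise the member with the highest mean within-family probability is
designated a *provisional* representative for later curation.

The redundancy filter emulates BLASTCLUST-style clustering without running
it: greedy single-linkage over pairs meeting both a 95% identity and a 90%
length-coverage threshold, the coverage being required of *both* sequences
(the published footnote does not say which; both-sequences is the stricter
reading), keeping the longest member per cluster. Output is invariant to
input order.

## Cross-classification analytics

Equivalence between two classifications is one-to-one greedy best-first
matching of domains on the same PDB entry with ≥ 80% mutual residue
coverage in both directions (the 80% rule is published; the matching
procedure is not, so a deterministic greedy matching on total mutual
coverage is used). Homologous pairs are unordered pairs of equivalent
domains sharing a node at the homology level; up to three pair sets are
intersected by exact set algebra into seven Venn regions with fractions
over the union (counts are reported alongside so fractions over any one
classification are recoverable). The merge histogram counts, per H-group,
the distinct foreign homology units its equivalent domains map to.
Distribution utilities: domains-per-chain (multi-chain domains in an `MC`
bucket), domain lengths in 25-residue bins (no published width), growth
curves dating each group by its oldest member deposition (undated groups
are excluded with a warning), and TM-score histograms in 20 bins banded by
HHsearch probability (low ≤ 20%, 20% < medium < 90%, high ≥ 90%).

## Structure kernels

Kabsch superposition is solved by SVD with the determinant sign correction,
guaranteeing a proper rotation; fewer than three points or collinear point
sets are rejected as degenerate. TM-score uses
d0(L) = 1.24·(L−15)^⅓ − 1.8, clamped to 0.5 Å for L ≤ 21 (standard
practice), normalized by the target length by default (a flag switches the
normalization; the published figures do not state the choice). The score is
maximized by seed-and-extend refinement — superpose on a fragment, keep
pairs within d0 (growing the cutoff when fewer than three survive),
re-superpose to convergence — seeded exhaustively over all fragments for
alignments of ≤ 40 pairs and over the standard L, L/2, L/4 ladder above
that; the result never falls below the full-length superposition score.
Full dynamic-programming alignment search (as in TM-align proper) and DALI
Z-score computation are out of scope. The BLOSUM filter is the arithmetic
mean of BLOSUM62 values over aligned columns (only "BLOSUM-based" is
published; the matrix is pluggable), with nonstandard residues scored via
the X wildcard row.

## Synthetic data: what it emulates and what it does not

The generator produces the complete input surface of the pipeline:
a reference hierarchy (defaults: 4 X-groups × 2 H × 2 T × 2 F × 2 domains),
per-family sequence motifs mutated per domain (substitution only, rate
1–5% within the reference and 2–8% for queries, no indels), query chains
concatenated from mutated reference domains (100 chains of 1–4 domains by
default), and hit files in every supported format. Evidence routes are
drawn per domain: 10% structure-only (present solely in the DALI table),
15% profile-only, the rest BLAST (single-domain sequence-route chains also
receive a whole-chain BLAST hit that exercises one-pass architecture
transfer). True hit scores are sampled strictly inside the gates; with
probability 10% a chain carries one decoy sampled *exactly at* a printed
threshold (E = 2e-3, coverage = 0.80, probability = 90.0, or 10 residues
uncovered) and aimed at a wrong family, so any strict-versus-non-strict
inequality bug becomes a lineage error rather than passing silently.
An optional `peptide_rate` adds short hit-less chains for triage testing
(default 0, so the standard recovery experiment stays all-classifiable).
Everything derives from one integer seed and regenerates byte-identically.

Deliberately not emulated: realistic profile-search score statistics,
alignment gaps/indels, 3D coordinates for the DALI rows (structure-kernel
tests use hand-built geometric toys), and conformational heterogeneity.
Perfect recovery on these fixtures therefore demonstrates the correctness
of the *decision logic* — thresholds, conflict handling, mapping,
optimization — not the sensitivity of the underlying search tools on real
proteins.

## Problem sizes and numerical notes

The standard experiments are sized for exactness and speed: recovery runs
5 seeds × 100 chains; the clustering oracle checks 500 random tables of up
to 10 items (the clique-and-maximality check is polynomial and exactly
characterizes complete-linkage output, where enumerating all partitions
would not scale); Venn consistency runs 1000 random triples; the Kabsch
invariance property runs 1000 random rigid transforms with a 1e-9 RMSD
drift tolerance. TM self-comparison equals 1.0 exactly in floating point
because zero distances contribute terms of exactly 1. Classification
tables and all hit formats round-trip bit-exactly because writers emit a
canonical formatting that the parsers invert.

## Known limitations

- Homology verdicts, topology sameness and architecture membership are
  inputs; the package cannot discover a new homologous link by itself.
- The boundary optimizer is a stated stand-in for an unpublished
  procedure; on real chains with long linkers its nearest-boundary split is
  a heuristic.
- DALI and HHsearch are parsed or emulated, never executed; converting
  native DaliLite output into the documented TSV dialect is the caller's
  contract.
- The reproduction of the published tandem-repeat superposition (PDB 3cbn)
  needs one small network fetch and a choice of repeat correspondence; the
  published value came from a manually adjusted structure alignment, so the
  check carries a ±0.2 Å tolerance.
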