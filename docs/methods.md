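# Methods

This note documents the models, parameter choices and numerical details
behind `butyragene`, and what the synthetic fixtures do and do not show
about real data.

## Reference curation

A reference protein is characterised by its span over the gene-family
model: coverage = (last filled model position − first filled model
position) / model length.  The full-length filter keeps coverage ≥ 0.93;
the boundary is inclusive (a reference at exactly 93% passes, since the
rule removes sequences *below* 93%).

Pairwise protein dissimilarity is pairwise-deletion identity: columns
gapped in either sequence are skipped and the distance is 1 − identical
pairs / compared columns.  When reference lengths differ, sequences are
brought to common columns by a progressive star alignment against a
central scaffold (the longest sequence, ties broken by id) using global
BLOSUM62 alignment with gap open 10 / extend 1; for coverage-filtered
full-length families the inputs are usually already aligned.  A star
alignment stands in for a profile/consensus alignment: it preserves
column homology for near-full-length references without requiring an
external profile model, but it is not appropriate for highly fragmented
inputs.

Trees are built with canonical Saitou–Nei neighbor joining.  Joins are
tie-broken by id order so output is deterministic.  Negative
branch-length estimates (possible for non-additive inputs) are clamped to
zero with the deficit moved to the sibling edge of the join, keeping all
edge lengths non-negative for the partition step; on additive inputs the
tree reproduces the input distances exactly (property-tested to 1e-9).

Curation partitions the tree by edge cuts: among all bipartitions induced
by edges of the unrooted tree, the largest leaf set containing every
verified-positive anchor and no verified decoy is kept.  The result is
invariant to rooting and leaf order; if no edge separates the anchors the
partition is reported as unresolvable together with the conflicting
anchors.  With no negative anchors the whole leaf set is kept.

Merging uses single linkage at dissimilarity strictly below 0.02: any
chain of pairs under the cutoff coalesces.  Single linkage is the most
permissive reading of "merge references under 2%"; complete linkage can
be swapped in via `community.complete_linkage_from_matrix` if a stricter
grouping is wanted.  Group representatives are the lexicographically
smallest member id, again for determinism.

## Frameshift-aware alignment

The aligner is a local (Smith–Waterman-style) dynamic program over
(nucleotides consumed, reference residues consumed) with states:

* **M** — match: 3 nt + 1 aa, scored by BLOSUM62 on the translated codon
  (standard code; ambiguous codons translate to X);
* frameshift transitions into M: 1, 2 or 4 nt + 1 aa at a flat penalty
  of 12 per event (no substitution component);
* **Ix** — codon insertion in the read: 3 nt, affine gap (open 10,
  extend 1, amino-acid units);
* **Iy** — residue gap in the read: 1 aa, same affine costs.

All scores are in BLOSUM62 units and configurable.  The recurrence is
filled by a numba-compiled kernel; cells are floored at zero (local
alignment) and the optimum is the maximum M cell.  Both strands are
aligned and the better score wins, ties to the forward strand.  The
traceback translates matched codons in the phase the optimum chose and
writes the *reference* residue at frameshift columns — a correction, not
a literal translation — so identity is computed on the corrected protein
and frameshift columns count as identical by construction.  DP optimality
is verified against an independent memoised-recursion oracle on 500
random small instances per run of the acceptance suite.

Quality control (read length ≥ 300 nt after barcode/primer trimming, no
ambiguous bases, mean Phred ≥ 20) stands in for an unspecified upstream
pipeline; all three thresholds are parameters.  Gates: initial pass at
identity ≥ 30% and aligned length ≥ 100 aa (*but*) / 125 aa (*buk*);
downstream pass at identity ≥ 70%; both boundaries inclusive.  Reads
whose best reference lies outside the curated anchor cluster are dropped
after the gates, mirroring a tree-based exclusion of non-target homologs.

## Community statistics

Shannon diversity uses the natural logarithm.  The Chao–Jaccard
dissimilarity estimates, for each assemblage, the total relative
abundance it places on shared species (U, V), corrects both upward for
unseen shared species using shared singleton/doubleton counts
(f₊₁/2f₊₂ and f₁₊/2f₁₂ terms, denominator floored at one doubleton), caps
U and V at 1, and returns 1 − UV/(U+V−UV).  The implementation is
cross-checked in the tests against values frozen from an independent
ecology package (vegan 2.7-1, `vegdist(method="chao")`), agreeing to
1e-10.

NMDS minimises Kruskal stress-1 with isotonic regression on ranks, using
20 seeded random restarts plus one restart initialised from classical
(Torgerson) metric scaling; the best configuration is reported together
with its Shepard pairs.  The classical start guarantees the result is
never worse than a metric-scaling solution.  Convergence tolerance is
1e-9 on relative stress improvement, 500 iterations per restart.  An
all-equal distance matrix yields a warning and an arbitrary (but seeded)
layout.

Conservation profiles count per-column residue frequencies with gaps
excluded from denominators; the consensus takes the modal residue with
alphabetical tie-break, and a column is conserved when its top frequency
strictly exceeds 0.95.  "Jointly conserved" requires the rule to hold in
the reference and the amplicon alignment simultaneously.  In the
pipeline, amplicon rows are placed at their reference offset and reads
whose corrected protein contains internal gaps are skipped (at most 500
rows are profiled, which bounds the cost without materially changing the
frequencies).

## qPCR quantification

Standard curves are ordinary least squares of Cq on log₁₀ copies over
10-fold dilution series (10²–10⁷ copies for gene assays, 10³–10⁸ for
total 16S; at least four points, slope must be negative).  Efficiency is
10^(−1/slope) − 1, so a perfect doubling gives slope −3.3219 and
efficiency 1.00.  Replicate Cq values are back-transformed to copies
*before* averaging, and the half-range over replicates is the error bar —
both on the copies scale, matching how duplicate ranges are displayed.
Copies below the 10² detection limit propagate as 0 with a flag (not NA),
with a relative epsilon so a measurement at exactly the limit is not
flagged.

Percent-of-community puts every assay on a common genome basis: gut
bacteria average five 16S operons, so single-copy functional-gene copies
are multiplied by 5 before division by total 16S copies, while
16S-targeted assays are first divided by their own taxon's copy number
and then scaled by the same factor of 5.  Taxon screening of 16S count
tables applies the identical normalisation per candidate genus (species
level where genera are functionally heterogeneous), with taxa carrying
both pathways contributing to both, and unknown copy numbers falling back
to 5 with a warning.

## Synthetic fixtures

The generator emulates the structure of a real run from a single seed:

* **References**: each family grows from a random 160 aa (*but*) / 180 aa
  (*buk*) ancestor; members diverge 5–15% from the ancestor by point
  substitution, decoys 45–55% (branching before the family radiation);
  one near-duplicate pair at 1% exercises the merge rule, and 15% of
  entries get partial model spans (coverage 0.75–0.90) to exercise the
  coverage filter.  Protein lengths are set so the amplicon window
  (read length / 3) covers most of the gene, which keeps alignment cost
  proportional to the amplicon rather than to a full-length gene.
* **Reads**: reference windows are reverse-translated with uniform
  synonymous codon usage, substituted at 1% per nt, and given ±1
  homopolymer indels (runs ≥ 3 nt preferred).  Indel counts per read are
  zero-inflated Poisson with parameters solved from the target mean and
  nonzero fraction — 0.6 and 30% for *but*, 1.6 and 58% for *buk*.
  Indel sites are kept ≥ 21 nt from the read ends and from each other so
  every planted indel is one independently recoverable frameshift: a
  terminal indel can be soft-clipped by a local aligner and two nearby
  indels are cheaper to explain as a substitution than as two penalised
  events, which would make the planted truth unverifiable rather than the
  aligner wrong.  Half the reads are emitted reverse-complemented.
* **Contaminants**, as fractions matching the run statistics the
  workflow was designed around: planted QC failures (13% / 6%), random
  off-target reads standing in for host-derived sequence (41% / 3% of
  QC-passing reads, which fail the identity/length gate), reads from an
  unreferenced 40%-diverged variant that land between the 30% and 70%
  identity gates (1.8% / 6.8%), and reads from decoy references (0.5%)
  that survive the gates and are removed by the out-of-cluster exclusion.
* **qPCR**: curve efficiencies drawn from U(0.92, 1.02), Gaussian Cq
  noise (σ = 0.05 cycles) on duplicates; per-sample truth percentages
  span the 2.6–74.1% range observed across healthy and post-surgical gut
  communities, including one sample planted below the detection limit.
* **Taxon tables**: Dirichlet genome-equivalent fractions over twelve
  genera with 16S copy numbers between 4 and 10, converted to counts via
  the copy numbers at a depth of 50,000.

What passing on these fixtures does **not** show: real 454 flowgram
noise (no chimeras, no quality-score structure beyond constant-plus-
noise), real database annotation error beyond the planted decoys, codon
usage bias, or PCR/WGA amplification bias.  Fixture scale (8 samples ×
250 reads per family, ~160–180 aa references) is chosen so the full
pipeline runs in minutes on one core; statistics reported at this scale
are therefore stochastic within the usual sampling error at n ≈ 2,000
reads per family.

## Known limitations

* The frameshift penalty (12) and gap costs (10/1) are plausible
  defaults, not fitted to a reference implementation; absolute pass
  rates on real data will shift slightly with these choices.
* Identity counts corrected frameshift columns as matches; an identity
  defined on literal translations would be systematically lower for
  indel-rich reads.
* The star reference alignment assumes near-full-length references;
  fragmented references should be aligned externally first.
* NMDS group ellipses are not implemented; ordination output is
  coordinates, stress and Shepard pairs.
* Inosine in primers is treated as a universal base (matches everything,
  degeneracy factor 1), so the invariant degeneracy = |expansion| holds
  only for inosine-free primers.
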