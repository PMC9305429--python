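# Methods

## Scope and data model

`lavauth` authenticates lavender samples against an 11-accession reference
panel: *L. angustifolia* cv. White and Blue, *L. × intermedia* cv. Abrial
and Grosso, *L. allardi*, *L. canariensis*, *L. dentata*, *L. latifolia*,
*L. pinnata*, *L. stoechas* cv. Pedunculata, and the outgroup *Perovskia
atriplicifolia*. Two independent evidence channels are computed per sample
and then fused: a genetic channel over three barcode markers and a
chemical channel over UHPLC peak tables.

## Genetic channel

**Primer matching and in-silico PCR.** The three marker primer pairs
(rbcL: rbcLbF/rbcLbR; trnH-psbA: psbA3′f/trnHf_05; ITS: LavF1/LavR1)
contain IUPAC ambiguity codes. Matching is asymmetric: an ambiguity code
on the primer side is compatible with any base it denotes, while the
template must be concrete (template N never satisfies a primer position).
The lowest-mismatch site wins, ties go to the smallest position, and up to
`max_mismatches` incompatibilities (default 2) are tolerated; degenerate
positions never count as mismatches. The amplicon spans the forward site
through the reverse site inclusive, with 0-based half-open coordinates.
Failure to place either primer yields an explicit no-amplification result
naming the missing primer rather than an exception, since a negative PCR
is a data point, not a programming error.

**Read merging.** Forward/reverse read pairs are merged by scanning all
suffix/prefix overlaps of length ≥ 30 between the forward read and the
reverse-complemented reverse read, keeping the highest-identity overlap
(ties go to the longer one) and requiring ≥ 80% identity. Disagreeing
overlap positions become N — a deliberately conservative consensus, as an
N can never prove two haplotypes identical downstream.

**Distances and trees.** The distance model is the uncorrected p-distance;
sites where either sequence is not a concrete A/C/G/T are excluded from
numerator and denominator. No substitution-model correction is applied:
at the panel's divergences (≈ 0.004–0.02 substitutions/site) corrections
are well below the decision thresholds of every downstream step. UPGMA is
implemented directly (average linkage, joined node at half the join
distance, size-weighted distance update). Because agglomeration order is
undefined under ties, ties are broken by the lexicographically smallest
pair of sorted member-label tuples, making every tree reproducible.
Sequences of equal length per marker are assumed (the panel construction
guarantees it); unequal lengths are refused rather than silently aligned —
indel handling is out of scope.

**Bootstrap.** Clade support resamples alignment columns with replacement,
rebuilds the tree, and counts exact leaf-set recurrence of each internal
node of the original tree, reported as a percentage of replicates
(default 1000). Replicate *r* draws from the *r*-th spawned substream of
the seed so results are order-independent. Identical-sequence clusters
have zero internal distance in every replicate and receive 100% support.

**Discrimination.** A marker set's haplotype partition groups taxa by
exact (bit-identical) sequence equality over the concatenated amplicons;
any sequence containing an ambiguous base forms its own group. Singleton
groups are "fully differentiated" taxa. Concatenation records per-marker
boundary offsets for provenance and is column-order invariant for all
distance computations.

## Chemical channel

**Peak matching.** Each library compound takes the largest-area observed
peak within ± `rt_tolerance` (default 0.05 min, typical UHPLC
retention-time reproducibility) of its reference retention time; one peak
may serve several compounds whose references collide within tolerance
(the library carries two diterpenes at 12.85 min). Unmatched compounds
get area 0. m/z is carried through file formats but not used for
matching, since the classification criteria are stated on compounds.

**Criteria.** "Major presence" (criteria 1 and 2) is a relative-area
cutoff: area / total matched area of the sample > `presence_threshold`
(default 5%). Criteria 3–7 use simple presence (any nonzero match);
the depside criterion requires ≥ 2 family members so a single spurious
match cannot flip it, the diterpene criterion requires ≥ 1. Criteria 3
(compounds 15 and 16 both present) and 4 (neither present) can never both
hold, but both are false for a sample carrying exactly one of the pair —
two reference rows are of exactly that kind, so the pair is mutually
exclusive, not exhaustive.

**Cluster assignment.** Classification is nearest-reference-profile
matching over the 11-row criteria key (Hamming distance on the 7-vector),
ties broken by lowest cluster number then row order, unassigned beyond
`max_hamming` (default 2). A nearest-profile rule was chosen over a
hand-written decision tree because the printed key rows are internally
consistent while the narrative cluster descriptions are not; the rows are
treated as authoritative. One column of the printed key (criterion 6 on
the angustifolia/intermedia rows) is typographically uncertain in the
source; the packaged key records it as printed and `load_chemokey`
accepts per-cell overrides.

**Marker-compound selection.** A compound is flagged when its relative
matched area exceeds the presence threshold in at least one sample;
the zero-noise panel flags exactly the seven discriminant compounds
(8, 14, 15, 16, 21, 37, 53), ranked by maximum relative area.

## Evidence fusion

Genetics dominates: sequence identity is invariant to growth stage and
harvest conditions, chemistry is not. A genetic singleton is
species-resolved regardless of chemistry (an unassigned chemotype only
downgrades confidence in the verdict's evidence notes). Within a
multi-member haplotype group, candidates are intersected with the taxa
whose key row shares the sample's assigned cluster and — where a
refinement rule applies — its sub-pattern: the single default rule states
that inside chemical cluster 1, the (c2, c3) pattern separates the
Blue/Grosso chemotype from White/Abrial. The rule is named and
configurable rather than hardcoded because rosmarinic-acid levels vary
with development stage and the split should be easy to disable. An empty
intersection is reported as a conflict with both evidence sets listed;
chemistry can therefore narrow but never merge genetic groups, so
combined resolution is always ≥ genetic-only resolution. On the reference
panel this yields 6 taxa resolved by genetics, Grosso additionally by
chemistry, and two residual pairs ({White, Abrial}, {allardi, dentata}).

## Synthetic panel

No sequences or chromatograms are deposited for the physical accessions,
and the pipeline's claims depend only on the *structure* of the data —
which taxa share haplotypes, which compounds are present where — so the
generator emulates exactly that structure:

- **Sequences.** Per marker, a random core is drawn and each haplotype
  class receives a mutated copy (default 2% of core sites, a realistic
  congeneric plastid/ITS divergence; classes are verified pairwise
  distinct). Within-class divergence is fixed at zero — haplotype classes
  are *defined* by exact identity, and any nonzero value would break the
  construction. References embed the amplicon (one seeded concrete
  resolution of each degenerate primer site, so ambiguity handling is
  exercised on the primer side) in 60 bp flanks. Encoded classes:
  rbcL/trnH-psbA — A = {White, Abrial, Grosso}, B = {Blue, latifolia},
  C = {allardi, dentata}; ITS — D = {White, Blue, Abrial, Grosso},
  E = {allardi, dentata}; others singletons. Amplicons are 690/273/490 bp.
- **Reads.** Each read covers ~60% of its reference from one end,
  guaranteeing a long overlap; base errors (default rate 0) are injected
  only outside the overlap core so the merged consensus is recoverable.
- **Peaks.** Each taxon's table is synthesized from its key row:
  criterion-mandated compounds at major area (1000 units), presence-only
  compounds at trace area (20), plus `n_noise_peaks` (default 5) noise
  peaks (10 units) placed ≥ 0.15 min (3 tolerance widths) from every
  library retention time, and Gaussian RT jitter (default sd 0.01 min ≪
  tolerance). Compound 21 co-occurs with the coumaric/ferulic pair and 37
  with chemical cluster 2 so that selection flags the seven discriminant
  compounds; rows marking neither criterion 3 nor 4 carry compound 15
  only. The retention times of compounds 21 and 37 are synthetic
  placements (no published values); all others are the reference values.

What the generator does **not** emulate: real sequence homology (cores
are random, so absolute tree heights are arbitrary even though the
identity structure and therefore every discrimination count is exact),
indels and length variation, ITS intra-individual copy variation,
chromatographic co-elution and baseline drift, and quantitative compound
ratios. Passing tests therefore demonstrate the pipeline's correctness on
the published discrimination structure, not instrument-level robustness.

## Numerical and scale choices

All randomness flows from integer seeds through numpy `SeedSequence`
spawning (markers, read simulation and chemistry use separate
substreams). The full panel is small — 11 taxa, ≤ 1453 aligned columns —
so a complete run with 1000 bootstrap replicates takes a few seconds; the
test suite uses 100–1000 replicates and 100 random matrices for the
UPGMA/brute-force equivalence checks, and 20 seeds for end-to-end
parameter recovery. Bootstrap estimates are compared with an exhaustive
column-multiset enumeration on a 6-column toy alignment at a 3-percentage-
point tolerance (≈ 3 binomial standard errors at n = 1000).

## Known limitations

- With the default RT jitter, compound 51 (reference 6.45 min) can
  occasionally capture rosmarinic acid's large peak (6.52 min) since
  their separation (0.07 min) is only 1.4 tolerance widths; criteria and
  cluster assignments are unaffected, but the jittered marker-compound
  list can transiently include a depside. The zero-noise panel is the
  defined reference condition.
- The classification key is panel-specific: samples outside the 11
  reference taxa are at best assigned "nearest" profiles.
- No mixture deconvolution: each sample is assumed to be a single taxon.
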