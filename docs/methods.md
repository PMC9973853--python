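# Methods

This note documents the models and procedures implemented in
`bgcnovelty`, the defaults that matter, what the synthetic-data
generator does and does not emulate, and the numerical conventions.

## 1. Feature space and GCF reference

A BGC is represented by its biosynthetic domain content. Given a
vocabulary of domain identifiers, a cluster maps to a count vector with
one reserved trailing bin that accumulates domains absent from the
vocabulary — unrecognized content should *increase* distance to every
known family, not vanish. Three scalings are available: raw counts,
counts capped at 5 (default; repeated modules in one giant assembly-line
cluster otherwise dominate distances), and unit-L2 normalization.

A GCF reference is built by greedy centroid clustering in this space.
Records are processed in a fixed order (descending domain count, then
lexicographic cluster id), each joining the nearest existing seed within
`build_threshold` (default 3.0 capped-count units) or founding a new
family; after the pass, centroids are recomputed as member means. The
ordering rule makes the build invariant to input order, and ties in
nearest-centroid queries break to the lexicographically smallest family
id. This is a deliberately simple, fully deterministic stand-in for
large-scale GCF engines; it does not attempt BIRCH-style clustering or
any GPU machinery.

The nearest-family distance is Euclidean. *d* values from an external
BiG-FAM export live on that platform's scale and use its literal
novelty threshold τ = 900; a local reference has its own scale, so τ is
calibrated as the 95th-percentile (nearest-rank) of member-to-centroid
distances. Two details matter:

- **Leave-one-out correction.** A member's distance to a mean centroid
  that includes the member underestimates the distance of a fresh
  cluster from the same family. For a mean centroid the held-out
  distance is exactly `‖x − c‖ · n/(n−1)`, and calibration uses these
  corrected values; without the correction, roughly half of held-out
  family members land above τ and the measured novel fraction is badly
  inflated.
- Singleton families carry radius 0 and no scale information; a
  reference consisting only of singletons cannot be calibrated and
  requires an explicit τ.

"Novel" is a strict inequality, d > τ.

## 2. The BiNI score

BiNI = Σd/n per strain. The published wording leaves two readings open,
so both are implemented and every result records its mode: `mean_all`
(default) sums every in-scope distance; `thresholded_sum` sums only
d > τ while n still counts all in-scope clusters, so the two modes are
directly comparable (thresholded ≤ mean always). Likewise the cluster
scope: `all_regions` (default, matching a count of every detected
region) or `complete_only` (clusters not truncated at a contig edge,
the convention similarity networks use). A strain with zero in-scope
clusters raises an explicit undefined-score error — never a silent 0,
which would mis-rank it. Cohort summaries report unweighted per-group
means (and medians) of strain scores and a descending ranking with
deterministic ties.

## 3. Similarity networks

The pairwise raw distance is `1 − (w_J·J + w_AI·AI)` with weights
0.7/0.3: J is the Jaccard index of domain sets, AI the Jaccard index of
the sets of adjacent ordered domain pairs (genomic order). The
domain-sequence-similarity term of the full BiG-SCAPE distance needs
per-domain alignments and is intentionally omitted; the remaining
weights are renormalized. Conventions for degenerate inputs: two
records with no domains are at distance 1; when neither record has an
adjacent pair (single-domain clusters), AI is 1 if their domain sets
are equal and 0 otherwise, so identical single-domain clusters are at
distance 0 and disjoint ones at distance 1.

Edges connect complete clusters at raw distance ≤ 0.3 (inclusive);
connected components are the families; singletons are degree-0 nodes —
clusters with no neighbour within the cutoff, the natural reading of
singleton even though captions elsewhere describe them loosely.
Component labels are ordered by each component's smallest member id,
making serialized networks byte-stable. Reference annotation labels a
component when any member is within the cutoff of any reference record
(nearest reference wins; ties break on the label).

## 4. Pan-genome stage

Protein-family clustering mirrors a usearch-style greedy pass: proteins
sorted longest-first join the first existing family whose founding
(centroid) sequence aligns at identity ≥ 0.5. Identity is computed from
a global Needleman–Wunsch alignment with match +1, mismatch 0, linear
gap −1, identity = matches / alignment length, and a fixed traceback
preference (diagonal, then up, then left) so results are bit-for-bit
reproducible. The DP kernel is numba-compiled; its optimum is
cross-checked in the tests against Biopython's `PairwiseAligner` score
under identical scoring.

The family-by-genome presence matrix partitions into core (all
genomes), unique (exactly one, credited to that genome) and accessory
(the rest); the partition requires ≥ 2 genomes. Rarefaction draws 500
random genome orderings (seeded) and records pan(N) and core(N) for
every prefix; pan curves are non-decreasing and core curves
non-increasing by construction. Heaps' law is fitted by least squares
on log pan(N) vs log N — on the median curve for the point estimate,
and on every stored permutation curve for a bootstrap percentile CI on
γ. The pan-genome is called open when the CI lower bound exceeds 0.02;
the threshold is small but positive so that sampling noise on a flat
curve does not read as openness.

The "mean accessory" language used in flower-diagram reports is
ambiguous (total accessory families vs per-genome mean); the export
reports both.

## 5. Synthetic data: what it emulates

The generator produces every input with planted ground truth. Defaults
are the study conditions used by the tests and the acceptance script.

**Landscape** (`LandscapeConfig`): 20 regular GCFs over a 200-domain
vocabulary. Centroids carry 18–30 domains, a quarter drawn from a
12-domain common pool (ubiquitous transport/regulatory-like content),
and are rejection-sampled to pairwise capped-count distance ≥ 5.5.
Members are centroids with 1 random domain substitution (8 members per
family). Four small common families — disjoint common-pool triples at
multiplicity 2, no within-family jitter — model short, highly conserved
clusters (the ectoine/siderophore tier) that many strains carry. The
separation, jitter and build threshold satisfy a worst-case margin
(within-family scatter ≤ ~2.8 < 3.0 threshold < ~4.3 cross-family), so
reference building recovers the planted partition exactly rather than
statistically.

**Strains** (`StrainSimConfig`): 20 strains of 10–20 clusters. A
novelty fraction f (scalar, range, or per strain; default 0.5) sets the
share of planted-novel clusters; members are fresh jittered centroid
copies with small common families oversampled 3×. Novel clusters are
drawn with 32–56 domains — the large assembly-line end of the size
spectrum, where uncharted chemistry concentrates — and rejection-sampled
to distance ≥ 3.0 from every centroid, so "planted novel" is defined on
the same scale as τ and is recoverable by construction.

**Fragmentation** (`FragmentationConfig`): per cluster, Poisson(1.5)
cuts split the ordered domain list; every fragment is flagged
incomplete; the domain multiset is conserved. This emulates contig
breaks in low-quality assemblies. The observable consequence — median
BiNI drops on fragmented input — emerges from the landscape design:
pieces of a large novel cluster land much closer to the small common
families than the intact cluster lies to anything, while n inflates
with low-distance fragments.

**Pan-genome** (`PangenomeSimConfig`): 8 genomes by default, 50 core
families, 30 accessory (presence probability 0.5, forced into [2, G−1]
genomes so "accessory" is genuine), 12 private families per genome,
protein length 200, within-family substitution rate 0.1 per site
(within-family identity ≈ 0.85, random between-family identity ≈ 0.12
under the alignment scoring above — both far from the 0.5 threshold).
The openness experiments use 12 genomes with 20 unique families each.

What the generator does **not** emulate: real Pfam domain grammars and
their genomic organisation, nucleotide sequence (assemblies are
placeholder N-runs in fixtures), horizontal transfer, paralogy and
domain-level homology between families, or the scale of real reference
databases (millions of clusters; here dozens). Passing tests therefore
demonstrate correctness of the algorithms and the internal consistency
of the analysis under controlled conditions — not that any particular
real strain is novel. Problem sizes (20-family landscapes, 20-strain
cohorts, ~600–1000-protein pan-genomes, 500 rarefaction permutations)
were chosen so the full study runs in well under a minute.

## 6. Numerical conventions and edge cases

- Percentiles use the nearest-rank (inverted-CDF) convention.
- GenBank coordinates are converted to 0-based half-open on parse;
  fixture writing refuses overlapping regions on one contig, since
  domain features are associated with regions by position.
- N50 is the length at which the descending-length cumulative sum first
  reaches half the assembly size; G+C mol% excludes N/ambiguity codes
  and is reported to 0.1.
- All generators and experiments take explicit seeds; a single RNG
  stream per call, no global state. CLI outputs embed the resolved
  configuration, seed and package version, and identical invocations
  are byte-identical.
- Known limitations: the GCF engine's greedy pass is order-stabilized
  but still greedy (families are not globally optimal); the network
  distance ignores domain sequence similarity; protein clustering is
  first-fit against family founders, as in the usearch convention, so a
  borderline protein joins the first acceptable family rather than the
  best one.
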