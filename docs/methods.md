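# Methods

`genospec` implements genome-based species and subspecies delineation for
prokaryotes: pairwise genome similarity measures, type-radius affiliation,
threshold-linkage clustering, marker-gene identity statistics, distance
trees, and a biogeographic classifier, exercised end-to-end on synthetic
genomes with a planted taxonomy.

## The delineation model

A *genomic species* is operationally a set of strains that are mutually
within established similarity thresholds: 70% digital DNA:DNA hybridization
(dDDH), with 67%/73% as its lower/upper confidence bounds, or 96% average
nucleotide identity (ANI); 79% dDDH is the subspecies cutoff. The procedure
has three steps:

1. **Type-radius affiliation.** Every strain whose similarity to a
   described type strain meets the radius threshold is attributed to that
   species. Strains inside two or more radii are *ambiguities*.
2. **De-novo clustering.** Unaffiliated strains are clustered by threshold
   linkage: strains at distance ≤ T are *linked*, and two clusters merge
   when the fraction of linked inter-cluster pairs is ≥ F. F = 0 is single
   linkage (one link suffices), F = 1 complete linkage (all pairs linked);
   F = 0.5 is the default. Similarities are converted to distances as
   (100 − s)/100 (TETRA: 1 − r).
3. **Ambiguity scan.** One putative type strain (PT) is chosen per novel
   cluster — the member whose radius captures its whole cluster and nothing
   else, with a medoid rule (maximal within-cluster minimum similarity,
   lowest label) breaking ties or standing in when no member qualifies —
   and the affiliation scan is repeated over described + putative types.

The merge order in step 2 is fully deterministic: among admissible merges
the pair with maximal link fraction wins; ties break by minimal mean
inter-cluster distance, then by the lexicographically smallest label pair.
The exact agglomeration order of the original threshold-linkage tools is
not published; this total order is this package's convention and makes
partitions bit-for-bit reproducible. Step 2 clusters only the strains left
unaffiliated in step 1; affiliated strains join their type's cluster (an
ambiguous strain joins its most similar type). Ambiguities are counted as
*strains* (not type pairs) against the final described + putative type set.

Subspecies are delineated by re-running the fraction-linkage clustering
inside each multi-member species cluster at the subspecies cutoff.
Single-strain sub-clusters are recorded but not counted as subspecies.

## Pairwise genome measures

**Fragment ANI (ANI_b-style).** The query is cut into consecutive 1020 bp
fragments (terminal fragments ≥ 100 bp kept). Each fragment is located on
the reference by exact 15-mer seeding with gap-free diagonal chaining, then
aligned with edlib (semi-global in the fragment) against the anchored
reference window; fragments are retained when identity ≥ 30% over ≥ 70%
coverage (the JSpecies defaults), and ANI is the mean identity of retained
fragments. Because anchoring requires an exact seed match, homologs below
roughly 60% identity will not anchor — irrelevant at species-delineation
divergences, but a stated approximation relative to BLAST-based ANI.
Matrices are built from both directions of each pair, averaged.

**Approximate alignment ANI (ANI_m-style).** Exact 20-mer anchors (sampled
every 4 query positions) chained gap-free along diagonals (chain gap ≤ 200);
identity is the length-weighted mean over chained blocks, measured by direct
comparison over the full chained spans. Flagged `approximate=True`: it is an
anchoring method, not a MUMmer reimplementation. Indel-free chains match the
simulator exactly; on real data with indels the chains break at each indel.

**TETRA.** 256 tetranucleotide z-scores per genome, both strands of every
contig, with the maximal-order Markov expectation
E(n1n2n3n4) = N(n1n2n3)·N(n2n3n4)/N(n2n3) and its variance; similarity is
the Pearson correlation of z-vectors.

**GBDP-style distance.** Gap-free high-scoring segment pairs (11-mer seeds,
score +1/−1) are trimmed greedily in descending score order so no query or
reference position is counted twice; the surrogate distance is
d = 1 − matches/length over the trimmed HSPs. 100 replicate distances are
obtained by resampling HSPs with replacement (seeded) — the analogue of
bootstrapping whole genes — and feed pseudo-bootstrap branch support. The
mapping to the dDDH percent scale is pluggable: the default surrogate is
100·(1 − d) (an identity-scale proxy, *not* the GGDC regression), a
calibration callable can be supplied, and precomputed dDDH matrices can be
used directly, which is what any comparison against published dDDH values
should do.

Because the surrogate dDDH sits on the identity scale, the pipeline's
simulate mode states its thresholds on the ANI scale: 96% for species
(the published ANI equivalent of 70% dDDH) and 98% for subspecies (this
package's calibration of the 79% dDDH subspecies cutoff onto the identity
scale; it cleanly separates the planted within-subspecies band, ~99.5%
identity, from the within-species band, ~97%).

## Marker-gene statistics

Pairwise identity supports two gap conventions: `gaps-are-differences`
(a column gapped in one sequence counts as a mismatch — the "number of
differences" convention used for the MLSA screen) and `exclude-pairwise`.
Columns with an N in either sequence are excluded from the pair; columns
gapped in all sequences are dropped. Kimura two-parameter distances use
d = −½·ln((1−2P−Q)·√(1−2Q)) over ungapped, unambiguous sites; saturated
pairs (non-positive log argument) raise, or become missing values with a
warning in matrix/summary context. The eight housekeeping loci concatenate
in the fixed order clpA, atpD, gyrB, rpoH, secF, dnaJ, rpoD, rpoS
(12,283 bp at the default locus lengths). The MLSA screen calls
same-species above 98.13% identity and different-species below 97.77%, with
a grey zone between; the 16S genus screen tests inter-group identities
against 94.8% ± 0.25.

## Trees and biogeography

UPGMA (average linkage) is implemented in-repo with the same lexicographic
tie-breaking discipline as the clustering; output is ultrametric by
construction. Neighbor joining delegates to scikit-bio and replaces the
original balanced minimum-evolution (FastME) inference: NJ is fully
specified, deterministic, and sufficient for clade-level checks; tiny
negative NJ branches are clamped to zero. Replicate support attaches to
each internal bipartition the percentage of replicate trees containing it.

The biogeography classifier maps isolation regions to macro-regions
(default: Central Asian soda-lake regions — Kulunda Steppe, Buriatia,
Transbaikal, Mongolia — plus East Africa, North Africa, North America, and
Engineered sources). One macro-region among a cluster's located members ⇒
candidate-endemic; several ⇒ candidate-disjunct; clusters with fewer than 4
located strains keep a provisional verdict flagged not confident. Region
granularity is a convention; per-cluster verdicts on real data depend on it.

## The synthetic-data generator

Genomes evolve down a planted hierarchy root → species ancestor →
subspecies ancestor → strain under a Kimura two-parameter substitution
process (default transition:transversion ratio 2.0), with each edge
carrying half of the target *pairwise* band: within-subspecies 0.005
substitutions/site, within-species 0.03, between-species 0.10 (plus the
within-species edges), genus-level 0.25. The bands are chosen so that
within-species pairs land above 96% fragment ANI and between-species pairs
below 94%, straddling the species thresholds; the 0.03 ↔ ~97% ANI
calibration is asserted empirically in tests rather than assumed, since ANI
depends on fragment retention. Species without planted subspecies structure
place every strain in its own trivial subspecies (strains then sit at the
full within-species band from each other, and the subspecies cut correctly
recovers singletons).

Root chromosomes are drawn from an order-3 Markov chain whose per-context
transition probabilities are Dirichlet-sampled (concentration 1.0) around
the target base composition (default G+C 0.62, realised approximately).
This plants genuine fourth-order compositional structure — the signal
tetranucleotide z-scores measure; an i.i.d. root would make TETRA
meaninglessly noisy. Signature strength grows roughly with the square root
of genome length, so at the scaled-down default of 200 kb (real genomes are
~3 Mb) within-species TETRA correlations land near 0.997–0.999, slightly
below the published Mb-scale thresholds (0.989/0.999); the ordering across
divergence bands — what the clustering uses — is preserved and tested.
Genomes are emitted as 5 contigs cut at uniform random breakpoints. No
indels are simulated: the identity statistics treat gaps as differences,
and indel-free chromosomes keep the ANI oracle analytic.

Marker loci (16S plus the eight housekeeping genes, default lengths from
the real alignments, e.g. 16S 1360 bp, gyrB 2457 bp) evolve on the same
hierarchy with per-locus rate multipliers; 16S uses 0.15× the genomic band
(16S distances are observed at roughly 0.15× MLSA distances in this genus),
housekeeping genes 0.6–1.3×.

What passing synthetic tests do **not** show: robustness to indels,
rearrangements, horizontal transfer, repeat content, or contamination —
none of which are simulated — nor exact agreement with BLAST/MUMmer/GGDC
numerics on real genomes, for which the approximate modes are labelled and
precomputed published matrices are the supported input path.

## Problem sizes and numerical conventions

The planted-recovery suite uses 20 seeds × 20 genomes × 200 kb (cluster
sizes 6/5/4/3/1/1, half the species carrying a described type), the
package's default study scale. Threshold comparisons use ≤ on distances
(≥ on similarities) with a 1e−12 epsilon; directional similarity pairs are
symmetrized by arithmetic mean with asymmetry beyond 0.5 percentage points
treated as data corruption; matrix diagonals are forced to the declared
scale (100 / 1.0 / 0.0). GBDP-style distances are not metric; triangle
violations are expected and not asserted. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; identical
configurations reproduce byte-identical outputs.
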