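# Methods

## Scope and data model

`triadkit` analyses a phased triploid genome given three haploid
assemblies (FASTA), gene models (GFF3), protein/CDS FASTA, a 12-column
tab-separated protein-similarity table (BLAST outfmt-6 dialect),
featureCounts-style gene counts with effective lengths, and NLR locus
intervals (BED). All interval logic is 1-based closed (the GFF3
convention); BED input is converted at the boundary (+1 to the start) and
back on output. Strand is recorded but never used to flip coordinates:
every overlap computation is strand-blind, which is the right resolution
for locus-versus-gene-span questions.

## Allele-triad construction

Genes are assigned to haplotypes by an ID scheme (default: the token
before the first underscore) or an explicit lookup. From the hit table we
keep, per (query, target-haplotype), the best hit — highest percent
identity, ties broken by bit score and then lexicographic subject ID —
after dropping hits below 60% identity or below 0.5 query coverage
(alignment length / query length). Both thresholds are exposed; the
defaults are deliberately permissive because subgenomes of hybrid origin
can be well diverged.

A **triad** is a closed triangle of reciprocal best hits spanning the
three haplotypes. Reciprocity is the default (a one-way mode is
available): it is the minimal standard rule consistent with a strict
1:1:1 correspondence. Links not in any triangle are resolved by a greedy
maximum-identity matching — equivalent to repeatedly deleting the weaker
link of any open chain — rather than transitive closure, which could
merge paralogous families. A gene appearing in two triangles is a hard
error, since it signals upstream multi-mapping. The resulting partition
(triads / pairs / singletons) is validated as exhaustive and disjoint on
every run, and is invariant to hit-table row order. Groups can optionally
be anchored to a reference assembly gene when a strict majority of
members share a best hit there.

## Expression bias

TPM is computed genome-wide per sample, replicate samples are averaged
per tissue, and a triad is *expressed* iff any homoeolog exceeds 0.5 TPM
(strictly) in any tissue. Filtering is at triad level — whole triads are
kept or dropped together, so expressed-gene counts are exactly three
times expressed-triad counts; a per-homoeolog variant is available behind
a flag. The combined analysis takes the arithmetic mean of per-tissue TPM
per homoeolog before standardisation; mean is the most common choice for
integrating tissues and keeps the combined vector within the convex hull
of the per-tissue vectors.

Classification is nearest-centroid in the ternary plane with the seven
centroids given in the README, with the fixed tie order (balanced, H1D,
H2D, H3D, H1S, H2S, H3S). No no-call distance band is applied: every
expressed triad receives a label, and the distance vector and runner-up
margin are reported so a caller can impose their own band. The scheme is
equivariant under haplotype relabelling (tested over all six
permutations) and scale-invariant by construction.

Chromosomal density of biased genes uses fixed non-overlapping windows
(default 100 kb); a gene is counted once, in the window containing its
span midpoint.

## Ka/Ks

NG86 with equal pathway weighting and Jukes–Cantor correction. Mutational
pathways through stop codons are excluded; when every pathway is blocked,
all steps count as nonsynonymous (the common convention — implementations
differ, so it is stated here). Changes *to* stop codons count as
nonsynonymous when tallying sites. N and S are averaged over the two
sequences; gapped or ambiguous codon columns are dropped pairwise; the
ratio is undefined when Sd = 0, and saturation (p ≥ 3/4) is flagged
rather than silently clipped. A triad is summarised by the mean of its
three pairwise ratios. Correctness is established against an
independently written brute-force path-enumeration oracle, exhaustively
over all 61×61 sense-codon pairs and on random alignments.

The per-category comparison reports n, mean, median and quartiles of
defined ratios, plus a one-sided Mann–Whitney U of pooled non-balanced
versus balanced ratios as a descriptive statistic.

## Genome features

**Telomeres.** The scanner anchors at the first exact 7-mer unit
(CCCATTT inward from the 5′ end; TTTAGGG ending at the 3′ end) within
`max_offset` (default 10 kb) and extends unit by unit, tolerating
mismatched units while running purity stays ≥ 0.9, then trims back to the
last matching unit. Purity is unit-level (a unit matches exactly or not;
any N fails), matching the query-repeat framing of telomere annotation.
Calls need ≥ 100 copies. On perfect planted tracts the reported length is
exact. A chromosome with calls at both ends is T2T. The copy/purity
thresholds and window are package defaults, exposed as flags.

**Centromere candidates.** A simplified periodicity scanner, not a
general tandem-repeat finder: for each candidate unit length u (default
100–200 bp) it finds maximal segments of lag-u self-matches (≥ 80%
density, sub-unit runs ignored), validates each against its modal unit,
and selects non-overlapping arrays longest-first; the longest array
≥ 10 kb per chromosome is the centromere candidate. This finds planted
high-copy satellite arrays — which is what the pipeline consumes — and
reports unit length, copy number and an identity×length score. It does
not build satellite consensus monomers and is not tuned for highly
degenerate arrays.

**NLR loci.** A locus is *genic* iff it overlaps any annotated gene span
by ≥ 1 bp (largest overlap wins, ties lexicographic); gene-span rather
than CDS overlap because the genic/intergenic contrast is drawn at gene
resolution, and an optional allowlist restricts which genes count.
Clusters are single-linkage chains with gaps ≤ 200 kb reporting at least
5 loci, summarised as a "n_genic/n_loci" ratio string with the span in
Mb. Loci entirely in intergenic space are candidate pseudogenized
sequences.

## Synthetic data generator

The generator emulates the *statistical* structure the pipeline consumes,
not sequence realism. Defaults (the study conditions for all tests):

| parameter | default | note |
|---|---|---|
| chromosomes / haplotype | 3 × 400 kb | keeps a full run in seconds |
| triads / pairs / singletons | 60 / 6 / 9 | pairs and singletons rotate through haplotypes |
| CDS length | 300 codons | N ≈ 690, S ≈ 210 sites per pair |
| pairwise Ka, Ks targets | U(0.01–0.05), U(0.05–0.20) | all under purifying selection (ratio < 1) |
| telomere copies / end | U{100–500} | 0.7–3.5 kb tracts |
| centromere | unit U{100–200} bp, array 10–20 kb | one array mid-chromosome |
| NLR loci / haplotype | 6 genic + 9 intergenic | on chromosome 1 |
| tissues | root, leaf, flower, fruit | one sample each |
| category proportions | 0.52 balanced, 0.04 × 3 dominant, 0.12 × 3 suppressed | ≈52/12/36% balanced/dominant/suppressed |
| Dirichlet concentration | 100 | see below |
| library size | 5 × 10⁶ reads | Poisson noise; NB optional |

Coding divergence: each triad has an ancestral random CDS (haplotype 1);
haplotypes 2 and 3 accumulate synonymous/nonsynonymous single-nucleotide
substitutions (one per codon, stop codons rejected) until the realized
NG86 rates are within ±10% of target — substitutions are discrete, so the
last move is reverted if it would overshoot further than the remaining
undershoot, and an unreachable target is an error carrying the realized
values. The truth table records the realized rates of all three pairs
(the H2–H3 pair is roughly twice the planted target, as both diverged
independently from the ancestor). Hit-table identities are the exact
protein identities of the simulated sequences, so pairing thresholds act
on exact values and triad recovery can be required to be perfect.

Expression: per triad and tissue, the relative vector is Dirichlet with
α = c·m where c is the concentration and m the category centroid pulled
5% toward the simplex centre (boundary centroids have zero components,
which a Dirichlet cannot take; the softening preserves the nearest
centroid and the c → ∞ limit for the balanced class). Triad abundance is
log-normal (σ = 1); expected counts scale with abundance × share × gene
length, normalised to the library size; noise is Poisson (negative
binomial with configurable overdispersion available). Concentration 100
keeps component standard deviations ≈ 0.05, a realistic within-category
spread that still separates the categories (boundary half-distances are
≥ 0.2).

What the generator does **not** emulate — hence what passing tests do not
show about real data: repeat landscapes and transposons, introns and
alternative isoforms, strand variation, mapping ambiguity between close
homoeologs (counts are drawn per gene, not re-mapped), batch effects and
replicate structure, and paralogous gene families that could stress the
open-chain resolution rule.

## Numerical choices and degenerate inputs

A zero-sum TPM vector is a flagged *undefined* state, not an error, and
is excluded from summaries; an all-zero sample yields all-zero TPM with a
warning. Ties in best hits, nearest centroids and overlap assignment are
broken by fixed documented orders so all outputs are deterministic.
Percentages are rounded to 2 decimals. All stochastic stages take
explicit integer seeds; nothing is time-seeded.

## Problem sizes

The shared test simulation uses 12 triads on 3 × 200 kb chromosomes; the
default (acceptance) run uses 60 triads on 3 × 400 kb chromosomes;
classifier-recovery runs use 1,000 bias-only triads without genome
assembly. These sizes make the full suite and the acceptance script run
in well under a minute each while every rate being estimated has enough
events to be meaningful.

## Known limitations

The centromere scanner reports array boundaries to within one unit length
(random flanking bases can extend a lag-u match by a few positions). The
NG86 implementation applies no weighting for transition/transversion bias
(that is a property of the NG86 method, not a shortcut). Open-chain
resolution by weaker-link deletion is deterministic but greedy; a
maximum-weight matching over an entire ambiguous family could differ on
adversarial inputs.
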