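# Methods

This note documents the models, estimators, and numerical choices behind
`chromarc`, and what the synthetic-data generator does and does not emulate.

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED convention). Overlap means at
least one shared base pair; book-ended intervals ([0,100) and [100,200)) do
not overlap but are joined by `merge_intervals` at gap 0, since their
separation is 0 bp. `merge_intervals(s, gap)` joins intervals whose
separation is ≤ gap; it is idempotent and order-invariant, and gap = 1000
reproduces the 1 kb stitching used to build histone ChIP regions.

Nearest-TSS distances are measured from the site midpoint to the TSS base,
signed in the gene's transcriptional orientation (positive downstream).
Midpoint-to-point was chosen over edge-to-point because the downstream
profile analyses are all anchored on region centres; ties in absolute
distance break to the lexicographically smaller gene id so outputs are
reproducible. Sites more than 3 kb from any TSS are flagged distal; sites
on chromosomes absent from the annotation are flagged, never dropped.

The enhancer-taxonomy exclusion rule uses *edge* gap (region to TSS or to
the nearest promoter-mark region), because a multi-kb enhancer domain whose
edge abuts a promoter should be excluded no matter where its midpoint lies.

## Peak calling

Fixed 500 bp windows at 100 bp steps are scored against the mean per-bp
coverage of the flanking 10 kb on each side (scaled to window width).
Accessible-chromatin mode keeps windows > 4-fold over that local
background and merges survivors at gap 0. Immunoprecipitation mode
additionally requires > 2-fold over the depth-scaled input track and a
Poisson upper-tail BH q < 0.001 against the local rate, merging at gap
1000. Window, step, and flank sizes are configurable; the defaults are
fixed here since the upstream tooling that inspired them does not document
its internals.

## Differential testing

Counts are normalized to the mean library size. The test conditions on the
per-peak total: the group sum of n i.i.d. NB(μ, 1/φ) variables is
NB(nμ, n/φ), so under the null the split of the total between conditions
follows the normalized product of the two group-sum pmfs, and the
two-sided p-value sums the probabilities of all splits no more likely than
the observed one (computed in log space; ties included with a 1e-10
relative tolerance).

The common dispersion φ is estimated from replicate variability: per peak,
within-condition sums of squares are pooled; because a χ²-distributed
variance estimate's *median* understates the variance at low degrees of
freedom (at df = 2 by the factor qχ²(0.5, 2)/2 ≈ 0.69), the pooled
estimate is rescaled by that factor before the method-of-moments step
(φ̂ = (s²_corrected − m)/m²), and the genome-wide median (floored at 0.01)
is used for every peak. Without the correction the test ran visibly
anticonservative at two replicates (≈4.7% of a 10 000-peak global null
called at q < 0.05); with it the null call rate is ~0 while power on
planted |log2 FC| = 1.5 effects stays ≈ 0.9. A single replicate per
condition degenerates to a Poisson test (φ → 0) with a warning.

Fold changes use pseudocount 0.5 on normalized condition means, so zeros
stay finite. Calls are up/down/unchanged at |log2 FC| ≥ log2 1.5 and
BH q < 0.05 exactly; swapping condition labels negates every log2 FC and
leaves p-values unchanged.

## Tag-density clustering

Profiles are fragment-midpoint counts in 10 bp bins over peak centre
± 500 bp, scaled to fragments-per-10-million. Clustering distance is
1 − Pearson r on mean-centred rows, equivalently cosine distance on
centred unit-norm rows, so the update step is spherical: the centroid is
the renormalized mean of member rows, under which the objective
(sum of within-cluster 1 − r) is non-increasing; the recorded
`objective_history` asserts this. Initialization is seeded k-means++ in
the same metric, so a fixed seed gives bit-identical assignments. Rows
with zero variance have no defined correlation; they sit at distance 1
from every centroid and are assigned to the largest cluster with a
warning. Empty clusters are re-seeded with the worst-fit row (this rare
step can in principle break strict monotonicity; it is logged in the
history if it does).

The two-view input for the full pipeline concatenates the reference
condition's profile with the per-bin log2 change profile, capturing both
peak shape and its condition dependence in one metric space; k defaults
to 7 but is a free parameter.

## Enhancer taxonomy and the tangent cutoff

Enhancers are H3K4me regions whose edge gap to both the nearest TSS and
the nearest H3K4me3 region exceeds 1 kb (strictly); H3K27ac overlap
(≥ 1 bp) separates active from poised. Active regions carry the summed
score of overlapping acetylation regions.

Super-enhancers use a rank-curve tangent cutoff: scores are ranked
ascending, rank and score are rescaled to [0, 1], and the cutoff is the
first consecutive-point slope exceeding 1 (with a 1e-9 tolerance so an
exactly linear curve — slope ≡ 1 — yields none); every region ranked above
the cutoff is super. This makes the super set an upper set of the score
ranking and is checkable by exhaustive search over cut points. One
consequence worth knowing: *heavier* score tails produce *fewer*, more
exceptional super-enhancers, because an extreme outlier compresses the
rescaled curve and moves the slope-1 crossing upward. All-equal scores
yield none, with a warning.

Element enrichment assigns each site one primary label by the priority
promoter > TTS > 5'UTR > 3'UTR > exon > intron > intergenic (promoter =
TSS ± 1 kb, TTS = transcript end ± 1 kb), so observed counts partition the
site set. Expected counts come from the background set's composition;
log2 ratios use pseudocount 0.5 on both terms.

## Nucleosome spacing

Mononucleosome fragments are those with 180 ≤ length ≤ 247 bp, both bounds
inclusive. The dyad is the fragment midpoint (floor), the standard
surrogate. The profile accumulates dyads at 1 bp offsets over motif centre
± 500 bp and divides by the motif count; motif strand is ignored (the AP-1
element is quasi-palindromic). Optional Gaussian smoothing (default 10 bp
in the pipeline, 0 = raw for exact tests) stabilizes the argmax on sparse
data and is recorded in the profile metadata. The spacing estimate takes
the density argmax upstream of −50 bp and downstream of +50 bp (the
exclusion zone keeps the argmax off the factor-footprint valley), with
ties resolved toward the motif; no read-offset (+4/−5) correction is
applied by default since the generator plants dyads directly.

## Interaction enrichment

Interactions are kept when intra-chromosomal, with anchor-midpoint span in
[5 kb, 1 Mb] inclusive, and (by default) identical UMI strings on both
ends; each passing interaction counts once (a `--dedupe-umi`-style
collapse is deliberately not applied, and the UMI rule is interpreted as
chimera filtering). Endpoints receive every feature category whose nearest
feature midpoint is ≤ 3 kb from the anchor midpoint; unlabeled endpoints
remain in the endpoint pool. The null shuffles the endpoint label sets
uniformly across all 2n endpoint slots, holding the pairing and the label
multiset fixed; expected counts, sd, z, and a two-sided empirical p with
the +1 correction are reported per category pair, and log2 ratios use
pseudocount 0.5. Fewer than 10 permutations is an error.

## The synthetic-data generator

Every generator is a pure function of (config, seed); child RNG streams
are spawned per dataset kind from the master seed, so adding one generator
never perturbs another. Defaults encode the study conditions the analyses
assume:

- **Peak counts** — NB(mean = base × 2^effect × library factor, common
  dispersion 0.05), base intensities lognormal around 100, library factors
  uniform in [0.7, 1.3], two conditions × two replicates. The planted
  class structure is 12.5% loss and 5.2% gain at |log2 effect| = 1.5 —
  the changed-site fractions the analysis is built around.
- **Fragments** — a length mixture (defaults: sub-nucleosomal 60 ± 20 bp
  and mononucleosomal 200 ± 10 bp, equal weight). Mononucleosomal dyads
  fall Normal(± offset, 20 bp) around a random motif centre (offsets
  120 bp intact / 101 bp deficient, i.e. a planted 38 bp spacing loss),
  with a 20% uniform background; sub-nucleosomal fragments are uniform.
- **Marks/features** — 2 kb H3K4me domains on 40% of TSS-distal peaks,
  60% of them acetylated with Pareto(1.2)-tailed scores (heavy enough for
  a super-enhancer elbow), H3K4me3 at 80% of TSSs, motif sites and
  remodeler/AP-1 binding regions at peak-centre subsets.
- **Interactions** — anchors on a 5 kb grid inside 1 Mb blocks, so every
  same-chromosome anchor pair has a valid span; endpoint pairs are drawn
  from the anchor pool, and a planted (A, B) enrichment factor f is
  realized by forcing m A–B pairs, where m solves
  observed/shuffle-expected = f accounting for the label-frequency
  inflation that forcing itself causes (the achievable factor saturates
  near 1/(4q(1−q)) at label frequency q, so planted categories are kept
  rare). Spans therefore follow from anchor geometry rather than an
  explicit distribution — the design choice that keeps the permutation
  null exactly aligned with the generative model. Decoys violate the span
  window or carry mismatched UMIs.
- **Genes/expression** — disjoint three-exon gene models on 50 kb slots
  with the derived promoter/UTR/exon/intron/TTS partition; FPKM lognormal
  with ±1.5 log2 effects planted on genes nearest to changed sites.

What the generator does **not** emulate: GC/mappability bias, fragment
duplication, inter-replicate batch structure, peak-width heterogeneity,
genuine genomic clustering of regulatory elements, or distance-decay in
contact frequency. Passing tests therefore demonstrate correctness of the
estimators under the stated statistical model, not robustness to every
artefact of real libraries.

## Problem sizes and tolerances

The test and acceptance workloads use 10 000 peaks for differential
calibration (type-I ≤ nominal + 3 Monte-Carlo sd; power > 0.8), 50 000
mononucleosome fragments per condition around 500 motifs for spacing
(recovered reduction 38 ± 4 bp at bandwidth 10), 1 000 rows for clustering
recovery (ARI > 0.95), 10 000 interactions with 1 000 permutations
(null mean |log2| < 0.1; planted 5× within ±0.3 of log2 5), and ≥ 100
randomized instances per interval-op oracle. These sizes make every
stochastic check stable across seeds while the whole suite runs in well
under a minute per stage.

## Known limitations

- The NB exact-style test uses one genome-wide dispersion; peak-specific
  or trended dispersion (as in mature count-model packages) would gain
  power at high counts.
- The peak caller is a deliberately simple window scanner; it is not a
  drop-in replacement for production callers and is tuned only for the
  rectangular-enrichment regime the tests exercise.
- Percentages print with half-away-from-zero rounding at one decimal,
  matching the convention of the reported headline numbers.
- The cascade treats all overlaps as ≥ 1 bp; no reciprocal-fraction
  variant is implemented.
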