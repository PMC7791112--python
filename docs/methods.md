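# Methods

## Scope and model

`permdeg` addresses differential expression in a two-group bulk RNA-seq
design with very few replicates per group (the target design is 3 vs 3,
FPKM-quantified). With n = 3 per group, parametric t-test p-values are
fragile and the number of distinct label permutations is tiny (C(6,3) = 20),
so the caller is built around empirical calibration:

* two per-gene statistics — pooled-variance Student *t* and the
  log2-median-ratio (difference of group medians; the fold-change
  statistic, reported as test group minus reference);
* permutation nulls of both statistics, obtained by reassigning group
  labels over samples with group sizes preserved;
* two-sided empirical p-values with add-one correction,
  p = (1 + #{|null| ≥ |observed|}) / (1 + N), so p ∈ (0, 1] always;
* a signed Stouffer combination of the two p-values;
* a data-derived fold-change cutoff, (|q₂.₅| + |q₉₇.₅|)/2 of the pooled
  null fold-change distribution;
* the call: combined p < α (default 0.05) and |log2 fc| strictly greater
  than the cutoff.

"Adjusted p-value" here means this empirical permutation p-value; no
additional multiple-testing correction is applied by default because the
procedure thresholds the combined p directly at α (Benjamini–Hochberg is
available behind a flag for users who want FDR semantics).

## Null granularity

A 3v3 design admits 20 distinct label assignments, so a per-gene null can
never resolve p below 1/21. The default therefore pools permuted statistics
across genes (`null_mode="pooled"`), the common practice for permutation
differential expression; `per_gene` and `exhaustive` modes exist for
analysis and testing. Random permutations are drawn uniformly with
replacement from the label assignments; the identity assignment may appear,
which is standard and keeps the p-value distribution honest. The
fold-change cutoff always uses the pooled fold-change null, whatever the
p-value mode.

An important behavior of the pooled null on data with many strong effects:
under any 3v3 label split, the median of each pseudo-group of a strongly
bimodal gene still lands near one of the two group means, so permuted
fold-changes of truly differential genes stay close to their observed
effect. The pooled null is therefore contaminated in proportion to the
differential fraction, and the realized cutoff grows with both the planted
effect size and the fraction of differential genes. This is intrinsic to
deriving the cutoff from a pooled null and is the main driver of the
pipeline's conservatism (observed type-I DEG rates on effect-free
simulations run at ≈ 0.035 at α = 0.05, and false-discovery proportions on
planted-effect simulations at ≈ 0).

## Stouffer combination

Each two-sided empirical p is converted to a directional z via
z_i = max(Φ⁻¹(1 − p_i), 0) · sign_i, the two z's are averaged with weights
1/√2, and the combined two-sided p is 2(1 − Φ(|z_c|)). Two points are
deliberate:

* the quantile is Φ⁻¹(1 − p), not Φ⁻¹(1 − p/2): with this convention
  (p, p) concordant at 0.05 combines to 0.0200, the fixed point used by the
  test suite's independent normal-CDF oracle;
* the floor at z = 0 makes p = 1 contribute exactly nothing. Without it,
  p > 0.5 would map to negative z and, after sign multiplication, flip into
  evidence for the *opposite* direction, which is incoherent for a
  magnitude-based two-sided p. The cost is that p-values above 0.5 are
  treated as uninformative, which is the intended reading.

Degenerate variance: a gene with zero pooled variance and unequal means
gets a signed infinite t, which the empirical-p machinery ranks as more
extreme than every finite null value; zero variance with equal means gives
t = 0.

## Preprocessing

Expressed genes are those with FPKM ≥ 1 (boundary inclusive) in at least
one sample. Expression is then log2-transformed and quantile-normalized
(reference distribution = arithmetic mean of per-rank order statistics;
ties within a sample receive the mean of the reference entries over their
tied rank range, which preserves column sums and the grand mean).

The log2 transform takes an `offset` parameter, log2(v + offset). The
package default is 1.0, which is safe for real FPKM tables containing
zeros. The synthetic generator produces strictly positive FPKM, so the
recovery and error-rate measurements in the test suite and the acceptance
script use offset 0 — plain log2(FPKM), the scale on which the planted
effects are defined. The offset matters: +1 compresses log2 effects for
low-abundance genes (a planted 4-fold shift at baseline FPKM ≈ 2 shrinks
from 2.0 to ≈ 1.2 on the log2(v+1) scale), which costs roughly 8 points of
sensitivity under the recovery conditions below.

## Synthetic data

The generator emulates the target study design, not real FPKM marginals:

* per expressed gene, a baseline log2 mean drawn uniformly on [0, 10]
  (default), sample values Normal(mean, sigma_log2 = 0.35) on the log2
  scale, exponentiated to FPKM;
* differential genes shift the two group means by ± effect_log2/2
  (default effect 2.0, i.e. 4-fold), so the planted group difference is
  exact; the differential fraction defaults to 5%, split half up / half
  down (odd remainder to "up");
* silent genes (default 20%) are uniform FPKM on (0, 0.5), strictly below
  the detection cutoff, so the expressed-gene filter removes them in every
  run;
* ancillary generators plant TFs whose target sets are enriched for the
  differential genes (≥ 5 DE targets), gene sets with 75% DE members,
  promoter sequences with motif-consensus sites (reverse-complemented on
  the minus strand), and uniform random interaction edges.

What this does not model: count noise (negative binomial), library-size
variation, batch effects, correlated genes, realistic FPKM marginals.
Passing recovery tests therefore demonstrates the correctness and
calibration of the procedure under its own assumptions, not performance on
real tissue data.

All generators draw from per-generator child streams
(`SeedSequence(seed, spawn_key=(stream,))`) of one master seed, so any
module can be rerun independently and the full pipeline is byte-identical
under a fixed seed.

## Problem sizes used in validation

The packaged checks run at the scale of the target design: type-I error on
20 effect-free simulations of 2000 genes (3v3, 1000 permutations each);
recovery on 10 simulations of 2000 genes with 10% differential at effect
2.0 and sigma 0.35 (measured mean sensitivity ≈ 0.85, mean false-discovery
proportion 0.0, realized cutoff ≈ 1.65 log2); the exhaustive-enumeration
oracle on 50-gene matrices; the Fisher oracle over all 2×2 tables with
margins ≤ 30. The acceptance script's headline run uses 12 000 genes with
the default 5% differential fraction.

## Motif scanning

JASPAR-style PFMs (bracketed, labeled-plain and unlabeled row dialects) are
converted to log2-odds PWMs with a pseudocount (default 0.8) distributed in
proportion to the background (uniform by default):
p(b, j) = (count + pc · bg_b)/(colsum + pc). The relative score of a window
is min–max normalized over the matrix's own attainable score range; it is
1 exactly on a per-column argmax path and 0 on the anti-consensus. Hits are
windows with relative score strictly above the threshold (default 0.9),
scored on both strands (minus-strand windows via the base-complemented,
position-reversed matrix) and reported in plus-strand 0-based half-open
coordinates; windows containing N are skipped. Consensus ties resolve in
A,C,G,T order. Uninformative motifs (equal counts in every column, so
s_max = s_min) are rejected rather than scored.

## Enrichment

One-sided (greater) Fisher's exact test via the hypergeometric upper tail;
the universe defaults to the expressed genes surviving the FPKM filter
(configurable), annotations are intersected with the universe before
testing, and sets disjoint from the universe are skipped with a warning.
The major-TF rule requires both p < α and ≥ 5 DEG targets; the count floor
makes the rule conservative on null TF maps. Raw p-values are thresholded
by default (BH behind a flag), mirroring the direct p < 0.05 convention of
the enrichment tools this stage stands in for.

## Network assembly

Nodes are DEGs, optionally restricted to members of chosen enriched sets;
node attributes carry log2 fold change, direction and set memberships.
Edges are user-supplied (protein–protein, activation, inhibition with
direct/indirect evidence); undirected protein–protein edges are
canonicalized lexicographically to deduplicate, self-loops and edges with
unretained endpoints are dropped with a logged count. Exports (SIF plus
attribute tables, TSV pair, GraphML) round-trip exactly; GraphML carries
set memberships as a `;`-joined string since the format has no list type.

## Known limitations

* The pooled-null fold-change cutoff is sensitive to the differential
  fraction (see above); on data where most genes change, it becomes very
  conservative.
* Per-gene p-value resolution in 3v3 designs is bounded at 1/21; pooled
  mode trades exactness for resolution by borrowing across genes.
* Only two-group, unpaired designs with equal-variance t are supported; no
  covariates, no count models.
* Motif scanning calibrates scores against the matrix's own range, not a
  p-value model; thresholds are comparable across motifs only in the
  relative-score sense.
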