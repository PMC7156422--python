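# Methods

`hicreprog` re-implements, as a tested library, the chromatin-architecture
analyses used to characterize nuclear-reprogramming trajectories in early
mouse embryos from Hi-C data: matrix normalization, distance-decay state
classification, A/B compartments, insulation-score TADs, the relative TAD
intensity statistic, H3K9me3-marked TAD classification, and super-enhancer–
promoter interaction calling.  Because the real embryo datasets are not
bundled, every stage is validated against a synthetic generator that plants
the structures the analyses are supposed to detect.

## Synthetic generator

A cis bin pair (i, j) at separation s = |i−j|·(bin size) receives a Poisson
count with rate

    λ_ij ∝ s^α · f(s; d_c) · (1 + β·1[same TAD]) · (1 + γ·e_i·e_j) · loop fold

- **α** — distance-decay exponent; s⁻¹ emulates the interphase
  fractal-globule regime, s⁻⁰·⁵ the condensed metaphase regime.
- **f(s; d_c)** — metaphase fall-off: f = 1 for s ≤ d_c and
  exp(−(s−d_c)/d_c) beyond.  Damping applies only *past* the fall-off
  scale; this keeps the power-law regime below d_c clean (the fitted
  exponent over 0.5–3 Mb is unbiased) and places the maximum of the
  s⁻¹-normalized decay curve exactly at d_c for α > −1, which is what the
  fall-off detector measures.  Metaphase maps use d_c ≈ 10 Mb (mitotic) or
  ≈ 4 Mb (meiosis II).
- **β ≥ 0** — within-TAD contact boost over non-overlapping planted TAD
  intervals; β = 4 produces TADs of realistic visual strength, β ramps
  model maturation.
- **e, γ** — a ±1 per-bin compartment vector with plaid strength γ < 1
  (γ = 0.5 in mature stages; the rate multiplier 1 + γ·e_i·e_j stays
  positive).
- **loops** — focal (i, j, fold) enrichments for interaction calling.

Rates are scaled so the expected total count equals the requested depth.
Trans contacts, when requested, are uniform across inter-chromosome pairs
at a rate fixing their expected mass fraction.  Self-interactions are
excluded (diagonal zero), mirroring self-ligation removal in real
pipelines.  One master seed deterministically derives per-stage streams.

Default study conditions used by the tests and the acceptance script:
2,000–3,000 bins at 100 kb (a 200–300 Mb chromosome), depth 1–2 × 10⁶
contacts per map, five seeds per measured quantity.  These sizes keep a
full run in minutes on one CPU while leaving per-bin counts high enough
that parameter-recovery bands (±0.05 on exponents, ±25% on fall-off
scales) are dominated by the method, not by sampling noise.

What the generator does **not** emulate: restriction-fragment geometry and
ligation chemistry, mappability and GC coverage bias (ICE is exercised on
Poisson marginal noise only), nested/hierarchical TADs, cell-to-cell
heterogeneity, and overdispersion (counts are Poisson; the downstream
binomial caller assumes exactly this, so calibration results on synthetic
maps are a best case and real data would be overdispersed).  Passing tests
therefore demonstrate correctness of the computations and recoverability of
planted structure — not robustness to every artifact of real Hi-C.

## Contact matrices and normalization

Matrices are dense per-chromosome symmetric arrays with a BED-style bin
table (0-based half-open); the interchange format is the HiC-Pro triplet +
bin-table pair.  ICE balancing iterates W ← W / (s sᵀ) on normalized
marginals s until the coefficient of variation of nonzero-row marginals
drops below `tol` (default 1e-8, max 300 iterations), then rescales so the
mean over unmasked cells matches the pre-balancing mean.  Bins whose raw
marginal falls strictly below the 2nd percentile of nonzero marginals are
masked first (configurable; a guard against sparse-coverage artifacts —
the upstream convention, not a tuned value).  Depth scaling multiplies to a
common total of 1e8 counted pairs.  Masked bins stay zero and are excluded
from all means, medians and pair counts downstream.

## Distance decay and state classification

P(s) follows the plotted convention: separations are binned in log10 steps
of 0.05, mass per bin is divided by total mass (the raw curve sums to 1),
and the curve may be divided by a unit-normalized s⁻¹ reference computed
over the *same* pair geometry.  Matrix input uses a minimum separation of
2 bins to suppress residual self-ligation signal near the diagonal.

Because per-log-bin mass of an s^α law scales as s^(α+1), the exponent fit
divides each bin's mass by its locus-pair count, recovering the per-pair
mean contact frequency whose log-log slope is α.  The default fit window
is 0.5–3 Mb — inside both metaphase fall-off scales, so interphase and
metaphase maps are compared over a common power-law regime.

The fall-off detector returns the geometric bin center at the maximum of
the 3-bin-smoothed s⁻¹-normalized curve, None when the maximum sits at the
window edge.  State classification: a map is metaphase-like when its
fitted exponent is closer to −0.5 than to −1 *and* an interior fall-off is
detected (searched up to 30 Mb); fall-off ≤ 6 Mb ⇒ MII metaphase, > 6 Mb ⇒
mitotic metaphase; otherwise interphase.  The 6 Mb split is the log-scale
midpoint between the 4 and 10 Mb anchors.  Published comparisons judge
which reference scaling a curve better matches by eye, without a numeric
rule; this exponent-plus-fall-off rule is our formalization.  Note that on a sampled
pure power-law map the *noisy* normalized curve can have an interior
maximum; classification is robust to this because the exponent condition
fails, but `detect_falloff` alone should be interpreted only for maps whose
exponent test indicates a metaphase-like regime.

## Compartments

Per chromosome: observed/expected (each entry over its diagonal mean, on
unmasked bins), Pearson correlation matrix, leading eigenvector scaled by
√λ₁ as PC1 — so a strong plaid yields PC1 magnitudes near 1 and the
|ΔPC1| > 1 switching rule operates on a meaningful scale.  The sign is
oriented against an activity track (TSS density or an active-mark ratio):
bins at or above the track median must have the higher mean PC1, making
A = PC1 > 0 the active compartment.  Compartment switches require a PC1
sign change *and* |ΔPC1| > 1 between stages (X chromosome excluded);
replicate-based adjusted-p filtering used by the original external tool
cannot be reproduced on single-replicate synthetic data and is replaced by
this threshold rule.

The segregation ratio compares mean A–B to mean within-compartment (A–A or
B–B) contact frequency.  Because A–B pairs sit at systematically larger
separations, the ratio is computed per distance stratum (both classes must
have ≥ 10 pairs) and averaged unweighted across qualifying strata — pooling
masses across strata would re-introduce the distance confound and push the
ratio below 1 even for γ = 0 maps.  Trajectory clustering is K-means
(K = 10 by default, fixed seed, 10 restarts).

## TADs, insulation, RTI

Insulation: for bin b, the mean contact frequency of the 1 Mb × 1 Mb
square straddling b (rows b−w…b−1, columns b+1…b+w), log2-normalized by
the chromosome-wide mean of square means.  The delta vector is the mean
insulation over the upstream 200 kb window minus the downstream one;
boundaries sit at downward zero crossings whose surrounding delta
peak-to-trough amplitude is ≥ 0.25 (the `is/ids/nt` convention of the
reference script, restated from its flags).  Consecutive boundaries define
TADs; chromosome ends close the terminal TADs.

DI uses the classic 2 Mb window: A and B are the upstream/downstream
contact sums, E = (A+B)/2, DI = sign(B−A)·((A−E)²+(B−E)²)/E.

Aggregate TAD maps resample each TAD plus half-length flanks onto a fixed
grid by area-weighted block averaging (mass-stable, unlike
nearest-neighbor), average across TADs and normalize the aggregate to mean
1 so stages have equal matrix sums; stage differences are entrywise.

RTI: within the neighborhood embedding a TAD of L bins, each separation
d = 1…L−1 contributes median(I_in)/median(I_out), where I_in are pairs
with both ends inside and I_out pairs with exactly one end inside and the
partner within one TAD length of the TAD; the RTI is the median of row
ratios.  The extent of the embedding neighborhood admits two readings
(partner restricted to within one TAD length, or unrestricted along
the chromosome); the restricted reading is implemented because it keeps
I_out distance-comparable with I_in — rows at separation d then compare
pairs drawn from the same local neighborhood.  A uniform matrix gives
RTI = 1 exactly.  TADs are classified unreprogrammed when their RTI
exceeds the reference stage's by more than 1.2-fold (the source states no
numeric rule; 1.2 is this package's configurable default).  Marked-TAD
classification requires the length- and depth-normalized ChIP coverage to
exceed the input coverage strictly.

Region-to-feature assignment uses either-fraction semantics: overlap ≥ 50%
of the region or of the feature (the `-f 0.5 -r -e` convention); the
relative boundary distance of a region is Dmin/Dtad ∈ [0, 0.5].

## Interaction and super-enhancer calling

Significant interactions (100 kb resolution, 200 kb–20 Mb by default): the
expected contact probability per pair is the 3-bin-smoothed mean count per
pair in its 0.05 log10 distance bin divided by the total tested count; the
observed count is tested against Binomial(N, p_d); BH correction across
all tested pairs; significant at q < 0.01.  A second pass re-estimates the
expectation after removing first-pass significant pairs, preserving the
two-pass intent of spline-based callers without the spline (documented
substitute, not a port; testing is per chromosome).  On Poisson synthetic
maps the caller is conservative under the null and recovers a planted 50×
enrichment at 2 Mb at depth 2 × 10⁶.

Super-enhancers: promoter-overlapping peaks (any overlap) are removed,
survivors stitched within 20 kb (the stitching-window flag of the source
tool is unit-less; 20 kb is the conventional reading and is configurable),
entities ranked by aggregate signal, and the cutoff placed at the elbow of
the scaled rank–signal curve (argmin of y−x, where the tangent slope is 1
on a convex ascending curve).  Promoters are TSS ± 1 kb.  Interaction
regions derive from read 5′ ends and restriction sites, with regions under
500 bp replaced by the 500 bp window anchored at the site.  SE–P requires
≥ 50% of one region in a super-enhancer and ≥ 50% of the partner in a
promoter (order-symmetric); P–P requires both in promoters.

## Demo trajectory

`demo_scnt_trajectory` chains six synthetic stages — mature interphase
donor (α = −1, β = 4, γ = 0.5), mitotic metaphase (α = −0.5, d_c = 10 Mb,
no TADs/plaid), MII metaphase (d_c = 4 Mb), then interphase stages with
(β, γ) = (1, 0.25), (2, 0.35), (4, 0.5) — through the full battery on a
500-bin, 100 kb, depth-2e6 chromosome.  The summary table shows metaphase
state labels and zero insulation boundaries only at the two metaphase
stages, compartment recovery (|r| > 0.8 against the planted vector) only
at interphase stages, and RTI/segregation maturing monotonically across
the post-activation stages.

## Numerical conventions and limitations

- Coordinates are 0-based half-open everywhere; bin of a position is
  floor(pos / bin size); terminal short bins are kept.
- Ties in fall-off detection break to the smallest distance; empty
  expectation strata inherit the nearest occupied log bin.
- RTI rows with an empty class or a zero outside-median are skipped; all
  rows skipped is an error, as are degenerate inputs elsewhere (all-zero
  matrices, < 10 unmasked bins for PC1, < 5 occupied bins for a fit).
- Dense matrices cap practical size at a few thousand bins per chromosome;
  genome-wide runs at 10 kb would need a sparse/cooler backend, which is
  out of scope here.
- Real-data cohort numbers (boundary counts per stage, switch counts,
  marked-TAD and SE totals) depend on the deposited sequencing data and
  are not reproducible from synthetic maps; the package reproduces the
  *machinery* and its parameter-recovery behavior.
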