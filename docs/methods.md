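# Methods

`cnscreen` implements the analysis pipeline of a colony-array fitness screen
in which a prototrophic yeast deletion collection is grown on minimal media
built from every pairwise combination of four carbon sources (glucose,
galactose, ribose, glycerol) and seven nitrogen sources (ammonium, proline,
glutamate, glutamine, arginine, urea, allantoin).  This note records the
model, the numerical choices, and what the synthetic tests do and do not
demonstrate.

## Growth rates

The growth rate of a colony is the slope of the ordinary least-squares fit
of colony area (pixels) against time (seconds), with an intercept — pinned
colonies start at a nonzero area.  Plates are scanned at 0, 5, 10 and 24 h
(glycerol conditions add a 48 h scan).  Colonies with fewer than two finite
observations are missing (NaN); fitted negative slopes are defined to be 0,
before any normalization.  Positions manually curated as "plated but dead"
carry rate 0 and are serialized with a separate boolean flag so that "no
data" and "dead colony" remain distinguishable.

## Reference construction and normalization

The reference condition, glucose:ammonium, is grown as six replicate plate
sets.  Per array plate, the replicate with the fewest missing values is the
anchor; the other five are LOWESS-rescaled to it; the six are averaged
positionwise into the reference plate, and the positionwise sample SD of
the six residuals about that mean is the strain-wise SD `sd_strain`.

The LOWESS rescaling of a plate toward a target regresses the
(target/plate) rate ratio on the plate's own rate — locally linear window
covering 50 % of the jointly finite, nonzero positions, one robustifying
iteration — and multiplies each finite rate by the smoothed ratio at that
rate.  Identical plates are a fixed point, and a constant scale factor is
recovered to machine precision.  Zero rates pass through unchanged: the
ratio is undefined at zero and dead colonies must stay dead.

Two properties of this estimator matter for interpretation:

- **Errors-in-variables attenuation.**  Because the regressor (the plate's
  own rate) is noisy and shares its noise with the ratio, the fitted ratio
  curve tilts against the rate even when the true relationship is flat.
  This deterministically compresses normalized rates toward the plate
  centre; the compression grows with the ratio of measurement noise to the
  plate's genuine rate spread.
- **Outlier absorption above the bulk.**  A colony far above the plate's
  rate range is corrected by an extrapolated ratio, which can absorb a
  large part of a genuine faster-than-expected effect.  Below the bulk the
  fit is anchored by the collection's tail of constitutively sick strains,
  so slow effects survive.  Detection is therefore asymmetric: strong slow
  effects are recovered at high rates, while fast effects must be modest
  (inside or near the plate's rate distribution) to be seen.

## Spatial filter

Per plate, extreme values (the most extreme 5 % of the finite
distribution) and missing positions are temporarily replaced by the plate
mean; a 2-D Gaussian filter (σ = 2 grid units, kernel truncated at 3σ,
reflective boundary) supplies infill values for the missing positions; the
extremes are then restored and the infilled plate is smoothed again; the
zero-mean residual between that smoothed plate and its mean is subtracted.
The replacement is only temporary — it protects the infill from outliers —
because smoothing the trimmed plate instead would systematically
under-estimate any real gradient (extreme values concentrate in the
high-leverage edge columns).  As implemented, the filter removes ≈96 % of a
planted linear column gradient and preserves the plate mean exactly; it
cannot remove bias structure sharper than σ, and it slightly dampens real
spatial clusters of effects.  σ defaults to 2 because the bias of interest
(pinning, media thickness) varies over many colonies, while a single
colony's effect occupies one position.

## Modified z-scores and hit calling

Per plate and condition, the residual between the normalized rate and the
reference is standardized:

    z = (CondY' − GAref) / sqrt(sd_strain² + sd_plate²)

`sd_plate` is the SD of that plate's residuals under the condition
(general growth variation on the plate), computed per (plate, condition).
Strains present at several positions are averaged at the z level.  Glycerol
conditions are excluded from scoring: growth there is too slow for mutant
effects to rise above noise.

The 701 wild-type replicate positions provide a per-condition empirical
null; a normal distribution is fitted to their z-scores by moments, as the
null summarizes location and scale and the wild-type sample is large.
One-sided p-values against this null enter a Benjamini–Hochberg step-up
separately per (condition, direction) family; the condition-specific
threshold at an FDR level is the least extreme z among rejected tests
(±∞ when none).  Hit lists follow by thresholding; the glucose:ammonium
row of the hit-count summary is the mean over the six replicate instances,
which is why it can be fractional.

Two couplings limit exact calibration and are inherent to the design: the
reference mean and `sd_strain` are computed from the same six replicates,
which positively correlates the z numerator and denominator and makes the
tails slightly lighter than normal (the hit caller is conservative); and
the attenuation described above makes mutant z-scores wider-tailed than
the single-rate wild-type null whenever the collection's fitness spread is
comparable to the measurement noise (the hit caller is anti-conservative
for heterogeneous collections).  The null-calibration simulation is
therefore an isogenic, effect-free array — the exchangeability that the
wild-type replicate null itself assumes — and measures the calibration of
the z → null → BH → threshold chain in isolation.  Measured mean
false-discovery proportion over 20 such screens is ≈0.12 at nominal 0.20.

## Wild-type interaction model

Independent carbon and nitrogen contributions to growth rate should
combine multiplicatively, so the model is OLS of log(rate) on carbon main
effects, nitrogen main effects and carbon×nitrogen interactions, with
reference-cell coding (glucose, ammonium baselines; natural log).  Fitting
is replicate-level — every wild-type replicate rate, giving the term
standard errors — with zero rates excluded and counted.  Terms are judged
at α = 0.01.  The multiplicative-vs-additive family comparison evaluates
both models' likelihoods on the raw rate scale (the log-normal likelihood
carries the 1/y Jacobian) and compares AIC.

## Source-signature NMF

The binarized gene×condition matrix of significant slow effects at 20 %
FDR (glycerol columns removed; of the six reference replicate columns only
`glucose:ammonium01` kept; empty gene rows dropped) is decomposed as
Data ≈ Signatures × Coefficients, where Coefficients is the fixed binary
source-composition matrix (each condition column has a 1 in its carbon row
and its nitrogen row; 10 source rows; rank 9 for the full design since the
carbon and nitrogen indicator blocks share a constant).  Only the
non-negative Signatures matrix is fitted: uniform random start in (0,1)
from a seed, then 20 multiplicative updates
W ← W ∘ (V Hᵀ) ⊘ (W H Hᵀ + ε) with ε = 1e-9.  The reconstruction error is
recorded per iteration and is non-increasing (the standard property of the
multiplicative update with a fixed second factor).  Genes with a raw
signature value above 0.4 form each source's membership list; no column
rescaling is applied before the cutoff.  Slow effects only enter the
binary matrix by default (signatures are sensitivity lists); a flag admits
both directions.  Membership support of a planted factor is recovered
exactly across random starts; the Frobenius error after the fixed 20
updates is ≈2 % of ‖V‖ (convergence to <1 % would need ~50).

## Profile analyses

Gene–gene similarity is Pearson correlation over jointly finite
conditions, undefined below 10 shared conditions (with ~21 scored
conditions, shorter overlaps are unstable).  Precision–recall against a
co-annotation standard ranks unordered gene pairs by similarity (ties
broken lexicographically), counts a pair as positive if the genes share a
term, and uses the standard's co-annotation rate over evaluable pairs as
the background — which the precision at full recall equals exactly.
Condition clustering takes the 500 highest-variance gene profiles and
clusters both dimensions agglomeratively (average linkage on
1 − correlation).  Set overlaps use the upper-tail hypergeometric;
per-term enrichments are Bonferroni-corrected by the number of terms.
Directional coherence of an annotated gene set across two condition groups
is a binomial sign test on per-condition medians (success probability ½;
14 matching conditions of 14 give p = 0.5¹⁴ ≈ 6.10×10⁻⁵).

For comparison against an external genetic-perturbation compendium, both
profile matrices are restricted to the shared gene universe, missing set
to 0, and normalized by 10 alternating column/row unit-norm passes ending
on the row side — exact simultaneous unit row and column norms exist only
for square matrices, so the convention here is that the profile vectors
entering the inner product have length exactly 1 while the column passes
balance gene contributions.  Similarity is the inner product; the top 10 %
of queries per condition feed enrichment.

The liquid confirmation assay scores a well as maximum optical density
divided by the time to saturation, saturation being the first time OD
reaches 95 % of its maximum (the instant is otherwise undefined on noisy
series).  The adjusted score divides the mutant/wild-type mean-rate ratio
in a condition by the same ratio in glucose:ammonium, so 1 means "no
condition-specific effect".

## Synthetic experiment generator

The generator emulates the screen's design: 16 plates of 16×24 pinned
colonies; one full wild-type plate plus wild-type replicates scattered on
a generalized diagonal of every other plate, 701 in total (the diagonal
touches every row and most columns — covering literally every row *and*
column of a 16×24 plate would need ≥24 positions per plate and exceed
701); 4,772 mutant strains filling the remaining positions; six
glucose:ammonium replicate plate sets; all 28 conditions.

Expected colony rate is multiplicative — base rate (3×10⁻³ px/s)
× carbon effect × nitrogen effect × carbon–nitrogen interaction × strain
fitness × planted gene–environment effect — then a smooth additive
quadratic plate bias (amplitude 1.5×10⁻⁴ px/s, ≈5 % of base) and
multiplicative log-normal area noise (5 % per scan) are applied; colony
area grows linearly from a 20 px pin.  Carbon multipliers (1, 0.8, 0.35,
0.15) and nitrogen multipliers (descending from ammonium/glutamine to
urea at 0.6) follow the qualitative ordering of wild-type growth on these
sources; 15 of the 18 non-reference interaction cells deviate from 1 and
three are exactly 1, so the wild-type model has a known count of
independent-contribution conditions.  Strain fitness is left-skewed: a
tight healthy bulk (log-SD 0.05 — most non-essential deletions grow
within a few percent of wild type in benign media) plus a 12 % tail of
constitutively sick strains (median ≈0.70); the tail is what anchors the
low-rate end of the LOWESS ratio fit, as it does in a real deletion
collection.  Planted gene–environment effects default to 0.5× (slow) and
1.25× (fast — faster-than-expected effects are biologically modest); 1 %
of colonies fail, half flagged as curated zeros and half dropped.

What the synthetic tests show: every stage recovers planted structure
(slow effects, interaction terms, source signatures, shared-signature
overlaps, profile blocks) under the design's geometry and realistic noise,
and the hit-calling chain is calibrated on exchangeable nulls.  What they
do not show: calibration on a heterogeneous real collection (see the
attenuation discussion — the method itself is anti-conservative there),
recovery of strong fast effects (absorbed by the rate-dependent
normalization), image-segmentation artifacts, colony–colony competition,
or agreement with the published screen's gene-level biology, which
requires the published supplementary tables as inputs.

## Scales used in the test suite

Module tests run a scaled-down screen (4 plates of 8×12, 300 mutants, a
complete 4-carbon × 3-nitrogen sub-grid — a full cross keeps the
interaction model identifiable).  Null calibration uses 20 isogenic
screens of 8 plates of 12×16 with ~1,340 mutant tests per condition, the
smallest geometry at which the far-tail behaviour of the BH step-up is
representative.  The acceptance script runs the full 16-plate,
4,772-strain geometry once, with structured galactose/ribose sensitivities
planted to measure signature-overlap recovery.
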