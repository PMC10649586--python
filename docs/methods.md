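# Methods

## Problem setting

`mirsig` operates on two-group tumor cohorts — borderline (B) versus
malignant (M) — profiled on two platforms: a log2-scale miRNA microarray
matrix (RMA-normalized upstream; normalization itself is out of scope) and
RT-qPCR quantification cycles (Cq) for a validation panel. The goal is a
classifier built from miRNA expression *ratios*, chosen because a ratio of
two miRNAs measured in the same reaction cancels every per-sample
multiplicative factor (RNA input, labelling efficiency, reference-gene
choice), removing the normalization step that most often breaks biomarker
panels.

## Candidate selection

Selection is a two-step funnel over per-miRNA group means:

- **Stringent step**: keep miRNAs with |log2 FC| ≥ log2(factor) — default
  factor 2, boundary included — and mean log2 expression above the floor
  (default 5) in *at least one* group. The source protocol does not state
  which group the floor applies to; the OR reading is the weakest filter
  consistent with it and is configurable.
- **Fold-change-only step**: up-regulated miRNAs with log2 FC *strictly*
  above log2(factor), no expression floor, minus miRNAs already selected.
  The strict/non-strict asymmetry between the two steps mirrors the
  protocol's wording ("greater than or equal to" versus "greater than").

Fold-change is the difference of log2 group means, i.e. the log2 ratio of
linear-scale geometric means.

Each candidate also carries `n_errors`: the minimum resubstitution error of
a single-threshold classifier on its own values, orientation fixed by the
candidate's direction (up: call M above the threshold; down: below).
Thresholds are enumerated at midpoints of consecutive sorted unique values
plus ±∞; a value exactly on the threshold is classified on the B side.
With cohorts of this size only resubstitution error is meaningful, so no
cross-validation is attempted. Constant values return min(n_B, n_M), not
an error.

Two follow-up filters flag rather than drop candidates, so the funnel can
be audited: an expression rule (mean B expression > 5 **or** mean M
expression > 20, both configurable — the printed M threshold of 20 log2
exceeds plausible intensities and is kept only as the configurable default)
and PCR-probe availability against a plain-text probe list.

## Normalizer stability

Reference miRNAs for qPCR are chosen by a grouped stability model in the
NormFinder family. For log2 values of a candidate panel:

1. centre each sample over the panel (removes per-sample level);
2. compute per gene×group means `zbar_ig` and residual variances `v_ig`
   (denominator k_g − 1);
3. form the two-way interaction `d_ig = zbar_ig − zbar_i. − zbar_.g +
   zbar_..`;
4. estimate the interaction variance by method of moments,
   `tau2 = max(0, Σ d²/((n−1)(G−1)) − mean(v_ig/k_g))` — truncation at zero
   is standard practice and keeps the stability value real;
5. shrink: `d~_ig = d_ig · tau2/(tau2 + v_ig/k_g)` (defined as 0 when the
   denominator vanishes, so an all-constant panel scores exactly 0);
6. stability `rho_i` averages |d~_ig| plus its standard error over groups.

Lower ρ is more stable; a gene whose level tracks the group (the one thing
a normalizer must not do) is penalized through d, a noisy gene through v.
The published NormFinder tool prints no equations; this is one standard
grouped-model reading (two-way interaction with shrinkage), and numerical
equivalence with the original add-in is deliberately not asserted.

The panel (default k = 3, among candidates with mean expression ≥ 5,
ρ < 0.25, and optionally an available probe; ties broken by higher mean
expression, then id) defines a per-sample factor equal to the arithmetic
mean of the normalizers' log2 values — the log of their geometric mean —
subtracted from every miRNA. Normalization is exact in log space; linear
output is `2**value`.

## qPCR quantification

Replicates aggregate by arithmetic mean with SD reported for QC; no outlier
rejection. Missing wells ("undetermined") are treated as missing, never as
a censored maximum cycle — no limit-of-detection model is assumed. A sample
missing any normalizer is excluded entirely with a warning, because a
partial reference would shift that sample against the rest.

Relative expression is `2^−ΔCq` with ΔCq = Cq_target − Cq_ref and group
fold-change `2^−ΔΔCq` with ΔΔCq = mean ΔCq(M) − mean ΔCq(B). Differential
testing is a pooled-variance two-sample t-test, two-sided, sign convention
B − M, applied to log2 relative expression (−ΔCq) by default: the
equal-variance assumption is far more defensible on the log scale; linear
scale is available by flag. Degenerate inputs are defined, not errors:
zero pooled variance with equal means gives (t = 0, p = 1); with unequal
means, (±∞, 0).

## Ratios and ROC

Ratios divide the linear relative expression of each up-regulated miRNA by
each down-regulated one, per sample: `value_u/value_d = 2^(Cq_d − Cq_u)`.
The reference cancels exactly — asserted as a bit-level identity in the
tests — so ratios from ΔCq-normalized values equal ratios from raw Cqs.

ROC curves use the same explicit threshold grid as the error counts
(midpoints plus ±∞), rule "call M if value > t", orientation fixed
malignant-high and never auto-flipped (an AUC below 0.5 is reported as-is;
auto-flipping would silently change the classifier family). The trapezoid
AUC over this grid equals the rank statistic — the fraction of (M, B)
pairs ranked correctly with ties counted ½ — which the tests verify against
a brute-force double loop and against an independent library
implementation. The operating point maximizes the Youden index
J = sensitivity + specificity − 1; ties break toward higher specificity,
then the lower threshold, so degenerate constant input yields J = 0 at the
+∞ threshold (everything called B). Per-ratio t-tests are run on log2
ratios without multiplicity adjustment, matching the single-stage design
this reimplements; a Benjamini–Hochberg flag exists but is off by default.

## Double ratios

Pairs of ratios are admissible when their constituent miRNAs are all
distinct (≥ 4 distinct; for u/d ratios this equals "sharing no miRNA", and
the admissible count has the closed form C(ab,2) − a·C(b,2) − b·C(a,2)).
Each member keeps its own single-ratio Youden threshold — thresholds are
*not* re-optimized jointly per pair, which on a 23-sample cohort would be
pure overfitting. How two thresholded calls combine is not uniquely
determined by the source material, so the rule is explicit and recorded in
the output: **AND** (default; call malignant only when both ratios exceed
their thresholds — the conservative reading of a "malignant quadrant"),
**OR**, or **SUM** (positive summed log2 margins). A sample exactly on a
threshold is called borderline (strict ">"). Samples missing either ratio
are excluded from that pair's error count and reported via `n_samples`.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes:

    x_ij  = mu_i + delta_i·1[group j = M] + s_j + eps_ij          (microarray, log2)
    Cq_ijr = intercept − (mu_i + delta_i·1[M] + s_j) + eta_ijr    (qPCR, cycles)

- `mu_i` ~ Uniform(4, 12) log2 for background genes — straddling the
  expression-5 floor on purpose; genes designated as differential or as
  normalizers draw from Uniform(6, 12), because real validated candidates
  are by construction detectable, and planting signal below the detection
  floor would test the filter rather than recovery.
- Defaults mirror the reference design: 11 B vs 12 M samples; 5 up- and 10
  down-regulated miRNAs at |delta| = 2 log2; 5 normalizers with reduced
  measurement noise (0.1 vs 0.5 log2); per-sample offsets s_j ~ N(0, 0.5²)
  shared between the two views of the same virtual sample — the property
  that lets normalization and ratio cancellation be demonstrated on the
  same ground truth; Cq intercept 30 with slope −1 (perfect doubling per
  cycle, one log2 unit = one cycle); replicate noise 0.2 cycles,
  triplicates.
- Determinism: one integer seed drives three spawned streams (shared
  baselines/offsets, microarray noise, qPCR noise), so the two views agree
  on the latent samples and identical seeds give bit-identical output.

What the generator does **not** emulate: probe-level microarray structure
and RMA itself, PCR efficiency ≠ 2, limit-of-detection censoring,
batch×group confounding, and biological within-group heterogeneity beyond
i.i.d. Gaussian noise. In particular the qPCR view's within-group spread
comes only from replicate noise (both views measure the same extract), so
planted effects separate groups more cleanly by qPCR than real cohorts
would; passing recovery tests demonstrates correctness of the machinery,
not expected field performance.

## Problem sizes and test design

Stochastic checks run 100 simulated cohorts at the reference design
(1000 miRNAs × 23 samples), a size chosen to keep the full suite and the
acceptance script fast while leaving recovery probabilities near their
asymptotic values; oracle equivalences run on 1000 random small instances
(≤ 6 per group) where exhaustive enumeration is exact. The selection-funnel
acceptance check runs on a miniature series-matrix table engineered to
contain a known funnel (8 down + 1 up stringent, 18 fold-change-only); the
originally deposited arrays are not bundled, and the funnel counts on them
are not asserted here.

## Known limitations

- The stability model is one defensible reading of grouped NormFinder; no
  claim of numerical identity with the original published implementation.
- All error rates are resubstitution; with ~23 samples any held-out
  estimate would be too noisy to rank 900 pairs, but reported zero-error
  pairs are optimistic by construction.
- The pair-combination rule on real data is a modelling choice; results
  record which rule produced them.
- The expression rule's M-group threshold default (20 log2) is physically
  implausible and retained only for fidelity; set it per platform.
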