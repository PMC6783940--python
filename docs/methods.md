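# Methods

## The screen and its statistical model

The pipeline analyzes a 3³ full factorial perturbation screen of human
iPSC culture: three soluble activators — FGF2 (FGF signaling), TGFβ1
(TGFβ/Nodal signaling) and CHIR99021 (a GSK3β inhibitor activating
canonical Wnt signaling) — each at three doses (none, one-third input,
full input).  The 27 conditions are laid out with the Wnt activator
varying fastest and FGF2 slowest; the zero-everything basal condition
(E6 medium, "Sample 1") is run in biological triplicate, and mTeSR1 and
E8 media serve as non-factorial controls.  With 29 observations the
10-parameter full quadratic model leaves 28 total and 19 residual
degrees of freedom.

### Level coding

Doses are coded by nominal input fraction, not measured concentration:
level index 0/1/2 maps to f ∈ {0, 1/3, 1} and then X = 2(f − 1/2) ∈
{−1, −1/3, +1}.  This treats the mid dose as "one-third of full input"
even where the true concentration ratio differs (FGF2 35/100 = 0.35,
TGFβ 0.7/2 = 0.35); it is the framing under which the screen's doses
were chosen.  `code_levels(scheme="concentration")` codes by true
concentration ratio instead, and `orthogonal=True` replaces each
factor's linear/quadratic pair with Gram–Schmidt orthogonal polynomial
contrasts over the observation rows.  Simple centered coding is the
default because it is the most direct reading of "centered and scaled
polynomials"; the alternatives exist because the choice is not uniquely
determined and materially affects per-term sums of squares (see ANOVA
below).

A note on the TGFβ mid dose: sources for this screen state both 0.7 and
0.85 ng/mL; the run-level listings use 0.7, which is adopted here.
Under nominal coding the choice does not affect the model matrix.

### Comparative-Ct quantification

Relative expression is 2^−ΔΔCt: technical PCR replicates are averaged
on the Ct scale; ΔCt = mean Ct(target) − mean Ct(GAPDH) within a
sample; ΔΔCt subtracts the calibrator sample's ΔCt (mTeSR1 by default).
Averaging on the Ct scale before exponentiation is the standard Livak
usage.  Undetermined Ct values abort by default; `drop_undetermined`
drops the affected replicate with a warning instead, because silently
imputing detection failures biases low-expression genes.

### Normalization, panels, scores

Each gene is min–max normalized across the analyzed cohort (all
samples including controls by default — the controls anchor the
pluripotent end of each gene's range; a flag restricts the cohort to
the 27 factorial conditions).  A gene constant across samples has no
defined range and raises by default.  Panels average their member
genes' normalized values; gene symbols match case-insensitively through
a small alias map (T = Brachyury = TBXT, P75 = NGFR, OCT4 = POU5F1).
The five lineage scores are fixed zero-sum weighted combinations of the
five panels, shipped as YAML data (`stemfactor/data/weights.yaml`) so
alternative weightings are testable without code changes.  Replicated
observations (the E6 triplicate) are scored separately and never
pre-averaged, preserving the degrees-of-freedom accounting.

### Response-surface fitting and ANOVA

Each score is regressed on the coded design with ordinary least squares
via thin QR factorization (normal equations are never formed; noiseless
surfaces are recovered to ≤1e−8).  Control samples are excluded from
fitting by default: the stated df accounting (27 conditions + E6
triplicate → 28 df) implies the screen's own models excluded them, and
the controls have no coded dose coordinates.

Term significance uses single-df partial (Type III) F-tests: the
increase in residual SS when one term is removed from the full model,
divided by the full model's residual mean square, referred to
F(1, df_residual).  For 1-df terms this is identical to the squared
coefficient t-test (verified against statsmodels in the test suite).
Because the E6 triplicate unbalances the design and the coded columns
are not mutually orthogonal under simple centered coding, partial SS do
not decompose additively: a noiseless response depending on one term
alone still shows that term's partial SS below the model SS.  The exact
decomposition is recovered under orthogonal contrasts on the
unreplicated 27-run design, which the tests exercise.  No
multiple-testing correction is applied across the 9 terms or 5 models,
and models are never refined by dropping non-significant terms — both
choices match the screen methodology being reproduced.  A perfect fit
(residual variance ≈ 0) reports p = 0 for terms with nonzero SS, with a
warning.

### Clustering and PCA

Samples are clustered on their 5-score vectors with average linkage
(UPGMA) on Pearson correlation distance d = 1 − r (signed, not |r|,
following the Clustvis convention).  The UPGMA update is the
size-weighted average, equivalent to the unweighted mean over all
cross-pairs of the original matrix; ties break on the smallest cluster
id pair for determinism.  Merge heights are recorded as computed and
exported as a scipy-convention linkage matrix and as Newick with
ultrametric branch lengths.  `cut_clusters(k)` undoes the last k−1
merges.

PCA centers columns (unit-variance scaling off by default, both
exposed); missing entries are filled by iterative rank-2 truncated-SVD
reconstruction (initialize at column means, reconstruct, replace
missing cells, iterate to RMS change < 1e−6 or 100 iterations).  On
complete matrices the loop is a no-op and the result equals direct
SVD of the centered matrix (verified against covariance
eigendecomposition and scikit-learn).

## The synthetic-data generator

No raw Ct data are deposited for the original screen, so the generator
defines the study conditions the pipeline is exercised under.  Each
gene's true log2 relative expression L(X) is a quadratic surface in the
coded doses; Ct values invert the comparative-Ct readout:
Ct(target) = baseline − L + ε and Ct(GAPDH) = offset + ε′, with ε, ε′ ~
N(0, σ) independent per technical replicate, σ on the Ct (log) scale
reflecting qPCR error structure.  Defaults: σ = 0.25 cycles, 3
technical replicates (a common qPCR practice; the original count is
unstated).  The calibrator control (mTeSR1) has L ≡ 0 by definition of
"relative to mTeSR1", so the noiseless pipeline returns 2^L exactly;
E8 is generated as a pluripotency-maintaining override (pluripotency
genes +0.3, lineage genes −1 log2 units).  A single seeded RNG stream
with documented draw order makes output byte-reproducible; Ct is kept
exact in memory and written with 4 decimals.

### The Wnt-dominant preset

The preset encodes the qualitative biology the screen reported, as
signs and orderings, not numeric targets: CHIR drives cells out of
pluripotency toward mesendoderm, mesoderm commitment peaks at the
intermediate dose, and FGF2×CHIR synergy is negative for pluripotency
and positive for ectoderm/mesoderm.  Dominant CHIR main-effect sizes
are 2–4 log2 units and synergies 0.5–0.75, chosen so the dominant terms
are detected at p < 0.05 with power > 0.9 at σ = 0.25 (verified by
simulation in the test suite, not assumed).

Two constraints shaped the coefficients, both consequences of min–max
normalizing exponentiated values: (i) a monotone-increasing quadratic
on [−1, 1] can place the mid-dose response at most ≈ 2^−16/9·β₃ of the
maximum, so mesendoderm uses β₃ = 2 with β₃₃ = −1 (the steepest
mid-dose rise compatible with monotonicity); (ii) an interior-vertex
parabola with vertex at −1/3 drops four times as much (in log2) toward
full dose as toward zero dose, so the mesoderm profile necessarily
falls steeply at full input.  The mesoderm vertex
−(β₃ + β₁₃X₁)/(2β₃₃) stays inside (−2/3, +1/3) for every FGF2 stratum,
which guarantees the interior optimum at the discrete dose levels.
With these surfaces the 2-cluster UPGMA cut recovers the
CHIR-presence partition with Rand index 1.0 in ≥95% of replicates at
σ = 0.25.

### What the generator does not emulate

Real qPCR data carry amplification-efficiency differences between
assays, occasional non-detects, plate/block batch effects and
biological replicate variation beyond Ct noise; the generator models
none of these.  Passing tests therefore demonstrate the pipeline's
arithmetic, calibration and structural recovery under the stated noise
model — not robustness to assay artifacts, and not the original
screen's exact fitted values (its reported R² of 0.93–0.97 and PC1
variance of 91.3% depend on unavailable raw data and are treated as
qualitative context only).

## Problem sizes

Defaults used by the tests and the acceptance script: 29 observations
per dataset; 1,000–2,000 null simulations for ANOVA calibration; 500
replicate datasets for parameter recovery; 50–100 seeds for clustering
robustness; 200 random 6-sample instances for the UPGMA oracle.  These
sizes give Monte-Carlo error comfortably inside the asserted bands
while keeping a full run to a few minutes.

## Known limitations

- Fractional or 5-level designs, randomization/run-order handling and
  lack-of-fit testing against pure error are out of scope.
- Efficiency-corrected (Pfaffl) quantification is not implemented;
  2^−ΔΔCt assumes ~100% amplification efficiency.
- Score weights are fixed inputs; the package does not learn them.
- With only one replicated condition, residual variance pools pure
  error and lack-of-fit; per-term p-values inherit that assumption.
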