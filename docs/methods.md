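# Methods

## Problem and model

The package predicts whether a 1:1 API–coformer mixture forms a
coamorphous (COAM) phase from six pair descriptors: average molecular
weight (g/mol), the summed donor–acceptor difference Σ(HBD−HBA) over
both components (dimensionless), the excess enthalpy of mixing ΔH_mix
and of hydrogen bonding ΔH_hb of the two-component system (kcal/mol),
and the API-minus-coformer differences in the Hansen hydrogen-bonding
parameter Δδh (MPa^0.5) and the pseudo-chemical potential Δμ
(kcal/mol). The sign convention for all differences is API minus
coformer and is recorded in model metadata so features and trained
models cannot be silently mixed. A five-feature variant omits Δμ.

The classifier is PLS-DA: a partial least squares regression of the
class coding {not COAM: 0, COAM: 1} on the descriptors, thresholded
into a class. Features are autoscaled (mean-centred, unit sample
variance, n−1 denominator) because they carry heterogeneous units; the
response is mean-centred. Latent variables are extracted by NIPALS with
deflation of both X and y. With a univariate response the NIPALS inner
iteration converges in a single step, so each component is computed in
closed form (w ∝ E'f), making the fit exactly deterministic — there is
no iterative initialisation and no randomness. The convergence
tolerance (1e-10) only guards against numerically zero residual
covariance, which is reported as a convergence error naming the latent
variable.

The regression vector is b = W(P'W)⁻¹q and a prediction is
ŷ = ȳ + x_scaled·b, the continuous **COAM value**. It is deliberately
not clamped to [0, 1]: well-separated pairs legitimately score above 1.
Classification is COAM iff ŷ ≥ 0.5, with the threshold **inclusive** —
the validation tables place a 0.500 system on the COAM side while
0.463 falls on the other, bracketing the rule. Because
ŷ = ȳ + Σ_a q_a t_a for the projected scores, predictions and
score-space geometry agree exactly; the decision boundary drawn on the
LV1/LV2 plot is the line q₁·LV1 + q₂·LV2 = 0.5 − ȳ (vertical when the
response does not load on LV2). The default model uses two latent
variables, matching the two-dimensional score plots screening studies
present; this is configurable.

Autoscaling makes predictions invariant to positive rescaling of any
feature column (units cancel), and with as many components as features
the PLS fit coincides with ordinary least squares — both properties are
enforced by tests against independent oracles (closed-form least
squares; an SVD-based PLS reference; scikit-learn as a third route).

## Evaluation statistics

Screens are scored by cross-tabulating predicted against experimental
outcomes with predicted COAM as the positive row. Accuracy is the
integer percentage 100·(tp+tn)/n rounded half away from zero (5/7 → 71,
11/13 → 85), computed in exact rational arithmetic. The Fisher exact
probability is **one-sided toward positive association**: the
hypergeometric tail of tables at least as extreme as observed with both
margins fixed. For the seven-system screen's margins this equals 3/7 ≈
0.43 (the observed table is also the maximal tail there, so the tail
and point-probability conventions coincide; the tail is what is
implemented). Degenerate margins (an all-zero row or column) return 1
with an explicit flag. The implementation delegates to
`scipy.stats.fisher_exact`; tests verify it exhaustively against a
brute-force enumeration for every 2×2 table with total ≤ 20.

Systems that decompose on melting are counted as experimentally
not-COAM by default — a decomposed melt is not a single-phase amorphous
product, and the validation tables score a decomposed system predicted
"N" as a correct call. An `exclude` policy drops them instead, which
mirrors how decomposing APIs were removed from the earlier comelt data
set.

## Synthetic data: what it emulates and what it does not

No public training set exists for this descriptor space (the original
amino-acid training data and the solver that produced the descriptors
are unavailable), so model-level properties are demonstrated on
synthetic screens. Pairs are drawn class-conditionally from
multivariate normals with shared covariance — the simplest structure
under which PLS-DA is well-behaved and parameter recovery is checkable.

Default conditions (chosen once, documented here):

- n = 60 pairs, class balance 0.5.
- Centroids identical in all coordinates except ΔH_mix and ΔH_hb,
  where the COAM class is lower (mixing energetically favourable) by
  3 within-class standard deviations per coordinate (0.5 kcal/mol SD,
  1.5 kcal/mol shift; overall Mahalanobis separation 4.24). This
  concentrates the separation in a 2-D subspace, emulating the clean
  LV1/LV2 separation experimental score plots display, and makes the
  ≥ 90% leave-one-out recovery property stable across seeds.
- Remaining features are class-uninformative noise on pharmaceutically
  plausible scales: MW 320 ± 60 g/mol, Σ(HBD−HBA) −4 ± 2, Δδh 4 ± 3
  MPa^0.5, Δμ 1 ± 1.5 kcal/mol.

The Σ(HBD−HBA) coordinate is rounded to the nearest integer (it is a
count difference); all other coordinates are carried exactly, and the
drawn vectors are decomposed into per-component properties (MW split,
integer donor/acceptor counts, δh ≥ 0, μ) such that re-assembling
descriptors reproduces them to machine precision. Decomposition on
melting is a wet-lab phenomenon and is never generated synthetically.

What passing on synthetic data does **not** show: real solver-derived
descriptors are correlated, non-Gaussian and not class-balanced, real
effect sizes are unknown, and the printed continuous COAM values came
from a model whose coefficients are not public — those values are
consumed as inputs and cannot be regenerated here. Synthetic results
validate the algorithmic machinery, not field performance.

## Numerical and design choices

- Donor/acceptor counting from structure follows the Lipinski
  convention (N/O acceptors, N–H/O–H hydrogens as donors); the
  convention travels in provenance metadata. Note the bislactam
  coformer illustrates the gap between conventions: chemically it
  offers two carbonyl acceptor sites, while the Lipinski count is 4
  (2 N + 2 O). Fixture tables record Lipinski counts uniformly.
- The δh surrogate uses the Hoftyzer–Van Krevelen form
  δh = √(Σ nᵢE_hi / V) with a packaged per-group energy table (J/mol)
  and molar volume in cm³/mol, giving MPa^0.5. It is an opt-in
  replacement for solver-derived δh and should be flagged in
  provenance when used.
- Accuracy rounding is half away from zero on an exact `Fraction`, so
  50.0% → 50 and 12.5% → 13 regardless of binary representation.
- Model files are a versioned JSON document (`coamscreen-plsda/1`)
  written with full float repr, so serialisation round-trips are exact.
- Component names are case-sensitive keys; duplicate names and dangling
  pair references are validation errors, and missing optional fields
  are recorded as absent rather than zero.
- CSV is the canonical exchange format (comma, "." decimal, UTF-8,
  mandatory header), matching the tabular shape of published screens.

## Problem sizes

The test suite and the reproduction script run at desk scale: screens
of 7–13 pairs for the printed tables, 60-pair synthetic screens (5000
for the distributional convergence check), leave-one-out over 60 fits
per seed with three seeds, and the exhaustive Fisher sweep over all
2×2 tables with total ≤ 20 (~10⁴ tables). The full suite completes in
well under a minute.

## Known limitations

- The model is linear in the descriptors; strongly non-additive
  API–coformer interactions (e.g. specific stoichiometric hydrogen-bond
  motifs) are outside its reach.
- Ionic compounds (salts) are excluded by design.
- The continuous COAM value ranks formability, not stability: screens
  that followed up on stability found the score does not reliably order
  shelf life.
- Structure-derived donor/acceptor counts depend on the drawn
  tautomer/protonation state, which may differ from the state a solver
  used for the original descriptor values.
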