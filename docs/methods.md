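# Methods

## Models and metric

All four polytomous models are parameterized on the pure logistic metric
(scaling constant D = 1, the default of mainstream IRT software); published
item parameters are interpreted on that metric. For the graded response
model (GRM) with K ordered categories, the cumulative endorsement curves are
P\*ₖ(θ) = 1/(1 + exp(−a(θ − bₖ))) with strictly increasing thresholds
b₁ < … < b_{K−1}, P\*₀ = 1, P\*_K = 0, and category probabilities
Pₖ = P\*ₖ − P\*ₖ₊₁. Dichotomous items are the K = 2 special case, so yes/no
and five-point items live in one bank. The GPCM uses adjacent-category
logits with a free slope, the PCM fixes that slope at 1, and the NRM carries
per-category slopes/intercepts with the first category anchored at zero.
Fisher information is computed from analytic category-probability
derivatives, I(θ) = Σₖ P′ₖ²/Pₖ; a probability floor of 1e−10 is applied
before logs and divisions so likelihood and information stay finite at
extreme θ. Category codes are 0-based; missing responses use a dedicated
sentinel (−1) and contribute nothing to likelihoods.

## Calibration

Item parameters are estimated by marginal maximum likelihood with an EM
algorithm under a standard-normal trait prior discretized on 61 equally
spaced quadrature points on [−4, 4] with renormalized normal-density
weights (the same grid used for EAP scoring, so the two are consistent).
The E-step computes each person's posterior weights over the grid and the
expected per-item category counts; the M-step maximizes each item's expected
complete-data log-likelihood by L-BFGS with analytic gradients, warm-started
from the previous cycle. GRM threshold ordering is enforced by a log-gap
reparameterization (b₁ free, subsequent thresholds add positive increments).
Convergence: maximum absolute parameter change < 1e−4 or 500 cycles
(both configurable); non-convergence flags the result rather than raising.
Starting values are a = 1 with thresholds at logits of observed exceedance
frequencies. Missing responses are ignored in both steps
(missing-at-random). The slope is deliberately unconstrained in sign: with a
symmetric prior, label-flipped dichotomous data are fit equally well by
(a, b) → (−a, b) or by the latent mirror (a, −b), and the EM may land in
either equivalent mode.

With one lone item the slope is unidentified (the marginal likelihood
depends only on the implied marginal category rates), so degenerate-item
diagnostics (â → 0 for trait-unrelated items) hold only when other
informative items pin the trait down.

Model comparison uses −2LL, AIC = −2LL + 2p and BIC = −2LL + p·ln n;
the model minimizing AIC wins, ties broken by BIC then −2LL, with a flag
reporting whether all three indices agree.

## Pool screening

The battery runs in the fixed order below; any removal triggers GRM
recalibration (and EAP re-scoring) before the next step, and the whole
battery repeats on the survivors until a full pass removes nothing (at most
five passes, then it aborts with a diagnostic).

1. **Unidimensionality** — Pearson correlations of raw category codes
   (polychoric correlations would be the natural refinement; the pass
   thresholds here are ratio-based, which blunts the attenuation), leading
   eigenvector scaled by √λ₁ as first-factor loadings; items loading
   < 0.3 are removed; the pool-level flag requires λ₁/λ₂ ≥ 4 and
   λ₁/J ≥ 20 %.
2. **Model selection** — as above; no removals.
3. **Local independence** — Q3 = correlation across persons of score
   residuals xⱼ − E[xⱼ | θ̂] at the full-pool EAP point estimate. Pairs with
   |Q3| > 0.36 are flagged; the member with the larger cumulative |Q3|
   (row sum over all pairings) is removed.
4. **Item fit** — Orlando–Thissen S-X²: expected category proportions
   conditional on the total summed score, via Lord–Wingersky recursions over
   the quadrature prior (rest-score distributions computed per item);
   Pearson X² over score × category cells. Within each score row, adjacent
   category cells are merged until every retained cell has expected count
   ≥ 1; rows reduced to a single cell are dropped; df = cells − rows − item
   parameters, floored at 1. Items with p < 0.01 are removed; items with
   fewer than two usable rows are marked untestable and retained. With
   per-replicate refitting this test is well calibrated in simulation
   (rejection 0.008 at α = 0.01; Kolmogorov distance to uniform 0.02). Its
   power is misfit-specific: gross (non-monotone) violations are detected
   essentially always, whereas guessing-type distortions of an otherwise
   monotone curve are largely absorbed by the refitted slope and often
   escape detection — a known property of summed-score item-fit tests.
5. **Discrimination** — a < 0.5 removes (strict; a = 0.5 is retained);
   a > 2.5 is flagged but kept.
6. **DIF** — per item, proportional-odds (binary: logistic) models
   M0: response ~ θ̂ and M2: response ~ θ̂ + group + θ̂ × group;
   ΔR² = McFadden R²(M2) − R²(M0) with the intercept-only multinomial as
   the null; ΔR² > 0.02 removes. No purification loop is applied (the θ̂ is
   the full-pool EAP); a config hook is left for one.

## Adaptive-test engine

Post-hoc simulation from stored complete response vectors: a uniformly
random available first item, EAP re-scoring after every response (running
log-likelihood on the quadrature grid, so each update is O(grid)),
maximum-Fisher-information selection at the interim θ̂ among unanswered
items (ties to the earlier bank position), and stopping checked after each
item with precedence SE ≤ threshold → max items (50) → pool exhausted.
The SE is the information-based form 1/√ΣIⱼ(θ̂) evaluated at the current
EAP estimate (not the posterior SD), matching the stopping-rule identity
reliability = 1 − SE². Items a person never answered are excluded from
candidacy, and persons missing over half the bank are flagged.

## Evaluation

Cohort summaries per stopping rule: mean/SD of items used, mean SE,
marginal reliability = mean over persons of 1 − 1/I(θ̂ᵢ) (zero-information
persons excluded and counted), and the Pearson correlation with full-pool
EAP scores. The reliability curve reports 1 − 1/I(θ) along a grid.
AUC uses the rank (Mann–Whitney) formulation with tie correction —
equivalently the all-pairs concordance proportion, which the tests exploit
as an oracle; the operating point maximizes Youden's J = Se + Sp − 1 over
the empirical ROC curve (a fixed cutoff can be supplied instead; bootstrap
percentile CIs, 2000 seeded resamples, are optional).

## Synthetic cohorts

The default generator mirrors the study conditions: n = 999 persons
(pipeline split ≈ 50/50 into calibration and validation), θ ~ N(0, 1), a
90-item GRM bank of 28 dichotomous + 62 five-category items (the split
inferred from the published pool composition), slopes from a normal
(1.22, 0.41²) truncated to [0.5, 2.5], five-category thresholds as a random
lowest location plus positive gaps inside −3.3…5.2. Diagnosis labels follow
a logistic link on θ with slope 1.7 and an intercept solved to hit the
configured prevalence (default 12 %, inside the published male/female
positive-rate envelope); that slope yields full-pool AUCs near 0.83–0.87
without being tied to any single published value. The criterion score is
r·θ_std + √(1 − r²)·noise with target correlation 0.6.

Planted defects:

* **Off-dimension item** — generated from an independent N(0, 1) trait;
  removed by the loading screen.
* **Locally dependent pair** — both members respond at θ + cⱼ·u with one
  shared u ~ N(0, 1) per person. The scale cⱼ = (π/√3)·λ/√(1−λ²)/aⱼ makes
  λ the nuisance factor's loading on each member's θ-conditional latent
  response propensity (residual propensity correlation λ²), the
  conventional factor-analytic meaning of a local-dependence loading; the
  naive reading "θ + λu on the trait metric" produces Q3 ≈ 0.18 at λ = 0.8,
  invisible at the 0.36 cutoff, whereas this construction gives Q3 ≈ 0.5.
* **DIF item** — all thresholds of the focal-group copy shifted by a
  constant (uniform DIF). In the fixed planted-defect design the DIF item
  is a five-category item with slope 1.8: a 0.75-logit shift on such an
  item produces McFadden ΔR² in the 0.02–0.05 range reported for removed
  biased items, while the same shift on an average-slope item yields
  ΔR² ≈ 0.015 and would sit below the removal cutoff (the ΔR² > 0.02
  criterion is conservative).

What the generator does **not** emulate: item content and context effects,
non-normal trait distributions (beyond mean/SD), missingness mechanisms,
response styles, or real multidimensional structure. Passing tests on these
cohorts therefore demonstrate the statistical machinery under the stated
generative conditions, not the clinical performance of any real instrument;
published real-sample summaries (mean items administered, AUCs, validity
correlations) are used only as property-shaped expectations, never as
reproduction targets.

## Problem sizes and determinism

Default analysis sizes — 500–1000 person cohorts, 20–90 item banks, five
replicate cohorts for screening power, 200-resample bootstraps — keep every
computation deterministic under a single seed (all per-stage and per-person
generators derive from it) while matching the scale of the emulated study.
The acceptance script's reported quantities are all recomputed at run time
at these sizes.

## Known limitations

* Pearson (not polychoric) correlations in the unidimensionality screen;
  loadings for strongly skewed dichotomous items are attenuated.
* No standard errors on item parameters; no multiple-group concurrent
  calibration; no DIF purification iteration.
* S-X² has limited power against guessing-type misfit (see above).
* The CAT engine implements no exposure control or content balancing across
  the nine diagnostic criteria.
* With α = 0.01 item-fit testing inside a repeated battery over ~20 clean
  items, occasional single false-positive removals are expected by design;
  the per-defect detection rates are the meaningful screening-power
  measure.
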