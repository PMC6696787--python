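# Methods

## Scope and procedure

The package quantifies scene images on three behavioral properties —
categorizability, shrinkability and perceived distinctiveness — and
relates them to externally supplied memorability scores. The analysis
chain is: per-image scoring from trial-level tables, per-category
split-half consistency, within-category standardization, and raw plus
distinctiveness-controlled correlation analyses. Feature-space
distinctiveness measures (k-NN sparseness, PCA+KDE negative log
likelihood) and Fourier phase-scrambled mask generation round out the
pipeline. Because the behavioral data are external inputs, a synthetic
generator with known ground truth stands in for them in all tests.

## Scoring rules

- Categorizability: correct congruent trials / all congruent trials per
  image. A trial without a response counts as incorrect and stays in the
  denominator. Images with no congruent trials are dropped with a
  warning.
- Shrinkability: mean search RT per image over trials with outcome
  `correct` or `timeout`; timeout RTs are fixed at the response limit
  (6 s default); `wrong_click` trials are excluded. Lower values mean
  higher shrinkability. No RT trimming or transformation is applied.
- Exclusion rate: wrong-click trials / all trials per image.
- Perceived distinctiveness: arithmetic mean of the 7-point ratings.
- Signal detection (per participant): H = P(correct | congruent),
  F = P('yes' | incongruent) = P(incorrect | incongruent);
  d′ = z(H) − z(F), β = exp((z(F)² − z(H)²)/2) from the same corrected
  rates. Extreme rates default to the half-count correction (0 → 1/(2N),
  1 → 1 − 1/(2N)); `correction="none"` raises instead. The correction is
  configurable because published analyses rarely state their convention.

## Split-half consistency

Participants are partitioned at random into halves of size ⌊n/2⌋ and
⌈n/2⌉; the scoring rule is applied to each half's trials; Spearman's ρ
(average ranks for ties) is computed per category over images scoreable
in both halves; the per-split correlations are averaged over `n_splits`
(default 1000). Splits leaving a category with fewer than three usable
images, or a constant score vector, contribute no sample and are logged.
No Spearman–Brown correction is applied — the estimate is the raw mean ρ
at half the pool size. For the built-in scorers each per-image score is a
ratio of per-trial sums, so half-pool scores are computed from
participant × image numerator/denominator matrices; 10⁴ splits take
seconds. Arbitrary scorer callables fall back to rescoring each half's
trial table.

## Association statistics

Scores are z-scored within category (sample SD, n − 1) before image-level
correlations so that between-category mean differences cannot drive them.
Pearson tests use the exact t reference distribution with df = n − 2;
first-order partials use the closed form
(r_xy − r_xz·r_yz)/√((1 − r_xz²)(1 − r_yz²)) with df = n − 3, and an
equivalent residual-regression route kept as an internal cross-check.
`partial_from_correlations` accepts published zero-order values directly,
which is how the reanalysis of the original summary statistics is
reproduced. The correlation matrix flags two-sided significance at
α/m (Bonferroni, m = number of pairs). The congruent-vs-incongruent
accuracy comparison is a paired t-test (df = n − 1), matching the
degrees of freedom the original analysis implies. Missing images are
dropped pairwise with a logged count.

## Synthetic generative model

Each image i carries two independent latent traits, goodness g_i and
contextual distinctiveness d_i, both N(0, trait_sd²), trait_sd = 1.

- Memorability: m_i = logistic(1.0 + w_gm·g_i + w_dm·d_i + ε),
  ε ~ N(0, 0.5²), with w_gm = 0.35, w_dm = 0.55. The logistic squashing
  and standard-normal traits are chosen for closed-form moments; the
  intercept 1.0 centers memorability near 0.7.
- Categorization difficulty: c_i = κ_cat − (w_gc·g_i + w_dc·d_i) + ε,
  with w_gc = 0.35, w_dc = −0.40, per-category offsets
  κ_cat ~ N(0, 0.8²) (categories genuinely differ in ease, which
  produces ceiling effects in the per-category descriptives), and
  ε ~ N(0, 0.5²).
- Study 1 trials: each of 147 participants sees all 616 images once;
  per participant and category a random half (22/44) is congruent — with
  an odd count the extra image goes to the congruent half. Correctness is
  lapse/2 + (1 − lapse)·logistic(1.3 + a_p − c_i) on congruent trials,
  with participant ability a_p ~ N(0, 0.35²) and lapse = 0.02;
  incongruent trials add a 'no'-bias of 0.9 inside the logistic,
  reproducing the conservative criterion (β > 1) and the higher
  incongruent accuracy. 0.5% of trials are non-responses, recorded
  incorrect.
- Study 2 trials: each of 75 participants searches a random 30-of-44
  subset per category (420 trials). log RT = μ + a_p + w_gr·g_i +
  w_dr·d_i + σε with w_gr = −0.12, w_dr = −0.08, σ = 0.45,
  a_p ~ N(0, 0.15²). μ is solved from the marginal log-normal so the
  expected timeout fraction is 2% (an explicit `rt_location` overrides
  this). Raw RTs beyond 6 s become timeouts with RT fixed at 6 s; 3% of
  the remaining trials are wrong clicks, whose RTs come from the same
  distribution (immaterial downstream — they are excluded from scoring).
- Study 3 trials: each of 137 participants completes 1 + Poisson(3.5)
  category blocks (capped at 14; ≈ 4.5 on average, giving ≈ 44 ratings
  per image), rating every image of a block once. The latent judgment
  d_i + bias_p + ε (bias ~ N(0, 0.35²), ε ~ N(0, 0.8²)) is discretized
  through fixed thresholds (−1.35, −0.35, 0.45, 1.25, 2.05, 2.85) onto
  −3..3; the right-shifted thresholds put most images on the
  representative (negative) side, as in the original descriptives.
- Feature vectors: category centers ~ N(0, 5²·I); an image's
  displacement from its center has magnitude scaled by
  max(0, 1 + 0.4·d_i), so distance to the category centroid grows with
  latent distinctiveness.

Effect sizes were derived analytically so the latent correlations land in
the regime of interest: with the values above, corr(cat, mem) ≈ −0.10
(raw, attenuated by binomial noise), corr(dist, cat) ≈ −0.5,
corr(dist, mem) ≈ +0.6, and the partial categorizability–memorability
correlation controlling distinctiveness ≈ +0.2. The qualitative pattern
(raw ≤ 0, partial > 0) is stable across seeds at the original sample
sizes; the magnitudes are not calibrated to any particular dataset
beyond this sign structure. The remaining nuisance parameters were set so
simulated cohorts land near the original studies' general performance
(mean percent correct ≈ 78%, d′ ≈ 1.4–1.7, β ≈ 1.3–1.5, mean RT ≈ 2.4 s,
3% wrong clicks, 2% timeouts).

Every simulator is a pure function of (params, seed): a single global
seed feeds `numpy.random.SeedSequence(entropy=seed, spawn_key=(stage,))`
with one spawn key per stage (population, study 1–3, features, fixture
images), so stages are independently reproducible.

What the generator does **not** emulate: display timing and masking
effectiveness, block and break structure, learning or fatigue across
trials, per-trial distractor composition in the search task, rater
idiosyncrasies beyond an additive bias, and any image content. Passing
tests therefore demonstrate that the *analysis* recovers the structure a
cohort of this design carries — not that real data will show that
structure.

## Feature-space measures

Sparseness is the exact Euclidean distance to the k-th nearest
same-category neighbor (k = 3 default, self excluded); ties in neighbor
rank are broken by distance sorting, which cannot change the score. The
KDE measure projects the category context onto its top principal
components (default: smallest count retaining 95% of context variance,
capped at min(n_context − 1, dim)) and evaluates an isotropic Gaussian
kernel density, bandwidth h = σ̄·n^(−1/(d+4)) (Scott; Silverman and fixed
rules available), where σ̄ is the RMS per-component SD of the projected
context. `include_self=True` by default — the convention when the scored
images are part of their own context — with a leave-one-out option.

Caveat: on isotropic synthetic features the variance-fraction rule
retains nearly all dimensions, and in high dimension the self-kernel
dominates the density at outlying points, compressing exactly the tail
the measure is meant to resolve. Real CNN embeddings are strongly
low-rank, which is what the variance-fraction default presumes. The
property test for the distinctiveness link therefore pins a fixed
low-dimensional projection (5 components); small contexts (44 images per
category) are too small for a stable high-dimensional density either
way, which is why a larger external context can be supplied separately
from the scored set.

## Mask generation

The phase-deviation field Δφ is drawn uniformly on [−π·strength, π·
strength] on a half plane and mirrored with negation, so conjugate
antisymmetry Δφ(−u, −v) = −Δφ(u, v) holds exactly by construction;
self-conjugate frequencies (DC and Nyquist combinations) are pinned to 0,
which preserves mean luminance. One field is shared by all three color
channels. Per channel the spectrum is multiplied by exp(iΔφ) and inverse
transformed; the imaginary residue is verified below 10⁻⁸ of the signal
norm (a larger residue indicates a malformed field) and discarded. The
deviation distribution is uniform at full strength by default, the common
choice for masking stimuli; clipping to the value range is the default
finalization, with affine rescaling and raw output as alternatives.
Amplitude-spectrum preservation is checked relative to the spectrum's
scale (max |ΔA| / max A), since pointwise ratios are ill-defined at
near-zero Fourier coefficients.

## Numerical and design choices

- Sample SD (n − 1) throughout; average ranks for ties; exact-t p-values
  (never the normal approximation).
- Odd participant pools split ⌊n/2⌋ / ⌈n/2⌉.
- Score tables serialize as UTF-8 CSV with header
  `image_id,category,score_kind,score,n_responses`; unknown extra
  columns are preserved on read but ignored. A column-mapping option
  bridges externally deposited files whose headers differ.
- Degenerate inputs raise typed errors (parameter / schema / numerical
  degeneracy) that the CLI maps to exit codes 2 / 3 / 4; loading never
  silently drops rows.
- Published summary statistics for the original FIGRIM-based studies
  (per-category descriptives, image-level zero-order correlations) ship
  in `gestaltmem.reference` as inputs for summary-level reanalyses.

## Problem sizes in the test suite

The suite exercises the original design sizes (616 images; 147/75/137
participants) wherever a check depends on them — design counts, the
sign-flip property over 20 seeded cohorts, the ~74-responses- and
~44-ratings-per-image checks. Oracles that enumerate or brute-force
(exhaustive split-half partitions, pairwise-distance sorts, kernel sums)
run on deliberately small fixtures (8 participants × 6 images, 200
vectors, 300 context points) where exact expectations are computable.
Split-half resampling in tests uses 10⁴ splits where the enumeration
oracle requires it and 10²–10³ elsewhere.

## Known limitations

- The generator's effect sizes are free parameters expressing a causal
  hypothesis, not estimates from any dataset; only their signs and rough
  magnitudes are meaningful.
- Numeric reproduction of the original CNN-based distinctiveness scores
  is not attempted: the original PCA dimension and bandwidth are not
  public, and no CNN inference is performed here (feature vectors are
  inputs).
- Split-half consistency is reported raw, at half the pool size; it
  underestimates full-pool reliability.
- The rating model is a simple ordinal-threshold discretization; it does
  not model scale-use differences beyond an additive rater bias.
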