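# Methods

This document records the models implemented in `castrop`, the numerical
choices made, and the scope and limitations of the synthetic data
generator. All distances are in millimetres, powers and vergences in
dioptres (dpt), unless stated otherwise; internally the optics code works
in metres.

## 1. The Castrop vergence model

### Geometry and constants

The pseudophakic eye is modelled as four refracting surfaces in a paraxial
(first-order) approximation:

1. spectacle correction at vertex distance `dVD` in air,
2. corneal front surface, power `P_CA = (n_C − 1)/R_CA`, `n_C = 1.376`,
3. corneal back surface, power `P_CP = (n − n_C)/R_CP`, `n = 1.336`,
   separated from the front surface by the corneal thickness `d_C`,
4. a thin IOL at the effective lens position
   `ELP = ACD + C·LT + H` behind the corneal front surface.

`C` (dimensionless, bounded to [0.35, 0.45]) scales the lens-thickness
contribution to the postoperative lens plane; `H` (mm, [−0.8, 0.8]) is an
additive position offset; `R` (dpt, [−0.8, 0.8]) is an additive offset on
the predicted spherical-equivalent refraction. The three constants are
lens-model specific and are estimated from observed outcomes (§4).

When tomographic measurements are unavailable the posterior radius
defaults to the fixed Gullstrand-eye ratio `R_CP = R_CA · 6.4/7.77` and
the corneal thickness to `d_C = 0.5` mm. Measured `rcp` / `dc` values,
when supplied, take precedence element-wise (NaN falls back to the model
eye).

### Vergence propagation

Two primitives build every formula:

- refraction: `V' = V + P`
- translation over distance `d` in medium of index `n`:
  `V' = V / (1 − V·d/n)`; a denominator within 1e-12 of zero raises
  `VergenceSingularityError` (the beam focuses exactly at the target
  plane).

Forward direction (power for a target refraction): start with
`target − R` at the spectacle plane, translate over `dVD`, refract at
`P_CA`, translate `d_C` in `n_C`, refract at `P_CP`, translate
`ELP − d_C` in `n`; then `P_IOL = n/(AL − ELP) − V`. The inverse
direction (predicted refraction for an implanted power) back-propagates
the required retinal vergence through the same surfaces with negated
steps and adds `R` at the spectacle plane. The two closed forms are exact
algebraic inverses; tests verify the round trip and also compare both
against an independent element-list ray trace built only from the two
primitives (agreement < 1e-9 dpt over randomized biometry).

### Model-eye parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `n_cornea` | 1.376 | — | physiological corneal index |
| `n_aqueous` | 1.336 | — | aqueous/vitreous index used for the IOL vergence |
| `vertex_distance` | 12.0 | mm | common clinical convention; configurable in `ModelEye` because published descriptions of vergence formulae do not always state it |
| `corneal_thickness_default` | 0.5 | mm | population central corneal thickness |
| `posterior_anterior_ratio` | 6.4/7.77 | — | Gullstrand schematic-eye radii ratio |

## 2. Classical comparator formulae

All four comparators are implemented from their published forms, each with
its own keratometric conventions; a shared thin-IOL vergence kernel
expresses predicted refraction as a ratio of linear forms in `P_IOL`, so
every formula has a closed-form inverse (power ↔ refraction round trip to
1e-9 dpt).

- **SRK/T**: `K = 337.5/r`; corneal width
  `Cw = −5.41 + 0.58412·LCOR + 0.098·K` with `LCOR = AL` below 24.2 mm and
  `LCOR = −3.446 + 1.716·AL − 0.0237·AL²` above; corneal height
  `H = r − sqrt(r² − Cw²/4)` (a negative radicand is a domain error —
  very long eyes with steep corneas are outside the model's validity);
  `ACDconst = 0.62467·A − 68.747`, ELP offset `ACDconst − 3.336`; optical
  axial length `Lopt = AL + (0.65696 − 0.02029·AL)`; vergence with
  `na = 1.336`, `ncm1 = 0.333`.
- **Hoffer Q** (with published errata): predicted chamber depth
  `ACD = pACD + 0.3·(AL − 23.5) + tan²K + 0.1·M·(23.5 − AL)²·tan(0.1·(G − AL)²) − 0.99166`
  with degrees-mode tangents, `(M, G) = (+1, 28)` for `AL ≤ 23` and
  `(−1, 23.5)` otherwise, and `AL` clamped to [18.5, 31] inside the
  prediction; vergence `1336/(AL − ACD − 0.05)` against the corneal power
  vertex-corrected from the spectacle plane at 12 mm.
- **Holladay 1**: anterior-segment size `AG = AL·12.5/23.45` capped at
  13.5 mm, corneal radius clamped to ≥ 7 mm in the anatomical chamber
  depth `0.56 + r − sqrt(r² − AG²/4)`, surgeon factor `SF` added, modified
  axial length `AL + 0.2`, keratometric index 4/3 (`ncm1 = 1/3`).
- **Haigis**: `ELP = a0 + a1·ACD + a2·AL`, corneal power `331.5/r`,
  two-surface vergence. *Simple* mode optimizes `a0` with `a1 = 0.4`,
  `a2 = 0.1` fixed; *triplet* mode optimizes all three.

The Haigis vergence chain is cross-checked in tests against an
independent re-derivation from the generic refract/translate primitives.

## 3. Preprocessing

- Spherical equivalent `SE = sphere + cylinder/2`; mean corneal radius
  from two meridians.
- Optional **Cooke axial-length correction** for sum-of-segments
  consistency: `CMAL = 1.23853 + 0.95855·AL − 0.05467·LT`. The
  coefficients live in configuration
  (`preprocessing.DEFAULT_COOKE_COEFFICIENTS`) and the step is off by
  default in the CLI.
- Record filtering: rows with postoperative decimal visual acuity below
  `va_min` (default 0.6 when filtering for constant optimization) or with
  missing required fields are removed; each removed row is attributed one
  reason (acuity checked first) and counts are returned in a
  `FilterReport`. Filtering is idempotent.

## 4. Constant optimization

Constants minimize the sum of squared prediction errors
`PE_i = SE_i − predSE_i` (reported as `rmsPE = sqrt(SSE/n)`), using an
in-house **projected Levenberg–Marquardt** scheme:

- forward finite-difference Jacobian, step 1e-6 (stepping inward at an
  active upper bound);
- Marquardt damping of the normal equations by `λ·diag(JᵀJ)`, initial
  `λ = 1e-2`, multiplied by 10 on a rejected step and divided by 10 on an
  accepted one; only improving steps are accepted;
- trial steps clipped to the box constraints of §1 (projection);
- termination: step norm < 1e-14 (`converged_by = "step"`), SSE
  improvement < 1e-16 (`"ftol"`), or 100 iterations (`"max_iter"`).

The recorded SSE trajectory is monotonically non-increasing by
construction. A hand-rolled optimizer is used because the constraints are
boxes and the damping/termination schedule needed to be explicit and
reproducible; `scipy.optimize.least_squares` (trf) is used in the test
suite as an independent cross-check of the minima, not in the
implementation. Non-finite residuals abort with the index of the
offending record. For the Castrop triplet, a near-constant lens thickness
makes `C` and `H` jointly unidentifiable (only `ACD + C·LT + H` matters);
`fit` warns when `sd(LT) < 0.05` mm.

Verified behaviour: on noise-free synthetic data the generating triplet
is recovered exactly (≤ 1e-3) in under ten iterations; on noisy data a
50-replicate study recovers the truth within two standard errors; the
single-constant Haigis `a0` agrees with a brute-force grid search to
2e-3.

## 5. Evaluation protocol

- **Split**: random disjoint exhaustive split with
  `n_test = floor((1 − f)·N)`; at `N = 1452`, `f = 0.7` this gives
  1017 training / 435 test eyes. Seeded `numpy.random.default_rng`
  permutation, reproducible.
- **Statistics**: mean, SD (ddof = 1), median, min/max, and 5 %/95 %
  quantiles of PE and |PE| using type-7 (linear interpolation) quantiles —
  numpy's default, matching R's default.
- **Within-limit fractions** of |PE| at 0.25 / 0.5 / 1.0 / 2.0 dpt and the
  empirical cumulative curve of |PE|.
- **Robust axial-length bias slope**: OLS of PE on AL, removal of points
  with externally Studentized residual |t| > 2, refit (statsmodels
  influence measures). Perfect fits yield NaN Studentized residuals;
  those points are treated as inliers.
- **Formula performance index** (higher is better):
  `FPI = 1 / (sd(PE) + MedAE + |slope| + 0.1·(1 − frac₀.₅))` where
  `frac₀.₅` is the within-±0.5 dpt fraction. The weights follow the
  published protocol's four components and are configurable
  (`evaluation.FPI_WEIGHTS`); the shortfall weight 0.1 keeps the fraction
  term on the scale of the dioptric terms.
- **Paired Wilcoxon signed-rank test** on |PE| against the reference
  formula: zero differences discarded (classic convention), exact null
  distribution for n ≤ 25 without ties, otherwise normal approximation
  with continuity correction; Bonferroni adjustment `min(1, m·p)` over
  the m non-reference formulae. The exact branch is validated in tests
  against direct sign enumeration.

## 6. Synthetic biometry generator

The generator emulates a preoperative biometry population plus a
plausible surgical outcome process; it is meant for method development,
not for clinical inference.

### Marginals and correlations

Four biometric variables are drawn from a correlated latent Gaussian and
box-truncated to observed ranges:

| variable | mean | SD | range |
|---|---|---|---|
| AL | 23.497 | 1.082 | [20.635, 29.041] |
| ACD | 3.099 | 0.389 | [2.000, 4.354] |
| LT | 4.608 | 0.422 | [3.345, 5.794] |
| RCA | 7.668 | 0.271 | [6.671, 8.676] |

Correlations: AL–ACD 0.45, AL–RCA 0.35, AL–LT −0.25, ACD–LT −0.45
(plausible biometric structure; the matrix is checked for positive
definiteness). Because truncation shrinks moments (for AL the SD would
fall by ≈ 1.6 %), the latent (μ, σ) of each variable are **calibrated**
with `scipy.stats.truncnorm` moment equations solved by `fsolve`, so the
truncated marginals reproduce the target mean and SD essentially exactly;
at n = 10⁵ all sample moments match within 1 %. Sampling is by Cholesky
factorization plus rejection of out-of-range draws.

Keratometry is split into two meridians `RCA ± astigmatism/2`
(astigmatism ≈ N(0.12, 0.08) mm), corneal thickness is drawn around
0.55 mm, and decimal visual acuity around 0.95 (clipped to [0.1, 1.6]).

### Outcome process

For each eye a target refraction is drawn from a mixture (80 %
N(−0.25, 0.25), 20 % N(−2.0, 0.35) dpt), the exact Castrop power for the
generating triplet (default (0.424, −0.312, 0.077)) is computed and
rounded to the manufacturing step (0.5 dpt), and the achieved refraction
is the model prediction for the rounded power plus Gaussian noise
(SD 0.45 dpt, the scale of realistic refraction outcomes). By default the
achieved refraction is then expressed as a clinically quantized
sphere/cylinder pair on a 0.25 dpt grid and recombined into SE. The
outcome stream uses an independent RNG (`seed + 1`) so biometry is
identical with and without outcomes.

### Limitations

- The latent-Gaussian copula captures first and second moments and linear
  correlations only; real biometry has skewness (long-eye tail) and
  nonlinear dependence not reproduced here.
- Outcomes are generated *by* the Castrop model, so the generator is
  suitable for optimizer/protocol validation (recovery, ranking
  sensitivity, noise floors) but makes the Castrop formula the true model
  by construction — comparative rankings on synthetic data measure model
  mismatch of the comparators, not clinical superiority.
- Measurement error on the biometric inputs themselves is not modelled;
  all noise enters through the refraction.

### Problem sizes

The reference cohort size is n = 1452 (70/30 split → 1017/435); tests
additionally use n = 400 cohorts for fitting behaviour and n = 10⁵ for
moment verification. Generation of 1452 eyes takes well under a second;
the full six-formula evaluation protocol on 1452 eyes runs in ≈ 1 s.

## 7. Numerical conventions

- Public API in mm/dpt; internal optics in metres; vergence singularity
  tolerance 1e-12.
- Scalar inputs return Python floats, array inputs return numpy arrays;
  both paths share one vectorized implementation.
- All randomness flows through `numpy.random.default_rng(seed)`; every
  CLI artifact embeds the seed and a SHA-256 hash of the effective
  configuration, making runs byte-for-byte reproducible.
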