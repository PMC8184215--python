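# Methods

This note documents the models, estimators and numerical choices behind
`cpstim`, and what the synthetic-data generator does and does not emulate.

## Decision-threshold model

The core assumption is that the binary choice `D ∈ {−1, +1}` arises by
comparing a continuous decision variable `d` to a threshold `θ`, with
`D = +1` iff `d > θ` (this sign convention is shared by every module), and
that a neuron's per-trial spike count `r` and `d` are well approximated by a
bivariate Gaussian.  Two numbers then determine the neuron's choice
probability exactly: the correlation `ρ = corr(r, d)` and the choice rate
`pCR = p(d > θ) = Φ((⟨d⟩ − θ)/σ_d)`.  Conditional on a choice, the z-scored
response follows a skew-normal, and integrating the ROC gives

    CP = 1/2 + T(Φ⁻¹(pCR), ρ/√(2 − ρ²)) / (pCR (1 − pCR)),

with `T` Owen's T function (`scipy.special.owens_t`, validated against
adaptive quadrature to 1e−9 in the tests; the quadrature oracle stays
independent of the scipy kernel).  At `pCR = 0.5` the expression reduces to
the arctangent closed form, which the tests verify to 1e−12.

Expanding in small `ρ` gives the linear approximation
`CP ≈ 1/2 + (√2/π) h(pCR) ρ` with
`h(pCR) = √(2π) φ(Φ⁻¹(pCR)) / (4 pCR (1 − pCR))`.  The coefficient `√2/π`
is fixed by the expansion of the exact solution — the derivative of
`T(h, a)` in `a` at 0 is `exp(−h²/2)/(2π)` and `da/dρ = 1/√2` — and makes
the CP–CTA–CC relations mutually consistent: the choice-triggered average is
`CTA = (4 h(pCR)/√(2π)) ρ σ_r`, and composing it with
`CP = 1/2 + CTA/(2√π σ_r)` reproduces the linear CP identically (asserted to
1e−12).  The approximation stays within 0.01 of the exact CP for |ρ| ≤ 0.3
and pCR ∈ [0.1, 0.9], which the tests check on a dense grid.

Choice rates are accepted in `[1e−6, 1 − 1e−6]`; the exact expression
degenerates at the endpoints, and callers must clip empirical rates first.

## Gain-fluctuation extension

A feedforward population `r = f(s) + ξ` with linearized tuning
`f(s) = f0 + f′·Δs` is read out by `d = wᵀr`.  A multiplicative gain `g`
(mean 1, variance σ_G²) shared by the population makes the covariance
stimulus-dependent: `Σ(s) = Σ̄ + σ_G² f(s)f(s)ᵀ`, with `Σ̄` assumed
stimulus-independent.  Under the readout optimal for `Σ(s0)` (normalized to
`wᵀf′ = 1`, so `d` carries stimulus units), the choice correlation acquires
the linear profile

    CC_i(Δs) = CC_i(0) + σ_G λ_i (1 − CC_i(0)²) · Δs / σ_d,

with `λ_i² = σ_G² f_i² / Σ_ii(s0)` the gain-explained variance fraction and
`σ_d` evaluated at the decision boundary (consistent with the first-order
expansion of `Σ(s)`; higher-order terms are dropped).  The slope
`β_pCR = σ_G λ_i (1 − CC_i²)` is non-negative for σ_G ≥ 0, larger for
neurons with more gain-driven variance, and produces the asymmetric
(monotone) component of CP(pCR) profiles, while `h(pCR)` produces the
symmetric component.  The linearized profile agrees with the exact
covariance-based CC to O(Δs²) (the tests check the 4× error contraction when
Δs halves) and with simulated correlations within regression error.  The
first-order attenuation term is only trusted for |β_σr·Δs| < 0.2; profile
evaluation raises rather than clamps when |CC| would reach 1.

`cp_profile_prediction` maps a pCR grid to stimulus offsets through the
model-implied psychometric inverse `Δs = σ_d Φ⁻¹(pCR)` and converts the CC
profile to CP with the exact threshold-model solution.

## Synthetic-data generator

`simulate_trials` draws, per trial: a gamma gain (mean 1, variance σ_G²;
gamma makes the count marginals negative-binomial, so the moment estimator
below is exactly specified), latent rates `g·f_i(s)` from linearized tuning
floored at 0.1 counts, Poisson counts (optionally coupled through a Gaussian
copula when non-gain count correlation is requested; the default non-gain
noise is conditionally independent Poisson, i.e. `Σ̄ = diag(f)`, matching the
convention that the variance not associated with the gain equals the rate),
then `d = wᵀr` and the threshold choice.  Defaults emulate the classic
random-dot discrimination designs: ~13 signed coherence levels up to
±51.2%, 60 trials at zero coherence, 40 at weak and 30 at high coherences,
baseline rates 5–40 counts with both choice preferences represented.  The
threshold defaults to `wᵀf(0)`, giving an unbiased observer.

What the generator does *not* emulate: within-trial spike timing, feedback
dynamics (all choice covariation is feedforward), inhomogeneous or
cell-specific gains, and non-Poisson private noise.  Passing tests therefore
validate the estimators under the stated generative assumptions, not the
biology of any particular data set.

`estimate_gain_variance` fits the negative-binomial mean–variance relation
`var = μ + σ_G² μ²` across stimulus levels by least squares of `(v̂ − μ̂)`
on `μ̂²` through the origin, clipping at zero; it recovers σ_G² = 0.1 within
20% at 200 trials/level over 10 levels.

`simulate_threshold_trials` bypasses the population model and draws (count,
decision) pairs directly from the bivariate-Gaussian threshold model at
requested per-level choice rates — ground truth for the profile estimators.
Counts are an affine rounded transform of the z-scores; rank statistics are
unaffected up to rounding ties.

## CP estimation and profiles

Per level, the CP is the Mann–Whitney AUC with half credit for ties (so
identical samples give exactly 0.5), computed only when ≥ 15 trials and ≥ 4
per choice are available; exclusions are sentinels, not errors.  The SEM
approximation `1/√(12 K pCR (1 − pCR))` (valid for small |CP − 0.5|) defines
the weighting used everywhere: level CPs combine with unnormalized weights
`K·pCR·(1 − pCR)`, and a combination of total weight `W` has SEM
`1/√(12 W)`.  The same rule is applied iteratively to average bins within a
cell and cells within a group, so a cell's bin weight doubles as its weight
in the group average.

The five pCR bins are `[0, 0.3], [0.3, 0.5−ε], central, [0.5+ε, 0.7],
[0.7, 1]`, with `ε` set per data set to half the minimum |pCR − 0.5| over
informative levels so only zero-coherence trials can land in the central
bin.  The pCR attached to each level is the psychometric prediction (probit
binomial GLM with bias; logit available), clipped to [0.01, 0.99] — stabler
than raw choice fractions at high coherence.  Only cells with all five bins
estimable ("complete") enter group averages, and averaging is done
separately for cells with weighted-mean CP above vs below 0.5 (ties assigned
to "above"), since the threshold-induced modulation has opposite sign in the
two groups; a cell's "average CP" for grouping is the bin-weighted mean.

## Surrogate significance test

The null is a pCR-independent CP.  Responses from levels within a
low-information coherence window (default ±1.6%) are pooled after a
*choice-conditioned* z-scoring: the level mean is the unweighted average of
the two choice-conditional means, and the SD comes from the equally weighted
pooled squared deviations, so choice-rate imbalance does not shrink the
choice separation (with balanced choices this is ordinary z-scoring,
population-SD convention).  Each surrogate redraws, with replacement and per
level, the original number of trials of each choice from the choice-matched
pool; with-replacement sampling keeps level pools independent.

Profiles are summarized by the mean of consecutive bin differences
ΔCP_k: the *asymmetric* variant averages them as is; the *symmetric* variant
flips the sign of the two differences between bins below pCR = 0.5; the
*threshold-model* variant additionally inverts the statistic for profiles
with mean CP below 0.5.  The p-value is the one-sided fraction of surrogates
whose statistic reaches the observed one (ties count as exceeding; no
add-one smoothing, though `p = 0` should be read as `< 1/n_surrogates`).
Grouped tests compute the statistic on the across-cell weighted-average
profile, per surrogate.  The engine is vectorized level-wise (batched AUCs
over all surrogates at once), which is what makes 10⁵-surrogate-scale
calibration studies cheap.  Calibration: on constant-CP data the type-I
error at α = 0.05 is nominal within ±0.02 over 1000 runs.

## Clustering and slope fits

Profiles are clustered as vectors `CP − 0.5` under cosine distance
(spherical k-means, 100 random restarts under a master seed, best
within-cluster dissimilarity kept; zero vectors are excluded since cosine is
undefined).  Template projections use unit-norm templates over the five
bins: constant (symmetric magnitude) and centered slope-1 (asymmetry).  The
2-D embedding takes the main-cluster center difference as the horizontal
axis and, within each CP-sign group, the subcluster-center difference
orthogonalized against it as the vertical axis.  The empirical asymmetry
slope is the linear coefficient of an ordinary least-squares quadratic fit
of per-level CPs on stimulus level.  Cluster-level significance re-runs the
identical clustering on every surrogate replicate and matches surrogate
clusters to the originals greedily by center correlation (labels are
arbitrary under permutation, which the matching makes explicit).

## GLMs with stimulus–choice interactions

Counts follow a Poisson GLM with log link:
`log μ = Σ_{j=0..4} a_j s^j + Σ_{j=1..Nc} I_{Pj}(pCR) b_j D`, with `D`
coded −1/+1 and the stimulus polynomial fixed at order 4.  The stimulus
covariate is scaled by its maximum absolute value for conditioning and
coefficients are reported on the raw scale.  Fitting uses IRLS
(statsmodels); no regularization.  The bin partition `P` comes from exact
1-D k-means on the five bin CPs (optimal 1-D clusters are contiguous after
sorting, so enumeration over sorted splits is exact); non-contiguous pCR
groupings arise naturally for symmetric profiles, which is the point of
clustering rather than tiling pCR.  The partition is derived once per cell
from all data, not re-derived inside each cross-validation fold — a
potential source of mild optimism accepted for simplicity and determinism.

Model comparison uses the relative increase in likelihood
`RIL = (L(choice, stim) − L(stim)) / (L(stim) − L0)` with `L0` the
constant-rate null, averaged over 50 trial-matched cross-validation repeats:
within each choice-level group the training set takes 80% of the smaller
choice pool from *each* choice (exact balance by construction), the rest is
held out, and a fresh sub-seed derives each repeat's split from the master
seed.  For the stimulus-dependent family the better of Nc = 2, 3 by held-out
likelihood is reported.  RIL can be slightly negative under the null
(overfitting penalty); when the stimulus model fails to beat the constant
null the ratio is flagged as unstable rather than silently inverted.

## Problem sizes and tolerances

Monte-Carlo equivalence of the exact CP is checked at 10⁶ samples per
(ρ, pCR) grid point against the SEM-based 3σ band; surrogate calibration
uses 1000 runs × 200 surrogates; gain-slope recovery uses 50 neurons at 10⁴
trials/level (σ_G² moment recovery at the archive-like 200 trials/level);
GLM discrimination uses 20 sign-flipping runs at 50 CV repeats.  Convergence
of the Poisson GLM is declared by statsmodels' IRLS at tolerance 1e−10 with
non-finite parameters flagged as non-converged.  All randomness flows
through `numpy.random.Generator` seeds; fixed seeds give byte-identical
trial tables and pipeline outputs.

## Known limitations

* The theory treats counts as Gaussian; for very low rates the exact CP is
  only an approximation to the Poisson-world CP (the simulator cross-checks
  quantify the discrepancy at realistic rates).
* The gain model assumes a single global gain and an optimal linear
  readout; real populations have structured, partially private gains, so
  predicted asymmetry slopes should be read as rank predictors rather than
  calibrated magnitudes.
* The surrogate pool approximates the CP as constant inside the pooling
  window; with a very steep psychometric function inside the window this
  mildly inflates the null spread.
* The optional Neural Signal Archive adapter is out of scope; analyses
  expect the plain CSV trial-table format.
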