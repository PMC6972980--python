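# Methods

## Model and assumptions

The package models natural-log toxicity endpoints `x_i` (one per species,
geometric-mean aggregated) as a sample from a normal distribution — a
lognormal SSD on the concentration scale — whose observations may be
positively dependent through shared ancestry. The analysis chain is:

1. estimate the dependence with Moran's *I* on inverse patristic
   distances (`w_ij = 1/d_ij`, zero diagonal);
2. map *I*, read as a first-order autocorrelation parameter ρ, to a
   Cressie effective sample size `n_eff`;
3. refit the lognormal with the same location `x̄` but the corrected scale
   `s_a² = n_eff/(n(n_eff−1)) Σ(x_i−x̄)²`;
4. optionally correct the lower-tail estimate for small-sample bias with
   the Aldenberg–Jaworska noncentral-*t* extrapolation factor evaluated at
   the (possibly fractional) effective sample size.

Assumptions worth keeping in view: endpoints are treated as fixed, error-free
values; the dependence model behind step 2 is first-order autoregressive
decay of correlation with tree distance, which is an approximation to the
actual tree-structured covariance; and the location estimate `x̄` is left
uncorrected (it remains unbiased under dependence; only its efficiency
suffers).

## Signal indices

* **Moran's I** follows the autocorrelation definition with raw `1/d`
  weights, *not* row-normalized. (`ape::Moran.I` row-normalizes; the test
  suite pins this relationship explicitly by matching ape on the
  row-normalized matrix.) The analytic null expectation −1/(n−1) is exposed
  as a diagnostic only; inference is by trait permutation.
* **Abouheif's C_mean** is Moran's I under the Abouheif proximity: for each
  tip pair the product of 1/(number of direct descendants) over the
  internal nodes on the connecting path (MRCA included), rows normalized to
  sum to one and the matrix symmetrized. It uses topology only.
* **Blomberg's K** is the ratio (MSE0/MSE) / E[MSE0/MSE | BM] with the
  Brownian-motion covariance implied by the tree; K ≈ 1 under BM on the
  generating tree (checked by simulation), K → 0 with no signal.
* **Pagel's λ** scales the off-diagonal BM covariances; the MLE is found by
  bounded scalar search on [0, λ_max] with λ_max the largest value keeping
  the covariance positive-definite (found by bisection on Cholesky
  success — slightly above 1 for most ultrametric trees, so estimates such
  as 1.01 are representable). Likelihood ties are broken toward the
  smaller λ, so a flat profile (star tree) yields the boundary value 0.
  The test against λ = 0 uses the 50:50 χ²₀/χ²₁ boundary mixture.

## Permutation inference

Significance for I, C_mean and K comes from shuffling trait values across
tips with a seeded generator and the add-one estimator
`p = (1 + #{stat_perm ≥ stat_obs})/(n_perm + 1)`, one-sided "greater" by
default (large negative signal is biologically implausible — it would mean
close relatives are systematically *less* alike); "less" and "two-sided"
are available. Default `n_perm = 999` gives a p-value resolution of 0.001.
Results are reproducible bit-for-bit given (seed, n_perm); the generic and
the vectorized Moran engines draw identical permutation streams.

The correlogram bins tip pairs into equal-frequency (quantile) classes of
patristic distance — default 4 classes; equal-width bins empty out on
taxonomy trees with few distinct depths — computes class-restricted Moran's
I (still 1/d-weighted within the class), and flags each class
positive/negative/none against a central 95% permutation envelope. Classes
with fewer than two pairs are flagged `empty`, not errored.

## Effective sample size and corrected scale

ρ is taken directly as the Moran's I point estimate, untruncated: negative
estimates legitimately produce `n_eff > n`. The Cressie denominator is
strictly positive on ρ ∈ (−1, 1) (it approaches 0 as ρ → −1, so `n_eff`
diverges rather than turning negative); a defensive domain guard remains.
`n_eff` is carried as a continuous value into the corrected variance and
the extrapolation factor; integer rounding (half-up) is display-only. By
default the correction is applied regardless of the p-value — the case
studies report corrected values for significant and non-significant
datasets alike — with `correct_only_if_significant` as an opt-in gate.

The SSD scale uses the n−1 sample SD, not the MLE n-denominator, although
the two coincide asymptotically: the corrected variance formula reduces
exactly to the n−1 variance at `n_eff = n`, which makes ρ = 0 a bit-for-bit
no-op end to end, and the published uncorrected HC5s (0.151 and
0.0515 µg/L on the hypothetical datasets) are reproduced only under this
convention. All logs are natural; the extrapolation-factor construction is
base-invariant.

## Extrapolation factors

`k(n, p, γ) = q_γ[t′_{n−1}(z_{1−p}·√n)]/√n`, evaluated directly by
scipy's continuous noncentral t — no table interpolation — so fractional
degrees of freedom from effective sample sizes (8.29, 5.68) work without
special-casing. At γ = 0.5 this is the median-bias correction: k > z_{1−p}
for every finite n and decays monotonically to z_0.95 = 1.6449 as n → ∞.
The classical tabulated value 1.687 at n = 13 is reproduced to ±0.005; a
Monte-Carlo oracle (median of (x̄ − q̂_0.05)/s over simulated normal
samples) pins the construction independently. Confidence levels other than
0.5 (e.g. 95% lower limits) use the same formula but are not validated
against published tables here.

## Synthetic data generator

`SimulationConfig` draws trees (Yule, Kingman-style coalescent, balanced,
star — all hand-built and seeded) and log endpoints that are multivariate
normal with covariance `σ²·C_λ`, where `C` is the BM covariance (shared
root-path lengths) and λ scales its off-diagonals; λ = 0 is the iid null,
λ = 1 pure BM. Defaults — 30 tips, σ² = 1, log-mean 2 — sit inside the
case-study range (9–73 species, HC50s of a few µg/L). Log endpoints are
simulated directly since the SSD is lognormal, so no back-transform bias
arises.

What the generator does *not* emulate: endpoint measurement error,
replicate-level aggregation noise, non-ultrametric rate variation, or
model misspecification of the tree itself. Passing calibration tests
therefore demonstrate correctness of the statistics under the assumed
model, not robustness of the method on real regulatory datasets.

The two fully printed hypothetical chlorpyrifos endpoint tables ship as
fixtures verbatim. Their accompanying trees are synthetic taxonomy-shaped
stand-ins (group → species, unit branch lengths): the original
taxonomy-derived trees were published only as figures. Tests involving
those trees are therefore property-based; exact published Moran's I values
for the hypotheticals are not asserted.

## Numerical choices and edge cases

* Missing Newick branch lengths default to 1.0 (taxonomy trees carry
  implicit unit lengths); configurable. Multifurcations are kept as-is.
* Label matching trims/collapses whitespace and unifies underscores with
  spaces, case-sensitively.
* Zero patristic distance between distinct tips is a hard error by default
  (1/d undefined); an opt-in epsilon policy substitutes
  min-positive-distance × 1e-6.
* Zero trait variance is an error for every index (all are ratios with the
  trait sum of squares in the denominator).
* λ optimization tolerance 1e-8 on λ; covariance solves use Cholesky and
  report a condition number on failure.
* Problem sizes in the test suite (e.g. 1000 type-I replicates at 30 tips
  with 199 permutations, 200 λ-recovery fits at n = 50, 500 K replicates
  at n = 20) were chosen to keep each calibration check's Monte-Carlo error
  well inside the asserted band while the whole suite stays quick.

## Known limitations

* Estimator properties of the Moran's-I-as-ρ plug-in (bias, variance) are
  not characterized; the package inherits this open point of the method.
* Only the lognormal SSD is implemented — no log-logistic or Burr III, no
  regression-on-plotting-positions fitting (Hazen positions are exported
  for display only), no endpoint-uncertainty propagation.
* Published statistics for the full case-study datasets require the
  unpublished supplementary trees/tables and are treated as optional
  integration checks.
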