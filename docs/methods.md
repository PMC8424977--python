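# Methods

## Model and assumptions

MaRR treats a pair of replicate experiments as two rankings of the same M
metabolites (rank 1 = largest abundance) and works entirely on the
per-metabolite maximum rank Max_m. The ideal setting assumes a clean split:
every reproducible metabolite's scaled max rank falls at or below the
reproducible proportion π₁, and the two ranks of every irreproducible
metabolite are independent, which yields the closed-form limiting survival
function used in the MSE estimator. The realistic setting only assumes that
reproducible signals tend to outrank irreproducible ones, that reproducible
rank pairs are nonnegatively correlated, and that irreproducible rank pairs
are independent; there the estimator is conservatively biased because
reproducible max ranks can leak above π₁M. No distributional assumptions on
the abundances are made anywhere — the procedure is invariant to strictly
monotone transforms, which the suite checks explicitly.

The mFDR calculation relies on the irreproducible max ranks behaving like
maxima of two independent uniform draws over the positions above k̂, which
gives E[V(l)] = (l−k̂)²/(M−k̂); a Monte-Carlo test verifies this identity at
small M.

## Parameters

| parameter | default | meaning |
|---|---|---|
| α | 0.05 simulations / 0.01 real-data pipeline | nominal mFDR level of the classification threshold N̂ |
| λ | 0.9 | upper bound of the candidate region for k̂, as a fraction of M; lower values help when effect sizes are small and the reproducible proportion is clearly below λ |
| c_s | 0.7 | strict lower bound on the fraction of pairs calling a metabolite reproducible |
| c_m | 0.7 | strict lower bound on the fraction of metabolites called within a pair |
| max_missing_fraction | 0.2 | features missing in strictly more than this fraction of samples are removed |
| knn_k | 5 | neighbour count for kNN imputation |
| outlier_z | 3.5 | absolute z-score cut on per-sample median abundance |
| log base | 2 | final log transform; rank-invariant, so MaRR results do not depend on it |

Both filtering inequalities (c_s, c_m) are strict, so a fraction exactly
equal to the cut-off is not flagged.

## Numerical choices

* **MSE profile.** The tail MSE is evaluated for all candidates in O(M)
  total via suffix cumulative sums of Ŝ, Ŝ·x, Ŝ·x² and Ŝ² plus closed-form
  power sums (the ideal term is a quadratic in x−l on the tail). The suite
  checks exact agreement (to 1e-10 absolute, reflecting only summation
  order) with a literal double-loop implementation.
* **Ties in the MSE profile** go to the smallest candidate, making k̂
  conservative. **Ties in abundances** are broken uniformly at random by a
  seeded generator, so rank vectors are always exact permutations; every
  tie-break seed derives deterministically from the master seed and the pair
  identity (CRC32 of the pair id into a SeedSequence), making full runs
  bit-for-bit reproducible.
* **Degenerate cases.** If no l > k̂ attains mFDR ≤ α, N̂ = k̂ (the region
  (0, k̂] carries no expected false discoveries); an empty rejection grid
  with Q(l) = 0 gets mFDR 0; estimation requires M ≥ 3 and at least one
  candidate (⌊λM⌋ ≥ 1); missing or non-finite abundances are a hard error
  naming the offending index.
* **Pipeline order** is filter → impute → normalize → pool → log → MaRR.
  Pooling sums abundances on the normalized, pre-log scale; summing on the
  log scale would geometrically average raw abundances instead and change
  upper-layer results. This ordering is a package convention, chosen so that
  pooled totals remain sums of (approximately) raw-scale measurements.
* **kNN imputation** compares feature profiles with a Euclidean distance
  over jointly observed samples, rescaled for the overlap size; a missing
  cell becomes the mean of its k nearest features' observed values in that
  sample, with the feature's own observed mean as the fallback when no
  neighbour overlaps or no neighbour is observed at that sample. Bayesian
  PCA and random-forest imputation are intentionally not reimplemented; the
  CLI accepts pre-imputed matrices (`--pre-imputed`) so method comparisons
  can be orchestrated around the package.
* **Outlier screening** uses the absolute z-score of per-sample medians
  (|z| > 3.5), treating low- and high-signal outliers symmetrically.
* **NDR** is the fraction of truly reproducible signals not declared
  reproducible, and power = 1 − NDR; the empirical FDR divides false
  positives by the total declared count Q, with FDR ≡ 0 when Q = 0.

## Synthetic data

The simulation generators produce pairs of test statistics with planted
truth, calibrated to a processed untargeted LC-MS plasma data set
(M = 2860 features on the log scale): reproducible signals around mean
3.89–4.13 with sd 0.17, irreproducible around 3.2 with sd 0.05.

* **Study I** (24 settings): reproducible pairs bivariate normal with
  correlation ρ_R ∈ {0.45, 0.99}, π₁ ∈ {0.2, 0.4, 0.75, 0.9}; reproducible
  row count is round(π₁M).
* **Study II** (12 settings): t₁ ~ Uniform(4,5), t₂|t₁ ~ N(t₁, 1−r_m²) with
  r_m rising linearly from r₀ ∈ {0.4, 0.6, 0.99} at t₁ = 4 to 1 at t₁ = 5,
  so weakly ranked reproducible signals are noisiest.
* **Study III**: Study I with the irreproducible coordinates replaced by
  independent Student-t(3) draws located at 3.2 and scaled by 0.05 — the
  same centre and scale, heavier tails. (The t variates are scaled by
  σ_IR so that tail weight is the only difference from Study I.)
* The **ideal perfect-split generator** plants identical ranks 1..k in both
  replicates and independent uniform permutations of the remaining ranks.
* The **layered fixture generator** exposes the same signal structure as an
  abundance table over an arbitrary nested design, using an equicorrelated
  construction (shared per-feature latent + idiosyncratic noise) so every
  sample pair of a reproducible feature has correlation ρ_R, then
  exponentiates so the full preprocessing path (including log transform)
  applies; it can blank cells completely at random to exercise
  filtering/imputation.

What these generators deliberately do not emulate: heteroscedastic
intensity-dependent noise, missingness that depends on abundance
(censoring at the detection limit), correlated irreproducible features, or
batch structure beyond the run-day multiplicative effect. Passing tests
therefore certify the statistical machinery under the stated sampling
models, not robustness to every artefact of real spectra.

## Measured behaviour and limitations

The study-grid checks in the suite run 100 datasets per setting (the
package's standard profile for routine verification; any count can be
requested via `run_study`). Under Study I the procedure controls the
empirical FDR at α within Monte-Carlo error in all 24 settings with power
≈ 100%, and π̂₁ is nearly unbiased (|mean bias| < 0.001) because the two
normal components barely overlap, making the split effectively ideal.

Study II at low minimum correlation is genuinely harder: with conditional
sd up to √(1−r₀²) ≈ 0.92 at r₀ = 0.4, reproducible signals with t₁ near 4
often fall below the tight irreproducible cluster in the second replicate.
Their max ranks then look irreproducible, so π̂₁ is underestimated in
proportion to π₁ (mean bias down to ≈ −0.074 at r₀ = 0.4, π₁ = 0.9) and
power plateaus around 0.93–0.94 at r₀ = 0.4 (≥ 0.95 at r₀ ≥ 0.6). The FDR
remains controlled — the procedure errs conservative. This leakage is a
property of the data-generating equations themselves, not an estimator
artefact: no rank-based method can recover a signal whose second replicate
is indistinguishable from noise.

Other known limitations: the estimator needs π₁ < λ to have the true value
inside the candidate region; performance degrades for small π₁ (fewer
reproducible signals to anchor the survival fit); only strictly nested
(non-crossed) designs are supported; and the RSD baseline comparison shows
RSD ordering barely separates planted reproducible from irreproducible
features on Study-I draws, while MaRR achieves higher power at lower FDR at
a matched rejection count.
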