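# marrms

Maximum rank reproducibility (MaRR) for mass-spectrometry metabolomics.

Untargeted MS-metabolomics experiments routinely measure thousands of
features across technical and biological replicates, and a basic QC question
precedes any downstream analysis: *which metabolites are reproducible across
replicate experiments?* The conventional answer — filter features whose
relative standard deviation (RSD = 100·sd/|mean|) exceeds an arbitrary
cutoff — performs no statistical test and controls no error rate. `marrms`
implements the nonparametric MaRR procedure instead: it detects the
transition from reproducible to irreproducible signals from ranks alone and
classifies metabolites with marginal false-discovery-rate (mFDR) control.

## The statistic

For a pair of replicate experiments, each of the M metabolites gets a rank
in each replicate (rank 1 = largest abundance) and is summarised by its
maximum rank statistic

    Max_m = max(R_m,i, R_m,i′).

Jointly highly-ranked (reproducible) metabolites have small Max_m. With π₁
the reproducible proportion, the scaled max rank of an irreproducible
metabolite has the limiting survival function

    S_π1(x) = 1                          x < π₁
            = 1 − (x − π₁)²/(1 − π₁)²    π₁ ≤ x ≤ 1,

so π₁ is estimated by minimising, over candidate cut-offs l = 1..⌊λM⌋
(λ = 0.9 by default), the tail mean squared error between the empirical
survival function Ŝ_M of the scaled max ranks and the rescaled ideal form:

    MSE_M(l/M) = (M−l)⁻¹ Σ_{x=l..M} [Ŝ_M(x/M) − (1 − l/M)·S_{l/M}(x/M)]².

Writing k̂ for the minimiser, the expected number of irreproducible
metabolites with max rank in (k̂, l] is (l−k̂)²/(M−k̂), giving the mFDR
estimate of the rejection region (0, l]:

    mFDR(l) = (l−k̂)² / (Q(l)·(M−k̂)),   Q(l) = #{m : Max_m ≤ l}.

The classification threshold is N̂ = max{l > k̂ : mFDR(l) ≤ α} (falling back
to k̂ when no l qualifies) and metabolite m is declared reproducible iff
Max_m ≤ N̂. Everything is rank-based, so any strictly monotone transform of
the abundances leaves the results unchanged.

Multi-layer nested designs (e.g. operator → spike-in → technical replicate)
are handled by running MaRR on every within-group replicate pair at the
bottom layer and by summing abundances over lower layers to compare units of
upper layers. Per-layer calls form an M × J binary matrix that is filtered
data-adaptively: metabolite m is kept when its reproducible fraction across
pairs strictly exceeds c_s, and a sample pair is flagged when its
reproducible fraction across metabolites strictly exceeds c_m.

## Worked example

Score one simulated replicate pair (2860 features, 75% truly reproducible,
reproducible signals bivariate normal with correlation 0.45):

```python
from marrms.marr import marr_pair
from marrms.simulate import SimIConfig, simulate_I, evaluate_run

config = SimIConfig(mu_r=4.01, rho_r=0.45, pi1=0.75, m=2860)
t1, t2, truth = simulate_I(config, dataset_seed=0)
res = marr_pair(t1, t2, alpha=0.05, tie_seed=0)
m = evaluate_run(res.calls, truth, res.pi1.pi1_hat, config.pi1)
print(f"estimated pi1 = {res.pi1.pi1_hat:.4f} (true 0.75)")
print(f"threshold N_hat = {res.n_hat}, declared reproducible = {res.n_reproducible}")
print(f"empirical FDR = {m.fdr:.4f}, power = {m.power:.4f}")
```

prints

```
estimated pi1 = 0.7469 (true 0.75)
threshold N_hat = 2421, declared reproducible = 2245
empirical FDR = 0.0445, power = 1.0000
```

The estimator recovers the planted reproducible proportion to three decimal
places, and thresholding the max ranks at N̂ = 2421 declares 2245
metabolites reproducible with an empirical false discovery rate under the
nominal α = 0.05 while recovering every truly reproducible signal.

The same machinery is available from a shell. A complete pipeline on a
synthetic triple-layer fixture:

```sh
marrms fixture fix/ --layers operator,spikein,replicate --levels 3,3,3 \
    --n-features 500 --seed 1
marrms run fix/fixture_abundance.csv fix/fixture_metadata.csv out/ \
    --alpha 0.01 --seed 1
```

writes, per layer, the metabolite × pair call matrix, per-margin
reproducibility flags, the threshold summary table, histogram data, and the
reproducible-feature subset, plus a log of counts and seeds.

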