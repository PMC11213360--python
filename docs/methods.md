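# Methods

## The estimation problem

Let `a_i` (i = 1..p) be latent absolute abundances, `r_i = a_i / Σ a_j`
relative abundances, and `x_i` observed read counts with library size
`N = Σ x_j`. Only `x` is observed, and `N` is technically arbitrary, so any
statistic that is not invariant to per-replicate rescaling conflates
biology with sequencing depth. The targets are

* case B: `Corr[log a_i, b]` for an external, non-compositional variable
  `b`;
* case C: `Corr[log a_i, log b_k]` between two compositional datasets with
  reads `x` (p features) and `y` (q features).

Under the idealised reads model `x_i = r_i N`, log-ratios of reads equal
log-ratios of abundances, and the estimators work entirely through
log-ratio (co)variances.

## Basis variances (SparCC system)

Writing `T_ij = Var[log(x_i/x_j)] = ω_i + ω_j − 2 Cov[log a_i, log a_j]`
with `ω_i = Var[log a_i]`, the sparsity assumption — row averages of the
latent covariance matrix are ≈ 0 — reduces the row sums of `T` to the
linear system `((p−2)I + J) ω = t`, `t_i = Σ_{j≠i} T_ij`. The closed form

    ω_i = (t_i − Σt / (2p−2)) / (p−2)

is exact whenever `T` is exactly additive and costs O(p²) given `T` (a
generic dense solve is kept as a test oracle). Estimation is **single
pass**: no iterative exclusion of strongly correlated pairs is layered on
top. Negative solved variances are a known pathology of the system when
sparsity is violated or p is small; values below a floor of 1e-8 are
clipped and flagged with a warning. The floor keeps downstream divisions
finite; flagged features should be interpreted with caution.

## SparCEV and SparXCC

With `v_i = Cov[log(x_i + pc), b]`, bilinearity gives
`Cov[log(x_i/x_j), b] = v_i − v_j` and the base estimator collapses to

    ρ̂_i = (p/(p−1)) (v_i − mean(v)) / (σ̂_b α̂_i).

In case C, with `C_ik = Cov[log(x_i+pc), log(y_k+pc)]`, expanding each
log-ratio covariance into four `C` terms and summing over reference pairs
yields the closed form `t_ik = pq·C_ik − p·R_i − q·S_k + T_sum`
(row/column/grand sums of `C`), verified against the explicit quadruple sum
in the test suite before anything was built on it. The base estimate is
`ρ̂_ik = t_ik / ((p−1)(q−1) α̂_i β̂_k)`, with `α̂` and `β̂` estimated from
each dataset independently. Estimates can leave [−1, 1] when the
denominators are underestimated; reported values are clipped with flags and
the raw values retained (the base-vs-iterative diagnostic uses them).

All covariances and variances use the unbiased (n−1) denominator, one
convention everywhere. Logs are natural: correlations are base-invariant
but the basis variances are not, and the SparCC literature works in natural
logs. The pseudo-count (default 1, configurable) applies to count tables
only, never to the phenotype.

### Iterative bias correction

If a set R of truly-null features were known, averaging `v_i − v_j` over
j ∈ R would remove the bias term entirely. The iterative procedure
approximates R by `R_n = {i : |ρ̂_i^(n−1)| < t}` starting from all features,
re-estimates, and stops when the set stabilises. Two conventions here
deviate deliberately from the literal iteration formulas as usually
printed:

* the reference sum excludes j = i and normalises by `|R_n \ {i}|` (and
  `|S_n\{i}|·|T_n\{k}|` in case C) rather than a fixed `p−1` or
  `(p−1)(q−1)`. The exact identity that motivates the iteration averages
  over the *included set*, and this convention makes `t = ∞` reduce to the
  base estimator bit for bit — an identity the tests assert literally.
* when an update would leave some feature without any reference (no
  features fall under the thresholds), the procedure warns and returns the
  previous iterate — at n = 1 that is exactly the base estimate. This is
  the behaviour a practitioner wants: an over-tight threshold degrades to
  "no correction" rather than an error.

The case C restricted double sum is computed from restricted marginal sums
of `C` (O(pq) per iteration). Basis variances are computed once from the
full tables and reused across iterations. Oscillating reference sets
(detected by hashing) are reported as non-convergence with the last iterate
returned; `max_iter` defaults to 20.

### Threshold choice and detection

Thresholds come from permutations that break exactly the correlations
under study: in case B the phenotype vector is permuted; in case C the
replicate rows of each table are permuted independently (within-dataset
structure, including the basis-variance estimation problem, is preserved).
The pooled null estimates give the iteration threshold — by default the
80th percentile of pooled |ρ̂| in case B. In case C the set criterion is a
*mean* of q estimates, so its null distribution is tight and any common
bias (the very situation the iteration exists for) lifts every feature
above an 80th-percentile null threshold, emptying the reference sets; the
benchmark bank therefore uses the max-percentile rule (the pool maximum),
which keeps the vast majority of uncorrelated features eligible. For user
data the default remains the 80th percentile, to be judged with the
base-vs-iterative diagnostic: pairs of estimates on a slope-1 line with
non-zero intercept indicate a bias successfully removed; an intercept near
zero says the base estimates were already fine.

Detection uses the separate permutation threshold `m`: the maximum
absolute estimate over all features and permutations; observed estimates
above `m` are candidate true correlations. This deliberately avoids
p-values — with compositional bias and technical noise, any test statistic
would inherit uncontrolled bias, and the max-null threshold is transparent
about what it controls.

BCa bootstrap intervals (case B) resample replicates with replacement,
take the bias correction from the bootstrap distribution and the
acceleration from a leave-one-out jackknife, and truncate to [−1, 1].
Degenerate bootstrap distributions collapse to the point estimate with a
warning. n_boot ≥ 200 is enforced; 1000 is the default.

## The simulator

A Gaussian copula `g ~ N(0, Ψ)` over the p + q variables is pushed through
zero-inflated log-normal marginals: `Z_i = 0` when `g_i < Φ⁻¹(π_i)`
(a *biological* zero — the feature is truly absent), otherwise
`Z_i = F_i⁻¹(Φ(g_i))` so that `log Z_i | Z_i ≠ 0 ~ N(μ_i, σ_i²)` and
`P(Z_i = 0) = π_i`. Absolute abundances are `a = Z[:p]`; the phenotype in
case B is `b = log Z_{p+1}` with π = 0 (an ordinary normal variable); in
case C the second dataset's abundances are `Z[p:]`. Reads are drawn as
`x ~ Multinomial(⌈N⌉, r)` with `N ~ logNormal(μ_a, σ_a²)` per replicate —
the multinomial is the model of *technical* sequencing noise, and
*sampling* zeros from finite depth arise from it on top of the biological
ones. `Corr[log a_i, log a_j] = Ψ_ij` exactly when the π involved are
zero; with biological zeros Ψ remains the benchmarking ground truth and
the zeros act as an additional noise source.

Two Ψ constructions:

* **cluster** — `round(c·p)` OTUs (plus the phenotype in case B, or
  `round(c·q)` genes in case C) form one equicorrelated block at ρ; all
  other entries are 0. Gives exact control over sparsity (c) and effect
  size (ρ). The PSD condition `ρ ≥ −1/(m−1)` for block size m is checked.
  The block occupies the leading indices, a fixed convention.
* **loadings** — Ψ is the correlation matrix of `L Lᵀ` for a (p+q) × k
  loadings matrix with iid standard-normal entries: no exact zeros, mostly
  weak correlations, signs symmetric around zero; k = 1 degenerates to
  entries of ±1. The construction (no idiosyncratic noise term, plain
  normalisation) is this package's concrete choice among recipes with
  those properties, exposed as a pluggable function.

### Parameter choices

Marginals can be moment-matched to a real template table via the
log-normal identities `σ² = log(1 + σ_r²/μ_r²)`, `μ = log μ_r − σ²/2`,
with `π` set to half the observed zero fraction (the working assumption:
half of observed zeros are biological, half technical). Alternatively a
target diversity can be requested: one dominant OTU plus a uniform rest,
with the dominant share solved (bracketed root finding, tolerance 1e-10)
so that the effective number of OTUs `p_eff = exp(H)` — Shannon entropy
`H = −Σ r log r`, maximal at evenness — hits the target; there σ² = 1 and
π = 0.

For self-contained studies the package defines its own defaults
(`study_marginals`, `default_library_sizes`), chosen once as a realistic
middle ground and used for every benchmark in the tests and the acceptance
script:

* mean linear-scale abundances follow a geometric rank-abundance series
  (ratio 0.95 per rank) — the classic niche-preemption profile; for
  p = 100 this realises an effective number of OTUs around 34;
* log-scale variance σ² = 1 for every feature (counts overdispersed by a
  factor `e ≈ 2.7` on the linear scale, typical of 16S data);
* biological-zero probability π = 0.1 per OTU;
* phenotype `N(30, 1)` on the phenotype scale (case B);
* library sizes `logNormal(log 10⁴, 1)` — median 10k reads, middle 95%
  roughly 1.4k–71k, the depth variation of a real sequencing run.

### What the benchmarks do and do not show

The study runner repeats simulate → estimate → score over seeded datasets
(seeds spawned from a master seed via `numpy.random.SeedSequence`, so runs
are reproducible and parallelisable) and reports per-method means with
±1.96 SE envelopes. Scoring is restricted to the cross-block of Ψ (OTU ×
phenotype or OTU × gene pairs); within-dataset correlations are never
evaluated. For cluster truth the MAE is split into truly correlated and
truly uncorrelated pairs — the all-zero estimator scores a deceptively low
overall MAE of c·ρ, which is precisely why the split exists. For loadings
truth (no exact zeros) the MAE is reported above |Ψ| thresholds 0, 0.1,
…, 0.8. Empty strata are reported as missing, never as 0.

The bundled study cells are scaled for a laptop-class run: 100 simulated
datasets for the case B cell and 50 for case C (n = 50 replicates each),
with 20 permutations for threshold selection; the qualitative method
ordering is stable across master seeds at these sizes. Under these
conditions the dense-cluster (c = 0.4) cell shows the iterative estimators
clearly ahead of everything else, the base estimators statistically tied
with CLR, and log-TSS slightly ahead of both base and CLR — the expected
pattern when sparsity is badly violated and the community is only
moderately uneven. With very low-diversity communities (real skin or gut
templates) log-TSS degrades substantially relative to the compositionally
aware methods; the geometric profile used here is deliberately less
extreme, so the log-TSS column of the benchmarks should be read as a
favourable case for that baseline.

Other limits of the simulation: technical noise is exactly multinomial
(no per-feature overdispersion of the sequencing step), replicates are
exchangeable (no batch structure), the copula ties zeros to low latent
Gaussian values (absence correlates with "would have been rare"), and with
biological zeros present the estimand `Corr[log a_i, ·]` is itself only
approximately Ψ. Passing benchmarks therefore demonstrate correctness of
the estimators under this generative model, not performance guarantees on
any particular real dataset.

## Numerical conventions

* Pearson correlations clip float noise to [−1, 1]; constant columns give
  NaN with a warning naming the column rather than aborting a p × q run.
* `sparxcc_base(Y, X)` is the bitwise transpose of `sparxcc_base(X, Y)`:
  the cross-covariance product is evaluated in a canonical orientation and
  the marginal sums are computed in replicate space, because blocked BLAS
  kernels are not transpose-symmetric at the bit level.
* The iterative estimators special-case the full reference set to the base
  formula so the `t = ∞` reduction is exact, not merely close.
* Tables are replicates × features (the n × p statistical convention);
  feature-per-row files are read with `--transpose`.
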