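# compocross

Compositionally aware estimation of cross-correlations for sequencing data.

Microbiome (16S/ITS) and transcriptome count tables are *compositional*: the
library size is a technical artifact, so the observed reads carry only
relative information. Naively correlating log counts — or even log relative
abundances — with other variables produces spurious correlations driven by
the arbitrary total. `compocross` implements two estimators that correct for
this:

* **SparCEV** — correlations between log absolute OTU abundances and an
  external continuous variable (a clinical score, a phenotype): *case B*.
* **SparXCC** — the p × q matrix of cross-correlations between two
  compositional datasets (e.g. bacterial 16S vs fungal ITS, or microbiome
  vs RNA-seq): *case C*.

Both build on the SparCC idea: log-ratios `log(x_i/x_j)` are invariant to
the library size, and under a *sparsity assumption* (feature-wise
covariances average out) the unobservable quantities become estimable. With
`α_i² = Var[log a_i]` (the basis variance, solved from the log-ratio
variance matrix via the SparCC linear system) and `σ_b² = Var[b]`:

```
Corr[log a_i, b]        ≈ 1/(σ_b α_i) · 1/(p−1) Σ_{j≠i} Cov[log(x_i/x_j), b]          (SparCEV)
Corr[log a_i, log b_k]  ≈ t_ik / ((p−1)(q−1) α_i β_k),
t_ik = Σ_{j≠i} Σ_{l≠k} Cov[log(x_i/x_j), log(y_k/y_l)]                                 (SparXCC)
```

`t_ik` is computed in closed form, `t_ik = pq·C_ik − p·R_i − q·S_k + T`,
from the p × q log-scale cross-covariance matrix `C` and its marginal sums —
O(pq), never a quadruple loop.

When some features genuinely correlate with the target, the sparsity
assumption is violated and the base estimators carry a common bias. The
**iterative** variants re-estimate against a reference set restricted to
features currently deemed near-uncorrelated (|ρ̂| below a threshold chosen
from permutations of the data), iterating until the set stabilises.
Candidate correlated pairs are flagged by a permutation threshold *m* (the
largest absolute estimate seen after permuting the data), and BCa bootstrap
confidence intervals are available for case B.

The package also ships the full validation apparatus: baseline competitors
(Pearson correlation after log, log-TSS or CLR transformation), a
zero-inflated log-normal Gaussian-copula simulator with multinomial
sequencing noise, and stratified mean-absolute-error benchmarking.

## Worked example

```python
import compocross as cc

# simulate: 30 OTUs, 100 replicates; 6 OTUs (20%) truly correlated with the
# phenotype at rho = 0.75, the rest uncorrelated
psi = cc.cluster_correlation_matrix(30, 1, c=0.2, rho=0.75, case="B")
ds = cc.simulate_dataset(psi, cc.study_marginals(30, 1, "B"),
                         cc.default_library_sizes("B"),
                         n=100, case="B", q=1, seed=7)

est = cc.SparCEV(method="iterative", n_perm=50, random_state=0).fit(ds.X, ds.b)
m, detected = est.detect(ds.X, ds.b)
```

This prints (via the fitted attributes):

```
threshold t = 0.1344   iterations: 5
m = 0.3088             detected: 7 of 30
mean rho in cluster:   0.731
mean |rho| outside:    0.078
power: 1.0   fdr: 0.143
```

The iterative estimator recovers the true in-cluster correlation (0.731 vs
0.75) while out-of-cluster estimates stay near zero; all 6 truly correlated
OTUs exceed the permutation threshold `m`, with one false positive.
`SparXCC` works the same way with `fit(X, Y)` for two count tables and a
`rho_` matrix of shape (p, q). Both classes are sklearn-style estimators
(`get_params`/`set_params`, fitted attributes with trailing underscores).

The same analyses run from the shell:

```
compocross simulate --case B --p 30 --c 0.2 --rho 0.75 --n 100 --seed 7 --out-prefix sim_
compocross sparcev --counts sim_X.tsv --phenotype sim_b.tsv --seed 0 --out result.tsv
```

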