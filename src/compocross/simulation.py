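"""Synthetic sequencing data under a zero-inflated log-normal Gaussian copula.

The generative model (the SparseDOSSA2 parametric model, extended with a
second block of variables for cross-correlation studies) draws, per
replicate:

1. a latent Gaussian vector g ~ N(0, Psi) over the p OTUs and q other
   variables (the copula);
2. zero-inflated log-normal abundances Z_i: Z_i = 0 when
   g_i < Phi^-1(pi_i) ("biological zero", the feature is truly absent),
   otherwise Z_i = F_i^-1(Phi(g_i)) with F_i the zero-inflated log-normal
   cdf, so that log Z_i | Z_i != 0 ~ N(mu_i, sigma_i^2) and
   P(Z_i = 0) = pi_i;
3. absolute abundances a_i = Z_i; in case B the phenotype is
   b_j = log Z_{p+j} (with pi = 0, i.e. a plain normal variable), in case C
   the second dataset's absolute abundances are b_j = Z_{p+j};
4. relative abundances r = a / sum(a); a library size ceil(N) with
   N ~ logNormal(mu_a, sigma_a^2); and observed read counts
   x ~ Multinomial(ceil(N), r) — the multinomial is the model of technical
   sequencing noise.  Case C repeats 4 for the second dataset.

Corr[log a_i, log a_j] equals Psi_ij exactly when pi_i = pi_j = 0; with
biological zeros Psi remains the ground truth for benchmarking and the
zeros act as an extra noise source.

Two constructions of Psi are provided: the *cluster* method (an
equicorrelated block of round(c*p) OTUs, plus the phenotype / round(c*q)
genes, zero elsewhere — full control over sparsity) and the *loadings*
method (Psi from a random rank-k factor model — no exact zeros, mostly
weak, sign-symmetric correlations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MarginalParams",
    "LibrarySizeParams",
    "SimulatedDataset",
    "cluster_correlation_matrix",
    "loadings_correlation_matrix",
    "simulate_dataset",
    "template_params",
    "diversity_params",
    "effective_number_of_features",
    "study_marginals",
    "default_library_sizes",
    "cross_block",
]


@dataclass
class MarginalParams:
    """Per-variable zero-inflated log-normal parameters.

    ``mu`` and ``sigma2`` are log-scale mean and variance of the non-zero
    part; ``pi`` is the biological-zero probability.  Length p + q, OTUs
    first.
    """

    mu: np.ndarray
    sigma2: np.ndarray
    pi: np.ndarray

    def __post_init__(self):
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.sigma2 = np.atleast_1d(np.asarray(self.sigma2, dtype=float))
        self.pi = np.atleast_1d(np.asarray(self.pi, dtype=float))
        if not (self.mu.shape == self.sigma2.shape == self.pi.shape):
            raise ValueError("mu, sigma2, pi must have equal length")
        if (self.sigma2 <= 0).any():
            raise ValueError("sigma2 must be positive")
        if ((self.pi < 0) | (self.pi >= 1)).any():
            raise ValueError("pi must lie in [0, 1)")

    def __len__(self):
        return self.mu.shape[0]


@dataclass
class LibrarySizeParams:
    """Log-normal library-size parameters (second dataset's in case C)."""

    mu_a: float
    sigma2_a: float
    mu_b: float | None = None
    sigma2_b: float | None = None

    def __post_init__(self):
        if self.sigma2_a <= 0:
            raise ValueError("sigma2_a must be positive")
        if self.sigma2_b is not None and self.sigma2_b <= 0:
            raise ValueError("sigma2_b must be positive")


@dataclass
class SimulatedDataset:
    """A simulated study: count table(s), phenotype, and the ground truth."""

    X: pd.DataFrame
    truth: np.ndarray
    case: str
    Y: pd.DataFrame | None = None
    b: np.ndarray | None = None
    latent: dict = field(default_factory=dict)

    @property
    def truth_cross(self) -> np.ndarray:
        """The scored cross-block of Psi: OTU x phenotype/gene pairs."""
        p = self.X.shape[1]
        return cross_block(self.truth, p)


def cross_block(psi: np.ndarray, p: int) -> np.ndarray:
    """Cross-block Psi[:p, p:] — the only entries the benchmarks score."""
    return np.asarray(psi)[:p, p:]


def cluster_correlation_matrix(p: int, q: int, c: float, rho: float,
                               case: str = "B") -> np.ndarray:
    """Equicorrelated-cluster correlation matrix over p OTUs and q others.

    The first ``round(c*p)`` OTUs form the cluster; in case B all q
    phenotype variables join it, in case C the first ``round(c*q)`` genes
    do.  All cluster members are pairwise correlated at ``rho``; everything
    else is uncorrelated.  Placement of the cluster at the leading indices
    is a fixed convention (it is irrelevant to every statistic computed).
    """
    if not 0 <= c <= 1:
        raise ValueError("c must lie in [0, 1]")
    if not -1 < rho < 1:
        raise ValueError("rho must lie in (-1, 1)")
    if case not in ("B", "C"):
        raise ValueError("case must be 'B' or 'C'")
    n_otu = int(round(c * p))
    members = list(range(n_otu))
    if case == "B":
        members += list(range(p, p + q))
    else:
        members += list(range(p, p + int(round(c * q))))
    m = len(members)
    if m > 1 and rho < -1.0 / (m - 1):
        raise ValueError(
            f"equicorrelation rho={rho} violates positive semi-definiteness "
            f"for cluster size {m} (needs rho >= {-1.0 / (m - 1):.4f})"
        )
    psi = np.eye(p + q)
    idx = np.asarray(members, dtype=int)
    if m > 1:
        psi[np.ix_(idx, idx)] = rho
        psi[idx, idx] = 1.0
    return psi


def loadings_correlation_matrix(dim: int, k: int, seed=None) -> np.ndarray:
    """Random factor-model correlation matrix.

    Draws a dim x k loadings matrix L with iid standard-normal entries and
    normalises Sigma = L L^T to a correlation matrix.  Small k gives strong
    correlations (k=1 degenerates to entries of +/-1); large k gives mostly
    weak, sign-symmetric correlations with no exact zeros.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    L = rng.standard_normal((dim, k))
    sigma = L @ L.T
    d = np.sqrt(np.diag(sigma))
    psi = sigma / np.outer(d, d)
    np.fill_diagonal(psi, 1.0)
    return psi


def _sampling_root(psi: np.ndarray) -> np.ndarray:
    """Matrix A with A A^T = Psi; handles the rank-deficient loadings case."""
    try:
        return np.linalg.cholesky(psi)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(psi)
        if w.min() < -1e-8:
            raise ValueError("Psi is not positive semi-definite") from None
        return V * np.sqrt(np.clip(w, 0.0, None))


def _zero_inflated_lognormal(g: np.ndarray, marginals: MarginalParams) -> np.ndarray:
    """Map copula normals to zero-inflated log-normal draws, columnwise."""
    pi = marginals.pi
    mu = marginals.mu
    sigma = np.sqrt(marginals.sigma2)
    u = stats.norm.cdf(g)
    z = np.zeros_like(g)
    alive = u >= pi  # g_i >= Phi^-1(pi_i)
    # F^-1 of the zero-inflated log-normal on the non-zero branch
    inner = (u - pi) / (1.0 - pi)
    with np.errstate(divide="ignore", invalid="ignore"):
        quant = stats.norm.ppf(np.clip(inner, 0.0, 1.0 - 1e-16))
    z[alive] = np.exp((mu + sigma * quant)[alive])
    return z


def simulate_dataset(psi: np.ndarray, marginals: MarginalParams,
                     libsizes: LibrarySizeParams, n: int, case: str = "B",
                     q: int = 1, seed=None, keep_latent: bool = False) -> SimulatedDataset:
    """Draw n replicates from the copula model (see module docstring).

    Parameters
    ----------
    psi : (p+q) x (p+q) correlation matrix (the ground truth)
    marginals : MarginalParams of length p + q
    libsizes : LibrarySizeParams (``mu_b``/``sigma2_b`` required in case C)
    n : number of replicates
    case : "B" (phenotype) or "C" (second compositional dataset)
    q : number of non-OTU variables (phenotypes in B, genes in C)
    seed : anything accepted by numpy's default_rng
    keep_latent : retain (g, Z, a, r, N) for testing
    """
    psi = np.asarray(psi, dtype=float)
    dim = psi.shape[0]
    if psi.shape != (dim, dim) or len(marginals) != dim:
        raise ValueError("psi and marginals dimensions disagree")
    if case not in ("B", "C"):
        raise ValueError("case must be 'B' or 'C'")
    p = dim - q
    if p < 1 or q < 1:
        raise ValueError("need p >= 1 and q >= 1")
    if case == "B" and (marginals.pi[p:] != 0).any():
        raise ValueError("phenotype variables must have pi = 0 in case B")
    if case == "C" and (libsizes.mu_b is None or libsizes.sigma2_b is None):
        raise ValueError("case C requires mu_b and sigma2_b library-size parameters")

    rng = np.random.default_rng(seed)
    A = _sampling_root(psi)
    g = rng.standard_normal((n, dim)) @ A.T
    Z = _zero_inflated_lognormal(g, marginals)

    a = Z[:, :p]
    row_load = a.sum(axis=1)
    if (row_load == 0).any():
        raise RuntimeError(
            "a replicate drew zero total abundance (all OTUs absent); "
            "lower the zero-probabilities pi"
        )
    r_a = a / row_load[:, None]
    N_a = np.ceil(rng.lognormal(libsizes.mu_a, np.sqrt(libsizes.sigma2_a), size=n)).astype(np.int64)
    x = np.vstack([rng.multinomial(N_a[i], r_a[i]) for i in range(n)])

    otu_ids = [f"OTU_{i + 1}" for i in range(p)]
    rep_ids = [f"rep_{i + 1}" for i in range(n)]
    X = pd.DataFrame(x, columns=otu_ids, index=rep_ids)

    latent = {}
    if keep_latent:
        latent = {"g": g, "Z": Z, "a": a, "r_a": r_a, "N_a": N_a}

    if case == "B":
        b = np.log(Z[:, p:])
        b = b[:, 0] if q == 1 else b
        return SimulatedDataset(X=X, truth=psi, case="B", b=b, latent=latent)

    bz = Z[:, p:]
    row_load_b = bz.sum(axis=1)
    if (row_load_b == 0).any():
        raise RuntimeError("a replicate drew zero total abundance in dataset 2")
    r_b = bz / row_load_b[:, None]
    N_b = np.ceil(rng.lognormal(libsizes.mu_b, np.sqrt(libsizes.sigma2_b), size=n)).astype(np.int64)
    y = np.vstack([rng.multinomial(N_b[i], r_b[i]) for i in range(n)])
    gene_ids = [f"gene_{i + 1}" for i in range(q)]
    Y = pd.DataFrame(y, columns=gene_ids, index=rep_ids)
    if keep_latent:
        latent.update({"b_abs": bz, "r_b": r_b, "N_b": N_b})
    return SimulatedDataset(X=X, truth=psi, case="C", Y=Y, latent=latent)


def template_params(template) -> MarginalParams:
    """Moment-match marginal parameters to a real count table.

    Per feature, the empirical linear-scale mean mu_r and variance
    sigma_r^2 of the observed read counts are mapped through the log-normal
    moment identities

        sigma^2 = log(1 + sigma_r^2 / mu_r^2),   mu = log mu_r - sigma^2 / 2,

    and the zero-probability pi is set to half the observed zero fraction
    (the working assumption being that half the observed zeros are
    biological and half technical).  Features with zero mean cannot be
    matched and are dropped with a warning.
    """
    import warnings

    vals = np.asarray(template, dtype=float) if not isinstance(template, pd.DataFrame) \
        else template.to_numpy(dtype=float)
    if vals.ndim != 2 or vals.shape[0] < 2:
        raise ValueError("template needs at least 2 replicates")
    mean_r = vals.mean(axis=0)
    keep = mean_r > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} all-zero feature(s) from the template",
            RuntimeWarning, stacklevel=2,
        )
        vals = vals[:, keep]
        mean_r = mean_r[keep]
    if vals.shape[1] == 0:
        raise ValueError("template has no features with non-zero mean")
    var_r = vals.var(axis=0, ddof=1)
    sigma2 = np.log1p(var_r / mean_r ** 2)
    # a feature constant across replicates has zero variance; give it a
    # tiny log-scale variance rather than a degenerate distribution
    sigma2 = np.clip(sigma2, 1e-12, None)
    mu = np.log(mean_r) - sigma2 / 2.0
    pi = 0.5 * (vals == 0).mean(axis=0)
    return MarginalParams(mu=mu, sigma2=sigma2, pi=pi)


def effective_number_of_features(r) -> float:
    """exp(Shannon entropy) of a relative-abundance vector.

    Equals the number of features under perfect evenness and 1 when a
    single feature dominates; zero entries contribute nothing to H.
    """
    r = np.asarray(r, dtype=float)
    if (r < 0).any():
        raise ValueError("relative abundances must be non-negative")
    if abs(r.sum() - 1.0) > 1e-9:
        raise ValueError("relative abundances must sum to 1")
    nz = r[r > 0]
    H = -(nz * np.log(nz)).sum()
    return float(np.exp(H))


def diversity_params(p: int, p_eff_target: float, load: float = 1000.0) -> MarginalParams:
    """Marginals targeting a requested effective number of OTUs.

    One dominant OTU at mean relative abundance nu_1 and the rest uniform
    at (1 - nu_1)/(p - 1); nu_1 solves exp(H(nu)) = p_eff_target on the
    dominant branch nu_1 in [1/p, 1).  Linear-scale means are load * nu_i,
    mapped to log-scale with sigma_i^2 = 1 and pi_i = 0 throughout.
    """
    if not 1 < p_eff_target <= p:
        raise ValueError("p_eff_target must lie in (1, p]")

    def entropy(nu1):
        rest = (1.0 - nu1) / (p - 1)
        h = -nu1 * np.log(nu1)
        if rest > 0:
            h -= (p - 1) * rest * np.log(rest)
        return h

    target = np.log(p_eff_target)
    if abs(entropy(1.0 / p) - target) < 1e-12:
        nu1 = 1.0 / p  # uniform: p_eff = p exactly
    else:
        nu1 = optimize.brentq(lambda v: entropy(v) - target,
                              1.0 / p, 1.0 - 1e-12, xtol=1e-14, rtol=8.9e-16)
    nu = np.full(p, (1.0 - nu1) / (p - 1))
    nu[0] = nu1
    sigma2 = np.ones(p)
    mu = np.log(load * nu) - sigma2 / 2.0
    return MarginalParams(mu=mu, sigma2=sigma2, pi=np.zeros(p))


def study_marginals(p: int, q: int, case: str = "B", decay: float = 0.95,
                    load: float = 1000.0, sigma2: float = 1.0,
                    zero_prob: float = 0.1, pheno_mean: float = 30.0,
                    pheno_var: float = 1.0,) -> MarginalParams:
    """Default marginals for simulation studies.

    OTU mean linear-scale abundances follow a geometric rank-abundance
    series (nu_i proportional to decay^i, the classic niche-preemption
    profile of microbial communities), with log-scale variance ``sigma2``
    and biological-zero probability ``zero_prob`` for every OTU.  In case B
    the q phenotype variables are N(pheno_mean, pheno_var) on the phenotype
    scale with no zero inflation; in case C the second dataset gets the
    same geometric profile as the OTUs.
    """
    if not 0 < decay < 1:
        raise ValueError("decay must lie in (0, 1)")

    def geometric_mu(m):
        nu = decay ** np.arange(m)
        nu /= nu.sum()
        return np.log(load * nu) - sigma2 / 2.0

    mu = [geometric_mu(p)]
    s2 = [np.full(p, sigma2)]
    pi = [np.full(p, zero_prob)]
    if case == "B":
        mu.append(np.full(q, pheno_mean))
        s2.append(np.full(q, pheno_var))
        pi.append(np.zeros(q))
    else:
        mu.append(geometric_mu(q))
        s2.append(np.full(q, sigma2))
        pi.append(np.full(q, zero_prob))
    return MarginalParams(mu=np.concatenate(mu), sigma2=np.concatenate(s2),
                          pi=np.concatenate(pi))


def default_library_sizes(case: str = "B", mean_reads: float = 1e4,
                          sigma2: float = 1.0) -> LibrarySizeParams:
    """Log-normal library sizes with median ``mean_reads`` per replicate."""
    mu = float(np.log(mean_reads))
    if case == "B":
        return LibrarySizeParams(mu_a=mu, sigma2_a=sigma2)
    return LibrarySizeParams(mu_a=mu, sigma2_a=sigma2, mu_b=mu, sigma2_b=sigma2)
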