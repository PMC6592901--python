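"""Bayesian Gaussian phylogenetic generalized linear mixed model (PGLMM).

The comparative model is the standard "animal model" applied at the species
level: for species trait values ``y`` (one row per species),

    y = X beta + a + Z_u u + e
    a ~ N(0, sigma2_a * A),   u ~ N(0, sigma2_u * I),   e ~ N(0, sigma2_e * I)

where ``A`` is the phylogenetic correlation matrix derived from a time-scaled
tree (entries proportional to shared root-to-ancestor path length, unit
diagonal), ``a`` is the phylogenetic random effect, ``u`` an optional i.i.d.
grouping effect (e.g. presumed call function), and ``e`` the residual.

Inference is by a conjugate Gibbs sampler: Gaussian full conditionals for
``beta``, ``a`` and ``u``; inverse-Gamma full conditionals for the variance
components under independent IG(alpha, beta) priors (default alpha = beta =
0.001, a weakly informative choice) and a diffuse N(0, 1e10) prior on the
fixed effects.  The phylogenetic effect is sampled in the eigenbasis of ``A``,
where its full-conditional precision is diagonal, so each sweep costs two
n-by-n matrix-vector products.

Phylogenetic heritability is H^2 = sigma2_a / (sigma2_a + sigma2_e), the
fraction of non-fixed trait variance attributable to phylogeny (the analogue
of Pagel's lambda); any grouping variance is deliberately excluded from the
denominator.

Convergence diagnostics follow the classical toolkit: Gelman-Rubin potential
scale reduction factor across chains, Heidelberger-Welch stationarity test
within chains, and autocorrelation-based effective sample sizes with Geyer
initial-positive-sequence truncation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from numpy.linalg import LinAlgError
from scipy import special

__all__ = [
    "PhyloCorrelation",
    "ModelSpec",
    "Priors",
    "MCMCSettings",
    "PosteriorSummary",
    "PGLMMChains",
    "HeidelbergerResult",
    "read_newick",
    "prune",
    "phylo_correlation",
    "fit_pglmm",
    "summarize",
    "heritability",
    "hpd_interval",
    "p_mcmc",
    "gelman_rubin",
    "heidelberger_stationarity",
    "ess",
    "lag1_autocorr",
]


# ---------------------------------------------------------------------------
# trees and phylogenetic correlation
# ---------------------------------------------------------------------------

def read_newick(path) -> dendropy.Tree:
    """Read a Newick tree with branch lengths; zero/negative lengths raise."""
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    _check_branch_lengths(tree)
    return tree


def _check_branch_lengths(tree: dendropy.Tree) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:  # root edge may be absent
            continue
        if edge.length is None or edge.length <= 0:
            raise ValueError(
                f"edge above {edge.head_node} has non-positive or missing length"
            )


def prune(tree: dendropy.Tree, taxa: Sequence[str]) -> dendropy.Tree:
    """Prune to exactly ``taxa``, collapsing degree-2 nodes (lengths summed)."""
    labels = set(taxa)
    present = {t.label for t in tree.taxon_namespace}
    missing = sorted(labels - present)
    if missing:
        raise ValueError(f"taxa absent from tree: {missing}")
    # round-trip through Newick so the copy owns its taxon namespace and the
    # input tree is left untouched
    sub = dendropy.Tree.get(
        data=tree.as_string(schema="newick"), schema="newick", preserve_underscores=True
    )
    sub.retain_taxa_with_labels(labels)
    sub.purge_taxon_namespace()
    return sub


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


@dataclass(frozen=True)
class PhyloCorrelation:
    """Taxon-labelled phylogenetic correlation matrix (unit diagonal, SPD)."""

    taxa: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if len(set(self.taxa)) != n:
            raise ValueError("taxa labels must be unique")
        if m.shape != (n, n):
            raise ValueError("matrix shape must match number of taxa")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-8):
            raise ValueError("correlation matrix must have unit diagonal")
        try:
            np.linalg.cholesky(m + 1e-10 * np.eye(n))
        except LinAlgError:
            raise ValueError("correlation matrix is not positive definite") from None
        object.__setattr__(self, "matrix", m)

    def reordered(self, taxa: Sequence[str]) -> "PhyloCorrelation":
        idx = [self.taxa.index(t) for t in taxa]
        return PhyloCorrelation(tuple(taxa), self.matrix[np.ix_(idx, idx)])


def phylo_correlation(tree: dendropy.Tree) -> PhyloCorrelation:
    """Phylogenetic correlation matrix from a tree.

    C_ij is the shared root-to-MRCA path length of tips i and j; the
    correlation is A_ij = C_ij / sqrt(C_ii * C_jj).  For an ultrametric tree
    this equals scaling the covariance by the tree depth.
    """
    _check_branch_lengths(tree)
    leaves = [lf for lf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("need at least 2 tips")
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))
    # accumulate each edge's length onto all tip pairs below it
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tips = np.array([index[id(node)]])
        else:
            tips = np.concatenate([below.pop(id(c)) for c in node.child_nodes()])
        below[id(node)] = tips
        length = node.edge.length if node.parent_node is not None else (node.edge.length or 0)
        if length:
            C[np.ix_(tips, tips)] += length
    d = np.sqrt(np.diag(C))
    if np.any(d <= 0):
        raise ValueError("tree has tips at zero depth")
    A = C / np.outer(d, d)
    np.fill_diagonal(A, 1.0)
    return PhyloCorrelation(tuple(lf.taxon.label for lf in leaves), A)


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """What to regress on what.

    ``response`` and every fixed-effect name must be columns of the data
    table.  A habitat column holding the strings ``forest`` / ``other`` is
    dummy-coded with forest as the reference level (forest = 0, other = 1);
    set ``forest_reference=False`` to flip the contrast.
    """

    response: str
    fixed_effects: tuple[str, ...] = ()
    extra_random: str | None = None
    intercept: bool = True
    forest_reference: bool = True


@dataclass(frozen=True)
class Priors:
    """Diffuse Gaussian prior on fixed effects, IG(alpha, beta) on variances."""

    fixed_mean: float = 0.0
    fixed_variance: float = 1e10
    vc_shape_alpha: float = 0.001
    vc_scale_beta: float = 0.001

    def __post_init__(self) -> None:
        if self.fixed_variance <= 0 or self.vc_shape_alpha <= 0 or self.vc_scale_beta <= 0:
            raise ValueError("prior variance, shape and scale must be positive")


@dataclass(frozen=True)
class MCMCSettings:
    """Chain length configuration.

    The default mirrors long-run comparative practice: 11 million iterations,
    100,000 burn-in, thinning interval 10,000, three chains — retaining 1090
    samples per chain.  Use :meth:`test_scale` (minutes) or :meth:`quick`
    (seconds, for simulation studies) for smaller runs.
    """

    n_iter: int = 11_000_000
    burn_in: int = 100_000
    thin: int = 10_000
    n_chains: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")
        if self.retained_per_chain < 2:
            raise ValueError("settings retain fewer than 2 samples per chain")

    @property
    def retained_per_chain(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    @classmethod
    def long_run(cls, seed: int = 0) -> "MCMCSettings":
        return cls(seed=seed)

    @classmethod
    def test_scale(cls, seed: int = 0, n_chains: int = 3) -> "MCMCSettings":
        return cls(n_iter=55_000, burn_in=5_000, thin=50, n_chains=n_chains, seed=seed)

    @classmethod
    def quick(cls, seed: int = 0, n_chains: int = 1) -> "MCMCSettings":
        return cls(n_iter=3_500, burn_in=500, thin=3, n_chains=n_chains, seed=seed)


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior summary for one parameter."""

    parameter: str
    posterior_mean: float
    hpd95_lower: float
    hpd95_upper: float
    p_mcmc: float | None
    ess: float
    psrf: float | None


@dataclass
class PGLMMChains:
    """Retained Gibbs samples: ``params[name]`` has shape (n_chains, n_retained)."""

    params: dict[str, np.ndarray]
    fixed_names: tuple[str, ...]
    variance_names: tuple[str, ...]
    settings: MCMCSettings
    chain_seeds: tuple[int, ...]

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_retained(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def pooled(self, param: str) -> np.ndarray:
        if param not in self.params:
            raise KeyError(f"unknown parameter {param!r}; have {sorted(self.params)}")
        return self.params[param].ravel()

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per retained sample with a chain id column."""
        frames = []
        for c in range(self.n_chains):
            d = {name: arr[c] for name, arr in self.params.items()}
            f = pd.DataFrame(d)
            f.insert(0, "chain", c)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# design construction and the Gibbs sampler
# ---------------------------------------------------------------------------

_HABITAT_LEVELS = {"forest", "other"}


def _design_matrix(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    cols, names = [], []
    if spec.intercept:
        cols.append(np.ones(len(data)))
        names.append("intercept")
    for name in spec.fixed_effects:
        if name not in data.columns:
            raise ValueError(f"fixed effect column {name!r} not in data")
        col = data[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = set(col.astype(str))
            if not levels <= _HABITAT_LEVELS:
                raise ValueError(
                    f"categorical fixed effect {name!r} must have levels forest/other, "
                    f"got {sorted(levels)}"
                )
            ref = "forest" if spec.forest_reference else "other"
            x = (col.astype(str) != ref).astype(float).to_numpy()
        else:
            x = col.to_numpy(dtype=float)
            uniq = np.unique(x)
            if uniq.size == 1:
                raise ValueError(f"fixed effect {name!r} is constant")
        cols.append(x)
        names.append(f"beta_{name}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is singular")
    return X, names


def fit_pglmm(
    data: pd.DataFrame,
    A: PhyloCorrelation | None,
    spec: ModelSpec,
    priors: Priors = Priors(),
    settings: MCMCSettings = MCMCSettings.test_scale(),
) -> PGLMMChains:
    """Fit the PGLMM by Gibbs sampling and return retained samples per chain.

    ``data`` must have one row per species with a ``species`` column (matched
    against ``A.taxa``) and the columns named by ``spec``.  Pass ``A=None``
    to drop the phylogenetic random effect (ordinary Bayesian regression with
    the same priors), which is useful for oracle comparisons.

    Chain ``c`` uses seed ``settings.seed + c``; all randomness flows from one
    generator per chain, so results are reproducible bit-for-bit.
    """
    if spec.response not in data.columns:
        raise ValueError(f"response column {spec.response!r} not in data")
    if "species" not in data.columns:
        raise ValueError("data must have a 'species' column")
    if data["species"].duplicated().any():
        raise ValueError("data must have one row per species")

    if A is not None:
        if set(data["species"]) != set(A.taxa):
            extra = sorted(set(data["species"]) - set(A.taxa))
            miss = sorted(set(A.taxa) - set(data["species"]))
            raise ValueError(
                f"species mismatch with correlation matrix (not in A: {extra}; "
                f"missing from data: {miss})"
            )
        data = data.set_index("species").loc[list(A.taxa)].reset_index()

    y = data[spec.response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    X, fixed_names = _design_matrix(data, spec)
    n, p = X.shape

    if spec.extra_random is not None:
        if spec.extra_random not in data.columns:
            raise ValueError(f"grouping column {spec.extra_random!r} not in data")
        codes, _ = pd.factorize(data[spec.extra_random])
        groups = codes.astype(np.intp)
        q = int(groups.max()) + 1
    else:
        groups, q = None, 0

    if A is not None:
        lam, Q = np.linalg.eigh(A.matrix)
        if lam.min() <= 0:
            lam = np.maximum(lam, 1e-10)
    else:
        lam = Q = None

    XtX = X.T @ X
    V0 = priors.fixed_variance
    alpha0 = priors.vc_shape_alpha
    beta0 = priors.vc_scale_beta
    n_keep = settings.retained_per_chain

    param_names = list(fixed_names)
    variance_names = []
    if A is not None:
        variance_names.append("sigma2_a")
    if groups is not None:
        variance_names.append("sigma2_u")
    variance_names.append("sigma2_e")
    store = {
        name: np.empty((settings.n_chains, n_keep))
        for name in param_names + variance_names
    }
    chain_seeds = tuple(settings.seed + c for c in range(settings.n_chains))

    vy = float(np.var(y)) or 1.0
    for c, cseed in enumerate(chain_seeds):
        rng = np.random.default_rng(cseed)
        beta = np.zeros(p)
        a = np.zeros(n)
        at = np.zeros(n)
        u = np.zeros(q) if q else None
        zu = np.zeros(n)
        s2a = vy / 2 if A is not None else 0.0
        s2u = vy / 2 if q else 0.0
        s2e = vy / 2

        keep = 0
        for it in range(1, settings.n_iter + 1):
            # fixed effects: Gaussian full conditional under N(0, V0) prior
            r = y - a - zu
            prec = XtX / s2e + np.eye(p) / V0
            rhs = X.T @ r / s2e + priors.fixed_mean / V0
            L = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, rhs)
            beta = mean + np.linalg.solve(L.T, rng.standard_normal(p))
            xb = X @ beta

            # phylogenetic effect, sampled in the eigenbasis of A where the
            # full-conditional precision is diagonal
            if A is not None:
                r = y - xb - zu
                rt = Q.T @ r
                d = 1.0 / s2e + 1.0 / (s2a * lam)
                at = rt / s2e / d + rng.standard_normal(n) / np.sqrt(d)
                a = Q @ at
                quad_a = float(np.sum(at * at / lam))
                s2a = _rinvgamma(rng, alpha0 + n / 2, beta0 + quad_a / 2)

            # grouping effect (i.i.d. levels)
            if q:
                r = y - xb - a
                sums = np.bincount(groups, weights=r, minlength=q)
                counts = np.bincount(groups, minlength=q)
                dprec = counts / s2e + 1.0 / s2u
                u = sums / s2e / dprec + rng.standard_normal(q) / np.sqrt(dprec)
                zu = u[groups]
                s2u = _rinvgamma(rng, alpha0 + q / 2, beta0 + float(u @ u) / 2)

            resid = y - xb - a - zu
            s2e = _rinvgamma(rng, alpha0 + n / 2, beta0 + float(resid @ resid) / 2)

            if it > settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
                for j, name in enumerate(fixed_names):
                    store[name][c, keep] = beta[j]
                if A is not None:
                    store["sigma2_a"][c, keep] = s2a
                if q:
                    store["sigma2_u"][c, keep] = s2u
                store["sigma2_e"][c, keep] = s2e
                keep += 1

    return PGLMMChains(
        params=store,
        fixed_names=tuple(fixed_names),
        variance_names=tuple(variance_names),
        settings=settings,
        chain_seeds=chain_seeds,
    )


def _rinvgamma(rng: np.random.Generator, shape: float, scale: float) -> float:
    """One draw from IG(shape, scale) with density ∝ x^(−shape−1) e^(−scale/x)."""
    return scale / rng.gamma(shape, 1.0)


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def hpd_interval(samples: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing at least ``prob`` of the samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need >= 2 samples for an HPD interval")
    k = int(math.ceil(prob * n))
    k = min(max(k, 2), n)
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def p_mcmc(samples: np.ndarray) -> float:
    """MCMC sign probability: 2x the smaller tail, floored at 2/N.

    Zero-valued samples are split evenly between tails.  Invariant under
    positive rescaling of the chain.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    pos = float(np.sum(x > 0)) + 0.5 * np.sum(x == 0)
    neg = n - pos
    return float(max(2.0 * min(pos, neg) / n, 2.0 / n))


def summarize(
    chains: PGLMMChains, param: str, *, interval: str = "hpd"
) -> PosteriorSummary:
    """Posterior mean, 95% interval, pMCMC (fixed effects), ESS and PSRF."""
    arr = chains.params.get(param)
    if arr is None:
        raise KeyError(f"unknown parameter {param!r}; have {sorted(chains.params)}")
    pooled = arr.ravel()
    if interval == "hpd":
        lo, hi = hpd_interval(pooled)
    elif interval == "quantile":
        lo, hi = (float(q) for q in np.quantile(pooled, [0.025, 0.975]))
    else:
        raise ValueError("interval must be 'hpd' or 'quantile'")
    is_fixed = param in chains.fixed_names
    try:
        total_ess = float(sum(ess(arr[c]) for c in range(arr.shape[0])))
    except ValueError:  # chain too short or constant
        total_ess = float("nan")
    psrf = gelman_rubin(chains, param) if arr.shape[0] >= 2 else None
    return PosteriorSummary(
        parameter=param,
        posterior_mean=float(pooled.mean()),
        hpd95_lower=lo,
        hpd95_upper=hi,
        p_mcmc=p_mcmc(pooled) if is_fixed else None,
        ess=total_ess,
        psrf=psrf,
    )


def heritability(chains: PGLMMChains) -> tuple[np.ndarray, PosteriorSummary]:
    """Per-sample phylogenetic heritability H^2 = s2_a / (s2_a + s2_e).

    Any grouping variance (``sigma2_u``) is excluded from the denominator.
    Returns the (n_chains, n_retained) array of per-sample ratios and its
    posterior summary.
    """
    if "sigma2_a" not in chains.params:
        raise KeyError("model has no phylogenetic variance component")
    s2a = chains.params["sigma2_a"]
    s2e = chains.params["sigma2_e"]
    h2 = s2a / (s2a + s2e)
    aug = replace_params(chains, h2)
    return h2, summarize(aug, "h2")


def replace_params(chains: PGLMMChains, h2: np.ndarray) -> PGLMMChains:
    params = dict(chains.params)
    params["h2"] = h2
    return PGLMMChains(
        params=params,
        fixed_names=chains.fixed_names,
        variance_names=chains.variance_names,
        settings=chains.settings,
        chain_seeds=chains.chain_seeds,
    )


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def gelman_rubin(chains: PGLMMChains | np.ndarray, param: str | None = None) -> float:
    """Classic potential scale reduction factor.

    PSRF = sqrt( ((n-1)/n * W + B/n) / W ) with W the mean within-chain
    variance and B = n * variance of the chain means.  Values near 1 indicate
    the chains are indistinguishable.
    """
    if isinstance(chains, PGLMMChains):
        if param is None:
            raise ValueError("param required when passing PGLMMChains")
        arr = chains.params[param]
    else:
        arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("Gelman-Rubin needs >= 2 chains of equal length")
    m, n = arr.shape
    if n < 10:
        raise ValueError("chains too short for a meaningful PSRF")
    W = float(np.mean(np.var(arr, axis=1, ddof=1)))
    B = n * float(np.var(np.mean(arr, axis=1), ddof=1))
    if W == 0:
        raise ValueError("zero within-chain variance")
    return float(np.sqrt(((n - 1) / n * W + B / n) / W))


def _autocorrelations(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    if np.all(xc == 0):
        raise ValueError("constant chain: autocorrelation undefined")
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n] / n
    return acov / acov[0]


def ess(chain: np.ndarray) -> float:
    """Effective sample size: n / (1 + 2 * sum of autocorrelations).

    The sum is truncated by Geyer's initial-positive-sequence rule: lagged
    autocorrelations are added in consecutive pairs while each pair sum stays
    positive.
    """
    x = np.asarray(chain, dtype=float).ravel()
    n = x.size
    if n < 10:
        raise ValueError("chain too short for an ESS estimate")
    rho = _autocorrelations(x)
    tau = 1.0
    m = 1
    while m + 1 < n:
        pair = rho[m] + rho[m + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
        m += 2
    return float(n / tau)


def lag1_autocorr(chain: np.ndarray) -> float:
    """Sample autocorrelation at lag 1."""
    x = np.asarray(chain, dtype=float).ravel()
    if x.size < 10:
        raise ValueError("chain too short")
    return float(_autocorrelations(x)[1])


@dataclass(frozen=True)
class HeidelbergerResult:
    passed: bool
    p_value: float
    start_fraction: float  # fraction of the chain discarded before the test passed


def _spectrum0_ar(x: np.ndarray) -> float:
    """Spectral density at frequency zero via an AIC-selected AR fit."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    v0 = float(np.dot(xc, xc)) / n
    if v0 == 0:
        raise ValueError("constant series")
    max_order = min(int(10 * np.log10(n)), n - 2)
    acov = np.fft.irfft(
        np.abs(np.fft.rfft(xc, int(2 ** np.ceil(np.log2(2 * n))))) ** 2,
        int(2 ** np.ceil(np.log2(2 * n))),
    )[: max_order + 1] / n
    best = (n * math.log(v0), 0.0, v0)  # (aic, sum of AR coefs, innovation var)
    for p in range(1, max_order + 1):
        R = np.array([[acov[abs(i - j)] for j in range(p)] for i in range(p)])
        r = acov[1 : p + 1]
        try:
            phi = np.linalg.solve(R, r)
        except LinAlgError:
            continue
        s2 = float(acov[0] - phi @ r)
        if s2 <= 0:
            continue
        aic = n * math.log(s2) + 2 * p
        if aic < best[0]:
            best = (aic, float(phi.sum()), s2)
    _, phisum, s2 = best
    denom = (1.0 - phisum) ** 2
    if denom <= 1e-12:
        denom = 1e-12
    return s2 / denom


def _pcramer(q: float, eps: float = 1e-5) -> float:
    """CDF of the asymptotic Cramer-von Mises distribution."""
    if q <= 0:
        return 0.0
    total = 0.0
    for k in range(4):
        z = (
            special.gamma(k + 0.5)
            * math.sqrt(4 * k + 1)
            / (special.gamma(k + 1.0) * math.pi**1.5 * math.sqrt(q))
        )
        uval = (4 * k + 1) ** 2 / (16 * q)
        if uval > -math.log(eps):
            continue
        total += z * math.exp(-uval) * special.kv(0.25, uval)
    return min(max(total, 0.0), 1.0)


def heidelberger_stationarity(chain: np.ndarray, alpha: float = 0.05) -> HeidelbergerResult:
    """Heidelberger-Welch stationarity test.

    The Cramer-von Mises statistic of the standardized cumulative-sum
    (Brownian bridge) process is computed, with long-run variance estimated as
    the spectral density at zero (AR fit) from the second half of the chain.
    Starting from the full chain, the leading 10% is discarded repeatedly (up
    to 50%) until the test passes or the chain is declared non-stationary.
    """
    x = np.asarray(chain, dtype=float).ravel()
    n = x.size
    if n < 50:
        raise ValueError("Heidelberger test needs a chain of length >= 50")
    s0 = _spectrum0_ar(x[n // 2 :])
    p_val = 0.0
    for frac in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
        start = int(frac * n)
        seg = x[start:]
        m = seg.size
        S = np.cumsum(seg)
        ybar = seg.mean()
        k = np.arange(1, m + 1)
        bridge = (S - k * ybar) / math.sqrt(m * s0)
        stat = float(np.mean(bridge**2))
        p_val = 1.0 - _pcramer(stat)
        if p_val > alpha:
            return HeidelbergerResult(passed=True, p_value=p_val, start_fraction=frac)
    return HeidelbergerResult(passed=False, p_value=p_val, start_fraction=0.5)
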