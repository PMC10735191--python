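"""Phylogenetic signal statistics on rooted trees with branch lengths.

Under Brownian motion, a continuous trait's tip values are jointly normal
with covariance sigma^2 * C, where C[i, j] is the branch length shared by
the root-to-tip paths of tips i and j. Everything here is built on that
matrix:

* :func:`bm_loglik` — GLS ancestral mean, Brownian rate, and exact
  log-likelihood.
* :func:`fit_lambda` — Pagel's lambda by maximum likelihood: off-diagonal
  entries of C are scaled by lambda in [0, lambda_max] (lambda_max is the
  largest value keeping C positive definite, at least 1), with a
  likelihood-ratio test against lambda = 0 whose null distribution is
  obtained by Monte-Carlo simulation (the null sits on the parameter
  boundary, where chi-squared references miscalibrate badly).
* :func:`blomberg_k` — the variance-ratio statistic scaled so Brownian
  motion gives an expectation of 1, with a one-sided permutation p-value
  (high K = strong signal; "+1" pseudo-count keeps p > 0).
* :func:`fritz_purvis_d` — phylogenetic dispersion of a binary trait:
  the observed sum of sister-clade differences is positioned between a
  random-shuffle null (D = 1) and a Brownian-threshold null (D = 0).
* :func:`phylo_pca` — PCA of the evolutionary (GLS-centered,
  phylogeny-corrected) trait covariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .core_io import Phylogeny

logger = logging.getLogger("mgc_ecoscreen")


class DegenerateTraitError(ValueError):
    """Raised for traits that carry no usable variation (constant vectors,
    single-state binary traits)."""


@dataclass
class PhyloCovariance:
    """Brownian expected covariance C with its tip-label ordering."""

    C: np.ndarray
    tip_labels: list[str]

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.shape != (len(self.tip_labels), len(self.tip_labels)):
            raise ValueError("C shape does not match tip labels")
        self.C = C


@dataclass
class BMFit:
    mu_hat: float
    sigma2_hat: float
    loglik: float


@dataclass
class LambdaResult:
    lambda_hat: float
    loglik: float
    loglik0: float
    p_value: float


@dataclass
class DResult:
    d_obs: float
    d_r_mean: float
    d_b_mean: float
    D: float
    p_random: float
    p_brownian: float


@dataclass
class PPCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    contributions: pd.DataFrame


def phylo_vcv(tree: Phylogeny) -> PhyloCovariance:
    """Shared-path covariance: C[i, j] = branch length common to the
    root-to-tip paths of tips i and j; C[i, i] = depth of tip i."""
    if np.any(tree.edge_length < 0):
        raise ValueError("negative branch length")
    n = tree.n_tips
    C = np.zeros((n, n))
    tips_below: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if not tree.children[node]:
            tips_below[node] = np.array([node])
        else:
            tips_below[node] = np.concatenate(
                [tips_below[c] for c in tree.children[node]]
            )
        if node != tree.root:
            idx = tips_below[node]
            C[np.ix_(idx, idx)] += tree.edge_length[node]
    return PhyloCovariance(C=C, tip_labels=list(tree.tip_labels))


def _as_matrix(C: PhyloCovariance | np.ndarray) -> np.ndarray:
    return C.C if isinstance(C, PhyloCovariance) else np.asarray(C, dtype=float)


def bm_loglik(x: np.ndarray, C: PhyloCovariance | np.ndarray) -> BMFit:
    """Brownian-motion fit by generalized least squares.

    mu_hat = (1'C^-1 1)^-1 1'C^-1 x, sigma2_hat = r'C^-1 r / n with
    r = x - mu_hat, and the log-likelihood is the multivariate normal
    density of x at mean mu_hat and covariance sigma2_hat * C.
    """
    x = np.asarray(x, dtype=float)
    Cm = _as_matrix(C)
    n = x.shape[0]
    if Cm.shape != (n, n):
        raise ValueError("trait vector and covariance dimensions differ")
    if np.ptp(x) == 0.0:
        raise DegenerateTraitError("constant trait: Brownian rate is 0")
    try:
        cho = linalg.cho_factor(Cm, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError(f"covariance matrix is singular: {exc}") from exc
    one = np.ones(n)
    Ci_x = linalg.cho_solve(cho, x)
    Ci_1 = linalg.cho_solve(cho, one)
    denom = one @ Ci_1
    mu = (one @ Ci_x) / denom
    r = x - mu
    sigma2 = r @ linalg.cho_solve(cho, r) / n
    if sigma2 <= 0:
        raise DegenerateTraitError("zero Brownian rate after GLS centering")
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return BMFit(mu_hat=float(mu), sigma2_hat=float(sigma2), loglik=float(loglik))


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Scale off-diagonal entries of C by lambda; diagonal untouched."""
    Cl = np.asarray(C, dtype=float) * lam
    np.fill_diagonal(Cl, np.diag(C))
    return Cl


def lambda_max(C: np.ndarray) -> float:
    """Largest lambda keeping C(lambda) positive definite, at least 1.

    For a tree covariance the binding constraint is the deepest internal
    node: lambda_max = max(diag) / max(off-diag) (shrunk if a Cholesky
    factorization still fails numerically).
    """
    C = np.asarray(C, dtype=float)
    off = C[~np.eye(C.shape[0], dtype=bool)]
    top = off.max(initial=0.0)
    if top <= 0:
        return 1.0
    lam = float(np.max(np.diag(C)) / top)
    while lam > 1.0:
        try:
            linalg.cho_factor(lambda_transform(C, lam))
            break
        except linalg.LinAlgError:
            lam *= 0.999
    return max(lam, 1.0)


def _profile_loglik_grid(C: np.ndarray, X: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Profile Brownian log-likelihood of every column of X at every lambda
    in ``grid``; one Cholesky per grid point serves all columns. Returns an
    array of shape (len(grid), n_columns)."""
    n, m = X.shape
    one = np.ones(n)
    out = np.full((grid.size, m), -np.inf)
    for gi, lam in enumerate(grid):
        try:
            cho = linalg.cho_factor(lambda_transform(C, lam), lower=True)
        except linalg.LinAlgError:
            continue
        Ci_1 = linalg.cho_solve(cho, one)
        mu = (Ci_1 @ X) / (one @ Ci_1)
        R = X - mu[None, :]
        CiR = linalg.cho_solve(cho, R)
        sigma2 = np.einsum("ij,ij->j", R, CiR) / n
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        with np.errstate(divide="ignore"):
            out[gi] = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return out


def _lambda_grid(lam_hi: float) -> np.ndarray:
    return np.unique(np.concatenate([
        np.linspace(0.0, min(1.0, lam_hi), 41),
        np.linspace(1.0, lam_hi, 9) if lam_hi > 1.0 else [],
    ]))


def fit_lambda(
    x: np.ndarray,
    tree: Phylogeny | PhyloCovariance | np.ndarray,
    tol: float = 1e-8,
    n_sim: int = 999,
    seed: int | np.random.Generator | None = None,
) -> LambdaResult:
    """Maximum-likelihood Pagel's lambda with a Monte-Carlo calibrated LRT.

    The profile log-likelihood is maximized over lambda in [0, lambda_max]
    by bounded scalar search; lambda_hat is not clipped to 1. The p-value
    compares the likelihood-ratio statistic against its null distribution
    under lambda = 0: because the null sits on the parameter boundary the
    chi-squared reference is badly miscalibrated, but under lambda = 0 the
    statistic is pivotal (invariant to the trait's location and scale), so
    ``n_sim`` white-noise simulations with tip variances diag(C) give an
    exact test up to Monte-Carlo error ("+1" pseudo-count keeps p > 0).
    Observed and simulated statistics are evaluated on one shared lambda
    grid for comparability. ``n_sim=0`` skips the test (p = NaN).
    """
    C = phylo_vcv(tree).C if isinstance(tree, Phylogeny) else _as_matrix(tree)
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 4:
        raise ValueError("lambda estimation requires at least 4 tips")
    if np.ptp(x) == 0.0:
        raise DegenerateTraitError("constant trait")
    lam_hi = lambda_max(C)

    def negll(lam: float) -> float:
        try:
            return -bm_loglik(x, lambda_transform(C, lam)).loglik
        except (ValueError, linalg.LinAlgError):
            return np.inf

    result = optimize.minimize_scalar(
        negll, bounds=(0.0, lam_hi), method="bounded",
        options={"xatol": tol},
    )
    if not result.success:
        raise RuntimeError(f"lambda optimizer failed: {result.message}")
    # bounded search can stop a hair inside the interval; compare endpoints
    candidates = [(float(result.x), float(result.fun))]
    for lam in (0.0, 1.0, lam_hi):
        candidates.append((lam, negll(lam)))
    lam_hat, nll = min(candidates, key=lambda t: t[1])
    loglik = -nll
    loglik0 = -negll(0.0)

    if n_sim <= 0:
        p = float("nan")
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        grid = _lambda_grid(lam_hi)
        scale = np.sqrt(np.diag(C))
        obs_ll = _profile_loglik_grid(C, x[:, None], grid)
        lrt_obs = 2.0 * (obs_ll[:, 0].max() - obs_ll[0, 0])
        Z = scale[:, None] * rng.standard_normal((n, n_sim))
        sim_ll = _profile_loglik_grid(C, Z, grid)
        lrt_sim = 2.0 * (sim_ll.max(axis=0) - sim_ll[0])
        p = (1 + int(np.sum(lrt_sim >= lrt_obs))) / (n_sim + 1)
    return LambdaResult(
        lambda_hat=lam_hat, loglik=loglik, loglik0=loglik0, p_value=float(p)
    )


def _k_statistics(
    X: np.ndarray, cho, Ci_1: np.ndarray, expected_ratio: float
) -> np.ndarray:
    """Blomberg's K for each column of X (n x m), sharing one factorization."""
    n = X.shape[0]
    one = np.ones(n)
    mu = (Ci_1 @ X) / (one @ Ci_1)
    R = X - mu[None, :]
    mse0 = np.einsum("ij,ij->j", R, R) / (n - 1)
    CiR = linalg.cho_solve(cho, R)
    mse = np.einsum("ij,ij->j", R, CiR) / (n - 1)
    return (mse0 / mse) / expected_ratio


def blomberg_k(
    x: np.ndarray,
    tree: Phylogeny | PhyloCovariance | np.ndarray,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Blomberg's K with a one-sided permutation p-value.

    K = (MSE0 / MSE) / E[MSE0 / MSE], where MSE0 is the ordinary variance of
    the GLS-centered trait, MSE its phylogenetically corrected counterpart,
    and E[MSE0/MSE] = (trace(C) - n / (1'C^-1 1)) / (n - 1) the Brownian
    expectation, so K = 1 under Brownian motion. The p-value is
    (1 + #{K_perm >= K_obs}) / (n_perm + 1) over random reassignments of
    trait values to tips. K is invariant to affine rescaling of x.
    """
    C = phylo_vcv(tree).C if isinstance(tree, Phylogeny) else _as_matrix(tree)
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("Blomberg's K requires at least 3 tips")
    if np.ptp(x) == 0.0:
        raise DegenerateTraitError("constant trait")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cho = linalg.cho_factor(C, lower=True)
    one = np.ones(n)
    Ci_1 = linalg.cho_solve(cho, one)
    expected_ratio = (np.trace(C) - n / (one @ Ci_1)) / (n - 1)
    k_obs = float(_k_statistics(x[:, None], cho, Ci_1, expected_ratio)[0])
    if n_perm <= 0:
        return k_obs, float("nan")
    perms = np.empty((n, n_perm))
    for j in range(n_perm):
        perms[:, j] = rng.permutation(x)
    k_perm = _k_statistics(perms, cho, Ci_1, expected_ratio)
    p = (1 + int(np.sum(k_perm >= k_obs))) / (n_perm + 1)
    return k_obs, float(p)


# ---------------------------------------------------------------------------
# Fritz & Purvis' D
# ---------------------------------------------------------------------------

def _binary_structure(tree: Phylogeny):
    """(left, right, internal_postorder, n_nodes) for the binary-resolved tree."""
    bt = tree.resolve_polytomies()
    post = bt.postorder()
    internal = [nd for nd in post if bt.children[nd]]
    left = np.array([bt.children[nd][0] for nd in internal])
    right = np.array([bt.children[nd][1] for nd in internal])
    order = np.array(internal)
    return left, right, order, bt.n_nodes


def sister_diff_sums(tree: Phylogeny, X: np.ndarray) -> np.ndarray:
    """Sum over internal nodes of |difference between daughter values|, for
    each column of X; nodal values are unweighted means of the two daughters
    (branch lengths are not used). Polytomies are resolved to zero-length
    binary splits by child order before the sweep."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != tree.n_tips:
        X = X.T
    left, right, order, n_nodes = _binary_structure(tree)
    vals = np.zeros((n_nodes, X.shape[1]))
    vals[: tree.n_tips] = X
    total = np.zeros(X.shape[1])
    for nd, l, r in zip(order, left, right):
        diff = vals[l] - vals[r]
        total += np.abs(diff)
        vals[nd] = 0.5 * (vals[l] + vals[r])
    return total


def fritz_purvis_d(
    x: np.ndarray,
    tree: Phylogeny,
    n_sim: int = 1000,
    seed: int | np.random.Generator | None = None,
    C: np.ndarray | None = None,
) -> DResult:
    """Fritz & Purvis' D for a binary trait.

    d_obs is the observed sum of sister-clade differences. The random null
    shuffles tip states (prevalence fixed); the Brownian null simulates
    Brownian traits on the tree and assigns 1 to the tips above the quantile
    matching the observed prevalence. D = (d_obs - mean d_b) /
    (mean d_r - mean d_b): 1 for random traits, 0 for Brownian-threshold
    traits. p_random is the fraction of shuffle sums <= d_obs (clumping);
    p_brownian the fraction of Brownian sums >= d_obs (overdispersion).
    """
    x = np.asarray(x, dtype=float)
    n = tree.n_tips
    if x.shape != (n,):
        raise ValueError("trait vector length must equal tip count")
    if not set(np.unique(x)) <= {0.0, 1.0}:
        raise ValueError("trait must be binary 0/1")
    k = int(x.sum())
    if k == 0 or k == n:
        raise DegenerateTraitError("invariant trait: both states required")
    if n < 4:
        raise ValueError("D requires at least 4 tips")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    d_obs = float(sister_diff_sums(tree, x[:, None])[0])

    perms = np.empty((n, n_sim))
    for j in range(n_sim):
        perms[:, j] = rng.permutation(x)
    d_r = sister_diff_sums(tree, perms)

    Cm = phylo_vcv(tree).C if C is None else np.asarray(C, dtype=float)
    L = linalg.cholesky(Cm, lower=True)
    sims = L @ rng.standard_normal((n, n_sim))
    # threshold at the quantile matching observed prevalence: the k largest
    # tip values get state 1
    cut = np.partition(sims, n - k, axis=0)[n - k]
    binary = (sims >= cut[None, :]).astype(float)
    d_b = sister_diff_sums(tree, binary)

    d_r_mean = float(d_r.mean())
    d_b_mean = float(d_b.mean())
    if d_r_mean == d_b_mean:
        raise ValueError("degenerate nulls: identical mean sister-difference sums")
    D = (d_obs - d_b_mean) / (d_r_mean - d_b_mean)
    return DResult(
        d_obs=d_obs,
        d_r_mean=d_r_mean,
        d_b_mean=d_b_mean,
        D=float(D),
        p_random=float(np.mean(d_r <= d_obs)),
        p_brownian=float(np.mean(d_b >= d_obs)),
    )


def phylo_pca(X: pd.DataFrame, tree: Phylogeny) -> PPCAResult:
    """Phylogenetic PCA: eigen-decomposition of the evolutionary covariance.

    The GLS root state a = (1'C^-1 1)^-1 1'C^-1 X centers each trait; the
    evolutionary covariance R = (X - 1a)' C^-1 (X - 1a) / (n - 1) removes
    the expected phylogenetic covariance before the cross-trait covariance
    is estimated. Scores are the centered data projected on the
    eigenvectors; eigenvalues are sorted descending (rank-deficient R simply
    yields trailing zero eigenvalues). Contributions give each trait's
    squared-loading share of every component.
    """
    if list(X.index) != list(tree.tip_labels):
        X = X.loc[tree.tip_labels]
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    C = phylo_vcv(tree).C
    cho = linalg.cho_factor(C, lower=True)
    one = np.ones(n)
    Ci_1 = linalg.cho_solve(cho, one)
    a = (Ci_1 @ Xv) / (one @ Ci_1)
    Z = Xv - a[None, :]
    R = Z.T @ linalg.cho_solve(cho, Z) / (n - 1)
    eigenvalues, vectors = np.linalg.eigh(R)
    idx = np.argsort(eigenvalues)[::-1]
    eigenvalues = np.clip(eigenvalues[idx], 0.0, None)
    vectors = vectors[:, idx]
    # deterministic sign: largest-magnitude loading of each component positive
    for j in range(vectors.shape[1]):
        lead = np.argmax(np.abs(vectors[:, j]))
        if vectors[lead, j] < 0:
            vectors[:, j] = -vectors[:, j]
    comp_names = [f"PC{i + 1}" for i in range(p)]
    scores = pd.DataFrame(Z @ vectors, index=X.index, columns=comp_names)
    loadings = pd.DataFrame(vectors, index=X.columns, columns=comp_names)
    contributions = loadings**2
    contributions = contributions / contributions.sum(axis=0)
    return PPCAResult(
        scores=scores,
        loadings=loadings,
        eigenvalues=eigenvalues,
        contributions=contributions,
    )


def compute_signal(
    traits: pd.DataFrame,
    tree: Phylogeny,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Blomberg's K and Pagel's lambda for every trait column.

    Returns a DataFrame indexed by trait with columns K, p_K, lambda_hat,
    p_lambda. Degenerate (constant) traits are skipped with a warning.
    """
    traits = traits.loc[tree.tip_labels]
    C = phylo_vcv(tree)
    rng = np.random.default_rng(seed)
    rows = {}
    for trait in traits.columns:
        x = traits[trait].to_numpy(dtype=float)
        try:
            k, p_k = blomberg_k(x, C, n_perm=n_perm, seed=rng)
            lam = fit_lambda(x, C, n_sim=n_perm, seed=rng)
        except DegenerateTraitError as exc:
            logger.warning("trait %s skipped: %s", trait, exc)
            continue
        rows[trait] = (k, p_k, lam.lambda_hat, lam.p_value)
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["K", "p_K", "lambda_hat", "p_lambda"]
    )
    out.index.name = "trait_id"
    return out
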