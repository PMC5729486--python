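"""Phylogenetic comparative statistics on species x parameter matrices.

Implements the comparative toolkit applied to the network parameters:
phylogenetic signal (Blomberg's K and its multivariate extension Kmult,
Abouheif's Cmean), maximum-likelihood comparison of Brownian-motion (BM),
single-optimum Ornstein-Uhlenbeck (OU) and Early-burst (EB) models by AIC
weights, phylogenetic generalized least squares (PGLS), the distance-based
multivariate variant (D-PGLS) with residual-randomization permutation
inference, and the phylomorphospace projection (PCA of standardized traits
with ancestral states mapped into PC space).

All permutation p-values use the (count + 1) / (n_perm + 1) estimator, so
p is never exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .trees import PhyloTree

__all__ = [
    "SignalResult",
    "ModelFit",
    "PGLSResult",
    "DPGLSResult",
    "PhylomorphospaceResult",
    "blomberg_k",
    "kmult",
    "abouheif_cmean",
    "fit_evo_models",
    "pgls",
    "dpgls",
    "phylomorphospace",
    "ancestral_states",
]


@dataclass(frozen=True)
class SignalResult:
    statistic_name: str
    statistic: float
    p_value: float
    n_perm: int

    def stars(self) -> str:
        if self.p_value < 0.001:
            return "***"
        if self.p_value < 0.01:
            return "**"
        return ""


@dataclass
class ModelFit:
    model: str
    log_likelihood: float
    n_params: int
    aic: float
    params: dict = field(default_factory=dict)
    aic_weight: float | None = None
    converged: bool = True


@dataclass
class PGLSResult:
    coefficients: pd.Series
    F: float
    p_value: float
    r_squared: float
    df_num: int
    df_den: int


@dataclass
class DPGLSResult:
    F: float
    p_value: float
    n_perm: int
    df_num: int
    df_den: int


@dataclass
class PhylomorphospaceResult:
    scores: pd.DataFrame  # species x PC
    percent_variance: np.ndarray
    loadings: pd.DataFrame  # trait x PC
    node_scores: np.ndarray  # internal nodes x PC (root first, preorder)


# ---------------------------------------------------------------------------
# helpers


def _align_tree(tree: PhyloTree, index) -> tuple[list, np.ndarray]:
    species = list(index)
    report = tree.check_tips(species)
    if report["missing_in_tree"]:
        raise ValueError(
            f"species missing from tree: {report['missing_in_tree']}"
        )
    C = tree.vcv(order=species)
    return species, C


def _gls_root(Cinv: np.ndarray, Y: np.ndarray) -> np.ndarray:
    ones = np.ones(len(Cinv))
    w = Cinv @ ones
    return (w @ Y) / (ones @ w)


def _perm_pvalue(null: np.ndarray, observed: float) -> float:
    return (np.count_nonzero(null >= observed) + 1) / (len(null) + 1)


# ---------------------------------------------------------------------------
# phylogenetic signal


def _k_stat(y: np.ndarray, Cinv: np.ndarray, expected_ratio: float) -> float:
    a = _gls_root(Cinv, y)
    r = y - a
    mse0 = r @ r
    mse = r @ Cinv @ r
    return (mse0 / mse) / expected_ratio


def _expected_ratio(C: np.ndarray, Cinv: np.ndarray) -> float:
    n = len(C)
    return (np.trace(C) - n / Cinv.sum()) / (n - 1)


def blomberg_k(
    tree: PhyloTree, trait: pd.Series, n_perm: int = 999, seed: int = 0
) -> SignalResult:
    """Blomberg's K with a tip-shuffling randomization test.

    K is the ratio of the observed MSE0/MSE (mean squared error from the
    phylogenetic mean over the raw vs phylogenetically corrected scale) to
    its expectation under Brownian motion on the given tree; K = 1 is the
    BM expectation, K > 1 stronger-than-BM signal.
    """
    trait = trait.dropna()
    _, C = _align_tree(tree, trait.index)
    y = trait.to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        raise ValueError("trait has zero variance")
    Cinv = np.linalg.inv(C)
    exp_ratio = _expected_ratio(C, Cinv)
    k_obs = _k_stat(y, Cinv, exp_ratio)
    rng = np.random.default_rng(seed)
    null = np.array(
        [_k_stat(rng.permutation(y), Cinv, exp_ratio) for _ in range(n_perm)]
    )
    return SignalResult("Blomberg's K", float(k_obs), _perm_pvalue(null, k_obs),
                        n_perm)


def _kmult_stat(Y: np.ndarray, Cinv: np.ndarray, expected_ratio: float) -> float:
    a = _gls_root(Cinv, Y)
    R = Y - a
    mse0 = float(np.einsum("ij,ij->", R, R))
    mse = float(np.einsum("ij,ij->", R, Cinv @ R))
    return (mse0 / mse) / expected_ratio


def kmult(
    tree: PhyloTree,
    traits: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    standardize: bool = False,
) -> SignalResult:
    """Multivariate phylogenetic signal Kmult (Adams' generalization of K).

    Reduces exactly to Blomberg's K for a single trait.  ``standardize``
    z-scores the trait columns first (useful when traits live on very
    different scales).  Permutation p from shuffling tip rows.
    """
    traits = traits.dropna()
    _, C = _align_tree(tree, traits.index)
    Y = traits.to_numpy(dtype=float)
    if standardize:
        Y = (Y - Y.mean(axis=0)) / Y.std(axis=0, ddof=1)
    if np.linalg.matrix_rank(Y - Y.mean(axis=0)) < Y.shape[1]:
        warnings.warn("trait block is rank deficient", stacklevel=2)
    Cinv = np.linalg.inv(C)
    exp_ratio = _expected_ratio(C, Cinv)
    k_obs = _kmult_stat(Y, Cinv, exp_ratio)
    rng = np.random.default_rng(seed)
    null = np.array(
        [
            _kmult_stat(Y[rng.permutation(len(Y))], Cinv, exp_ratio)
            for _ in range(n_perm)
        ]
    )
    return SignalResult("Kmult", float(k_obs), _perm_pvalue(null, k_obs), n_perm)


def abouheif_cmean(
    tree: PhyloTree, trait: pd.Series, n_perm: int = 999, seed: int = 0
) -> SignalResult:
    """Abouheif's Cmean: Moran autocorrelation with the tree proximity matrix.

    The proximity of two tips is the product of 1/(number of direct
    descendants) over the internal nodes joining them; the statistic is the
    Moran index of the trait under these weights, tested one-sided
    (positive autocorrelation) by tip permutation.
    """
    trait = trait.dropna()
    species, _ = _align_tree(tree, trait.index)
    A = tree.abouheif_proximity(order=species)
    off = A[~np.eye(len(A), dtype=bool)]
    if np.allclose(off, off[0]):
        warnings.warn(
            "star-like tree: all proximities equal, Cmean is degenerate",
            stacklevel=2,
        )
    y = trait.to_numpy(dtype=float)
    s0 = A.sum()
    n = len(y)

    def cmean(v: np.ndarray) -> float:
        z = v - v.mean()
        return float(n * (z @ A @ z) / (s0 * (z @ z)))

    obs = cmean(y)
    rng = np.random.default_rng(seed)
    null = np.array([cmean(rng.permutation(y)) for _ in range(n_perm)])
    return SignalResult("Abouheif's Cmean", obs, _perm_pvalue(null, obs), n_perm)


# ---------------------------------------------------------------------------
# evolutionary model comparison


def _mvn_phylo_loglik(Y: np.ndarray, V: np.ndarray) -> tuple[float, dict]:
    """Profile log-likelihood of a BM-type model with tree covariance V.

    The trait covariance (rate) matrix and the root state are profiled out
    analytically: R = (Y-1a')' V^-1 (Y-1a') / n at the GLS root a.
    """
    n, p = Y.shape
    sign, logdet_v = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf, {}
    Vinv = np.linalg.inv(V)
    a = _gls_root(Vinv, Y)
    R0 = Y - a
    Rmat = R0.T @ Vinv @ R0 / n
    sign_r, logdet_r = np.linalg.slogdet(np.atleast_2d(Rmat))
    if sign_r <= 0:
        return -np.inf, {}
    ll = (
        -0.5 * n * p * np.log(2 * np.pi)
        - 0.5 * n * logdet_r
        - 0.5 * p * logdet_v
        - 0.5 * n * p
    )
    return float(ll), {"root": a, "rate_matrix": np.atleast_2d(Rmat)}


def _ou_corr(C: np.ndarray, T: float, alpha: float) -> np.ndarray:
    # fixed-root OU on an ultrametric tree; alpha -> 0 recovers C
    return np.exp(-2 * alpha * (T - C)) * (-np.expm1(-2 * alpha * C)) / (
        2 * alpha
    )


def _eb_transform(C: np.ndarray, r: float) -> np.ndarray:
    return np.expm1(r * C) / r


def _profile_fit(Y, C, T, transform, bounds, n_grid: int = 10):
    def neg_ll(x):
        return -_mvn_phylo_loglik(Y, transform(C, x))[0]

    grid = np.linspace(bounds[0], bounds[1], n_grid)
    best_x, best_f = None, np.inf
    for g in grid:
        f = neg_ll(g)
        if f < best_f:
            best_x, best_f = g, f
    lo = max(bounds[0], best_x - (bounds[1] - bounds[0]) / n_grid)
    hi = min(bounds[1], best_x + (bounds[1] - bounds[0]) / n_grid)
    res = minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded")
    if res.success and res.fun < best_f:
        return float(res.x), float(-res.fun), True
    return float(best_x), float(-best_f), bool(res.success)


def fit_evo_models(
    tree: PhyloTree,
    traits: pd.DataFrame | pd.Series,
    models: tuple[str, ...] = ("BM", "OU", "EB"),
) -> list[ModelFit]:
    """ML fits of BM, single-optimum OU and Early-burst models with AIC weights.

    Multivariate likelihood uses a common tree transformation per model and
    a full (profiled-out) trait covariance matrix.  OU assumes an
    ultrametric tree (checked).  EB's rate-decay parameter r <= 0; the
    r -> 0 limit recovers BM.
    """
    if isinstance(traits, pd.Series):
        traits = traits.to_frame()
    traits = traits.dropna()
    _, C = _align_tree(tree, traits.index)
    Y = traits.to_numpy(dtype=float)
    n, p = Y.shape
    T = float(np.max(np.diag(C)))
    base_k = p + p * (p + 1) // 2  # root states + rate matrix
    fits: list[ModelFit] = []
    for model in models:
        if model == "BM":
            ll, pars = _mvn_phylo_loglik(Y, C)
            fits.append(ModelFit("BM", ll, base_k, 2 * base_k - 2 * ll, pars))
        elif model == "OU":
            if not tree.is_ultrametric(rtol=1e-3):
                warnings.warn(
                    "OU closed form assumes an ultrametric tree", stacklevel=2
                )
            x, ll, ok = _profile_fit(
                Y, C, T, lambda c, a: _ou_corr(c, T, a), (1e-8, 50.0 / T)
            )
            _, pars = _mvn_phylo_loglik(Y, _ou_corr(C, T, x))
            pars["alpha"] = x
            k = base_k + 1
            fits.append(
                ModelFit("OU", ll, k, 2 * k - 2 * ll, pars, converged=ok)
            )
        elif model == "EB":
            r_min = np.log(1e-5) / T
            x, ll, ok = _profile_fit(
                Y, C, T, lambda c, r: _eb_transform(c, r), (r_min, -1e-10)
            )
            _, pars = _mvn_phylo_loglik(Y, _eb_transform(C, x))
            pars["r"] = x
            k = base_k + 1
            fits.append(
                ModelFit("EB", ll, k, 2 * k - 2 * ll, pars, converged=ok)
            )
        else:
            raise ValueError(f"unknown model {model!r}")
    aics = np.array([f.aic for f in fits])
    finite = np.isfinite(aics)
    if not finite.any():  # degenerate block (e.g. more traits than species)
        weights = np.full(len(fits), 1.0 / len(fits))
    else:
        rel = np.where(finite, np.exp(-0.5 * (aics - aics[finite].min())), 0.0)
        weights = rel / rel.sum()
    for f, w in zip(fits, weights):
        f.aic_weight = float(w)
    return fits


# ---------------------------------------------------------------------------
# regressions


def pgls(
    tree: PhyloTree,
    response: pd.Series,
    predictor: pd.Series | pd.DataFrame,
    log_predictor: bool = False,
) -> PGLSResult:
    """Phylogenetic GLS regression under a BM correlation structure.

    F tests the predictor block against the intercept-only model.  On a
    star phylogeny with equal branch lengths this reduces exactly to OLS.
    """
    if isinstance(predictor, pd.Series):
        predictor = predictor.to_frame()
    data = pd.concat([response, predictor], axis=1).dropna()
    y = data.iloc[:, 0].to_numpy(dtype=float)
    X = data.iloc[:, 1:].to_numpy(dtype=float)
    if log_predictor:
        X = np.log(X)
    _, C = _align_tree(tree, data.index)
    n, q = X.shape
    L = np.linalg.cholesky(C)
    Xd = np.column_stack([np.ones(n), X])
    Xt = np.linalg.solve(L, Xd)
    yt = np.linalg.solve(L, y)
    beta, _, rank, _ = np.linalg.lstsq(Xt, yt, rcond=None)
    if rank < Xd.shape[1]:
        raise ValueError("singular design matrix")
    resid = yt - Xt @ beta
    rss = resid @ resid
    # intercept-only reference
    x0 = Xt[:, :1]
    b0 = np.linalg.lstsq(x0, yt, rcond=None)[0]
    rss0 = float(np.sum((yt - x0 @ b0) ** 2))
    df_num, df_den = q, n - q - 1
    F = ((rss0 - rss) / df_num) / (rss / df_den) if rss > 0 else np.inf
    p = float(stats.f.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0
    names = ["intercept"] + list(data.columns[1:])
    return PGLSResult(
        coefficients=pd.Series(beta, index=names),
        F=float(F),
        p_value=p,
        r_squared=float(1 - rss / rss0) if rss0 > 0 else 1.0,
        df_num=df_num,
        df_den=df_den,
    )


def dpgls(
    tree: PhyloTree,
    traits: pd.DataFrame,
    group: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> DPGLSResult:
    """Distance-based phylogenetic GLS test of a binary factor (RRPP).

    Traits and design are whitened with the inverse square root of the tree
    covariance; F comes from sums of squares of the transformed residuals,
    and the p-value from residual randomization of the reduced
    (intercept-only) model.  For one trait on a star tree this is the
    classical one-way ANOVA F.
    """
    data = traits.dropna()
    g = group.reindex(data.index)
    if g.isna().any():
        raise ValueError("group factor missing for some species")
    levels = sorted(pd.unique(g))
    if len(levels) < 2:
        raise ValueError("group factor has a single level")
    _, C = _align_tree(tree, data.index)
    Y = data.to_numpy(dtype=float)
    n = len(Y)
    x = pd.get_dummies(g, drop_first=True).to_numpy(dtype=float)
    w, U = np.linalg.eigh(C)
    P = U @ np.diag(w**-0.5) @ U.T
    Yt = P @ Y
    Xf = P @ np.column_stack([np.ones(n), x])
    X0 = P @ np.ones((n, 1))

    def hat(X):
        return X @ np.linalg.pinv(X)

    Hf, H0 = hat(Xf), hat(X0)
    q = x.shape[1]
    df_num, df_den = q, n - q - 1

    def f_stat(Ymat) -> float:
        rss_f = float(np.sum((Ymat - Hf @ Ymat) ** 2))
        rss_0 = float(np.sum((Ymat - H0 @ Ymat) ** 2))
        return ((rss_0 - rss_f) / df_num) / (rss_f / df_den)

    F_obs = f_stat(Yt)
    fitted0 = H0 @ Yt
    resid0 = Yt - fitted0
    rng = np.random.default_rng(seed)
    null = np.array(
        [
            f_stat(fitted0 + resid0[rng.permutation(n)])
            for _ in range(n_perm)
        ]
    )
    return DPGLSResult(
        F=float(F_obs),
        p_value=_perm_pvalue(null, F_obs),
        n_perm=n_perm,
        df_num=df_num,
        df_den=df_den,
    )


# ---------------------------------------------------------------------------
# phylomorphospace


def ancestral_states(tree: PhyloTree, traits: pd.DataFrame) -> np.ndarray:
    """Brownian-motion ancestral estimates at internal nodes (preorder).

    Best linear unbiased predictions given the GLS root: for internal node
    v, a_v = mu + C_vt C^-1 (y - mu), with C_vt the shared-time vector
    between v and the tips.
    """
    species = list(traits.index)
    C = tree.vcv(order=species)
    Y = traits.to_numpy(dtype=float)
    Cinv = np.linalg.inv(C)
    mu = _gls_root(Cinv, Y)
    idx = {s: i for i, s in enumerate(species)}

    dtree = tree.dendropy_tree
    internal = [nd for nd in dtree.preorder_node_iter() if not nd.is_leaf()]
    tipsets = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            tipsets[id(node)] = frozenset([node.taxon.label])
        else:
            tipsets[id(node)] = frozenset().union(
                *(tipsets[id(c)] for c in node.child_nodes())
            )
    rows = []
    for v in internal:
        cov = np.zeros(len(species))
        vtips = tipsets[id(v)]
        h_v = float(v.root_distance or 0.0)
        for s in species:
            if s in vtips:
                cov[idx[s]] = h_v
            else:
                u = v.parent_node
                while u is not None and s not in tipsets[id(u)]:
                    u = u.parent_node
                cov[idx[s]] = float(u.root_distance or 0.0) if u is not None else 0.0
        rows.append(mu + cov @ Cinv @ (Y - mu))
    return np.array(rows)


def phylomorphospace(
    tree: PhyloTree,
    traits: pd.DataFrame,
    standardize: bool = True,
) -> PhylomorphospaceResult:
    """PCA of the trait matrix with ancestral nodes projected into PC space.

    ``standardize=True`` (default) performs correlation-matrix PCA
    (columns z-scored), appropriate when traits differ in scale by orders
    of magnitude; ``False`` uses the covariance matrix on centered traits.
    """
    traits = traits.dropna()
    mean = traits.mean(axis=0)
    sd = traits.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant trait column(s): {bad}")
    Z = traits - mean
    if standardize:
        Z = Z / sd
    Zm = Z.to_numpy(dtype=float)
    _, s, Vt = np.linalg.svd(Zm, full_matrices=False)
    scores = Zm @ Vt.T
    var = s**2
    pct = 100.0 * var / var.sum()
    pcs = [f"PC{i + 1}" for i in range(len(s))]
    anc = ancestral_states(tree, traits)
    anc_z = anc - mean.to_numpy()
    if standardize:
        anc_z = anc_z / sd.to_numpy()
    return PhylomorphospaceResult(
        scores=pd.DataFrame(scores, index=traits.index, columns=pcs),
        percent_variance=pct,
        loadings=pd.DataFrame(Vt.T, index=traits.columns, columns=pcs),
        node_scores=anc_z @ Vt.T,
    )
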