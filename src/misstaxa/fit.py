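"""Maximum-likelihood fitting of BM, BMS, OU and OUM to tip traits.

All four models are Gaussian on the tips, so each fit is a generalized
least-squares problem.  Writing the covariance as sigma2 * V0(shape
parameters) and the mean as W @ theta, the scale sigma2 and the mean
coefficients profile out in closed form:

    theta_hat = (W' V0^-1 W)^-1 W' V0^-1 x
    sigma2_hat = r' V0^-1 r / n          (ML, divisor n)
    logL = -(n/2) (log 2*pi + log sigma2_hat + 1) - (1/2) log det V0

leaving at most a single shape parameter — alpha for OU/OUM, the rate ratio
sigma2_1/sigma2_0 for BMS — to optimize numerically on a log scale.

Covariance and mean structures (tips i, j with depths d_i, d_j and MRCA
depth t_a; the root value is pinned to the root-regime optimum for OU/OUM):

* BM:  V_ij = sigma2 * t_a;  mean = free constant (root mean).  k = 2.
* BMS: V_ij = sum_r sigma2_r * (time in regime r on the root->MRCA path);
  free root mean.  k = 3.
* OU:  V_ij = sigma2/(2 alpha) e^{-alpha (d_i + d_j - 2 t_a)}
  (1 - e^{-2 alpha t_a});  mean = theta.  k = 3.
* OUM: same covariance; mean_i = sum over root->tip regime segments of
  theta_r (e^{-alpha (d_i - t_end)} - e^{-alpha (d_i - t_start)}) plus
  e^{-alpha d_i} on the root-regime optimum.  k = 4.

Model comparison uses AICc = -2 logL + 2k + 2k(k+1)/(n-k-1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, stats

__all__ = [
    "FitResult",
    "MODEL_K",
    "MODEL_ORDER",
    "bm_covariance",
    "bms_covariance",
    "ou_covariance",
    "ou_weight_matrix",
    "gls_profile",
    "fit_model",
    "fit_all",
    "model_loglik",
    "aicc",
    "select_best",
    "lrt_bm_vs_ou",
]

MODEL_ORDER = ("BM", "BMS", "OU", "OUM")
MODEL_K = {"BM": 2, "BMS": 3, "OU": 3, "OUM": 4}

#: log-scale search box for alpha and for the BMS rate ratio
_SHAPE_BOUNDS = (1e-6, 1e3)
_N_GRID = 5
_RIDGE = 1e-10


@dataclass(frozen=True)
class FitResult:
    model: str
    params: dict
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool = True


# ------------------------------------------------------------- covariances


def bm_covariance(tree):
    """Unit-rate BM covariance: C_ij = MRCA depth of tips i, j."""
    return tree.mrca_depths()


def _regime_path_depths(tree, painting):
    """(C0, C1): time spent in each regime on the root->MRCA(i,j) path."""
    rdepth = np.zeros((tree.n_nodes, 2))
    for v in tree.postorder[::-1][1:]:
        p = tree.parent[v]
        rdepth[v] = rdepth[p]
        rdepth[v, painting.state[p]] += tree.blen[v]
    mrca = tree._mrca_nodes()
    return rdepth[mrca, 0], rdepth[mrca, 1]


def bms_covariance(tree, painting, sigma2_by_regime):
    """Multi-rate BM covariance from per-regime shared path lengths."""
    s0, s1 = sigma2_by_regime
    C0, C1 = _regime_path_depths(tree, painting)
    return s0 * C0 + s1 * C1


def ou_covariance(tree, alpha, depths=None, mrca=None):
    """Fixed-root OU covariance at sigma2 = 1.

    V0_ij = (1/(2 alpha)) e^{-alpha (d_i + d_j - 2 t_a)} (1 - e^{-2 alpha t_a}).
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    d = tree.tip_depths() if depths is None else depths
    Ta = tree.mrca_depths() if mrca is None else mrca
    return (np.exp(-alpha * (d[:, None] + d[None, :] - 2.0 * Ta))
            * (1.0 - np.exp(-2.0 * alpha * Ta)) / (2.0 * alpha))


def ou_weight_matrix(tree, painting, alpha, depths=None):
    """Tips-by-optima weight matrix W of the multi-optimum OU mean.

    Row i distributes E[X_i] over (theta_0, theta_1) by integrating the OU
    mean along the regime segments of the root-to-tip path; the residual
    root weight e^{-alpha d_i} goes to the root regime's column.  Rows sum
    to 1 by telescoping.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    depth = tree.node_depths() if depths is None else depths
    state = painting.state
    W = np.zeros((tree.n_tips, 2))
    root = tree.root
    for tip in range(tree.n_tips):
        di = depth[tip]
        v = tip
        while v != root:
            p = tree.parent[v]
            r = state[p]
            W[tip, r] += (math.exp(-alpha * (di - depth[v]))
                          - math.exp(-alpha * (di - depth[p])))
            v = p
        W[tip, state[root]] += math.exp(-alpha * di)
    return W


# ------------------------------------------------------------ GLS profiling


def _chol(V0):
    try:
        return linalg.cho_factor(V0, lower=True)
    except linalg.LinAlgError:
        warnings.warn(f"covariance factorization failed; adding ridge {_RIDGE}",
                      stacklevel=3)
        return linalg.cho_factor(V0 + _RIDGE * np.eye(len(V0)), lower=True)


def gls_profile(x, V0, W):
    """Profile the Gaussian likelihood over mean coefficients and scale.

    Returns (coefficients, sigma2_hat, logL).  ``V0`` is the unit-scale
    covariance, ``W`` the mean design matrix.
    """
    x = np.asarray(x, dtype=float)
    W = np.asarray(W, dtype=float)
    if W.ndim == 1:
        W = W[:, None]
    n = len(x)
    c = _chol(V0)
    Vix = linalg.cho_solve(c, x)
    ViW = linalg.cho_solve(c, W)
    A = W.T @ ViW
    try:
        beta = linalg.solve(A, W.T @ Vix, assume_a="pos")
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(f"rank-deficient design matrix: {exc}") from exc
    r = x - W @ beta
    sigma2 = float(r @ linalg.cho_solve(c, r)) / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    if sigma2 <= 0 or not np.isfinite(sigma2):
        # numerically zero residual variance (e.g. constant trait)
        sigma2 = max(sigma2, 1e-12)
    logL = -0.5 * n * (math.log(2.0 * math.pi) + math.log(sigma2) + 1.0) - 0.5 * logdet
    return beta, sigma2, logL


def _optimize_shape(neg_loglik, bounds=_SHAPE_BOUNDS, n_grid=_N_GRID):
    """Gridded multistart + bounded Brent on a log-scaled shape parameter.

    Returns (value, converged) where converged is False when the optimum
    sits at the search-box boundary.
    """
    lo, hi = math.log(bounds[0]), math.log(bounds[1])
    grid = np.linspace(lo, hi, n_grid)
    vals = [neg_loglik(g) for g in grid]
    i = int(np.argmin(vals))
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(neg_loglik, bounds=(a, b), method="bounded",
                                   options={"xatol": 1e-8})
    best_log, best_val = (res.x, res.fun) if res.fun <= vals[i] else (grid[i], vals[i])
    at_boundary = best_log <= lo + 1e-6 or best_log >= hi - 1e-6
    return math.exp(best_log), not at_boundary


# ------------------------------------------------------------------ fitting


class _FitContext:
    """Caches the tree geometry shared by all four model fits."""

    def __init__(self, tree, painting, trait):
        if tree.n_tips < 5:
            raise ValueError("fitting requires at least 5 tips")
        self.tree = tree
        self.painting = painting
        x = trait.reindex(tree.tip_labels).to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError("trait does not cover every tip")
        self.x = x
        self.n = tree.n_tips
        self.depth = tree.node_depths()
        self.d = self.depth[: self.n]
        self.Ta = tree.mrca_depths()
        self.ones = np.ones((self.n, 1))
        self._regime_paths = None

    def regime_paths(self):
        if self._regime_paths is None:
            if self.painting is None:
                raise ValueError("BMS/OUM fitting requires a regime painting")
            edge_parents = self.painting.state[self.tree.parent[
                np.delete(np.arange(self.tree.n_nodes), self.tree.root)]]
            if len(np.unique(edge_parents)) < 2:
                raise ValueError("BMS/OUM fitting requires both regimes among edges")
            self._regime_paths = _regime_path_depths(self.tree, self.painting)
        return self._regime_paths

    def ou_cov(self, alpha):
        return ou_covariance(self.tree, alpha, depths=self.d, mrca=self.Ta)

    # ---- per-model fits -------------------------------------------------
    def fit(self, model):
        if model == "BM":
            beta, s2, logL = gls_profile(self.x, self.Ta, self.ones)
            params = {"sigma2_0": s2, "root_mean": float(beta[0])}
            conv = s2 > 1e-12
        elif model == "BMS":
            C0, C1 = self.regime_paths()

            def neg(log_ratio):
                return -gls_profile(self.x, C0 + math.exp(log_ratio) * C1,
                                    self.ones)[2]

            ratio, conv = _optimize_shape(neg)
            beta, s2, logL = gls_profile(self.x, C0 + ratio * C1, self.ones)
            params = {"sigma2_0": s2, "sigma2_1": s2 * ratio,
                      "root_mean": float(beta[0])}
            conv = conv and s2 > 1e-12
        elif model == "OU":

            def neg(log_alpha):
                return -gls_profile(self.x, self.ou_cov(math.exp(log_alpha)),
                                    self.ones)[2]

            alpha, conv = _optimize_shape(neg)
            beta, s2, logL = gls_profile(self.x, self.ou_cov(alpha), self.ones)
            params = {"sigma2_0": s2, "theta_0": float(beta[0]), "alpha": alpha}
            conv = conv and s2 > 1e-12
        elif model == "OUM":
            self.regime_paths()  # validates both regimes present

            def design(alpha):
                return ou_weight_matrix(self.tree, self.painting, alpha,
                                        depths=self.depth)

            def neg(log_alpha):
                a = math.exp(log_alpha)
                return -gls_profile(self.x, self.ou_cov(a), design(a))[2]

            alpha, conv = _optimize_shape(neg)
            beta, s2, logL = gls_profile(self.x, self.ou_cov(alpha), design(alpha))
            params = {"sigma2_0": s2, "theta_0": float(beta[0]),
                      "theta_1": float(beta[1]), "alpha": alpha}
            conv = conv and s2 > 1e-12
        else:
            raise ValueError(f"unknown model {model!r}")
        k = MODEL_K[model]
        return FitResult(model=model, params=params, loglik=float(logL), k=k,
                         n=self.n, aicc=aicc(logL, k, self.n), converged=bool(conv))


def fit_model(tree, painting, trait, model):
    """ML fit of one model to the tip trait; see the module docstring."""
    return _FitContext(tree, painting, trait).fit(model)


def fit_all(tree, painting, trait, models=MODEL_ORDER):
    """Fit several models sharing one geometry cache; returns {name: FitResult}."""
    ctx = _FitContext(tree, painting, trait)
    return {m: ctx.fit(m) for m in models}


def model_loglik(tree, painting, trait, spec):
    """Log-likelihood of the data at fully specified parameter values.

    Builds the analytic mean vector and covariance for ``spec`` and evaluates
    the Gaussian log-density directly (no profiling).  Used to check
    simulator/fitter consistency.
    """
    x = trait.reindex(tree.tip_labels).to_numpy(dtype=float)
    n = tree.n_tips
    if spec.model == "BM":
        V = spec.sigma2_root * bm_covariance(tree)
        m = np.full(n, spec.resolved_root_value)
    elif spec.model == "BMS":
        V = bms_covariance(tree, painting, (spec.sigma2_root, spec.sigma2_derived))
        m = np.full(n, spec.resolved_root_value)
    elif spec.model == "OU":
        V = spec.sigma2_root * ou_covariance(tree, spec.alpha)
        d = tree.tip_depths()
        m = (spec.theta_root
             + (spec.resolved_root_value - spec.theta_root) * np.exp(-spec.alpha * d))
    else:  # OUM, root pinned at the root-regime optimum
        V = spec.sigma2_root * ou_covariance(tree, spec.alpha)
        W = ou_weight_matrix(tree, painting, spec.alpha)
        m = W @ np.array([spec.theta_root, spec.theta_derived])
    c = _chol(V)
    r = x - m
    quad = float(r @ linalg.cho_solve(c, r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    return -0.5 * (n * math.log(2.0 * math.pi) + logdet + quad)


# ------------------------------------------------------------- model choice


def aicc(logL, k, n):
    """Small-sample-corrected AIC: -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * logL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def select_best(results):
    """Lowest-AICc model and per-model delta AICc.

    Ties go to the model with fewer parameters, then to the fixed order
    BM, BMS, OU, OUM.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 fits to compare")
    order = {m: i for i, m in enumerate(MODEL_ORDER)}
    best = min(results, key=lambda r: (r.aicc, r.k, order.get(r.model, 99)))
    deltas = {r.model: r.aicc - best.aicc for r in results}
    return best.model, deltas


def lrt_bm_vs_ou(fit_bm, fit_ou, alpha_level=0.05):
    """Likelihood-ratio test of BM against single-optimum OU.

    Statistic 2 (logL_OU - logL_BM) against the chi-square(1) critical value
    (3.841 at the 0.05 level); returns "OU" or "BM".
    """
    if fit_bm.n != fit_ou.n:
        raise ValueError("fits are not on the same data (n differs)")
    lam = 2.0 * (fit_ou.loglik - fit_bm.loglik)
    crit = stats.chi2.ppf(1.0 - alpha_level, df=1)
    return "OU" if lam > crit else "BM"
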