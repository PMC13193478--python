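"""Multi-regime BM/OU models of environmental-niche evolution.

Nine nested Gaussian models of a continuous niche variable evolving along
the phylogeny under leaf-habit regimes (evergreen / deciduous):

=======  ======================================================
BM1      single-rate Brownian motion
BMV      Brownian motion, rate sigma^2 differs by regime
OU1      single-optimum Ornstein-Uhlenbeck
OUA      OU, selection strength alpha differs by regime
OUV      OU, rate sigma^2 differs by regime
OUM      OU, optimum theta differs by regime
OUVA     OU, sigma^2 and alpha differ
OUMV     OU, theta and sigma^2 differ
OUMVA    OU, theta, sigma^2 and alpha differ
=======  ======================================================

Regime histories come from stochastic character mapping under a fitted
ARD Mk model (the classical two-step approximation to joint
discrete+continuous inference): the same fixed set of maps is shared
across all nine models and all variables, and per-map Gaussian
log-densities are combined by log-mean-exp. Under piecewise-constant
(alpha, sigma^2, theta) the tip distribution is exactly Gaussian, with
moments propagated segment-by-segment along each branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from mimodiv.trees import Phylogeny, RegimeMap

__all__ = [
    "OUModelSpec",
    "OUParams",
    "NicheFit",
    "NICHE_MODELS",
    "ou_tip_moments",
    "niche_loglik",
    "fit_niche_model",
    "compare_niche_models",
]

NICHE_MODELS = ("BM1", "BMV", "OU1", "OUA", "OUV", "OUM", "OUVA", "OUMV", "OUMVA")


@dataclass(frozen=True)
class OUModelSpec:
    name: str

    def __post_init__(self) -> None:
        if self.name not in NICHE_MODELS:
            raise ValueError(f"unknown model {self.name!r}")

    @property
    def is_bm(self) -> bool:
        return self.name.startswith("BM")

    @property
    def _suffix(self) -> str:
        return self.name[2:]  # letters after the BM/OU stem ('1', 'V', 'MVA', ...)

    @property
    def vary_sigma(self) -> bool:
        return "V" in self._suffix

    @property
    def vary_alpha(self) -> bool:
        return "A" in self._suffix

    @property
    def vary_theta(self) -> bool:
        return "M" in self._suffix

    @property
    def param_names(self) -> list[str]:
        names = ["log_sigma2_0", "log_sigma2_1"] if self.vary_sigma else ["log_sigma2_0"]
        if not self.is_bm:
            names += ["log_alpha_0", "log_alpha_1"] if self.vary_alpha else ["log_alpha_0"]
            names += ["theta_0", "theta_1"] if self.vary_theta else ["theta_0"]
        else:
            names += ["root_mean"]
        return names

    @property
    def n_params(self) -> int:
        """Continuous free parameters (the shared Mk rates are not counted
        because they are identical across the compared models)."""
        return len(self.param_names)

    def expand(self, x: np.ndarray) -> "OUParams":
        vals = dict(zip(self.param_names, np.asarray(x, dtype=float)))
        s0 = np.exp(vals["log_sigma2_0"])
        sigma2 = (s0, np.exp(vals["log_sigma2_1"])) if self.vary_sigma else (s0, s0)
        if self.is_bm:
            return OUParams(sigma2=sigma2, alpha=(0.0, 0.0), theta=(0.0, 0.0),
                            root_mean=vals["root_mean"])
        a0 = np.exp(vals["log_alpha_0"])
        alpha = (a0, np.exp(vals["log_alpha_1"])) if self.vary_alpha else (a0, a0)
        t0 = vals["theta_0"]
        theta = (t0, vals["theta_1"]) if self.vary_theta else (t0, t0)
        return OUParams(sigma2=sigma2, alpha=alpha, theta=theta, root_mean=None)


@dataclass
class OUParams:
    """Per-regime (evergreen=0, deciduous=1) OU parameters.

    ``root_mean`` is the ancestral state for BM models; for OU models the
    root value is fixed at the root regime's optimum (``root_mean=None``).
    """

    sigma2: tuple[float, float]
    alpha: tuple[float, float]
    theta: tuple[float, float]
    root_mean: float | None = None

    def __post_init__(self) -> None:
        if min(self.sigma2) <= 0:
            raise ValueError("sigma2 must be > 0")
        if min(self.alpha) < 0:
            raise ValueError("alpha must be >= 0")


def _edge_moments(segments, params: OUParams):
    """Fold piecewise-constant OU segments along one edge (parent->child).

    Returns (phi, delta, v): decay factor, deterministic shift, and added
    variance, so that  x_child = phi * x_parent + delta + N(0, v).
    """
    phi, delta, v = 1.0, 0.0, 0.0
    for dur, reg in segments:
        a = params.alpha[reg]
        s2 = params.sigma2[reg]
        th = params.theta[reg]
        if a * dur < 1e-12:
            f, add_v = 1.0 - a * dur, s2 * dur
            shift = th * a * dur
        else:
            f = np.exp(-a * dur)
            add_v = s2 * (1.0 - f * f) / (2.0 * a)
            shift = th * (1.0 - f)
        phi_seg, delta_seg, v_seg = f, shift, add_v
        # compose: segment acts after what has accumulated so far
        delta = phi_seg * delta + delta_seg
        v = phi_seg * phi_seg * v + v_seg
        phi = phi_seg * phi
    return phi, delta, v


class TreeContext:
    """Cached traversal structure shared by repeated likelihood evaluations."""

    def __init__(self, tree: Phylogeny):
        self.tree = tree
        self.preorder = tree.postorder[::-1]
        self.mrca = tree.mrca_index_matrix()


def ou_tip_moments(
    tree: Phylogeny, rmap: RegimeMap, params: OUParams, ctx: TreeContext | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Exact Gaussian tip mean vector and covariance matrix.

    Expectation and variance are propagated rootward along every edge with
    segment-wise constant (alpha, sigma^2, theta); tip covariance is the
    MRCA variance attenuated by the decay factors on both descending paths.
    """
    if ctx is None:
        ctx = TreeContext(tree)
    n = tree.n_tips
    nn = tree.n_nodes
    root = tree.root
    phi = np.ones(nn)
    delta = np.zeros(nn)
    vedge = np.zeros(nn)
    for v in range(nn):
        if v != root:
            phi[v], delta[v], vedge[v] = _edge_moments(rmap.segments[v], params)
    m = np.zeros(nn)  # node expectations
    s = np.zeros(nn)  # node variances
    P = np.ones(nn)  # cumulative decay product from root
    root_reg = int(rmap.node_state[root])
    m[root] = params.theta[root_reg] if params.root_mean is None else params.root_mean
    for v in ctx.preorder:
        p = tree.parent[v]
        if p < 0:
            continue
        m[v] = phi[v] * m[p] + delta[v]
        s[v] = phi[v] ** 2 * s[p] + vedge[v]
        if s[v] < -1e-12:
            raise FloatingPointError("negative variance accumulated")
        P[v] = phi[v] * P[p]
    # Cov(i, j) = s[mrca] * P_i P_j / P_mrca^2. When alpha*t is large the
    # decay products underflow; base then overflows while the outer product
    # underflows, and the true covariance is ~0 — repair non-finite entries
    # and set the diagonal (= s[tip]) directly.
    P2 = P * P
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        base = np.where(P2 > 0, s / P2, 0.0)
        cov = base[ctx.mrca] * np.outer(P[:n], P[:n])
    cov[~np.isfinite(cov)] = 0.0
    np.fill_diagonal(cov, s[:n])
    return m[:n].copy(), cov


def _mvn_logpdf(x, mean, cov, ridge: float = 1e-10):
    from scipy.linalg import solve_triangular

    n = x.size
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("singular tip covariance; adding 1e-10 ridge", stacklevel=3)
        L = np.linalg.cholesky(cov + ridge * np.eye(n))
    u = solve_triangular(L, x - mean, lower=True)
    return -0.5 * (n * np.log(2 * np.pi) + u @ u) - np.log(np.diag(L)).sum()


def niche_loglik(
    tree: Phylogeny,
    maps: list[RegimeMap] | RegimeMap,
    trait_values: np.ndarray,
    spec: OUModelSpec,
    params: OUParams,
    ctx: TreeContext | None = None,
) -> float:
    """Map-averaged Gaussian log-likelihood: log-mean-exp over regime maps."""
    if isinstance(maps, RegimeMap):
        maps = [maps]
    if not maps:
        raise ValueError("need at least one regime map")
    if ctx is None:
        ctx = TreeContext(tree)
    x = np.asarray(trait_values, dtype=float)
    lls = np.empty(len(maps))
    for i, rm in enumerate(maps):
        mean, cov = ou_tip_moments(tree, rm, params, ctx)
        lls[i] = _mvn_logpdf(x, mean, cov)
    return float(logsumexp(lls) - np.log(len(maps)))


@dataclass
class NicheFit:
    spec: OUModelSpec
    params: OUParams
    loglik: float  # map-averaged, at the ML parameters
    k: int
    n: int
    x: np.ndarray = field(default=None, repr=False)

    @property
    def aicc(self) -> float:
        k, n = self.k, self.n
        if n <= k + 1:
            return np.inf
        return 2 * k - 2 * self.loglik + 2 * k * (k + 1) / (n - k - 1)


def _start_vector(spec: OUModelSpec, x: np.ndarray, tree: Phylogeny) -> np.ndarray:
    var = max(np.var(x), 1e-6)
    T = tree.root_age
    vals = {
        "log_sigma2_0": np.log(var / T),
        "log_sigma2_1": np.log(var / T),
        "log_alpha_0": np.log(1.0 / T),
        "log_alpha_1": np.log(1.0 / T),
        "theta_0": float(np.mean(x)),
        "theta_1": float(np.mean(x)),
        "root_mean": float(np.mean(x)),
    }
    return np.array([vals[nm] for nm in spec.param_names])


def fit_niche_model(
    tree: Phylogeny,
    maps: list[RegimeMap],
    trait_values: np.ndarray,
    spec: OUModelSpec,
    n_starts: int = 3,
    seed: int = 0,
    maxiter: int = 200,
) -> NicheFit:
    """ML fit of one BM/OU model over a fixed shared set of regime maps.

    Continuous parameters only (log scale for sigma^2 and alpha); the maps
    are supplied, not refit, so AICc counts continuous parameters plus the
    root state/mean as dictated by the model.
    """
    x = np.asarray(trait_values, dtype=float)
    if x.size != tree.n_tips:
        raise ValueError("trait vector length must equal number of tips")
    ctx = TreeContext(tree)

    def nll(theta):
        try:
            params = spec.expand(theta)
            ll = niche_loglik(tree, maps, x, spec, params, ctx)
        except (FloatingPointError, np.linalg.LinAlgError, ValueError):
            return 1e10
        return -ll if np.isfinite(ll) else 1e10

    rng = np.random.default_rng(seed)
    x0 = _start_vector(spec, x, tree)
    lo_bounds = []
    for nm in spec.param_names:
        if nm.startswith("log_sigma2"):
            lo_bounds.append((np.log(1e-8), np.log(1e6)))
        elif nm.startswith("log_alpha"):
            lo_bounds.append((np.log(1e-8), np.log(50.0)))
        else:
            lo_bounds.append((None, None))
    best = None
    for i in range(n_starts):
        xi = x0 if i == 0 else x0 + rng.normal(0, 1.0, size=x0.size)
        res = minimize(nll, xi, method="L-BFGS-B", bounds=lo_bounds,
                       options={"maxiter": maxiter})
        if best is None or res.fun < best.fun:
            best = res
    if best.fun >= 1e10:
        raise RuntimeError(f"optimizer failed for {spec.name}: {best}")
    return NicheFit(
        spec=spec, params=spec.expand(best.x), loglik=-float(best.fun),
        k=spec.n_params, n=tree.n_tips, x=best.x,
    )


def compare_niche_models(fits: list[NicheFit]) -> pd.DataFrame:
    """AICc/Akaike-weight ranking of the nine models for one variable."""
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError("fits computed on different data sizes")
    aicc = np.array([f.aicc for f in fits])
    usable = np.isfinite(aicc)
    w = np.zeros(len(fits))
    if usable.any():
        d = aicc[usable] - aicc[usable].min()
        wu = np.exp(-0.5 * d)
        w[usable] = wu / wu.sum()
    tab = pd.DataFrame(
        {
            "model": [f.spec.name for f in fits],
            "logL": [f.loglik for f in fits],
            "k": [f.k for f in fits],
            "AICc": aicc,
            "usable": usable,
        }
    )
    tab["dAICc"] = tab["AICc"] - np.nanmin(np.where(usable, aicc, np.nan))
    tab["AICw"] = w
    return tab.sort_values("AICc", ignore_index=True)


def fit_all_niche_models(
    tree: Phylogeny,
    maps: list[RegimeMap],
    trait_values: np.ndarray,
    n_starts: int = 3,
    seed: int = 0,
) -> list[NicheFit]:
    return [
        fit_niche_model(tree, maps, trait_values, OUModelSpec(m),
                        n_starts=n_starts, seed=seed + i)
        for i, m in enumerate(NICHE_MODELS)
    ]
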