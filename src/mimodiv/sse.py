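"""Time-stratified state-dependent speciation/extinction (SSE) models.

The model family crosses four epoch scenarios — whether speciation depends
on the observed trait (leaf habit) in the early and/or late epoch — with
symmetric vs asymmetric and time-constant vs time-variable transition
rates, plus two unsliced (no temporal change) references.

States are composite: 2 observed (0 = evergreen, 1 = deciduous) x 2 hidden
(A, B), indexed ``s = 2*obs + hid``. "Dependent" epochs let speciation vary
by observed state; "independent" epochs let it vary by hidden state only
(the character-independent null with a matched parameter count). Extinction
is shared across composite states within an epoch; dual transitions
(simultaneous observed + hidden change) have rate zero.

Likelihoods integrate the standard D/E ordinary differential equations
tipward-to-rootward along each branch, switching rates at the slice age
(ages measured backward from the present; "early" means age > slice_age).
The integrator is an adaptive embedded Dormand-Prince RK45 (rtol 1e-8,
atol 1e-10) compiled with numba; the epoch boundary is always an
integration breakpoint.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize

from mimodiv.trees import Phylogeny, TraitTable

__all__ = [
    "SSEModelSpec",
    "SSEParams",
    "SSEFit",
    "build_model_set",
    "sse_loglik",
    "fit_sse",
    "compare_sse_models",
    "akaike_weights",
]

RATE_LO, RATE_HI = 1e-6, 10.0


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SSEModelSpec:
    """One member of the time-structured SSE model family."""

    slice_age: float | None  # None = unsliced reference model
    early_mode: str = "dependent"  # {'dependent', 'independent'}
    late_mode: str = "dependent"
    transition_symmetry: str = "asymmetric"  # {'symmetric', 'asymmetric'}
    transition_time_variation: str = "constant"  # {'constant', 'variable'}
    sampling_fraction: tuple[float, float] = (1.0, 1.0)
    n_hidden: int = 2

    def __post_init__(self) -> None:
        for m in (self.early_mode, self.late_mode):
            if m not in ("dependent", "independent"):
                raise ValueError(f"bad epoch mode {m!r}")
        if self.transition_symmetry not in ("symmetric", "asymmetric"):
            raise ValueError("bad transition_symmetry")
        if self.transition_time_variation not in ("constant", "variable"):
            raise ValueError("bad transition_time_variation")
        if self.slice_age is not None and self.slice_age <= 0:
            raise ValueError("slice_age must be positive")
        if self.slice_age is None:
            if self.early_mode != self.late_mode:
                raise ValueError("unsliced model cannot mix epoch modes")
            if self.transition_time_variation != "constant":
                raise ValueError("unsliced model cannot vary transitions in time")
        if self.n_hidden != 2:
            raise NotImplementedError("only 2 hidden states supported")
        f = self.sampling_fraction
        if not (0 < f[0] <= 1 and 0 < f[1] <= 1):
            raise ValueError("sampling fractions must lie in (0, 1]")

    @property
    def sliced(self) -> bool:
        return self.slice_age is not None

    @property
    def name(self) -> str:
        if not self.sliced:
            return f"unsliced_{self.early_mode}_{self.transition_symmetry}"
        return (
            f"{self.early_mode[:3]}Early_{self.late_mode[:3]}Late_"
            f"{self.transition_symmetry}_{self.transition_time_variation}"
            f"@{self.slice_age:g}"
        )

    @property
    def param_names(self) -> list[str]:
        epochs = ["early", "late"] if self.sliced else ["const"]
        names = []
        for e in epochs:
            names += [f"lam_{e}_0", f"lam_{e}_1", f"mu_{e}"]
        q_epochs = (
            ["early", "late"]
            if self.sliced and self.transition_time_variation == "variable"
            else ["const"]
        )
        for e in q_epochs:
            if self.transition_symmetry == "asymmetric":
                names += [f"q01_{e}", f"q10_{e}"]
            else:
                names += [f"q_{e}"]
            names += [f"qh_{e}"]
        return names

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def expand(self, x: np.ndarray) -> "SSEParams":
        """Free-parameter vector -> full per-epoch rate arrays."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_params,):
            raise ValueError(
                f"expected {self.n_params} free parameters, got {x.shape}"
            )
        vals = dict(zip(self.param_names, x))
        lam = np.zeros((2, 4))
        mu = np.zeros((2, 4))
        Q = np.zeros((2, 4, 4))
        epochs = ("early", "late") if self.sliced else ("const", "const")
        modes = (self.early_mode, self.late_mode)
        for e_ix, (e, mode) in enumerate(zip(epochs, modes)):
            l0, l1 = vals[f"lam_{e}_0"], vals[f"lam_{e}_1"]
            for s in range(4):
                obs, hid = divmod(s, 2)
                key = obs if mode == "dependent" else hid
                lam[e_ix, s] = l0 if key == 0 else l1
            mu[e_ix, :] = vals[f"mu_{e}"]
            qe = (
                e
                if (self.sliced and self.transition_time_variation == "variable")
                else "const"
            )
            if self.transition_symmetry == "asymmetric":
                q01, q10 = vals[f"q01_{qe}"], vals[f"q10_{qe}"]
            else:
                q01 = q10 = vals[f"q_{qe}"]
            qh = vals[f"qh_{qe}"]
            for s in range(4):
                obs, hid = divmod(s, 2)
                t_obs = 2 * (1 - obs) + hid  # flip observed, keep hidden
                Q[e_ix, s, t_obs] = q01 if obs == 0 else q10
                t_hid = 2 * obs + (1 - hid)  # flip hidden, keep observed
                Q[e_ix, s, t_hid] = qh
            for s in range(4):
                Q[e_ix, s, s] = -Q[e_ix, s].sum()
        return SSEParams(lam=lam, mu=mu, Q=Q, free=x.copy())


@dataclass
class SSEParams:
    """Full rates per epoch (row 0 = early, 1 = late) and composite state."""

    lam: np.ndarray  # (2, 4) speciation /Myr
    mu: np.ndarray  # (2, 4) extinction /Myr
    Q: np.ndarray  # (2, 4, 4) transition rates, diagonal = -row sum
    free: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.lam < 0) or np.any(self.mu < 0):
            raise ValueError("rates must be >= 0")
        off = self.Q.copy()
        off[:, np.arange(4), np.arange(4)] = 0.0
        if np.any(off < 0):
            raise ValueError("off-diagonal transition rates must be >= 0")
        if not np.allclose(self.Q.sum(axis=2), 0.0, atol=1e-10):
            raise ValueError("Q rows must sum to zero")


def build_model_set(
    slice_age: float, sampling_fraction: tuple[float, float] = (1.0, 1.0)
) -> list[SSEModelSpec]:
    """The full crossing of epoch scenarios, symmetry and time-variation,
    plus the two unsliced references (dependent / independent)."""
    if slice_age <= 0:
        raise ValueError("slice_age must be positive")
    specs = []
    for em, lm, sym, tv in itertools.product(
        ("dependent", "independent"),
        ("dependent", "independent"),
        ("symmetric", "asymmetric"),
        ("constant", "variable"),
    ):
        specs.append(
            SSEModelSpec(slice_age, em, lm, sym, tv, sampling_fraction)
        )
    for mode in ("dependent", "independent"):
        specs.append(
            SSEModelSpec(None, mode, mode, "asymmetric", "constant", sampling_fraction)
        )
    return specs


# ---------------------------------------------------------------------------
# likelihood kernel (numba)
# ---------------------------------------------------------------------------


@njit(cache=False)
def _rhs(y, lam, mu, Q, dy):
    # y = [E0..E3, D0..D3]
    for i in range(4):
        qi = -Q[i, i]
        sE = 0.0
        sD = 0.0
        for j in range(4):
            if j != i:
                sE += Q[i, j] * y[j]
                sD += Q[i, j] * y[4 + j]
        diag = lam[i] + mu[i] + qi
        dy[i] = mu[i] - diag * y[i] + lam[i] * y[i] * y[i] + sE
        dy[4 + i] = -diag * y[4 + i] + 2.0 * lam[i] * y[i] * y[4 + i] + sD


@njit(cache=False)
def _rk45_segment(y, t0, t1, lam, mu, Q, rtol, atol):
    """Adaptive Dormand-Prince RK45 from t0 to t1 (t1 > t0), in place."""
    span = t1 - t0
    if span <= 0.0:
        return 0
    h = span
    t = t0
    k1 = np.empty(8)
    k2 = np.empty(8)
    k3 = np.empty(8)
    k4 = np.empty(8)
    k5 = np.empty(8)
    k6 = np.empty(8)
    k7 = np.empty(8)
    ytmp = np.empty(8)
    y5 = np.empty(8)
    clipped = 0
    _rhs(y, lam, mu, Q, k1)
    while t < t1 - 1e-14 * span:
        if t + h > t1:
            h = t1 - t
        for i in range(8):
            ytmp[i] = y[i] + h * 0.2 * k1[i]
        _rhs(ytmp, lam, mu, Q, k2)
        for i in range(8):
            ytmp[i] = y[i] + h * (3.0 / 40.0 * k1[i] + 9.0 / 40.0 * k2[i])
        _rhs(ytmp, lam, mu, Q, k3)
        for i in range(8):
            ytmp[i] = y[i] + h * (
                44.0 / 45.0 * k1[i] - 56.0 / 15.0 * k2[i] + 32.0 / 9.0 * k3[i]
            )
        _rhs(ytmp, lam, mu, Q, k4)
        for i in range(8):
            ytmp[i] = y[i] + h * (
                19372.0 / 6561.0 * k1[i]
                - 25360.0 / 2187.0 * k2[i]
                + 64448.0 / 6561.0 * k3[i]
                - 212.0 / 729.0 * k4[i]
            )
        _rhs(ytmp, lam, mu, Q, k5)
        for i in range(8):
            ytmp[i] = y[i] + h * (
                9017.0 / 3168.0 * k1[i]
                - 355.0 / 33.0 * k2[i]
                + 46732.0 / 5247.0 * k3[i]
                + 49.0 / 176.0 * k4[i]
                - 5103.0 / 18656.0 * k5[i]
            )
        _rhs(ytmp, lam, mu, Q, k6)
        for i in range(8):
            y5[i] = y[i] + h * (
                35.0 / 384.0 * k1[i]
                + 500.0 / 1113.0 * k3[i]
                + 125.0 / 192.0 * k4[i]
                - 2187.0 / 6784.0 * k5[i]
                + 11.0 / 84.0 * k6[i]
            )
        _rhs(y5, lam, mu, Q, k7)
        errnorm = 0.0
        for i in range(8):
            e4 = y[i] + h * (
                5179.0 / 57600.0 * k1[i]
                + 7571.0 / 16695.0 * k3[i]
                + 393.0 / 640.0 * k4[i]
                - 92097.0 / 339200.0 * k5[i]
                + 187.0 / 2100.0 * k6[i]
                + 1.0 / 40.0 * k7[i]
            )
            sc = atol + rtol * max(abs(y[i]), abs(y5[i]))
            d = (y5[i] - e4) / sc
            errnorm += d * d
        errnorm = np.sqrt(errnorm / 8.0)
        if errnorm <= 1.0:
            t += h
            for i in range(8):
                y[i] = y5[i]
                k1[i] = k7[i]  # FSAL
            for i in range(4):
                if y[i] < 0.0:
                    y[i] = 0.0
                elif y[i] > 1.0:
                    y[i] = 1.0
                if y[4 + i] < 0.0:
                    y[4 + i] = 0.0
                    clipped += 1
        fac = 0.9 * errnorm ** (-0.2) if errnorm > 1e-12 else 5.0
        if fac > 5.0:
            fac = 5.0
        elif fac < 0.2:
            fac = 0.2
        h *= fac
        if h < 1e-12 * span:
            h = 1e-12 * span
    return clipped


@njit(cache=False)
def _integrate_branch(y, a0, a1, slice_age, lam, mu, Q, rtol, atol):
    """Integrate tipward age a0 -> rootward a1 with an epoch switch."""
    clipped = 0
    if slice_age > 0.0 and a0 < slice_age < a1:
        clipped += _rk45_segment(y, a0, slice_age, lam[1], mu[1], Q[1], rtol, atol)
        clipped += _rk45_segment(y, slice_age, a1, lam[0], mu[0], Q[0], rtol, atol)
    else:
        e = 0 if (slice_age > 0.0 and a0 >= slice_age) else 1
        if slice_age <= 0.0:
            e = 0  # unsliced: early row holds the single rate set
        clipped += _rk45_segment(y, a0, a1, lam[e], mu[e], Q[e], rtol, atol)
    return clipped


@njit(cache=False)
def _sse_prune(
    n_tips,
    post,
    child_flat,
    child_start,
    child_count,
    node_age,
    tip_D,
    tip_E,
    lam,
    mu,
    Q,
    slice_age,
    rtol,
    atol,
):
    nn = node_age.shape[0]
    D = np.zeros((nn, 4))
    E = np.zeros((nn, 4))
    logcomp = 0.0
    clipped = 0
    for v in range(n_tips):
        for s in range(4):
            D[v, s] = tip_D[v, s]
            E[v, s] = tip_E[v, s]
    y = np.empty(8)
    for ix in range(post.shape[0]):
        v = post[ix]
        if v < n_tips:
            continue
        av = node_age[v]
        if slice_age > 0.0 and av > slice_age:
            e_v = 0
        elif slice_age > 0.0:
            e_v = 1
        else:
            e_v = 0
        Dv = np.ones(4)
        first = True
        for ci in range(child_count[v]):
            c = child_flat[child_start[v] + ci]
            for s in range(4):
                y[s] = E[c, s]
                y[4 + s] = D[c, s]
            clipped += _integrate_branch(
                y, node_age[c], av, slice_age, lam, mu, Q, rtol, atol
            )
            if first:
                for s in range(4):
                    E[v, s] = y[s]
                    Dv[s] = y[4 + s]
                first = False
            else:
                for s in range(4):
                    Dv[s] = Dv[s] * y[4 + s] * lam[e_v, s]
        tot = 0.0
        for s in range(4):
            tot += Dv[s]
        if tot <= 0.0:
            return D, E, -np.inf, clipped
        for s in range(4):
            D[v, s] = Dv[s] / tot
        logcomp += np.log(tot)
    return D, E, logcomp, clipped


def _tree_arrays(tree: Phylogeny):
    post = tree.postorder
    nn = tree.n_nodes
    counts = np.array([len(tree.children[v]) for v in range(nn)], dtype=np.int64)
    start = np.zeros(nn, dtype=np.int64)
    start[1:] = np.cumsum(counts)[:-1]
    flat = np.concatenate(
        [np.asarray(tree.children[v], dtype=np.int64) for v in range(nn)]
        or [np.empty(0, dtype=np.int64)]
    )
    age = tree.node_age.copy()
    age[: tree.n_tips] = 0.0  # ultrametric within tolerance; pin tips at present
    return post, flat, start, counts, age


def sse_loglik(
    tree: Phylogeny,
    traits,
    spec: SSEModelSpec,
    params: SSEParams,
    root_weighting: str = "weighted",
    condition_on_survival: bool = True,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    _cache: dict | None = None,
) -> float:
    """Log-likelihood of tree + tip states under a (possibly sliced) SSE model.

    ``root_weighting``: 'weighted' uses the data-derived root-state weights
    (each state weighted by its share of the root D), 'flat' uses 1/4.
    ``condition_on_survival`` conditions on two crown lineages surviving.
    """
    states = traits.states_for(tree) if isinstance(traits, TraitTable) else np.asarray(traits)
    if _cache is not None and "arrays" in _cache:
        post, flat, start, counts, age = _cache["arrays"]
    else:
        arrays = _tree_arrays(tree)
        if _cache is not None:
            _cache["arrays"] = arrays
        post, flat, start, counts, age = arrays
    f = spec.sampling_fraction
    n = tree.n_tips
    tip_D = np.zeros((n, 4))
    tip_E = np.zeros((n, 4))
    for v in range(n):
        obs = int(states[v])
        for s in range(4):
            s_obs = s // 2
            tip_E[v, s] = 1.0 - f[s_obs]
            if s_obs == obs:
                tip_D[v, s] = f[obs]
    slice_age = float(spec.slice_age) if spec.sliced else 0.0
    D, E, logcomp, clipped = _sse_prune(
        n, post, flat, start, counts, age, tip_D, tip_E,
        params.lam, params.mu, params.Q, slice_age, rtol, atol,
    )
    if not np.isfinite(logcomp):
        return -np.inf
    if clipped > 0 and _cache is not None:
        _cache["clipped"] = _cache.get("clipped", 0) + clipped
    root = tree.root
    Droot, Eroot = D[root], E[root]
    root_age = age[root]
    e_root = 0 if (not spec.sliced or root_age > slice_age) else 1
    lam_root = params.lam[e_root]
    if root_weighting == "weighted":
        tot = Droot.sum()
        w = Droot / tot if tot > 0 else np.full(4, 0.25)
    elif root_weighting == "flat":
        w = np.full(4, 0.25)
    else:
        raise ValueError("root_weighting must be 'weighted' or 'flat'")
    if condition_on_survival:
        # floor the per-state survival probability: without it the optimizer
        # can inflate the conditioned likelihood without bound in the
        # near-certain-extinction corner (E -> 1 or lambda -> 0 at the root)
        denom = np.maximum(lam_root * (1.0 - Eroot) ** 2, 1e-12)
        lik = float(np.sum(w * Droot / denom))
    else:
        lik = float(np.sum(w * Droot))
    if lik <= 0:
        return -np.inf
    return float(np.log(lik) + logcomp)


# ---------------------------------------------------------------------------
# fitting and model comparison
# ---------------------------------------------------------------------------


@dataclass
class SSEFit:
    spec: SSEModelSpec
    params: SSEParams
    loglik: float
    k: int
    starts: list = field(default_factory=list)
    data_id: str = ""

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik


def _default_start(tree: Phylogeny, states: np.ndarray, spec: SSEModelSpec) -> np.ndarray:
    """Data-informed initial free-parameter vector (on the natural scale)."""
    n = tree.n_tips
    T = max(tree.root_age, 1e-6)
    lam0 = max(np.log(max(n, 3) / 2.0) / T, 1e-3)
    mu0 = 0.1 * lam0
    q0 = max(1.0, min(states.sum(), n - states.sum())) / max(
        tree.total_branch_length(), 1e-9
    )
    vals = {}
    for name in spec.param_names:
        if name.startswith("lam"):
            vals[name] = lam0
        elif name.startswith("mu"):
            vals[name] = mu0
        elif name.startswith("qh"):
            vals[name] = 0.5 * q0
        else:
            vals[name] = q0
    return np.array([vals[nm] for nm in spec.param_names])


def fit_sse(
    tree: Phylogeny,
    traits,
    spec: SSEModelSpec,
    n_starts: int = 2,
    seed: int = 0,
    root_weighting: str = "weighted",
    condition_on_survival: bool = True,
    maxiter: int = 300,
) -> SSEFit:
    """Bounded ML fit (log-rate scale) with seeded multi-start.

    Start 1 is data-informed; further starts are log-uniform perturbations
    around it. All starts are recorded for multimodality diagnosis.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    states = traits.states_for(tree) if isinstance(traits, TraitTable) else np.asarray(traits)
    cache: dict = {}
    lo, hi = np.log(RATE_LO), np.log(RATE_HI)

    def nll(logx):
        try:
            params = spec.expand(np.exp(logx))
        except ValueError:
            return 1e10
        ll = sse_loglik(
            tree, states, spec, params,
            root_weighting=root_weighting,
            condition_on_survival=condition_on_survival,
            _cache=cache,
        )
        return -ll if np.isfinite(ll) else 1e10

    rng = np.random.default_rng(seed)
    x0 = np.clip(np.log(_default_start(tree, states, spec)), lo, hi)
    k = spec.n_params
    # Latin-hypercube style spread of extra starts around the heuristic
    extra = []
    if n_starts > 1:
        grid = (np.arange(n_starts - 1)[:, None] + rng.random((n_starts - 1, k))) / (
            n_starts - 1
        )
        for row in grid:
            extra.append(np.clip(x0 + (row - 0.5) * 3.0, lo, hi))
    starts, best = [], None
    for x_init in [x0] + extra:
        res = minimize(
            nll, x_init, method="L-BFGS-B", bounds=[(lo, hi)] * k,
            options={"maxiter": maxiter, "ftol": 1e-10},
        )
        starts.append(
            {"x0": np.exp(x_init), "x": np.exp(res.x), "loglik": -res.fun,
             "converged": bool(res.success)}
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e10:
        raise RuntimeError(f"all optimizer starts failed for {spec.name}: {starts}")
    params = spec.expand(np.exp(best.x))
    return SSEFit(spec=spec, params=params, loglik=-float(best.fun), k=k, starts=starts)


def akaike_weights(aic: np.ndarray) -> np.ndarray:
    """exp(-dAIC/2), normalized to sum to one."""
    aic = np.asarray(aic, dtype=float)
    d = aic - aic.min()
    w = np.exp(-0.5 * d)
    return w / w.sum()


def compare_sse_models(fits: list[SSEFit]) -> pd.DataFrame:
    """Ranked AIC table with Akaike weights (ascending AIC)."""
    ids = {f.data_id for f in fits}
    if len(ids) > 1:
        raise ValueError(f"fits computed on different datasets: {ids}")
    tab = pd.DataFrame(
        {
            "model": [f.spec.name for f in fits],
            "logL": [f.loglik for f in fits],
            "k": [f.k for f in fits],
            "AIC": [f.aic for f in fits],
        }
    )
    tab["dAIC"] = tab["AIC"] - tab["AIC"].min()
    tab["AICw"] = akaike_weights(tab["AIC"].to_numpy())
    return tab.sort_values("AIC", ignore_index=True)


def rate_summary(fit: SSEFit) -> pd.DataFrame:
    """Per-epoch observed-state rates of the fitted model (long format)."""
    rows = []
    epochs = ("early", "late") if fit.spec.sliced else ("const",)
    for e_ix, e in enumerate(epochs):
        lam, mu, Q = fit.params.lam[e_ix], fit.params.mu[e_ix], fit.params.Q[e_ix]
        for obs, label in ((0, "evergreen"), (1, "deciduous")):
            s = 2 * obs  # hidden state A representative
            rows.append(
                {
                    "epoch": e,
                    "state": label,
                    "speciation": lam[s],
                    "extinction": mu[s],
                    "transition_out": Q[s, 2 * (1 - obs)],
                }
            )
    return pd.DataFrame(rows)
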