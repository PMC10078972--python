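"""Multi-regime Ornstein-Uhlenbeck and Brownian-motion models on trees.

The model family is the standard seven-member set used for state-dependent
trait evolution: BM1 and OU1 (regime-independent), BMS (regime-specific
Brownian rates), and OUM / OUMV / OUMA / OUMVA (regime-specific optima theta,
optionally with regime-specific diffusion sigma^2 [V] and/or pull alpha [A]).
The starting state theta0 is estimated in every model except BMS, where the
root mean is the only mean parameter.

Likelihood is the exact multivariate Gaussian implied by piecewise-OU
integration along each root-to-tip path: per branch segment of duration t in
regime k the mean decays toward theta_k with factor e^(-alpha_k t) and the
variance propagates as v' = v e^(-2 alpha_k t) + sigma2_k (1 - e^(-2 alpha_k
t)) / (2 alpha_k); tip covariance is the variance at the MRCA times the decay
factors down both descending paths.  alpha = 0 segments use the Brownian
limits.

For fitting, theta0 and the thetas enter the tip mean linearly and are
profiled out by generalized least squares at each evaluation, and the overall
sigma^2 scale is profiled in closed form, so the numerical search runs over
at most (log) alphas and sigma^2 ratios.  Model selection uses AICc; each fit
carries the Hessian-eigenvalue diagnostic (all eigenvalues of the negative
log-likelihood Hessian at the optimum must exceed 0) and fits failing it are
excluded from comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .phylo import Phylo

__all__ = [
    "MODELS",
    "OUParams",
    "OUFit",
    "RegimePainting",
    "paint_regimes",
    "ou_moments",
    "ou_loglik",
    "fit_model",
    "compare_models",
    "aicc",
    "aicc_weights",
    "half_life",
    "stationary_variance",
    "hessian_check",
    "central_hessian",
    "FitConfig",
]

_BM_SWITCH = 1e-8  # below alpha*t, use Brownian limits (matches the simulator)

# model id -> (alpha structure, sigma^2 structure, optimum structure)
# "zero": Brownian; "shared": one value across regimes; "per": one per regime
MODELS: dict[str, tuple[str, str, str]] = {
    "BM1": ("zero", "shared", "none"),
    "BMS": ("zero", "per", "none"),
    "OU1": ("shared", "shared", "shared"),
    "OUM": ("shared", "shared", "per"),
    "OUMV": ("shared", "per", "per"),
    "OUMA": ("per", "shared", "per"),
    "OUMVA": ("per", "per", "per"),
}


def n_free_params(model: str, k: int) -> int:
    """Free-parameter count: every independently estimated quantity,
    including the estimated root state / root mean."""
    amode, smode, tmode = MODELS[model]
    n_mean = {"none": 1, "shared": 2, "per": 1 + k}[tmode]
    n_alpha = {"zero": 0, "shared": 1, "per": k}[amode]
    n_sigma = {"shared": 1, "per": k}[smode]
    return n_mean + n_alpha + n_sigma


@dataclass
class RegimePainting:
    """Assignment of one selective regime to every branch.

    ``regime[v]`` is the regime index of the branch subtending node ``v``
    (the root's entry is its own state and affects nothing).
    """

    regime: np.ndarray
    labels: list[str]
    derivation: str = "supplied"

    def __post_init__(self) -> None:
        self.regime = np.asarray(self.regime, dtype=np.int64)
        if self.regime.size and (
            self.regime.min() < 0 or self.regime.max() >= len(self.labels)
        ):
            raise ValueError("regime indices outside label range")

    @property
    def n_regimes(self) -> int:
        return len(self.labels)


def paint_regimes(
    tree: Phylo,
    tip_states: Mapping[str, str],
    node_states: Mapping[int, str] | Sequence[str],
    labels: Sequence[str] | None = None,
    terminal: str = "rootward",
) -> RegimePainting:
    """Paint branches from node states: each branch takes the state of its
    rootward (parental) node; with ``terminal="tipward"`` terminal branches
    take their own tip's state instead.

    ``node_states`` maps internal node id -> state label (tip entries are
    ignored if present).
    """
    if terminal not in ("rootward", "tipward"):
        raise ValueError("terminal must be 'rootward' or 'tipward'")
    if labels is None:
        labels = sorted(set(tip_states.values()))
    index = {lab: i for i, lab in enumerate(labels)}

    def node_state(v: int) -> str:
        try:
            s = node_states[v]
        except (KeyError, IndexError):
            raise ValueError(f"missing state for internal node {v}") from None
        return s

    regime = np.zeros(tree.n_nodes, dtype=np.int64)
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if v < tree.n_tips and terminal == "tipward":
            regime[v] = index[tip_states[tree.tips[v]]]
        elif p < 0:
            regime[v] = index[node_state(v)]
        else:
            regime[v] = index[node_state(p)]
    return RegimePainting(regime=regime, labels=list(labels), derivation="from node states")


@dataclass
class OUParams:
    """Full parameter set of one model: root state theta0, per-regime optima
    theta (trait units), pull strengths alpha (1/Ma) and diffusion rates
    sigma2 (trait^2/Ma)."""

    model: str
    theta0: float
    theta: np.ndarray
    alpha: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.sigma2 = np.atleast_1d(np.asarray(self.sigma2, dtype=float))

    def validate(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model id {self.model!r}")
        if np.any(self.alpha < 0):
            raise ValueError("alpha must be >= 0")
        if np.any(self.sigma2 <= 0):
            raise ValueError("sigma2 must be > 0")
        if not (self.theta.shape == self.alpha.shape == self.sigma2.shape):
            raise ValueError("theta, alpha, sigma2 must share one length (k regimes)")


# ---------------------------------------------------------------------------
# moments and likelihood
# ---------------------------------------------------------------------------

def _structures(
    tree: Phylo,
    painting: RegimePainting,
    alpha: np.ndarray,
    sigma2: np.ndarray,
    theta_mode: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One preorder sweep giving, per node, the log decay from the root and
    the trait variance, plus the tip design matrix X with mean = X @ beta.

    beta is (theta0,), (theta0, theta) or (theta0, theta_1..theta_k)
    depending on ``theta_mode``.  Coefficients obey c_child = c_parent * e +
    (1 - e) * e_regime with e = exp(-alpha t) and always sum to 1, so only
    k - 1 optimum columns need their own recursion.
    """
    n = tree.n_nodes
    k = alpha.size
    parent = tree.parent.tolist()
    blen = tree.blen.tolist()
    reg = painting.regime.tolist()
    al = alpha.tolist()
    s2 = sigma2.tolist()
    logD = [0.0] * n
    v = [0.0] * n
    nw = k - 1 if theta_mode == "per" else 0
    W = [[0.0] * n for _ in range(nw)]
    for node in tree.preorder.tolist():
        p = parent[node]
        if p < 0:
            continue
        r = reg[node]
        a = al[r]
        t = blen[node]
        if a * t < _BM_SWITCH:
            logD[node] = logD[p]
            v[node] = v[p] + s2[r] * t
            for w in W:
                w[node] = w[p]
        else:
            e = math.exp(-a * t)
            e2 = e * e
            logD[node] = logD[p] - a * t
            v[node] = v[p] * e2 + s2[r] * (1.0 - e2) / (2.0 * a)
            for i, w in enumerate(W):
                w[node] = w[p] * e + ((1.0 - e) if i + 1 == r else 0.0)
    logD_arr = np.asarray(logD)
    v_arr = np.asarray(v)
    nt = tree.n_tips
    D = np.exp(logD_arr[:nt])
    if theta_mode == "none":
        X = D[:, None]
    elif theta_mode == "shared":
        X = np.column_stack([D, 1.0 - D])
    else:
        rest = [np.asarray(w[:nt]) for w in W]
        w0 = 1.0 - D - (np.sum(rest, axis=0) if rest else 0.0)
        X = np.column_stack([D, w0, *rest])
    return logD_arr, v_arr, X


def _tip_cov(tree: Phylo, logD: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Tip covariance from per-node scalars via the cached MRCA matrix:
    Cov(i, j) = v_mrca * exp(logD_i + logD_j - 2 logD_mrca)."""
    M = tree.mrca_matrix()
    nt = tree.n_tips
    ld = logD[:nt]
    if logD.min() > -300.0:  # fast path: decays representable without logs
        D = np.exp(logD)
        s = v / (D * D)
        return np.outer(D[:nt], D[:nt]) * s[M]
    return v[M] * np.exp(ld[:, None] + ld[None, :] - 2.0 * logD[M])


def ou_moments(
    tree: Phylo, painting: RegimePainting, params: OUParams
) -> tuple[np.ndarray, np.ndarray]:
    """Exact tip mean vector and tip covariance matrix for the painted model."""
    params.validate()
    logD, v, X = _structures(tree, painting, params.alpha, params.sigma2, "per")
    cov = _tip_cov(tree, logD, v)
    beta = np.concatenate([[params.theta0], params.theta])
    mean = X @ beta
    return mean, cov


def ou_loglik(trait: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """Multivariate normal log-density via Cholesky (no explicit inverse);
    a tiny jitter (1e-10 x mean diagonal) is applied before factorization."""
    trait = np.asarray(trait, dtype=float)
    n = trait.size
    C = np.array(cov, dtype=float)
    idx = np.arange(n)
    C[idx, idx] += 1e-10 * float(C[idx, idx].mean())
    try:
        L = scipy.linalg.cholesky(C, lower=True, check_finite=False)
    except scipy.linalg.LinAlgError:
        w = np.linalg.eigvalsh(np.asarray(cov, dtype=float))
        raise np.linalg.LinAlgError(
            f"covariance not positive definite after jitter (min eigenvalue {w[0]:.3e})"
        ) from None
    r = scipy.linalg.solve_triangular(L, trait - mean, lower=True, check_finite=False)
    return float(
        -0.5 * n * np.log(2.0 * np.pi) - np.log(np.diag(L)).sum() - 0.5 * r @ r
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    n_restarts: int = 3
    seed: int = 0
    alpha_bounds: tuple[float, float] = (1e-6, 50.0)
    ratio_bounds: tuple[float, float] = (1e-6, 1e6)
    xatol: float = 1e-4
    fatol: float = 1e-7
    maxiter: int = 400
    diagnostics: bool = True
    hessian_step: float = 5e-3
    warm_start: np.ndarray | None = None  # free-parameter vector (log scale)


@dataclass
class OUFit:
    """One fitted model: ML parameters, fit statistics and diagnostics."""

    model: str
    params: OUParams
    lnL: float
    p: int
    n: int
    aicc: float
    half_life: np.ndarray
    stationary_variance: np.ndarray
    hessian_eigenvalues: np.ndarray | None = None
    diagnostic_pass: bool | None = None
    at_bound: bool = False
    # on ultrametric trees, shared-alpha models cannot separate theta0 from a
    # uniform shift of the optima (the theta0 weight column e^(-alpha T) 1 is
    # exactly collinear with the theta columns); the alias is resolved by the
    # stationary-start convention theta0 = theta of the root's regime
    theta0_aliased: bool = False
    n_restarts: int = 0
    free_optimum: np.ndarray = field(default_factory=lambda: np.zeros(0))
    weight: float | None = None


def aicc(lnL: float, p: int, n: int) -> float:
    """Small-sample Akaike criterion: -2 lnL + 2p + 2p(p+1)/(n-p-1)."""
    if n <= p + 1:
        raise ValueError(f"AICc undefined for n={n} <= p+1={p + 1}")
    return -2.0 * lnL + 2.0 * p + 2.0 * p * (p + 1.0) / (n - p - 1.0)


def aicc_weights(values: Iterable[float]) -> np.ndarray:
    """Akaike weights: w_i proportional to exp(-Delta_i / 2)."""
    vals = np.asarray(list(values), dtype=float)
    d = vals - vals.min()
    w = np.exp(-0.5 * d)
    return w / w.sum()


def half_life(alpha: np.ndarray) -> np.ndarray:
    """Phylogenetic half-life ln(2)/alpha per regime (inf under Brownian)."""
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    with np.errstate(divide="ignore"):
        return np.where(alpha > 0, np.log(2.0) / alpha, np.inf)


def stationary_variance(alpha: np.ndarray, sigma2: np.ndarray) -> np.ndarray:
    """Stationary (equilibrium) variance sigma^2/(2 alpha) per regime."""
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    sigma2 = np.atleast_1d(np.asarray(sigma2, dtype=float))
    with np.errstate(divide="ignore"):
        return np.where(alpha > 0, sigma2 / (2.0 * alpha), np.inf)


def _free_layout(model: str, k: int) -> tuple[int, int]:
    """Number of free log-alpha entries and log-sigma-ratio entries."""
    amode, smode, _ = MODELS[model]
    na = {"zero": 0, "shared": 1, "per": k}[amode]
    ns = {"shared": 0, "per": k - 1}[smode]
    return na, ns


def _expand_free(model: str, k: int, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Free vector (log alphas, log sigma ratios) -> per-regime alpha and
    relative sigma^2 (first regime fixed at 1)."""
    amode, smode, _ = MODELS[model]
    na, _ = _free_layout(model, k)
    if amode == "zero":
        alpha = np.zeros(k)
    elif amode == "shared":
        alpha = np.full(k, np.exp(x[0]))
    else:
        alpha = np.exp(x[:k])
    if smode == "shared":
        rel = np.ones(k)
    else:
        rel = np.concatenate([[1.0], np.exp(x[na:])])
    return alpha, rel


def _profiled_nll(
    tree: Phylo,
    painting: RegimePainting,
    y: np.ndarray,
    model: str,
    x: np.ndarray,
    alias_theta0: bool = False,
) -> tuple[float, np.ndarray, float]:
    """Negative lnL at free vector x, profiling the mean parameters (GLS)
    and the overall sigma^2 scale; returns (nll, beta, sigma2_scale).

    With ``alias_theta0`` the theta0 column is folded into the root regime's
    optimum column (stationary-start convention; see OUFit.theta0_aliased).
    The fold is also applied when theta0 is *effectively* unidentifiable at
    this alpha — every tip's root weight e^(-alpha path) below 1e-2 — which
    is the per-regime-alpha analogue of the structural alias.
    Returns (nll, beta, sigma2_scale, folded).
    """
    k = painting.n_regimes
    alpha, rel = _expand_free(model, k, x)
    tmode = MODELS[model][2]
    logD, v, X = _structures(tree, painting, alpha, rel, tmode)
    folded = False
    if tmode != "none" and (alias_theta0 or X[:, 0].max() < 1e-2):
        folded = True
        if tmode == "shared":
            X = (X[:, 0] + X[:, 1])[:, None]
        else:
            root_reg = int(painting.regime[tree.root])
            X = X.copy()
            X[:, 1 + root_reg] += X[:, 0]
            X = X[:, 1:]
    C = _tip_cov(tree, logD, v)
    n = y.size
    idx = np.arange(n)
    C[idx, idx] += 1e-10 * float(C[idx, idx].mean())
    try:
        L = scipy.linalg.cholesky(C, lower=True, check_finite=False, overwrite_a=True)
    except scipy.linalg.LinAlgError:
        return np.inf, np.zeros(1), np.nan, folded
    W = scipy.linalg.solve_triangular(L, X, lower=True, check_finite=False)
    z = scipy.linalg.solve_triangular(L, y, lower=True, check_finite=False)
    beta, *_ = np.linalg.lstsq(W, z, rcond=None)
    resid = z - W @ beta
    rss = float(resid @ resid)
    if rss <= 0:
        rss = 1e-300
    s_hat = rss / n
    nll = 0.5 * n * (np.log(2.0 * np.pi * s_hat) + 1.0) + float(
        np.log(np.diag(L)).sum()
    )
    return nll, beta, s_hat, folded


def _assemble_params(
    model: str,
    k: int,
    x: np.ndarray,
    beta: np.ndarray,
    s_hat: float,
    alias_theta0: bool = False,
    root_reg: int = 0,
) -> OUParams:
    alpha, rel = _expand_free(model, k, x)
    tmode = MODELS[model][2]
    if tmode == "none":
        theta0 = float(beta[0])
        theta = np.full(k, theta0)
    elif alias_theta0:
        if tmode == "shared":
            theta = np.full(k, float(beta[0]))
        else:
            theta = np.asarray(beta[:k], dtype=float)
        theta0 = float(theta[root_reg])
    elif tmode == "shared":
        theta0 = float(beta[0])
        theta = np.full(k, float(beta[1]))
    else:
        theta0 = float(beta[0])
        theta = np.asarray(beta[1 : 1 + k], dtype=float)
    return OUParams(
        model=model, theta0=theta0, theta=theta, alpha=alpha, sigma2=s_hat * rel
    )


def fit_model(
    tree: Phylo,
    painting: RegimePainting,
    trait: np.ndarray | Mapping[str, float],
    model: str,
    config: FitConfig | None = None,
) -> OUFit:
    """Maximum-likelihood fit of one model to per-tip trait values.

    ``trait`` is an array in tip order or a mapping tip label -> value.
    Optimization runs over log alphas and log sigma^2 ratios only (mean
    parameters and the sigma^2 scale are profiled); seeded multi-restart with
    the best optimum kept.  Derived quantities (AICc, half-life, stationary
    variance) and the Hessian diagnostic are filled in.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model id {model!r}")
    cfg = config or FitConfig()
    if isinstance(trait, Mapping):
        missing = [t for t in tree.tips if t not in trait]
        if missing:
            raise ValueError(f"trait missing for tips {missing[:5]}")
        y = np.array([trait[t] for t in tree.tips], dtype=float)
    else:
        y = np.asarray(trait, dtype=float)
        if y.size != tree.n_tips:
            raise ValueError("trait length must equal the number of tips")
    k = painting.n_regimes
    na, ns = _free_layout(model, k)
    dim = na + ns
    la_lo, la_hi = np.log(cfg.alpha_bounds)
    lr_lo, lr_hi = np.log(cfg.ratio_bounds)
    alias = MODELS[model][0] == "shared" and tree.is_ultrametric(1e-6)

    def nll(x: np.ndarray) -> float:
        return _profiled_nll(tree, painting, y, model, x, alias)[0]

    depth = float(tree.node_depths()[: tree.n_tips].mean())
    rng = np.random.default_rng(cfg.seed)
    best_x = np.zeros(dim)
    n_done = 0
    if dim == 0:
        pass
    elif dim == 1 and na == 1:
        res = scipy.optimize.minimize_scalar(
            lambda u: nll(np.array([u])),
            bounds=(la_lo, la_hi),
            method="bounded",
            options={"xatol": cfg.xatol},
        )
        best_x = np.array([res.x])
        n_done = 1
    elif dim == 1:
        res = scipy.optimize.minimize_scalar(
            lambda u: nll(np.array([u])),
            bounds=(lr_lo, lr_hi),
            method="bounded",
            options={"xatol": cfg.xatol},
        )
        best_x = np.array([res.x])
        n_done = 1
    else:
        lo = np.concatenate([np.full(na, la_lo), np.full(ns, lr_lo)])
        hi = np.concatenate([np.full(na, la_hi), np.full(ns, lr_hi)])
        # cfg.n_restarts counts non-warm starts (heuristic first, then seeded
        # random draws); a warm start, when supplied, is always tried and may
        # stand alone (n_restarts=0)
        starts = []
        if cfg.warm_start is not None:
            starts.append(np.clip(np.asarray(cfg.warm_start, dtype=float), lo, hi))
            n_starts = len(starts) + max(cfg.n_restarts, 0)
        else:
            n_starts = max(cfg.n_restarts, 1)
        # heuristic: pull with half-life of half the tree depth, equal rates
        h = np.concatenate(
            [np.full(na, np.log(np.log(2.0) / max(depth / 2.0, 1e-6))),
             np.zeros(ns)]
        )
        starts.append(np.clip(h, lo, hi))
        while len(starts) < n_starts:
            starts.append(lo + (hi - lo) * 0.1 + rng.uniform(size=dim) * (hi - lo) * 0.5)
        best_f = np.inf
        for x0 in starts[:n_starts]:
            res = scipy.optimize.minimize(
                nll,
                x0,
                method="Nelder-Mead",
                bounds=list(zip(lo, hi)),
                options={
                    "xatol": cfg.xatol,
                    "fatol": cfg.fatol,
                    "maxiter": cfg.maxiter,
                },
            )
            n_done += 1
            if res.fun < best_f:
                best_f = res.fun
                best_x = np.asarray(res.x)

    f, beta, s_hat, folded = _profiled_nll(tree, painting, y, model, best_x, alias)
    if not np.isfinite(f):
        raise RuntimeError(f"{model}: likelihood not finite at optimum")
    params = _assemble_params(
        model, k, best_x, beta, s_hat, folded, int(painting.regime[tree.root])
    )
    at_bound = False
    if na:
        at_bound = bool(
            np.any(np.abs(best_x[:na] - la_lo) < 1e-3)
            or np.any(np.abs(best_x[:na] - la_hi) < 1e-3)
        )
    p = n_free_params(model, k)
    n = y.size
    fit = OUFit(
        model=model,
        params=params,
        lnL=-f,
        p=p,
        n=n,
        aicc=aicc(-f, p, n),
        half_life=half_life(params.alpha),
        stationary_variance=stationary_variance(params.alpha, params.sigma2),
        at_bound=at_bound,
        n_restarts=n_done,
        free_optimum=best_x.copy(),
        theta0_aliased=folded,
    )
    if cfg.diagnostics:
        hessian_check(tree, painting, y, fit, step=cfg.hessian_step)
    return fit


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def _full_vector(fit: OUFit) -> tuple[np.ndarray, list[str]]:
    """Flatten the model's identifiable quantities into one vector for the
    Hessian (theta0 is omitted when structurally aliased)."""
    model = fit.model
    amode, smode, tmode = MODELS[model]
    k = fit.params.theta.size
    if fit.theta0_aliased:
        names, vals = [], []
    else:
        names = ["theta0"]
        vals = [fit.params.theta0]
    if tmode == "shared":
        names += ["theta"]
        vals += [float(fit.params.theta[0])]
    elif tmode == "per":
        names += [f"theta_{i}" for i in range(k)]
        vals += list(fit.params.theta)
    if amode == "shared":
        names += ["alpha"]
        vals += [float(fit.params.alpha[0])]
    elif amode == "per":
        names += [f"alpha_{i}" for i in range(k)]
        vals += list(fit.params.alpha)
    if smode == "shared":
        names += ["sigma2"]
        vals += [float(fit.params.sigma2[0])]
    else:
        names += [f"sigma2_{i}" for i in range(k)]
        vals += list(fit.params.sigma2)
    return np.asarray(vals, dtype=float), names


def _params_from_vector(
    model: str, k: int, vec: np.ndarray, alias: bool = False, root_reg: int = 0
) -> OUParams:
    amode, smode, tmode = MODELS[model]
    i = 0
    if alias:
        theta0 = None
    else:
        theta0 = vec[i]
        i += 1
    if tmode == "none":
        theta = np.full(k, theta0)
    elif tmode == "shared":
        theta = np.full(k, vec[i])
        i += 1
    else:
        theta = vec[i : i + k].copy()
        i += k
    if theta0 is None:
        theta0 = float(theta[root_reg])
    if amode == "zero":
        alpha = np.zeros(k)
    elif amode == "shared":
        alpha = np.full(k, vec[i])
        i += 1
    else:
        alpha = vec[i : i + k].copy()
        i += k
    if smode == "shared":
        sigma2 = np.full(k, vec[i])
    else:
        sigma2 = vec[i : i + k].copy()
    return OUParams(model=model, theta0=theta0, theta=theta, alpha=alpha, sigma2=sigma2)


def central_hessian(f, x0: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Central-difference Hessian of a scalar function with per-coordinate
    steps ``h``."""
    m = x0.size
    H = np.empty((m, m))
    f0 = f(x0)
    for i in range(m):
        e = np.zeros(m)
        e[i] = h[i]
        H[i, i] = (f(x0 + e) - 2.0 * f0 + f(x0 - e)) / h[i] ** 2
    for i in range(m):
        for j in range(i + 1, m):
            ei = np.zeros(m)
            ej = np.zeros(m)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def hessian_check(
    tree: Phylo,
    painting: RegimePainting,
    trait: np.ndarray,
    fit: OUFit,
    step: float = 5e-3,
) -> OUFit:
    """Central-difference Hessian of -lnL over the full parameter vector at
    the optimum; the fit passes iff all eigenvalues are > 0 and no alpha sits
    on its optimization bound.  Updates and returns ``fit``."""
    y = np.asarray(trait, dtype=float)
    k = painting.n_regimes
    x0, _ = _full_vector(fit)
    m = x0.size
    # positive-constrained entries (alphas, sigma2s) must stay positive
    n_mean = {"none": 1, "shared": 2, "per": 1 + k}[MODELS[fit.model][2]]
    if fit.theta0_aliased:
        n_mean -= 1
    positive = np.zeros(m, dtype=bool)
    positive[n_mean:] = True
    root_reg = int(painting.regime[tree.root])

    def f(vec: np.ndarray) -> float:
        pars = _params_from_vector(fit.model, k, vec, fit.theta0_aliased, root_reg)
        if np.any(pars.sigma2 <= 0) or np.any(pars.alpha < 0):
            return np.inf
        mean, cov = ou_moments(tree, painting, pars)
        try:
            return -ou_loglik(y, mean, cov)
        except np.linalg.LinAlgError:
            return np.inf

    h = step * np.maximum(np.abs(x0), 1.0)
    h = np.where(positive & (x0 > 0), np.minimum(h, 0.45 * np.abs(x0)), h)
    H = central_hessian(f, x0, h)
    if not np.all(np.isfinite(H)):
        fit.hessian_eigenvalues = np.full(m, -np.inf)
        fit.diagnostic_pass = False
        return fit
    w = np.linalg.eigvalsh(0.5 * (H + H.T))
    fit.hessian_eigenvalues = w
    fit.diagnostic_pass = bool(w.min() > 0.0) and not fit.at_bound
    return fit


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def compare_models(
    tree: Phylo,
    painting: RegimePainting,
    trait: np.ndarray | Mapping[str, float],
    models: Sequence[str] | None = None,
    config: FitConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, OUFit]]:
    """Fit a model set and rank by AICc.

    Fits failing the Hessian diagnostic are retained in the table (flagged)
    but excluded from the Akaike-weight computation, mirroring the exclusion
    of diagnostically failing fits from model comparison.
    Returns (comparison table sorted by AICc, fits by model id).
    """
    models = list(models) if models is not None else list(MODELS)
    fits: dict[str, OUFit] = {}
    for m in models:
        fits[m] = fit_model(tree, painting, trait, m, config)
    ok = [m for m in models if fits[m].diagnostic_pass is not False]
    if ok:
        w = aicc_weights([fits[m].aicc for m in ok])
        for m, wi in zip(ok, w):
            fits[m].weight = float(wi)
    rows = []
    for m in models:
        fit = fits[m]
        row: dict[str, object] = {
            "model": m,
            "lnL": fit.lnL,
            "p": fit.p,
            "AICc": fit.aicc,
            "weight": fit.weight if fit.weight is not None else np.nan,
            "diagnostic_pass": fit.diagnostic_pass,
            "theta0": fit.params.theta0,
        }
        for i, lab in enumerate(painting.labels):
            row[f"theta[{lab}]"] = fit.params.theta[i]
            row[f"alpha[{lab}]"] = fit.params.alpha[i]
            row[f"sigma2[{lab}]"] = fit.params.sigma2[i]
            row[f"half_life[{lab}]"] = fit.half_life[i]
            row[f"stat_var[{lab}]"] = fit.stationary_variance[i]
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("AICc", kind="mergesort").reset_index(drop=True)
    best = table.loc[table["diagnostic_pass"] != False, "AICc"]  # noqa: E712
    ref = best.min() if len(best) else table["AICc"].min()
    table.insert(4, "dAICc", table["AICc"] - ref)
    return table, fits
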