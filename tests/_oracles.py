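"""Independent brute-force oracles used by the test suite.

Everything here deliberately avoids the package's fast code paths: discrete
likelihoods are computed by exhaustive enumeration over internal-state
assignments with per-branch matrix exponentials, OU moments by plain forward
Monte-Carlo summaries, Gaussian densities by the dense formula with an
explicit inverse and determinant, and percentile intervals by hand-rolled
sort-and-interpolate indexing.
"""

from __future__ import annotations

import itertools

import numpy as np
import scipy.linalg

from climniche.phylo import Phylo


def enum_mk_root_conditionals(tree: Phylo, tipL: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """L_s(root) by summing over all internal-state assignments."""
    S = Q.shape[0]
    P = [scipy.linalg.expm(Q * t) for t in tree.blen]
    internals = [v for v in range(tree.n_tips, tree.n_nodes)]
    rootL = np.zeros(S)
    for assign in itertools.product(range(S), repeat=len(internals)):
        state = {v: s for v, s in zip(internals, assign)}
        like = 1.0
        for v in range(tree.n_nodes - 1):  # every non-root node's branch
            ps = state[tree.parent[v]]
            if v < tree.n_tips:
                like *= sum(P[v][ps, s] * tipL[v, s] for s in range(S))
            else:
                like *= P[v][ps, state[v]]
        rootL[state[tree.root]] += like
    return rootL


def enum_mk_loglik(tree: Phylo, tipL: np.ndarray, Q: np.ndarray,
                   root_mode="maddfitz") -> float:
    rootL = enum_mk_root_conditionals(tree, tipL, Q)
    S = Q.shape[0]
    if root_mode == "maddfitz":
        w = rootL / rootL.sum()
    elif root_mode == "flat":
        w = np.full(S, 1.0 / S)
    else:
        w = np.asarray(root_mode, dtype=float)
    return float(np.log(w @ rootL))


def enum_mk_marginals(tree: Phylo, tipL: np.ndarray, Q: np.ndarray,
                      root_mode="maddfitz") -> np.ndarray:
    """Marginal state probabilities at every node by enumeration, with root
    weights frozen at their full-data values."""
    S = Q.shape[0]
    rootL = enum_mk_root_conditionals(tree, tipL, Q)
    if root_mode == "maddfitz":
        w = rootL / rootL.sum()
    elif root_mode == "flat":
        w = np.full(S, 1.0 / S)
    else:
        w = np.asarray(root_mode, dtype=float)
    P = [scipy.linalg.expm(Q * t) for t in tree.blen]
    internals = [v for v in range(tree.n_tips, tree.n_nodes)]
    nt = tree.n_tips
    marg = np.zeros((tree.n_nodes, S))
    # enumerate internal assignments; tip states are summed out analytically
    # (tips are conditionally independent given their parent's state)
    for assign in itertools.product(range(S), repeat=len(internals)):
        state = {v: s for v, s in zip(internals, assign)}
        base = w[state[tree.root]]
        for v in internals:
            if v != tree.root:
                base *= P[v][state[tree.parent[v]], state[v]]
        tipfac = [
            sum(P[v][state[tree.parent[v]], s] * tipL[v, s] for s in range(S))
            for v in range(nt)
        ]
        total = base * np.prod(tipfac)
        for v in internals:
            marg[v, state[v]] += total
        for v in range(nt):
            others = base * np.prod([tipfac[u] for u in range(nt) if u != v])
            ps = state[tree.parent[v]]
            for s in range(S):
                marg[v, s] += others * P[v][ps, s] * tipL[v, s]
    return marg / marg.sum(axis=1, keepdims=True)


def random_constrained_rates(rng: np.random.Generator) -> np.ndarray:
    """Four free rates on a broad log scale."""
    return np.exp(rng.uniform(np.log(0.05), np.log(3.0), size=4))


def dense_mvn_loglik(y: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """Dense-formula Gaussian log-density with explicit inverse and det."""
    n = y.size
    diff = y - mean
    inv = np.linalg.inv(cov)
    sign, logdet = np.linalg.slogdet(cov)
    assert sign > 0
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet + diff @ inv @ diff))


def sort_index_percentile(values: np.ndarray, q: float) -> float:
    """Percentile by explicit sort and linear interpolation on ranks."""
    x = np.sort(np.asarray(values, dtype=float))
    pos = q / 100.0 * (x.size - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return float(x[lo] * (1 - frac) + x[hi] * frac)


def mc_tip_moments(tip_values: np.ndarray):
    """Sample mean/cov of forward simulations plus standard errors.

    Returns (mean, mean_se, cov, cov_se) where cov_se uses the Gaussian
    approximation SE(c_ij) = sqrt((c_ii c_jj + c_ij^2) / n).
    """
    n = tip_values.shape[0]
    mean = tip_values.mean(axis=0)
    cov = np.cov(tip_values, rowvar=False)
    cov = np.atleast_2d(cov)
    var = np.diag(cov)
    mean_se = np.sqrt(var / n)
    cov_se = np.sqrt((np.outer(var, var) + cov**2) / n)
    return mean, mean_se, cov, cov_se
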