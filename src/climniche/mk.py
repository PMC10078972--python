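"""Constrained Mk models and marginal ancestral-state reconstruction.

The default character is the 3-state canopy habitat coding (closed, both,
open).  Transitions are all-rates-different (ARD) with structural zeros
prohibiting direct closed <-> open changes: a lineage must pass through the
generalist "both" state, so the rate matrix has 4 free parameters.

Likelihood is the standard pruning recursion with per-node rescaling; branch
transition kernels are matrix exponentials (scaling-and-squaring, batched
over branches).  Root handling supports a flat prior, a fixed prior, and the
"maddfitz" weighting in which each root state is weighted by its own
conditional likelihood (FitzJohn-Maddison-Otto).  Marginal reconstructions
combine the downward partials with an upward pass under root weights frozen
at their full-data values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg
import scipy.optimize

from .phylo import Phylo

__all__ = [
    "RateMatrixSpec",
    "canopy_rate_spec",
    "binary_ard_spec",
    "build_Q",
    "mk_loglik",
    "fit_mk",
    "marginal_asr",
    "MkFit",
    "AsrResult",
    "tip_state_matrix",
]

RATE_BOUNDS = (1e-9, 100.0)  # events/Ma


@dataclass(frozen=True)
class RateMatrixSpec:
    """Which off-diagonal rates exist and which are structural zeros.

    ``index[i, j] >= 0`` gives the free-parameter slot for the i -> j rate;
    ``-1`` marks a prohibited (structurally zero) transition.
    """

    states: tuple[str, ...]
    index: np.ndarray

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_params(self) -> int:
        return int(self.index.max()) + 1

    def state_index(self, label: str) -> int:
        return self.states.index(label)


def canopy_rate_spec() -> RateMatrixSpec:
    """ARD spec over (closed, both, open) with direct closed <-> open
    transitions prohibited; 4 free rates."""
    idx = np.array(
        [
            [-1, 0, -1],
            [1, -1, 2],
            [-1, 3, -1],
        ],
        dtype=np.int64,
    )
    return RateMatrixSpec(states=("closed", "both", "open"), index=idx)


def binary_ard_spec(states: tuple[str, str] = ("ground", "arboreal")) -> RateMatrixSpec:
    """ARD spec for a binary character (2 free rates); used for the nesting
    character whose ancestral states paint the OU regimes."""
    idx = np.array([[-1, 0], [1, -1]], dtype=np.int64)
    return RateMatrixSpec(states=states, index=idx)


def build_Q(rates: Sequence[float], spec: RateMatrixSpec) -> np.ndarray:
    """Assemble the generator: prohibited cells exactly 0, diagonal = minus
    the row sum of off-diagonals."""
    rates = np.asarray(rates, dtype=float)
    if rates.size != spec.n_params:
        raise ValueError(f"expected {spec.n_params} rates, got {rates.size}")
    if np.any(rates < 0):
        raise ValueError("rates must be >= 0")
    S = spec.n_states
    Q = np.zeros((S, S))
    for i in range(S):
        for j in range(S):
            if i != j and spec.index[i, j] >= 0:
                Q[i, j] = rates[spec.index[i, j]]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def tip_state_matrix(
    tree: Phylo,
    tip_states: Mapping[str, str | set[str] | frozenset[str]],
    states: Sequence[str],
) -> np.ndarray:
    """0/1 matrix (n_tips x S): 1 where the tip is compatible with a state.

    A tip may carry a single label, a set of labels (ambiguity), or the
    string form ``"a&b"``.
    """
    S = len(states)
    pos = {s: i for i, s in enumerate(states)}
    out = np.zeros((tree.n_tips, S))
    for i, label in enumerate(tree.tips):
        if label not in tip_states:
            raise ValueError(f"no state for tip {label!r}")
        val = tip_states[label]
        if isinstance(val, str):
            parts = val.split("&")
        else:
            parts = list(val)
        if not parts:
            raise ValueError(f"empty state set for tip {label!r}")
        for s in parts:
            out[i, pos[s]] = 1.0
    return out


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def _branch_kernels(tree: Phylo, Q: np.ndarray) -> np.ndarray:
    P = scipy.linalg.expm(Q[None, :, :] * tree.blen[:, None, None])
    if not np.all(np.isfinite(P)):
        raise FloatingPointError("non-finite transition kernel on some branch")
    return np.clip(P, 0.0, None)


def _down_pass(
    tree: Phylo, tipL: np.ndarray, P: np.ndarray
) -> tuple[np.ndarray, float]:
    """Conditional likelihoods at every node (rescaled) and the summed log
    scaling factor."""
    S = tipL.shape[1]
    L = np.ones((tree.n_nodes, S))
    L[: tree.n_tips] = tipL
    logscale = 0.0
    for v in tree.postorder:
        if v < tree.n_tips:
            continue
        acc = np.ones(S)
        for c in tree.children(v):
            acc = acc * (P[c] @ L[c])
        m = acc.max()
        if m <= 0:
            raise FloatingPointError("zero likelihood at an internal node")
        L[v] = acc / m
        logscale += np.log(m)
    return L, logscale


def _root_weights(rootL: np.ndarray, root_mode, S: int) -> np.ndarray:
    if root_mode == "maddfitz":
        tot = rootL.sum()
        if tot <= 0:
            raise FloatingPointError("all root conditional likelihoods are zero")
        return rootL / tot
    if root_mode == "flat":
        return np.full(S, 1.0 / S)
    pi = np.asarray(root_mode, dtype=float)
    if pi.shape != (S,) or abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("fixed root prior must be a probability vector over states")
    return pi


def mk_loglik(
    tree: Phylo,
    tipL: np.ndarray,
    Q: np.ndarray,
    root_mode: str | np.ndarray = "maddfitz",
) -> float:
    """Pruning log-likelihood.

    ``tipL`` is the 0/1 tip compatibility matrix (see ``tip_state_matrix``).
    ``root_mode`` is ``"maddfitz"`` (root weights proportional to the root
    conditionals themselves), ``"flat"``, or an explicit prior vector; the
    returned value is ``log sum_s w_s L_s(root)``.
    """
    P = _branch_kernels(tree, Q)
    L, logscale = _down_pass(tree, tipL, P)
    rootL = L[tree.root]
    w = _root_weights(rootL, root_mode, tipL.shape[1])
    tot = float(w @ rootL)
    if tot <= 0:
        raise FloatingPointError("zero total likelihood at the root")
    return float(np.log(tot) + logscale)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class MkFit:
    """ML rates (events/Ma) for a constrained Mk model."""

    spec: RateMatrixSpec
    rates: np.ndarray
    lnL: float
    Q: np.ndarray
    converged: bool
    n_restarts: int
    root_mode: str = "maddfitz"


def fit_mk(
    tree: Phylo,
    tip_states: Mapping[str, str | set[str]],
    spec: RateMatrixSpec,
    root_mode: str | np.ndarray = "maddfitz",
    n_restarts: int = 10,
    seed: int = 0,
) -> MkFit:
    """Maximize the pruning likelihood over the free rates.

    Rates are optimized on the log scale within ``RATE_BOUNDS`` by bounded
    quasi-Newton from ``n_restarts`` seeded log-uniform starting points; the
    best converged optimum is kept.
    """
    tipL = tip_state_matrix(tree, tip_states, spec.states)
    lo, hi = np.log(RATE_BOUNDS[0]), np.log(RATE_BOUNDS[1])

    def nll(logr: np.ndarray) -> float:
        Q = build_Q(np.exp(logr), spec)
        try:
            return -mk_loglik(tree, tipL, Q, root_mode)
        except FloatingPointError:
            return np.inf

    rng = np.random.default_rng(seed)
    # expected total change of order 1 per unit depth is a sane center
    depth = float(tree.node_depths()[: tree.n_tips].mean())
    center = np.log(1.0 / max(depth, 1e-9))
    best = None
    n_conv = 0
    for r in range(max(n_restarts, 1)):
        if r == 0:
            x0 = np.full(spec.n_params, center)
        else:
            x0 = rng.uniform(center - 4.0, center + 2.0, size=spec.n_params)
        x0 = np.clip(x0, lo, hi)
        res = scipy.optimize.minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=[(lo, hi)] * spec.n_params,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if np.isfinite(res.fun):
            n_conv += 1
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise RuntimeError(
            f"all {n_restarts} optimizer restarts failed to produce a finite "
            "likelihood; check the character and tree"
        )
    rates = np.exp(best.x)
    return MkFit(
        spec=spec,
        rates=rates,
        lnL=-float(best.fun),
        Q=build_Q(rates, spec),
        converged=bool(best.success),
        n_restarts=n_conv,
        root_mode=root_mode if isinstance(root_mode, str) else "fixed",
    )


# ---------------------------------------------------------------------------
# marginal reconstruction
# ---------------------------------------------------------------------------

@dataclass
class AsrResult:
    """Per-node marginal state probabilities.

    ``marginals[v]`` is the probability vector over states for node ``v``
    (internal nodes and tips); ``root`` is the root's vector.  Vectors sum
    to 1.
    """

    states: tuple[str, ...]
    marginals: np.ndarray
    root: np.ndarray = field(init=False)
    method: str = "maddfitz"

    def __post_init__(self) -> None:
        self.root = self.marginals[-1]

    def most_probable(self) -> np.ndarray:
        return self.marginals.argmax(axis=1)


def marginal_asr(
    tree: Phylo,
    tip_states: Mapping[str, str | set[str]] | np.ndarray,
    Q: np.ndarray,
    root_mode: str | np.ndarray = "maddfitz",
    states: Sequence[str] | None = None,
) -> AsrResult:
    """Marginal ancestral states by one down-pass plus one up-pass.

    For node v and state s the marginal is proportional to
    ``down_v(s) * up_v(s)``: the probability of the data below v given s,
    times the probability of the rest of the data with the root weighted by
    the (frozen, full-data) root weights.  Under the maddfitz mode the root's
    own marginal is proportional to the squared root conditionals.
    """
    S = Q.shape[0]
    if states is None:
        states = tuple(f"s{i}" for i in range(S))
    if isinstance(tip_states, np.ndarray):
        tipL = tip_states
    else:
        tipL = tip_state_matrix(tree, tip_states, states)
    P = _branch_kernels(tree, Q)
    L, _ = _down_pass(tree, tipL, P)
    w = _root_weights(L[tree.root], root_mode, S)

    up = np.zeros_like(L)
    up[tree.root] = w
    for v in tree.preorder:
        ch = tree.children(v)
        for c in ch:
            sib = np.ones(S)
            for b in ch:
                if b != c:
                    sib = sib * (P[b] @ L[b])
            msg = (up[v] * sib) @ P[c]
            tot = msg.sum()
            up[c] = msg / tot if tot > 0 else msg
    marg = L * up
    sums = marg.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise FloatingPointError("zero marginal at some node")
    marg = marg / sums
    return AsrResult(
        states=tuple(states),
        marginals=marg,
        method=root_mode if isinstance(root_mode, str) else "fixed",
    )
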