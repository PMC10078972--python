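"""Forward simulators with known ground truth.

Every downstream stage of the pipeline (occurrence cleaning, canopy coding,
Mk ancestral states, multi-regime OU fitting, parametric bootstrap) is tested
against data produced here, so the generators are exact rather than
approximate:

* birth-death trees are grown by the simple forward algorithm (exponential
  waiting times, retry on whole-clade extinction);
* discrete characters evolve by sampling from the exact transition kernel
  ``expm(Q t)`` branch by branch;
* continuous traits evolve by the exact one-step Ornstein-Uhlenbeck
  transition per branch segment (no Euler discretization), falling back to
  the Brownian-motion limit when ``alpha * t`` underflows.

All generators are seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import scipy.linalg

from .ou import OUParams, RegimePainting
from .phylo import Phylo

__all__ = ["SimTruth", "simulate_tree", "simulate_discrete", "simulate_ou"]

_MAX_TREE_RETRIES = 1000
# below this, the OU one-step moments are numerically 0/0; use the BM limit
_BM_SWITCH = 1e-8


@dataclass
class SimTruth:
    """Ground truth carried alongside simulated data.

    ``node_states`` holds the discrete state index at every node (tips
    included) for Mk simulations; ``tip_values`` holds continuous trait
    values, shape ``(n_reps, n_tips)``, for OU simulations.
    """

    seed: int
    params: dict[str, Any] = field(default_factory=dict)
    node_states: np.ndarray | None = None
    tip_values: np.ndarray | None = None

    def tip_state_map(self, tree: Phylo, labels: list[str]) -> dict[str, str]:
        if self.node_states is None:
            raise ValueError("no discrete states in this SimTruth")
        return {tree.tips[i]: labels[self.node_states[i]] for i in range(tree.n_tips)}


# ---------------------------------------------------------------------------
# birth-death trees
# ---------------------------------------------------------------------------

def simulate_tree(
    n_tips: int,
    birth: float,
    death: float,
    seed: int,
    max_retries: int = _MAX_TREE_RETRIES,
) -> Phylo:
    """Simulate an ultrametric birth-death tree with exactly ``n_tips`` tips.

    The process starts from the root split (two lineages at time 0) and runs
    forward with per-lineage speciation rate ``birth`` and extinction rate
    ``death`` until exactly ``n_tips`` lineages are alive; the present is the
    (unrealized) next event time, so all pendant branches are positive.
    Extinct side branches are pruned and unifurcations suppressed.
    Whole-clade extinction triggers a retry; after ``max_retries`` failures a
    ``RuntimeError`` names the cap.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if not (birth > death >= 0):
        raise ValueError("require birth > death >= 0")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        tree = _grow_once(n_tips, birth, death, rng)
        if tree is not None:
            return tree
    raise RuntimeError(
        f"birth-death simulation went extinct in all {max_retries} retries"
    )


def _grow_once(n_tips: int, birth: float, death: float, rng) -> Phylo | None:
    total = birth + death
    # per-lineage records; lineages 0 and 1 are the basal split at time 0
    tstart = [0.0, 0.0]
    t_end = [np.nan, np.nan]
    kids: list[tuple[int, int] | None] = [None, None]
    alive = [0, 1]
    t = 0.0
    while len(alive) < n_tips:
        k = len(alive)
        t += rng.exponential(1.0 / (k * total))
        j = alive[rng.integers(k)]
        if rng.random() < birth / total:
            a, b = len(tstart), len(tstart) + 1
            tstart.extend([t, t])
            t_end.extend([np.nan, np.nan])
            kids.extend([None, None])
            kids[j] = (a, b)
            t_end[j] = t
            alive.remove(j)
            alive.extend([a, b])
        else:
            t_end[j] = t
            alive.remove(j)
            if not alive:
                return None
    # present = the next (unrealized) event time, so pendant branches are > 0
    present = t + rng.exponential(1.0 / (len(alive) * total))
    alive_set = set(alive)

    # prune to extant tips; spec = ("tip",) or ("int", split_time, sa, sb);
    # unifurcations vanish because branch lengths come from node times alone
    def prune(j: int) -> Any | None:
        if kids[j] is None:
            return ("tip",) if j in alive_set else None
        ra, rb = prune(kids[j][0]), prune(kids[j][1])
        if ra is None:
            return rb
        if rb is None:
            return ra
        return ("int", t_end[j], ra, rb)

    r0, r1 = prune(0), prune(1)
    if r0 is None or r1 is None:
        root_spec = r0 if r1 is None else r1
        if root_spec[0] == "tip":
            return None  # single surviving lineage cannot carry >= 2 tips
    else:
        root_spec = ("int", 0.0, r0, r1)

    rows: list[dict] = []  # filled postorder, root last

    def build(spec: tuple) -> int:
        if spec[0] == "tip":
            rows.append({"tip": True, "time": present})
        else:
            _, t_split, sa, sb = spec
            ia = build(sa)
            ib = build(sb)
            rows.append({"tip": False, "time": t_split, "ch": (ia, ib)})
        return len(rows) - 1

    build(root_spec)
    tip_rows = [i for i, r in enumerate(rows) if r["tip"]]
    int_rows = [i for i, r in enumerate(rows) if not r["tip"]]
    newid = {i: k for k, i in enumerate(tip_rows)}
    newid.update({i: len(tip_rows) + k for k, i in enumerate(int_rows)})
    n = len(rows)
    parent_arr = np.full(n, -1, dtype=np.int64)
    blen_arr = np.zeros(n)
    for i, r in enumerate(rows):
        if not r["tip"]:
            for c in r["ch"]:
                parent_arr[newid[c]] = newid[i]
                blen_arr[newid[c]] = rows[c]["time"] - r["time"]
    tips = [f"t{k + 1}" for k in range(len(tip_rows))]
    return Phylo(tips=tips, parent=parent_arr, blen=blen_arr)


# ---------------------------------------------------------------------------
# discrete characters (Mk forward simulation)
# ---------------------------------------------------------------------------

def simulate_discrete(
    tree: Phylo, Q: np.ndarray, root_probs: np.ndarray, seed: int
) -> SimTruth:
    """Evolve a discrete character down the tree under generator ``Q``.

    The root state is drawn from ``root_probs``; along each branch of length
    ``t`` the child state is drawn from the exact kernel ``expm(Q t)`` row of
    the parent state.  States at every node (internal and tip) are recorded.
    """
    Q = np.asarray(Q, dtype=float)
    root_probs = np.asarray(root_probs, dtype=float)
    S = Q.shape[0]
    if Q.shape != (S, S):
        raise ValueError("Q must be square")
    if root_probs.shape != (S,):
        raise ValueError("root_probs length must match Q dimension")
    if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-10):
        raise ValueError("Q rows must sum to 0")
    off = Q - np.diag(np.diag(Q))
    if np.any(off < -1e-12):
        raise ValueError("off-diagonal rates must be >= 0")
    if abs(root_probs.sum() - 1.0) > 1e-10 or np.any(root_probs < 0):
        raise ValueError("root_probs must be a probability vector")

    rng = np.random.default_rng(seed)
    P = scipy.linalg.expm(Q[None, :, :] * tree.blen[:, None, None])
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=2, keepdims=True)
    states = np.empty(tree.n_nodes, dtype=np.int64)
    for v in tree.preorder:
        p = tree.parent[v]
        if p < 0:
            states[v] = rng.choice(S, p=root_probs)
        else:
            states[v] = rng.choice(S, p=P[v, states[p]])
    return SimTruth(
        seed=seed,
        params={"Q": Q.tolist(), "root_probs": root_probs.tolist()},
        node_states=states,
    )


# ---------------------------------------------------------------------------
# multi-regime Ornstein-Uhlenbeck traits
# ---------------------------------------------------------------------------

def simulate_ou(
    tree: Phylo,
    painting: RegimePainting,
    params: OUParams,
    seed: int,
    n_reps: int = 1,
) -> SimTruth:
    """Evolve a continuous trait under a branch-painted OU process.

    The root value is exactly ``theta0``.  Along a branch of duration ``t``
    in regime ``k`` the value moves by the exact OU transition: mean
    ``x e^(-a t) + theta_k (1 - e^(-a t))`` and variance
    ``sigma2_k (1 - e^(-2 a t)) / (2 a)`` with ``a = alpha_k``; when
    ``a * t < 1e-8`` the Brownian limit (mean ``x``, variance
    ``sigma2_k t``) is used instead.  ``n_reps`` independent replicates share
    the tree and painting; returned ``tip_values`` has shape
    ``(n_reps, n_tips)``.
    """
    params.validate()
    if painting.regime.size != tree.n_nodes:
        raise ValueError("painting must cover every branch of the tree")
    rng = np.random.default_rng(seed)
    alpha = np.asarray(params.alpha, dtype=float)
    sigma2 = np.asarray(params.sigma2, dtype=float)
    theta = np.asarray(params.theta, dtype=float)

    x = np.empty((tree.n_nodes, n_reps))
    for v in tree.preorder:
        p = tree.parent[v]
        if p < 0:
            x[v] = params.theta0
            continue
        k = painting.regime[v]
        a, s2, th, t = alpha[k], sigma2[k], theta[k], tree.blen[v]
        if a * t < _BM_SWITCH:
            mean = x[p]
            var = s2 * t
        else:
            e = np.exp(-a * t)
            mean = x[p] * e + th * (1.0 - e)
            var = s2 * (1.0 - e * e) / (2.0 * a)
        x[v] = mean + np.sqrt(var) * rng.standard_normal(n_reps)
    return SimTruth(
        seed=seed,
        params={
            "model": params.model,
            "theta0": params.theta0,
            "theta": theta.tolist(),
            "alpha": alpha.tolist(),
            "sigma2": sigma2.tolist(),
        },
        tip_values=x[: tree.n_tips].T.copy(),
    )
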