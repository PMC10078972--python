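"""Parametric bootstrap of a fitted OU/BM model and CI-based comparisons.

Uncertainty follows the parametric recipe: simulate replicate tip datasets
under the fitted model at its ML parameters (50 replicates by default),
refit the same model to each, and take 2.5/97.5 percentile intervals of the
replicate estimates for every parameter and derived quantity (per-regime
half-life and stationary variance included).  Replicates whose refit fails
the Hessian diagnostic are dropped from the intervals (their count is
reported).  Between-regime differences are called significant when the two
95% intervals are disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .ou import FitConfig, OUFit, RegimePainting, fit_model, half_life, stationary_variance
from .phylo import Phylo
from .synthetic import simulate_ou

__all__ = ["BootstrapResult", "parametric_bootstrap", "ci_overlap", "regime_significance",
           "percentile_ci"]


def percentile_ci(values: np.ndarray, level: float = 95.0) -> tuple[float, float]:
    """Percentile confidence interval (linear-interpolation quantiles)."""
    lo = (100.0 - level) / 2.0
    a, b = np.percentile(np.asarray(values, dtype=float), [lo, 100.0 - lo])
    return float(a), float(b)


@dataclass
class BootstrapResult:
    """Replicate estimates, intervals and coverage flags for one fit."""

    model: str
    n_sims: int
    n_failed: int
    estimates: pd.DataFrame  # one row per surviving replicate
    cis: dict[str, tuple[float, float]]
    observed: dict[str, float]
    in_ci: dict[str, bool]
    seed: int
    regime_labels: list[str]


def _param_row(fit: OUFit, labels: list[str]) -> dict[str, float]:
    row = {"theta0": fit.params.theta0}
    for i, lab in enumerate(labels):
        row[f"theta[{lab}]"] = float(fit.params.theta[i])
        row[f"alpha[{lab}]"] = float(fit.params.alpha[i])
        row[f"sigma2[{lab}]"] = float(fit.params.sigma2[i])
        row[f"half_life[{lab}]"] = float(half_life(fit.params.alpha)[i])
        row[f"stat_var[{lab}]"] = float(
            stationary_variance(fit.params.alpha, fit.params.sigma2)[i]
        )
    return row


def parametric_bootstrap(
    tree: Phylo,
    painting: RegimePainting,
    fit: OUFit,
    n_sims: int = 50,
    seed: int = 0,
    config: FitConfig | None = None,
) -> BootstrapResult:
    """Simulate ``n_sims`` datasets under ``fit`` and refit its model.

    Refits warm-start from the original optimum (one extra seeded restart).
    More than 50% replicate failures aborts with an error.
    """
    labels = painting.labels
    base = config or FitConfig()
    warm = fit.free_optimum.copy() if fit.free_optimum.size else None
    # refits warm-start from the original optimum; replicates that fail the
    # diagnostic get one retry with fresh (heuristic + random) starts before
    # being dropped
    cfg = replace(base, warm_start=warm, n_restarts=0, seed=seed)
    retry_cfg = replace(base, warm_start=warm, n_restarts=2, seed=seed + 1)
    sims = simulate_ou(tree, painting, fit.params, seed=seed, n_reps=n_sims)
    rows = []
    n_failed = 0
    for r in range(n_sims):
        y = sims.tip_values[r]
        refit = None
        for attempt_cfg in (cfg, retry_cfg):
            try:
                refit = fit_model(tree, painting, y, fit.model, attempt_cfg)
            except (RuntimeError, np.linalg.LinAlgError):
                refit = None
                continue
            if refit.diagnostic_pass is not False:
                break
        if refit is None or refit.diagnostic_pass is False:
            n_failed += 1
            continue
        rows.append(_param_row(refit, labels))
    if n_failed > n_sims / 2:
        raise RuntimeError(
            f"{n_failed}/{n_sims} bootstrap replicates failed refitting or "
            "diagnostics"
        )
    est = pd.DataFrame(rows)
    observed = _param_row(fit, labels)
    cis = {}
    in_ci = {}
    for name in est.columns:
        vals = est[name].to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size == 0 or finite.size < vals.size:
            # infinite replicate estimates (Brownian limits) make percentile
            # bounds infinite; keep them as such
            cis[name] = percentile_ci(vals) if vals.size else (np.nan, np.nan)
        else:
            cis[name] = percentile_ci(vals)
        lo, hi = cis[name]
        in_ci[name] = bool(lo <= observed[name] <= hi)
    return BootstrapResult(
        model=fit.model,
        n_sims=n_sims,
        n_failed=n_failed,
        estimates=est,
        cis=cis,
        observed=observed,
        in_ci=in_ci,
        seed=seed,
        regime_labels=list(labels),
    )


def ci_overlap(ci_a: tuple[float, float], ci_b: tuple[float, float]) -> bool:
    """True iff the two closed 95% intervals are disjoint, the operational
    definition of a significant between-regime difference; intervals sharing
    an endpoint are not significant."""
    (a_lo, a_hi), (b_lo, b_hi) = ci_a, ci_b
    if a_lo > a_hi or b_lo > b_hi:
        raise ValueError("interval bounds out of order")
    return bool(a_hi < b_lo or b_hi < a_lo)


def regime_significance(result: BootstrapResult) -> dict[str, bool]:
    """Per-quantity flags: are the two regimes' 95% CIs disjoint?

    Only defined for two-regime paintings.
    """
    if len(result.regime_labels) != 2:
        raise ValueError("regime significance defined for exactly 2 regimes")
    a, b = result.regime_labels
    out = {}
    for base in ("theta", "alpha", "sigma2", "half_life", "stat_var"):
        ka, kb = f"{base}[{a}]", f"{base}[{b}]"
        if ka in result.cis and kb in result.cis:
            out[base] = ci_overlap(result.cis[ka], result.cis[kb])
    return out
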