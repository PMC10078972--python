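"""End-to-end orchestration: synthetic inputs (or files) through occurrence
cleaning, canopy coding, ancestral states, OU model selection and bootstrap,
finishing in a deterministic machine-readable manifest.

The configuration is a flat YAML/dict with explicit seeds; running the same
configuration and seed twice produces byte-identical manifests (relative
file names only, no timestamps).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bootstrap import parametric_bootstrap, regime_significance
from .canopy import code_species, load_scheme
from .mk import binary_ard_spec, canopy_rate_spec, fit_mk, marginal_asr
from .occurrence import dedupe_unique, filter_complete, summarize_species, validate_table
from .ou import FitConfig, OUParams, compare_models, paint_regimes
from .phylo import Phylo, read_newick
from .synthetic import simulate_discrete, simulate_ou, simulate_tree
from .world import generate_occurrences, toy_world

__all__ = ["run_pipeline", "load_config", "DEFAULT_VARIABLES"]

DEFAULT_VARIABLES = ["BIO1", "BIO4", "BIO6", "BIO7", "BIO11", "BIO12"]
DEFAULT_MODELS = ["BM1", "BMS", "OU1", "OUM", "OUMV", "OUMA", "OUMVA"]


def load_config(config: str | Mapping[str, Any]) -> dict[str, Any]:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def run_pipeline(config: str | Mapping[str, Any], out_dir: str | None = None) -> dict:
    """Execute the full pipeline described by ``config``.

    Stages: input synthesis or loading; record validation, deduplication,
    completeness filtering and species summaries; canopy coding under the
    configured scheme(s); constrained 3-state Mk fit and marginal ancestral
    states for the canopy character; and, when a nesting character is
    available, binary-Mk regime painting, per-variable seven-model OU
    comparison and parametric bootstrap of the best-fit model.  Any stage
    failure raises with the stage name.  Returns the manifest (also written
    to ``manifest.json`` in the output directory).
    """
    cfg = load_config(config)
    out = Path(out_dir or cfg.get("out_dir", "climniche_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": seed,
        "config": {k: _jsonable(v) for k, v in cfg.items() if k != "out_dir"},
        "outputs": {},
        "results": {},
    }

    def emit(name: str, df: pd.DataFrame, index: bool = True) -> None:
        df.to_csv(out / name, index=index)
        manifest["outputs"][name.split(".")[0]] = name

    # ---- stage: inputs ---------------------------------------------------
    try:
        syn = cfg.get("synthetic", {})
        if "tree_file" in cfg:
            tree = read_newick(cfg["tree_file"])
        else:
            tree = simulate_tree(
                int(syn.get("n_tips", 60)),
                float(syn.get("birth", 1.0)),
                float(syn.get("death", 0.3)),
                seed=seed + 1,
            )
        world = toy_world(int(syn.get("world_seed", 0)))
        if "occurrences_file" in cfg:
            records = pd.read_csv(cfg["occurrences_file"])
        else:
            nps = syn.get("n_per_species", [3, 20])
            nps = int(nps) if isinstance(nps, int) else (int(nps[0]), int(nps[1]))
            records, _truth = generate_occurrences(
                tree.tips,
                world,
                n_per_species=nps,
                error_rates=syn.get("error_rates", {}),
                seed=seed + 3,
            )
        nesting_tips: dict[str, str] | None = None
        nesting_truth_nodes: np.ndarray | None = None
        nspec = binary_ard_spec(("ground", "arboreal"))
        if "nesting_file" in cfg:
            ndf = pd.read_csv(cfg["nesting_file"])
            nesting_tips = dict(zip(ndf["species"], ndf["state"]))
        elif "nesting_rates" in syn:
            r = [float(x) for x in syn["nesting_rates"]]
            Qn = np.array([[-r[0], r[0]], [r[1], -r[1]]])
            sim = simulate_discrete(tree, Qn, np.array([1.0, 0.0]), seed=seed + 4)
            nesting_truth_nodes = sim.node_states
            nesting_tips = sim.tip_state_map(tree, list(nspec.states))
        (out / "tree.nwk").write_text(tree.to_newick() + "\n")
        manifest["outputs"]["tree"] = "tree.nwk"
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'inputs' failed: {err}") from err

    # ---- stage: occurrence prep -----------------------------------------
    try:
        tolerance = float(cfg.get("tolerance", 1.0))
        valid, rejects = validate_table(records, world, tolerance=tolerance)
        deduped = dedupe_unique(valid)
        complete, n_dropped = filter_complete(deduped)
        summaries = summarize_species(complete)
        emit("species_medians.csv", summaries.medians)
        emit("biome_props.csv", summaries.biome_props)
        emit("realm_props.csv", summaries.realm_props)
        emit("rejections.csv", rejects, index=False)
        manifest["results"]["occurrence_prep"] = {
            "n_records": int(len(records)),
            "n_rejected": int(len(rejects)),
            "n_after_dedup": int(len(deduped)),
            "n_dropped_incomplete": n_dropped,
            "n_species_summarized": int(len(summaries.medians)),
        }
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'occurrence_prep' failed: {err}") from err

    # ---- stage: canopy coding -------------------------------------------
    try:
        scheme_names = cfg.get("scheme", "primary")
        if isinstance(scheme_names, str):
            scheme_names = [scheme_names]
        characters = {}
        for sname in scheme_names:
            scheme = load_scheme(sname)
            chars = code_species(summaries.biome_props, scheme)
            characters[sname] = chars
            emit(f"canopy_{sname}.csv", chars)
        primary_chars = characters[scheme_names[0]]
        manifest["results"]["canopy"] = {
            s: dict(characters[s]["state"].value_counts().sort_index())
            for s in scheme_names
        }
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'canopy_coding' failed: {err}") from err

    # ---- stage: canopy ancestral states ---------------------------------
    try:
        spec = canopy_rate_spec()
        tip_states: dict[str, str | set[str]] = {}
        n_missing = 0
        for t in tree.tips:
            if t in primary_chars.index:
                tip_states[t] = primary_chars.loc[t, "state"]
            else:  # species lost every record: fully ambiguous tip
                tip_states[t] = set(spec.states)
                n_missing += 1
        mkfit = fit_mk(
            tree, tip_states, spec,
            n_restarts=int(cfg.get("asr_restarts", 5)), seed=seed + 5,
        )
        asr = marginal_asr(tree, tip_states, mkfit.Q, states=spec.states)
        node_df = pd.DataFrame(
            asr.marginals[tree.n_tips:],
            columns=[f"P({s})" for s in spec.states],
            index=pd.Index(range(tree.n_tips, tree.n_nodes), name="node"),
        )
        emit("asr_node_probs.csv", node_df)
        labels = {
            v: asr.states[int(asr.marginals[v].argmax())]
            for v in range(tree.n_tips, tree.n_nodes)
        }
        (out / "asr_tree.nwk").write_text(tree.to_newick(internal_labels=labels) + "\n")
        manifest["outputs"]["asr_tree"] = "asr_tree.nwk"
        manifest["results"]["canopy_asr"] = {
            "rates_events_per_Ma": {
                f"{spec.states[i]}->{spec.states[j]}": float(mkfit.Q[i, j])
                for i in range(3) for j in range(3)
                if spec.index[i, j] >= 0
            },
            "lnL": mkfit.lnL,
            "root_probs": _jsonable(asr.root),
            "n_tips_without_character": n_missing,
        }
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'discrete_asr' failed: {err}") from err

    # ---- stage: OU branch (requires a nesting character) ----------------
    if nesting_tips is None:
        manifest["results"]["ou"] = {"skipped": "no nesting character supplied"}
    else:
        try:
            if (
                cfg.get("painting", "asr") == "truth"
                and nesting_truth_nodes is not None
            ):
                node_states = {
                    v: nspec.states[nesting_truth_nodes[v]]
                    for v in range(tree.n_nodes)
                }
                painting = paint_regimes(
                    tree, nesting_tips, node_states, labels=list(nspec.states)
                )
            else:
                nfit = fit_mk(
                    tree, nesting_tips, nspec,
                    n_restarts=int(cfg.get("asr_restarts", 5)), seed=seed + 6,
                )
                nasr = marginal_asr(tree, nesting_tips, nfit.Q, states=nspec.states)
                node_states = {
                    v: nspec.states[int(nasr.marginals[v].argmax())]
                    for v in range(tree.n_nodes)
                }
                painting = paint_regimes(
                    tree, nesting_tips, node_states, labels=list(nspec.states)
                )
            variables = list(cfg.get("variables", DEFAULT_VARIABLES))
            models = list(cfg.get("models", DEFAULT_MODELS))
            fit_cfg = FitConfig(
                n_restarts=int(cfg.get("fit_restarts", 2)), seed=seed + 7
            )
            traits: dict[str, dict[str, float]] = {}
            n_imputed = 0
            if cfg.get("ou_traits", "from_occurrences") == "simulate":
                sim_cfg = cfg["ou_sim"]
                true_params = OUParams(
                    model=sim_cfg.get("model", "OUMVA"),
                    theta0=float(sim_cfg["theta0"]),
                    theta=np.asarray(sim_cfg["theta"], dtype=float),
                    alpha=np.asarray(sim_cfg["alpha"], dtype=float),
                    sigma2=np.asarray(sim_cfg["sigma2"], dtype=float),
                )
                for i, var in enumerate(variables):
                    sim = simulate_ou(tree, painting, true_params, seed=seed + 10 + i)
                    traits[var] = dict(zip(tree.tips, sim.tip_values[0]))
                manifest["results"]["ou_truth"] = _jsonable(sim.params)
            else:
                med = summaries.medians
                for var in variables:
                    col = med[var]
                    fallback = float(col.median())
                    vals = {}
                    for t in tree.tips:
                        if t in col.index and np.isfinite(col.loc[t]):
                            vals[t] = float(col.loc[t])
                        else:  # species lost all records: global-median impute
                            vals[t] = fallback
                            n_imputed += 1
                    traits[var] = vals
            ou_results: dict[str, Any] = {
                "painting": painting.derivation,
                "n_trait_values_imputed": n_imputed,
            }
            boot_cfg = cfg.get("bootstrap", {})
            for i, var in enumerate(variables):
                table, fits = compare_models(
                    tree, painting, traits[var], models=models, config=fit_cfg
                )
                emit(f"model_comparison_{var}.csv", table, index=False)
                passing = table[table["diagnostic_pass"] != False]  # noqa: E712
                best_model = str(passing.iloc[0]["model"]) if len(passing) else None
                var_res: dict[str, Any] = {
                    "best_model": best_model,
                    "aicc": {m: float(fits[m].aicc) for m in fits},
                    "excluded_by_diagnostics": [
                        m for m in fits if fits[m].diagnostic_pass is False
                    ],
                }
                if best_model and boot_cfg.get("enabled", True):
                    boot = parametric_bootstrap(
                        tree,
                        painting,
                        fits[best_model],
                        n_sims=int(boot_cfg.get("n_sims", 50)),
                        seed=seed + 20 + i,
                        config=fit_cfg,
                    )
                    boot.estimates.to_csv(out / f"bootstrap_{var}.csv", index=False)
                    manifest["outputs"][f"bootstrap_{var}"] = f"bootstrap_{var}.csv"
                    var_res["bootstrap"] = {
                        "n_sims": boot.n_sims,
                        "n_failed": boot.n_failed,
                        "cis": _jsonable(boot.cis),
                        "observed": _jsonable(boot.observed),
                        "observed_in_ci": _jsonable(boot.in_ci),
                        "significant_regime_difference": _jsonable(
                            regime_significance(boot)
                        ),
                    }
                ou_results[var] = var_res
            manifest["results"]["ou"] = ou_results
        except Exception as err:
            raise RuntimeError(f"pipeline stage 'ou_models' failed: {err}") from err

    manifest_json = json.dumps(_jsonable(manifest), sort_keys=True, indent=2)
    (out / "manifest.json").write_text(manifest_json + "\n")
    return manifest
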