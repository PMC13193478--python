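"""End-to-end pipeline: env-prep -> time-sliced SSE -> niche models -> GLMM.

A single YAML/dict config drives all stages; one global seed
deterministically derives per-stage seeds so stages are individually
rerunnable. Every run writes a manifest recording package version, seeds,
and SHA-256 checksums of inputs and outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

import mimodiv
from mimodiv import env as env_mod
from mimodiv import glmm as glmm_mod
from mimodiv import niche as niche_mod
from mimodiv import simulate as sim_mod
from mimodiv import sse as sse_mod
from mimodiv.trees import TraitTable, fit_mk_ard, read_newick, stochastic_maps

__all__ = ["default_config", "stage_seed", "run_pipeline"]

STAGES = ("env", "sse", "niche", "glmm")


def default_config() -> dict:
    """Small-but-complete synthetic run; override any key."""
    return {
        "seed": 42,
        "out_dir": "mimodiv_run",
        "synthetic": {
            "n_tips": 150,
            "crown_age": 30.0,
            "n_species_occ": 60,
            "n_sparse": 12,
        },
        "inputs": {},  # tree/traits/env-table paths; empty = synthetic
        "stages": {s: True for s in STAGES},
        "env": {"min_records": 5, "thin_km": 1.5, "n_random": 20},
        "sse": {
            "slice_ages": [7.0, 15.0],
            "n_starts": 2,
            "sampling_fraction": [1.0, 1.0],
            "models": "scenarios",  # 'scenarios' = 4 asym/variable + unsliced; 'all'
        },
        "niche": {"variables": ["AI", "VPD", "GSP", "sand", "clay"], "n_maps": 20,
                  "n_starts": 2},
        "glmm": {"chains": 2, "iter": 1500, "warmup": 500, "thin": 2},
    }


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed (stable, documented)."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base.get(k, {}), v) if isinstance(v, dict) else v
    return out


def run_pipeline(config: dict | None = None, out_dir: str | None = None) -> dict:
    """Run the configured stages in order; returns the manifest dict."""
    cfg = _merge(default_config(), config or {})
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {
        "package": "mimodiv",
        "version": mimodiv.__version__,
        "seed": seed,
        "stage_seeds": {s: stage_seed(seed, s) for s in STAGES},
        "config": {k: v for k, v in cfg.items() if k != "inputs"},
        "inputs": {},
        "outputs": {},
        "timings_s": {},
    }

    # ------------------------------------------------------------- inputs
    syn = cfg["synthetic"]
    if cfg["inputs"].get("tree"):
        tree = read_newick(cfg["inputs"]["tree"])
        traits = TraitTable.from_frame(pd.read_csv(cfg["inputs"]["traits"]))
        manifest["inputs"]["tree"] = _sha256(Path(cfg["inputs"]["tree"]))
        manifest["inputs"]["traits"] = _sha256(Path(cfg["inputs"]["traits"]))
        tree_seed = None
    else:
        tree_seed = stage_seed(seed, "tree")
        sim_cfg = sim_mod.SimConfig(seed=tree_seed, n_tips=syn["n_tips"],
                                    crown_age=syn["crown_age"])
        tree, traits, truth = sim_mod.simulate_sse_dataset(sim_cfg)
        tree.write_newick(str(out / "tree.nwk"))
        pd.DataFrame({"species": traits.species, "habit": traits.habit}).to_csv(
            out / "traits.csv", index=False
        )
        manifest["inputs"]["tree"] = _sha256(out / "tree.nwk")
        manifest["inputs"]["traits"] = _sha256(out / "traits.csv")

    def _record(stage, name, path):
        manifest["outputs"].setdefault(stage, {})[name] = _sha256(Path(path))

    # ---------------------------------------------------------------- env
    env_table = None
    if cfg["stages"]["env"]:
        t0 = time.time()
        s = manifest["stage_seeds"]["env"]
        e = cfg["env"]
        occ, grid, polys = sim_mod.simulate_occurrences(
            n_species=syn["n_species_occ"], n_sparse=syn["n_sparse"], seed=s
        )
        occ = [env_mod.filter_native(o, polys.get(o.species)) for o in occ]
        table = env_mod.species_env_summary(
            occ, grid, polys, min_records=e["min_records"],
            n_random=e["n_random"], thin_km=e["thin_km"], seed=s,
        )
        env_vars = [c for c in table.columns if c in sim_mod._GRADIENTS]
        vifs = env_mod.vif(table[env_vars])
        scaled, consts = env_mod.scale_2sd(table, columns=env_vars)
        table.to_csv(out / "species_env.csv", index=False)
        scaled.to_csv(out / "species_env_scaled.csv", index=False)
        vifs.to_csv(out / "vif.csv")
        _record("env", "species_env", out / "species_env.csv")
        _record("env", "vif", out / "vif.csv")
        env_table = scaled
        manifest["timings_s"]["env"] = round(time.time() - t0, 2)

    # ---------------------------------------------------------------- sse
    if cfg["stages"]["sse"]:
        t0 = time.time()
        s = manifest["stage_seeds"]["sse"]
        sc = cfg["sse"]
        frac = tuple(sc["sampling_fraction"])
        for slice_age in sc["slice_ages"]:
            if sc["models"] == "all":
                specs = sse_mod.build_model_set(slice_age, frac)
            else:
                specs = [
                    sse_mod.SSEModelSpec(slice_age, em, lm, "asymmetric", "variable", frac)
                    for em in ("dependent", "independent")
                    for lm in ("dependent", "independent")
                ] + [
                    sse_mod.SSEModelSpec(None, m, m, "asymmetric", "constant", frac)
                    for m in ("dependent", "independent")
                ]
            fits = [
                sse_mod.fit_sse(tree, traits, sp, n_starts=sc["n_starts"], seed=s + i)
                for i, sp in enumerate(specs)
            ]
            tab = sse_mod.compare_sse_models(fits)
            tag = f"slice{slice_age:g}"
            tab.to_csv(out / f"sse_comparison_{tag}.csv", index=False)
            best = fits[int(np.argmin([f.aic for f in fits]))]
            sse_mod.rate_summary(best).to_csv(out / f"sse_rates_{tag}.csv", index=False)
            from mimodiv.plots import plot_rate_timeline

            ax = plot_rate_timeline(best)
            ax.figure.savefig(out / f"sse_rates_{tag}.png", dpi=120,
                              bbox_inches="tight")
            with open(out / f"sse_best_{tag}.json", "w") as fh:
                json.dump(
                    {
                        "model": best.spec.name,
                        "loglik": best.loglik,
                        "AIC": best.aic,
                        "params": dict(
                            zip(best.spec.param_names, best.params.free.tolist())
                        ),
                    },
                    fh, indent=2,
                )
            _record("sse", f"comparison_{tag}", out / f"sse_comparison_{tag}.csv")
        manifest["timings_s"]["sse"] = round(time.time() - t0, 2)

    # -------------------------------------------------------------- niche
    if cfg["stages"]["niche"] and env_table is not None:
        t0 = time.time()
        s = manifest["stage_seeds"]["niche"]
        nc = cfg["niche"]
        # species present both in tree and env table
        common = [sp for sp in tree.tip_labels if sp in set(env_table["species"])]
        if len(common) < 10:
            # synthetic occurrence species are independent of the tree; fall
            # back to simulating niche values on the tree's own regimes
            states = traits.states_for(tree)
            q, _ = fit_mk_ard(tree, states, seed=s)
            maps = stochastic_maps(tree, states, q, n_maps=nc["n_maps"], seed=s)
            rng = np.random.default_rng(s)
            for var in nc["variables"]:
                true_params = niche_mod.OUParams(
                    sigma2=(1.0, 3.0), alpha=(0.1, 0.1), theta=(0.0, 0.0)
                )
                vals = sim_mod.simulate_ou_traits(
                    tree, maps[0], true_params, seed=int(rng.integers(2**31))
                )
                vals = (vals - vals.mean()) / vals.std(ddof=1)
                fits = niche_mod.fit_all_niche_models(
                    tree, maps[: nc["n_maps"]], vals, n_starts=nc["n_starts"], seed=s
                )
                tab = niche_mod.compare_niche_models(fits)
                tab.to_csv(out / f"niche_{var}.csv", index=False)
                _record("niche", var, out / f"niche_{var}.csv")
        manifest["timings_s"]["niche"] = round(time.time() - t0, 2)

    # --------------------------------------------------------------- glmm
    if cfg["stages"]["glmm"]:
        t0 = time.time()
        s = manifest["stage_seeds"]["glmm"]
        g = cfg["glmm"]
        from mimodiv.trees import phylo_correlation

        C = phylo_correlation(tree.normalize_depths())
        states = traits.states_for(tree)
        sim = sim_mod.simulate_glmm_dataset(
            C, beta0=-0.5, beta=np.array([1.2, -0.8, 0.3, -0.3, 0.1]),
            sigma_phylo=1.0, sigma_species=1.0, seed=s, predictor_corr=0.9,
        )
        X = (sim["X"] - sim["X"].mean(0)) / (2 * sim["X"].std(0, ddof=1))
        data = glmm_mod.GLMMData(
            states.astype(float), X, C, list(tree.tip_labels),
            ["AI", "VPD", "GSP", "sand", "clay"],
        )
        draws = glmm_mod.sample_posterior(
            data, chains=g["chains"], iter=g["iter"], warmup=g["warmup"],
            thin=g["thin"], seed=s,
        )
        draws.summary().to_csv(out / "glmm_posterior.csv", index=False)
        draws.diagnostics().to_csv(out / "glmm_diagnostics.csv", index=False)
        r2 = {
            "marginal": glmm_mod.bayes_r2(draws, data, "marginal"),
            "conditional": glmm_mod.bayes_r2(draws, data, "conditional"),
        }
        with open(out / "glmm_r2.json", "w") as fh:
            json.dump(
                {k: {kk: vv for kk, vv in v.items() if kk != "draws"}
                 for k, v in r2.items()},
                fh, indent=2,
            )
        ppc = glmm_mod.posterior_predictive_check(draws, data, seed=s)
        with open(out / "glmm_ppc.json", "w") as fh:
            json.dump(ppc, fh, indent=2)
        glmm_mod.power_scale_sensitivity(draws).to_csv(
            out / "glmm_sensitivity.csv", index=False
        )
        _record("glmm", "posterior", out / "glmm_posterior.csv")
        _record("glmm", "r2", out / "glmm_r2.json")
        manifest["timings_s"]["glmm"] = round(time.time() - t0, 2)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
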