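"""End-to-end orchestration: simulate/load -> diversity -> indices -> models.

A run is driven by a :class:`RunManifest` (usually a YAML file): either a
synthetic-landscape configuration or paths to user data (site CSV,
function CSV, classic OTU TSV, newick tree).  ``run_all`` chains the
stages in order — diversity metrics, averaging multifunctionality,
multiple-threshold curves, OLS + SAR regressions, random-forest
importance, path model — writing every intermediate artifact plus a
machine-readable ``summary.json`` into the run directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import (
    OtuTable,
    diversity_profile,
    rarefy,
    read_otu_table,
    remove_singletons,
    write_otu_table,
)
from .mfi import FUNCTION_COLUMNS, averaging_index
from .pathmodel import (
    PathModelSpec,
    bollen_stine,
    bootstrap_pvalues,
    fit_path_model,
    fit_statistics,
    total_effects_on,
)
from .regression import build_spatial_weights, compare_models, ols_fit, sar_error_fit
from .rf import permutation_significance
from .synthetic import (
    COVARIATES,
    SimulationConfig,
    simulate_landscape,
    simulate_otu_table,
    simulate_phylogeny,
)
from .thresholds import summarize_curve, threshold_slopes

logger = logging.getLogger(__name__)

DIVERSITY_VAR = "microbial_diversity"
MF_VAR = "multifunctionality"


def default_model_spec() -> PathModelSpec:
    """Default a-priori path model: covariates -> diversity -> multifunctionality.

    Climate and soil pH also act on multifunctionality directly; the two
    spatial surrogates (distance from equator, altitude) act only through
    diversity, leaving 2 degrees of freedom for the fit tests.
    """
    edges = [(c, DIVERSITY_VAR) for c in COVARIATES]
    edges += [("MAT", MF_VAR), ("MAP", MF_VAR), ("soil_pH", MF_VAR)]
    edges += [(DIVERSITY_VAR, MF_VAR)]
    return PathModelSpec(edges=edges)


@dataclass
class RunManifest:
    """Everything needed to reproduce a run."""

    seed: int = 0
    outdir: str = "multifun_run"
    simulation: SimulationConfig | None = None
    inputs: dict = field(default_factory=dict)  # sites/functions/otu_table/tree paths
    rarefaction_depth: int | None = None
    weights_k: int = 8
    rf_trees: int = 5000
    rf_permutations: int = 5000
    path_bootstrap: int = 2000
    model_spec: PathModelSpec | None = None
    compute_rf_significance: bool = True
    compute_bollen_stine: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunManifest":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        sim = doc.pop("simulation", None)
        spec = doc.pop("model_spec", None)
        manifest = cls(**doc)
        if sim is not None:
            if "seed" not in sim:
                sim["seed"] = manifest.seed
            for key in (
                "effect_diversity_on_functions",
                "effect_covariates_on_diversity",
                "effect_covariates_on_functions",
                "evenness_range",
            ):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            manifest.simulation = SimulationConfig(**sim)
        if spec is not None:
            manifest.model_spec = PathModelSpec.from_yaml(spec)
        if manifest.simulation is None:
            for key in ("sites", "functions"):
                if key not in manifest.inputs:
                    raise ValueError(f"manifest needs inputs.{key} or a simulation block")
                if not Path(manifest.inputs[key]).exists():
                    raise FileNotFoundError(manifest.inputs[key])
        return manifest


def validate_inputs(
    sites: pd.DataFrame,
    functions: pd.DataFrame,
    otu: OtuTable | None = None,
) -> list[dict]:
    """Cross-check identifiers and usability; returns a list of issues."""
    issues = []
    orphans_f = functions.index.difference(sites.index)
    if len(orphans_f):
        issues.append({"kind": "orphan_sites", "table": "functions",
                       "ids": orphans_f.tolist()})
    orphans_s = sites.index.difference(functions.index)
    if len(orphans_s):
        issues.append({"kind": "orphan_sites", "table": "sites",
                       "ids": orphans_s.tolist()})
    if otu is not None:
        orphan_samples = [s for s in otu.samples if s not in sites.index]
        if orphan_samples:
            issues.append({"kind": "orphan_samples", "table": "otu_table",
                           "ids": orphan_samples})
    for c in functions.columns:
        x = functions[c].to_numpy(dtype=float)
        n_missing = int(np.sum(~np.isfinite(x)))
        if n_missing:
            issues.append({"kind": "missing_values", "column": c, "n": n_missing})
        finite = x[np.isfinite(x)]
        if finite.size and finite.std(ddof=1) == 0:
            issues.append({"kind": "constant_column", "column": c,
                           "note": "unusable for z-scoring"})
    return issues


def _provenance(stage: str, manifest: RunManifest, **params) -> str:
    bits = " ".join(f"{k}={v}" for k, v in params.items())
    return (f"# multifun v{__version__} stage={stage} seed={manifest.seed}"
            + (f" {bits}" if bits else ""))


def _write_csv(df: pd.DataFrame, path: Path, stage: str, manifest: RunManifest,
               **params) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(stage, manifest, **params) + "\n")
        df.to_csv(fh)


def run_all(manifest: RunManifest) -> dict:
    """Execute the full analysis chain; returns the summary dict.

    Any stage failure raises with the stage name; artifacts written so
    far are left in place for inspection.
    """
    out = Path(manifest.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("multifun")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"seed": manifest.seed, "version": __version__, "stages": {}}
    stage = "setup"
    try:
        # ------------------------------------------------ data
        stage = "data"
        if manifest.simulation is not None:
            cfg = manifest.simulation
            sites, functions, truth = simulate_landscape(cfg)
            table = simulate_otu_table(
                cfg.n_sites, cfg.n_taxa, truth.evenness_sigma, cfg.read_depth,
                seed=cfg.seed + 101,
            )
            newick = simulate_phylogeny(cfg.n_taxa, seed=cfg.seed + 202)
            (out / "tree.nwk").write_text(newick + "\n")
            summary["stages"]["data"] = {"source": "simulation",
                                          "n_sites": cfg.n_sites}
        else:
            sites = pd.read_csv(manifest.inputs["sites"], index_col=0, comment="#")
            functions = pd.read_csv(manifest.inputs["functions"], index_col=0,
                                    comment="#")
            table = (read_otu_table(manifest.inputs["otu_table"])
                     if "otu_table" in manifest.inputs else None)
            newick = (Path(manifest.inputs["tree"]).read_text().strip()
                      if "tree" in manifest.inputs else None)
            summary["stages"]["data"] = {"source": "files",
                                          "n_sites": sites.shape[0]}
        missing_fn = [c for c in FUNCTION_COLUMNS if c not in functions.columns]
        if missing_fn:
            raise ValueError(f"function table lacks columns: {missing_fn}")
        _write_csv(sites, out / "sites.csv", "data", manifest)
        _write_csv(functions, out / "functions.csv", "data", manifest)
        issues = validate_inputs(sites, functions, table)
        summary["stages"]["validate"] = {"n_issues": len(issues), "issues": issues}

        # ------------------------------------------------ diversity
        stage = "diversity"
        if table is not None:
            write_otu_table(table, out / "otu_table.tsv")
            table = remove_singletons(table)
            depth = manifest.rarefaction_depth or int(table.sample_totals().min())
            table = rarefy(table, depth, seed=manifest.seed + 7)
            profile = diversity_profile(table, tree=newick,
                                        rarefaction_depth=depth)
            _write_csv(profile.table, out / "diversity.csv", "diversity",
                       manifest, depth=depth)
            diversity = profile.table["shannon_bits"].reindex(sites.index)
            summary["stages"]["diversity"] = {
                "rarefaction_depth": depth,
                "mean_shannon_bits": float(diversity.mean()),
                "mean_richness": float(profile.table["richness"].mean()),
            }
            if "faith_pd" in profile.table:
                summary["stages"]["diversity"]["mean_faith_pd"] = float(
                    profile.table["faith_pd"].mean()
                )
        else:
            if DIVERSITY_VAR not in sites.columns:
                raise ValueError(
                    f"no OTU table and no {DIVERSITY_VAR!r} column in the site table"
                )
            diversity = sites[DIVERSITY_VAR]
            summary["stages"]["diversity"] = {"source": "site_table"}

        # ------------------------------------------------ multifunctionality
        stage = "multifunctionality"
        index = averaging_index(functions)
        _write_csv(index.table, out / "multifunctionality.csv", stage, manifest)
        M = index.M
        summary["stages"]["multifunctionality"] = {
            "transforms": index.transforms,
            "site_mean": float(M.mean()),
        }

        # ------------------------------------------------ thresholds
        stage = "thresholds"
        curve = threshold_slopes(functions, diversity)
        with open(out / "threshold_curve.csv", "w") as fh:
            fh.write(_provenance(stage, manifest) + "\n")
            curve.table.to_csv(fh, index=False)
        summary["stages"]["thresholds"] = summarize_curve(curve)

        # ------------------------------------------------ regression
        stage = "regression"
        X = pd.DataFrame({"diversity": diversity.to_numpy()}, index=sites.index)
        W = build_spatial_weights(
            sites[["latitude", "longitude"]].to_numpy(),
            k=min(manifest.weights_k, sites.shape[0] - 1),
        )
        fit_ols = ols_fit(M.to_numpy(), X)
        fit_sar = sar_error_fit(M.to_numpy(), X, W)
        comparison = compare_models([fit_ols, fit_sar])
        reg = {
            "ols": fit_ols.to_dict(),
            "sar": fit_sar.to_dict(),
            "comparison": comparison.to_dict(orient="records"),
        }
        (out / "regression.json").write_text(json.dumps(
            {"_provenance": _provenance(stage, manifest), **reg}, indent=2))
        summary["stages"]["regression"] = {
            "ols_diversity_slope": float(fit_ols.params["diversity"]),
            "ols_p": float(fit_ols.pvalues["diversity"]),
            "ols_r2": fit_ols.r2,
            "ols_aicc": fit_ols.aicc,
            "sar_diversity_slope": float(fit_sar.params["diversity"]),
            "sar_lambda": fit_sar.lam,
            "sar_r2": fit_sar.r2,
            "sar_aicc": fit_sar.aicc,
        }

        # ------------------------------------------------ random forest
        stage = "rf_importance"
        Xrf = sites[COVARIATES].copy()
        Xrf[DIVERSITY_VAR] = diversity
        if manifest.compute_rf_significance:
            rf_res = permutation_significance(
                Xrf, M.to_numpy(),
                n_permutations=manifest.rf_permutations,
                n_trees=manifest.rf_trees,
                seed=manifest.seed + 11,
                compute_model_p=True,
                cv_trees=max(50, manifest.rf_trees // 10),
            )
            rf_payload = rf_res.to_dict()
            importance = rf_res.importance
        else:
            from .rf import rf_importance as _rf_imp

            importance = _rf_imp(Xrf, M.to_numpy(), n_trees=manifest.rf_trees,
                                 seed=manifest.seed + 11)
            rf_payload = {"importance_pct_inc_mse": importance.to_dict()}
        (out / "rf_importance.json").write_text(json.dumps(
            {"_provenance": _provenance(stage, manifest), **rf_payload}, indent=2))
        ranking = importance.sort_values(ascending=False)
        summary["stages"]["rf_importance"] = {
            "ranking": list(ranking.index),
            "importance": ranking.to_dict(),
            "diversity_rank": int(list(ranking.index).index(DIVERSITY_VAR)) + 1,
        }

        # ------------------------------------------------ path model
        stage = "path_model"
        spec = manifest.model_spec or default_model_spec()
        data = sites[COVARIATES].copy()
        data[DIVERSITY_VAR] = diversity
        data[MF_VAR] = M
        fit = fit_path_model(data, spec)
        fstats = fit_statistics(fit)
        boot_p = bootstrap_pvalues(data, spec, n_boot=manifest.path_bootstrap,
                                   seed=manifest.seed + 13)
        bs_p = None
        if manifest.compute_bollen_stine and fstats["df"] >= 1:
            bs_p = bollen_stine(data, spec, n_boot=min(manifest.path_bootstrap, 500),
                                seed=manifest.seed + 17)
        effects = total_effects_on(fit, MF_VAR)
        payload = {
            "_provenance": _provenance(stage, manifest),
            **fit.to_dict(),
            "fit_statistics": fstats,
            "bootstrap_p": boot_p.to_dict(),
            "bollen_stine_p": bs_p,
            "total_effects_on_multifunctionality": effects.to_dict(),
        }
        (out / "path_model.json").write_text(json.dumps(payload, indent=2))
        effects.rename("total_effect").to_frame().to_csv(out / "total_effects.csv")
        summary["stages"]["path_model"] = {
            "direct_diversity_effect": fit.path_coefficient(DIVERSITY_VAR, MF_VAR),
            "diversity_total_effect": float(effects[DIVERSITY_VAR]),
            "r2_multifunctionality": fit.r2[MF_VAR],
            "chi2": fstats["chi2"],
            "rmsea": fstats["rmsea"],
            "bollen_stine_p": bs_p,
        }

        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        logger.info("run complete: %s", out)
        return summary
    except Exception as exc:
        logger.exception("stage %r failed; artifacts preserved in %s", stage, out)
        raise RuntimeError(
            f"pipeline stage {stage!r} failed: {exc} (see {log_path})"
        ) from exc
    finally:
        root.removeHandler(handler)
        handler.close()
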