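"""End-to-end orchestration of the two-stage genomic-selection analysis.

One config drives: population simulation -> dosage calling -> marker QC
-> stage-1 longitudinal fit (structure selection, heritability, entry
means) -> relationship matrices -> stage-2 prediction models ->
replicated cross-validation with the tetraploid/diploid coding
comparison.  The run report collects marker counts surviving each
filter, the structure-selection trace, both heritabilities and the
per-model predictive-ability table.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from polygs import crossval, dosage, kinship, phenomodel, simpop, wgr

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Thresholds, protocols and the simulation settings for one run.

    Filter defaults are the conventional ones for this pipeline: mean
    depth 25, MAF 1%, missingness 5%, blend weight 0.99.
    """

    sim: simpop.SimConfig = field(default_factory=simpop.SimConfig)
    min_mean_depth: float = 25.0
    min_maf: float = 0.01
    max_missing: float = 0.05
    min_posterior: float = 0.8
    call_seq_error: float = 0.01
    vcov_candidates: tuple = ("ID", "DIAG", "CS", "CSHet", "AR1", "AR1Het", "Po", "PoHet")
    models: tuple = ("GBLUP", "BRR", "BA", "BB", "BC", "BL")
    n_folds: int = 5
    n_replications: int = 10
    mcmc_iterations: int = 4_000
    mcmc_burn_in: int = 1_000
    blend_weight: float = 0.99
    run_phenomodel: bool = True
    run_comparison: bool = True
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim_raw = raw.pop("sim", {})
        resid = sim_raw.pop("residual_vcov_spec", None)
        if resid is not None:
            sim_raw["residual_vcov_spec"] = phenomodel.VcovStructure(
                resid["name"], resid["L"], resid.get("params"), resid.get("times")
            )
        sim = simpop.SimConfig(**sim_raw)
        for key in ("vcov_candidates", "models"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(sim=sim, **raw)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(raw)


def _stage(report: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s started", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            elapsed = time.perf_counter() - self.t0
            report.setdefault("stages", {})[name] = {
                "seconds": round(elapsed, 3),
                "failed": exc_type is not None,
            }
            if exc_type is not None:
                logger.error("stage %s failed after %.1fs: %s", name, elapsed, exc)
            else:
                logger.info("stage %s finished in %.1fs", name, elapsed)
            return False

    return _Timer()


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Run the enabled stages in order and return the machine-readable report."""
    report: dict = {"seed": config.seed, "config": {"models": list(config.models)}}
    rng = np.random.default_rng(config.seed)

    with _stage(report, "simulate"):
        sim_config = replace(config.sim, seed=config.seed)
        pop = simpop.simulate_population(sim_config)
        report["simulation"] = {
            "n_offspring": pop["offspring"].n_individuals,
            "n_plants_total": len(pop["trial"].layout),
            "n_markers": pop["offspring"].n_markers,
        }

    with _stage(report, "call"):
        reads = dosage.filter_min_depth(pop["reads"], config.min_mean_depth)
        called, diag = dosage.call_dosages(
            reads,
            ploidy=sim_config.ploidy,
            seq_error=config.call_seq_error,
            min_posterior=config.min_posterior,
        )
        marker_counts = {
            "simulated": pop["reads"].n_markers,
            "depth_filter": reads.n_markers,
        }

    with _stage(report, "filter"):
        filtered = dosage.filter_maf(called, config.min_maf)
        marker_counts["maf_filter"] = filtered.n_markers
        filtered = dosage.filter_missing(filtered, config.max_missing)
        marker_counts["missing_filter"] = filtered.n_markers
        imputed = dosage.impute_dose_frequency(
            filtered, np.random.default_rng(rng.integers(2**31))
        )
        redundancy = dosage.redundancy_groups(imputed)
        report["marker_counts"] = marker_counts
        report["redundancy"] = {
            k: redundancy[k] for k in ("n_markers", "n_unique", "n_redundant", "percent_unique")
        }

    trial = pop["trial"]
    L = sim_config.n_harvests
    if config.run_phenomodel:
        with _stage(report, "pheno-fit"):
            candidates = [
                phenomodel.VcovStructure(name, L) for name in config.vcov_candidates
            ]
            g_struct, r_struct, trace = phenomodel.select_vcov(
                trial.phenotypes, candidates
            )
            fit = trace["final_fit"]
            cs_fit = phenomodel.fit_longitudinal(
                trial.phenotypes,
                phenomodel.VcovStructure("CS", L),
                phenomodel.VcovStructure("ID", L),
            )
            h2_broad = phenomodel.generalized_heritability(cs_fit)
            entry_means = phenomodel.adjusted_entry_means(fit)
            report["phenomodel"] = {
                "selected_g": g_struct.name,
                "selected_r": r_struct.name,
                "selection_table": {
                    step: trace[step]["models"]
                    for step in ("step1_genetic", "step2_residual")
                },
                "generalized_heritability": h2_broad.h2,
            }
    else:
        entry_means = trial.genetic_values + sim_config.mu

    with _stage(report, "kinship"):
        A = kinship.build_a_tetraploid(pop["pedigree"])
        A_off = A.subset(imputed.individuals)

    with _stage(report, "cv"):
        plan = crossval.CvPlan(
            n_folds=config.n_folds,
            n_replications=config.n_replications,
            seed=config.seed,
        )
        specs = [
            wgr.WgrSpec(
                model=m,
                iterations=config.mcmc_iterations,
                burn_in=config.mcmc_burn_in,
                seed=config.seed,
            )
            for m in config.models
        ]
        y = entry_means.reindex(imputed.individuals)
        if config.run_comparison:
            comparison = crossval.compare_td_dd(
                imputed, y, specs, plan=plan, A=A_off, blend_weight=config.blend_weight
            )
            report["comparison"] = {
                "table": comparison["table"].to_dict(),
                "mean_td": comparison["mean_td"],
                "mean_dd": comparison["mean_dd"],
                "superiority_pct": comparison["superiority_pct"],
                "n_markers_panel": comparison["n_markers"],
            }
        gblup_spec = next((s for s in specs if s.model == "GBLUP"), None)
        if gblup_spec is not None:
            K = kinship.build_k(imputed)
            K_star = kinship.blend(K, A_off, config.blend_weight)
            gfit = wgr.fit_gblup(K_star, y)
            report["narrow_heritability"] = wgr.narrow_heritability(gfit)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonify)
        entry_means.rename("entry_mean").to_csv(out_dir / "entry_means.csv")
    return report


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.Series, pd.DataFrame)):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")
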