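"""End-to-end orchestration: simulate/load -> qc -> assoc -> enrich -> prs
-> model -> bootstrap, with a content-hashed run manifest.

Every stage is a pure function of (inputs, sub-config, seed); a single
global seed fans out to per-stage named substreams, so re-running the
same config reproduces every output byte-identically.  A stage failure
halts the run with the stage name while retaining partial outputs.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .association import DEFAULT_COVARIATE_CANDIDATES, screen_covariates, snp_association
from .containers import GenotypeMatrix
from .enrichment import EnrichmentAnalysis, EnrichmentConfig, cumulative_sets
from .modeling import CpspPredictionModel, bootstrap_validate, compare_auc
from .prs import build_prs_model, compute_prs, impute_missing_mode, lasso_select
from .qc import QCConfig, filter_variants, ld_prune
from .simulate import SimConfig, simulate_cohort

STAGES = ("simulate", "qc", "assoc", "enrich", "prs", "model", "bootstrap")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


@dataclass
class InputPaths:
    vcf: str
    annotation: str
    ranked_genes: str
    phenotypes: str


@dataclass
class PRSOptions:
    cv_folds: int = 10
    standardize: bool = False


@dataclass
class ModelOptions:
    candidate_covariates: tuple = DEFAULT_COVARIATE_CANDIDATES
    entry_p: float = 0.05
    n_boot: int = 1000


@dataclass
class PipelineConfig:
    """One config object driving the whole run.

    Exactly one of ``sim`` (synthetic cohort) or ``inputs`` (paths to
    VCF/annotation/gene/phenotype files) must be given.
    """

    outdir: str
    sim: SimConfig | None = None
    inputs: InputPaths | None = None
    qc: QCConfig = field(default_factory=QCConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    prs: PRSOptions = field(default_factory=PRSOptions)
    model: ModelOptions = field(default_factory=ModelOptions)
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.inputs is None):
            raise ValueError("exactly one of sim / inputs must be provided")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs = {"outdir": raw["outdir"], "seed": int(raw.get("seed", 0))}
        if "sim" in raw:
            kwargs["sim"] = SimConfig(**raw["sim"])
        if "inputs" in raw:
            kwargs["inputs"] = InputPaths(**raw["inputs"])
        if "qc" in raw:
            kwargs["qc"] = QCConfig(**raw["qc"])
        if "enrichment" in raw:
            enr = dict(raw["enrichment"])
            if "maf_bands" in enr:
                enr["maf_bands"] = tuple(tuple(b) for b in enr["maf_bands"])
            kwargs["enrichment"] = EnrichmentConfig(**enr)
        if "prs" in raw:
            kwargs["prs"] = PRSOptions(**raw["prs"])
        if "model" in raw:
            mod = dict(raw["model"])
            if "candidate_covariates" in mod:
                mod["candidate_covariates"] = tuple(mod["candidate_covariates"])
            kwargs["model"] = ModelOptions(**mod)
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {
        name: int(ss.generate_state(1)[0] % (2**31))
        for name, ss in zip(STAGES, np.random.SeedSequence(config.seed).spawn(len(STAGES)))
    }
    manifest = {"seed": config.seed, "stages": []}

    def record(stage: str, outputs: dict, **info):
        manifest["stages"].append(
            {
                "stage": stage,
                "seed": seeds[stage],
                "outputs": {k: {"path": str(p), "sha256": _sha256(Path(p))} for k, p in outputs.items()},
                **info,
            }
        )

    # ---- simulate / load -------------------------------------------------
    try:
        if config.sim is not None:
            sim = SimConfig(**{**asdict(config.sim), "seed": seeds["simulate"]})
            cohort = simulate_cohort(sim)
            paths = cohort.write(outdir / "inputs")
            genotypes = cohort.genotypes
            annotation = cohort.annotation
            ranked = cohort.ranked_genes
            phenotypes = cohort.phenotypes
            record("simulate", paths, n_individuals=sim.n_individuals,
                   n_variants=genotypes.n_variants)
        else:
            annotation = io.read_annotation(config.inputs.annotation)
            genotypes = io.read_genotypes(config.inputs.vcf, annotation)
            ranked = io.read_ranked_genes(config.inputs.ranked_genes)
            record("simulate", {}, loaded_from=asdict(config.inputs),
                   n_variants=genotypes.n_variants)
            phenotypes = None
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc

    # ---- qc ---------------------------------------------------------------
    try:
        filtered, report = filter_variants(genotypes, annotation, config.qc)
        kept = ld_prune(filtered, annotation, config.qc.ld_window,
                        config.qc.ld_step, config.qc.ld_r2_max)
        pruned = filtered.subset_variants(kept)
        report_path = outdir / "qc_exclusions.tsv"
        report.to_frame().to_csv(report_path, sep="\t", index=False)
        kept_path = outdir / "qc_kept_variants.tsv"
        pd.DataFrame({"variant_id": kept}).to_csv(kept_path, sep="\t", index=False)
        record("qc", {"exclusions": report_path, "kept": kept_path},
               n_input=report.n_input, n_after_filters=report.n_retained,
               n_after_prune=len(kept))
    except Exception as exc:
        raise PipelineError("qc", str(exc)) from exc

    # ---- association -------------------------------------------------------
    try:
        if phenotypes is None:
            phenotypes = io.read_phenotypes(config.inputs.phenotypes)
        covariates = screen_covariates(phenotypes, config.model.candidate_covariates)
        assoc = snp_association(pruned, phenotypes, covariates)
        assoc_path = outdir / "association.tsv"
        assoc.to_csv(assoc_path, sep="\t", index=False)
        record("assoc", {"association": assoc_path}, covariates=covariates,
               n_variants=len(assoc))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("assoc", str(exc)) from exc

    # ---- enrichment --------------------------------------------------------
    try:
        analysis = EnrichmentAnalysis(assoc, annotation, ranked, config.enrichment)
        enr = analysis.fit(seed=seeds["enrich"])
        enr_path = outdir / "enrichment.tsv"
        enr.summary().to_csv(enr_path, sep="\t", index=False)
        minimal = enr.minimal_enriched_set
        record("enrich", {"enrichment": enr_path}, minimal_enriched_set=minimal,
               alpha=config.enrichment.alpha, n_runs=config.enrichment.n_runs)
        if minimal is None:
            raise PipelineError("enrich", "no cumulative set is enriched; "
                                "nothing to carry into PRS selection")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("enrich", str(exc)) from exc

    # ---- prs ----------------------------------------------------------------
    try:
        sets = dict(cumulative_sets(ranked, annotation, config.enrichment))
        minimal_variants = [v for v in sets[minimal] if v in set(pruned.variant_ids)]
        groups = dict(zip(phenotypes["individual_id"], phenotypes["race"])) if "race" in phenotypes else None
        imputed, imp_report = impute_missing_mode(
            pruned.subset_variants(minimal_variants), groups
        )
        selection = lasso_select(
            imputed, phenotypes, minimal_variants,
            cv_folds=config.prs.cv_folds, seed=seeds["prs"],
            standardize=config.prs.standardize,
        )
        if not selection.selected:
            raise PipelineError("prs", "dual-LASSO intersection is empty")
        prs_model = build_prs_model(assoc, annotation, selection.selected)
        scores = compute_prs(prs_model, imputed)
        model_path = prs_model.to_json(outdir / "prs_model.json")
        scores_path = outdir / "prs_scores.csv"
        scores[["individual_id", "prs"]].to_csv(scores_path, index=False)
        record("prs", {"model": model_path, "scores": scores_path},
               n_candidates=len(minimal_variants), n_selected=prs_model.m,
               n_imputed=imp_report["n_imputed"])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("prs", str(exc)) from exc

    # ---- prediction models ---------------------------------------------------
    try:
        data = phenotypes.merge(scores[["individual_id", "prs"]], on="individual_id")
        model = CpspPredictionModel(data)
        clinical = model.fit_stepwise(config.model.candidate_covariates,
                                      entry_p=config.model.entry_p)
        genetic = model.fit(clinical.terms + ["prs"])
        p_auc = compare_auc(genetic, clinical)
        summary = {
            "clinical_terms": clinical.terms,
            "clinical_auc": clinical.auc,
            "clinical_auc_ci": list(clinical.auc_ci),
            "genetic_auc": genetic.auc,
            "genetic_auc_ci": list(genetic.auc_ci),
            "auc_comparison_p": p_auc,
            "genetic_model": genetic.summary().to_dict(orient="records"),
            "clinical_model": clinical.summary().to_dict(orient="records"),
        }
        summary_path = outdir / "model_summary.json"
        summary_path.write_text(json.dumps(summary, indent=2) + "\n")
        roc_path = outdir / "roc_curves.csv"
        roc = pd.concat(
            [clinical.roc_curve().assign(model="clinical"),
             genetic.roc_curve().assign(model="genetic")]
        )
        roc.to_csv(roc_path, index=False)
        curve_path = outdir / "probability_curve.csv"
        crossing = None
        if "prs" in genetic.design.columns:
            fixed = {
                c: float(data[c].median()) if c in data else 0.0
                for c in genetic.design.columns if c != "prs"
            }
            grid = np.linspace(float(data["prs"].min()), float(data["prs"].max()), 101)
            curve, crossing = genetic.probability_curve("prs", grid, fixed)
            curve.to_csv(curve_path, index=False)
            outputs = {"summary": summary_path, "roc": roc_path, "probability_curve": curve_path}
        else:
            outputs = {"summary": summary_path, "roc": roc_path}
        record("model", outputs, clinical_auc=clinical.auc, genetic_auc=genetic.auc,
               auc_comparison_p=p_auc, prs_at_half_probability=crossing)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("model", str(exc)) from exc

    # ---- bootstrap -----------------------------------------------------------
    try:
        if config.model.n_boot <= 0:
            record("bootstrap", {}, n_boot=0, skipped=True)
            manifest_path = outdir / "manifest.json"
            manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
            return manifest
        boot = bootstrap_validate(
            data, genetic.terms, n_boot=config.model.n_boot, seed=seeds["bootstrap"]
        )
        boot_path = outdir / "bootstrap.tsv"
        boot.table.to_csv(boot_path, sep="\t", index=False)
        record("bootstrap", {"bootstrap": boot_path}, n_boot=boot.n_boot,
               n_redraws=boot.n_redraws)
    except Exception as exc:
        raise PipelineError("bootstrap", str(exc)) from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
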