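"""End-to-end pipeline orchestration: configuration, staged runs, reports.

The pipeline chains the stages simulate -> map -> build -> fba -> process ->
qc -> associate.  Every threshold is surfaced in :class:`PipelineConfig`
(none is hard-coded in the stages), the config round-trips losslessly
through YAML, and a run log records the seed, thresholds and SHA-256
checksums of every written output so full-run determinism can be checked by
comparing report checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from . import (
    association_stats as stats_mod,
    fba_engine,
    flux_pipeline,
    metabolomics_qc,
    model_assembly,
    synthetic_cohort,
    taxa_mapping,
)
from .errors import ConfigError, GutWbmError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the pipeline's canonical values."""

    seed: int = 0
    n_samples: int = 500
    coupling_factor: float = model_assembly.DEFAULT_COUPLING_FACTOR
    abundance_threshold: float = taxa_mapping.ABUNDANCE_FLOOR
    flux_decimals: int = fba_engine.FLUX_DECIMALS
    zero_frac: float = flux_pipeline.ZERO_FRAC
    ident_frac: float = flux_pipeline.IDENT_FRAC
    flux_tol: float = flux_pipeline.FLUX_TOL
    r2_threshold: float = flux_pipeline.R2_THRESHOLD
    met_missing_frac: float = metabolomics_qc.MET_MISSING_FRAC
    cv_max: float = metabolomics_qc.CV_MAX
    missing_sd_factor: float = metabolomics_qc.MISSING_SD_FACTOR
    knn_neighbors: int = metabolomics_qc.KNN_NEIGHBOURS
    stratify_alpha: float = 0.05
    diet_file: Optional[str] = None

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# staged runner (in-memory API used by the CLI and by tests)
# ---------------------------------------------------------------------------

def run_flux_study(
    effect_config: synthetic_cohort.EffectConfig,
    pipeline_config: Optional[PipelineConfig] = None,
) -> dict:
    """Synthetic inputs -> community models -> blood fluxes -> processed
    flux distributions, plus the intermediate artifacts.

    This is the modelling half of the pipeline (no metabolomics QC, no
    statistics); it returns everything needed by the association stage.
    """
    pc = pipeline_config or PipelineConfig(seed=effect_config.seed,
                                           n_samples=effect_config.n_samples)
    sim = synthetic_cohort.simulate(effect_config)

    # taxa mapping
    raw_table = sim["abundances"]
    species = taxa_mapping.filter_species_level(raw_table)
    mapped, report = taxa_mapping.map_to_resource(
        species, sim["manifest"]["resource_names"], raw=raw_table,
        floor=pc.abundance_threshold)
    final_table = taxa_mapping.renormalize(mapped, pc.abundance_threshold)
    per_sample_abund = taxa_mapping.community_abundances(final_table)

    # model assembly
    pan_models = {sp: model_assembly.build_pan_species(strains, pan_id=sp)
                  for sp, strains in sim["models"].items()}
    diet = sim["diet"]
    germfree = {}
    for sex, host in sim["hosts"].items():
        gf = host.copy()
        model_assembly.apply_diet(gf, diet)
        germfree[sex] = gf

    sample_models: Dict[str, model_assembly.MicrobiomeWBM] = {}
    sexes = sim["cohort"]["sex"]
    for sample, abund in per_sample_abund.items():
        community = model_assembly.build_community(
            pan_models, abund, coupling_factor=pc.coupling_factor)
        host = sim["hosts"][sexes[sample]]
        wbm = model_assembly.join_host_microbiome(host, community,
                                                  sample_sex=sexes[sample])
        model_assembly.apply_diet(wbm.model, diet)
        sample_models[sample] = wbm

    # FBA
    metabolites = sim["manifest"]["target_metabolites"]
    fm = fba_engine.predict_blood_fluxes(sample_models, germfree, metabolites)

    # processing
    processed, groups = flux_pipeline.process_fluxes(
        fm, zero_frac=pc.zero_frac, ident_frac=pc.ident_frac,
        tol=pc.flux_tol, r2_threshold=pc.r2_threshold)

    return {
        **sim,
        "pipeline_config": pc,
        "species_table": species,
        "mapped_table": mapped,
        "mapping_report": report,
        "final_abundances": final_table,
        "pan_models": pan_models,
        "germfree": germfree,
        "sample_models": sample_models,
        "flux_matrix": fm,
        "processed_fluxes": processed,
        "groups": groups,
    }


def run_associations(study: dict) -> dict:
    """The statistics half: derived scores plus the association battery."""
    cohort = study["cohort"]
    values = study["processed_fluxes"].analysis_values()
    values = values.reindex(cohort.index)

    subtests = cohort[[c for c in cohort.columns if c.startswith("subtest_")]]
    cognition, var_explained = stats_mod.global_cognition(subtests)
    weights = pd.Series(study["manifest"]["prs_weights"])
    prs = stats_mod.compute_prs(
        cohort[[c for c in cohort.columns if c.startswith("snp_")]], weights)

    age_results = stats_mod.flux_age_battery(values, cohort)
    cognition_results = stats_mod.flux_cognition_battery(values, cohort,
                                                         cognition)
    sex_results = stats_mod.flux_sex_battery(values, cohort)
    apoe_results = stats_mod.flux_apoe_battery(values, cohort)
    interaction_results = stats_mod.flux_sex_interaction_battery(
        values, cohort, cognition)
    prs_results = stats_mod.attach_fdr([
        stats_mod.regress_outcome(values[met], prs,
                                  pd.DataFrame({"sex": cohort["sex"]}),
                                  outcome=met, predictor="prs")
        for met in values.columns])

    attribution = stats_mod.driver_attribution(
        values, study["final_abundances"].data, study["pan_models"],
        precursors=study["manifest"]["precursors"])

    return {
        "cognition": cognition,
        "cognition_variance_explained": var_explained,
        "prs": prs,
        "age": age_results,
        "cognition_assoc": cognition_results,
        "sex": sex_results,
        "apoe": apoe_results,
        "interaction": interaction_results,
        "prs_assoc": prs_results,
        "attribution": attribution,
    }


# ---------------------------------------------------------------------------
# full run with on-disk artifacts
# ---------------------------------------------------------------------------

def run_pipeline(
    effect_config: synthetic_cohort.EffectConfig,
    outdir,
    pipeline_config: Optional[PipelineConfig] = None,
) -> dict:
    """Execute every stage, writing artifacts, a report and a run log."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pc = pipeline_config or PipelineConfig(seed=effect_config.seed,
                                           n_samples=effect_config.n_samples)
    try:
        study = run_flux_study(effect_config, pc)
    except GutWbmError:
        logger.error("pipeline failed in the modelling stages")
        raise

    qc_table = metabolomics_qc.run_qc(
        study["metabolomics"], k_sd=pc.missing_sd_factor,
        missing_frac=pc.met_missing_frac, cv_max=pc.cv_max,
        k_neighbors=pc.knn_neighbors)
    assoc = run_associations(study)

    # -- artifacts ------------------------------------------------------
    taxa_mapping.write_abundance_table(
        study["abundances"], out / "abundances_raw.tsv", out / "taxa_ranks.tsv")
    taxa_mapping.write_abundance_table(study["final_abundances"],
                                       out / "abundances_final.tsv")
    study["mapping_report"].to_frame().to_csv(out / "mapping_report.tsv",
                                              sep="\t", index=False)
    study["cohort"].to_csv(out / "cohort.tsv", sep="\t")
    fba_engine.write_flux_matrix(study["flux_matrix"], out / "flux")
    fba_engine.write_flux_matrix(study["processed_fluxes"],
                                 out / "flux_processed")
    flux_pipeline.write_groups(study["groups"], out / "metabolite_groups.tsv")
    qc_table.data.to_csv(out / "metabolomics_qc.tsv", sep="\t",
                         index_label="sample_id")
    synthetic_cohort.write_manifest(study["manifest"], out / "manifest.json")
    model_dir = out / "models"
    model_dir.mkdir(exist_ok=True)
    for sp, pan in study["pan_models"].items():
        pan.save_json(model_dir / f"{sp}.json")
    model_assembly.write_diet_tsv(study["diet"], out / "diet.tsv")

    tidy = stats_mod.results_frame(
        assoc["age"] + assoc["cognition_assoc"] + assoc["sex"]
        + [r for rs in assoc["apoe"].values() for r in rs]
        + [r for rs in assoc["interaction"].values() for r in rs]
        + assoc["prs_assoc"])
    tidy.to_csv(out / "associations.tsv", sep="\t", index=False)

    report = _build_report(study, assoc, qc_table)
    (out / "report.md").write_text(report)

    log = {
        "seed": effect_config.seed,
        "n_samples": effect_config.n_samples,
        "thresholds": dataclasses.asdict(pc),
        "checksums": {p.name: _sha256(p) for p in sorted(out.rglob("*"))
                      if p.is_file() and p.name != "run_log.json"},
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True)
                                      + "\n")
    return {**study, "qc": qc_table, "associations": assoc, "outdir": out,
            "run_log": log}


def _build_report(study: dict, assoc: dict,
                  qc_table: metabolomics_qc.MetabolomicsTable) -> str:
    rep = study["mapping_report"]
    groups = study["groups"]
    lines = [
        "# gutwbm pipeline report", "",
        f"Samples: {study['config'].n_samples}",
        f"Seed: {study['config'].seed}", "",
        "## Taxa mapping", "",
        f"- named taxa: {rep.n_named_taxa}; named species: "
        f"{rep.n_named_species}; mapped species: {rep.n_mapped_species}",
        f"- mean species read coverage: {rep.mean_species_coverage:.3f} "
        f"(SD {rep.sd_species_coverage:.3f})",
        f"- mean mapped read coverage: {rep.mean_mapped_coverage:.3f} "
        f"(SD {rep.sd_mapped_coverage:.3f})",
        f"- mean mapping coverage of species reads: "
        f"{rep.mean_mapped_of_species:.3f}", "",
        "## Flux predictions", "",
        f"- metabolites analysed: "
        f"{list(study['processed_fluxes'].scaled.columns)}",
        f"- dependent groups: {[g.name for g in groups]}", "",
        "## Metabolomics QC", "",
        f"- samples dropped: {sorted(qc_table.dropped_samples)}",
        f"- metabolites dropped: {sorted(qc_table.dropped_metabolites)}", "",
        "## Associations", "",
        f"- global cognition variance explained: "
        f"{assoc['cognition_variance_explained']:.3f}",
    ]
    for res in assoc["age"]:
        flag = " *" if res.fdr_p is not None and res.fdr_p < 0.05 else ""
        lines.append(f"- age ~ {res.outcome}: estimate {res.estimate:+.3f}, "
                     f"p {res.p:.3g}, FDR {res.fdr_p:.3g}{flag}")
    lines.append("")
    return "\n".join(lines)
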