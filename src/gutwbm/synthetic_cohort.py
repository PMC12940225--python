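"""Synthetic cohort generator: toy reconstructions, abundances, covariates,
metabolomics — every input the pipeline needs, with planted ground truth.

The generator emulates the *shape* of a 16S microbiome/metabolomics aging
cohort, not its biology: species-level relative-abundance vectors with a
configurable unmapped fraction, toy pan-species reconstructions with planted
producer species for target metabolites (including a lossy two-step bile
acid-like chain), covariates with planted standardized effect sizes, and a
metabolomics table with batch scale factors, missingness, and replicate
aliquots for CV estimation.

Every planted fact (producer identities, chain membership, effect slopes,
QC plants) is recorded in a machine-readable manifest so downstream recovery
tests can check the pipeline against ground truth.

Randomness is organised as one named substream per output artifact, derived
from the master seed, so adding an output never perturbs existing ones.
Fixed seeds give bit-identical outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError
from .metabolomics_qc import MetabolomicsTable
from .model_assembly import DEFAULT_BOUND, StoichiometricModel
from .taxa_mapping import RANK_HIGHER, RANK_SPECIES, AbundanceTable

# cohort-level demographic anchors (healthy aging cohort):
AGE_MEAN, AGE_SD, AGE_MIN, AGE_MAX = 61.7, 5.5, 51.0, 92.0
BMI_MEAN, BMI_SD = 27.4, 4.5
FEMALE_FRACTION = 608 / 1065
EDUCATION_PROBS = (62 / 1062, 348 / 1062, 320 / 1062, 332 / 1062)
APOE_GENOTYPES = ("E2/E2", "E2/E3", "E2/E4", "E3/E3", "E3/E4", "E4/E4")
APOE_PROBS = (5 / 1065, 121 / 1065, 25 / 1065, 644 / 1065, 251 / 1065, 19 / 1065)

#: cognitive-factor loading chosen so the first principal component of the
#: five subtests explains ~47% of variance (x_j = L*f + e, e ~ N(0,1))
COGNITION_LOADING = 0.714

HOST_ONLY_METABOLITE = "host_only_met"


@dataclass
class EffectConfig:
    """Configuration of the synthetic cohort and its planted effects.

    Defaults define the acceptance study conditions: a 500-sample cohort,
    seven mapped species including one sole producer per target metabolite,
    a planted standardized age slope of 0.3 on the L-arginine-like driver
    species, an APOE-group abundance shift on the bile-acid-like driver, and
    a two-batch metabolomics table with 5% missingness.
    """

    n_samples: int = 500
    seed: int = 0

    # species -> (target metabolite, monotone abundance-flux link)
    driver_species: Dict[str, Tuple[str, bool]] = field(default_factory=lambda: {
        "arg_driver": ("arg_like", True),
        "bile_driver": ("dca_like", True),
        "chain_producer": ("ba_a", True),
        "null_producer_1": ("null_met_1", True),
        "null_producer_2": ("null_met_2", True),
    })
    nonproducer_species: Tuple[str, ...] = ("null_sp_1", "null_sp_2")
    unmapped_species: Tuple[str, ...] = (
        "unmapped_sp_1", "unmapped_sp_2", "unmapped_sp_3", "unmapped_sp_4")
    higher_rank_taxa: Tuple[str, ...] = (
        "genus_a", "genus_b", "family_c", "order_d")

    # strict two-step chain: precursor -> product with the given yield; a
    # yield < 1 gives the product the smaller maximal flux (representative)
    chain: Tuple[str, str, float] = ("ba_a", "ba_b", 0.8)

    # (covariate, species, standardized slope on the log-abundance scale)
    covariate_effects: List[Tuple[str, str, float]] = field(
        default_factory=lambda: [("age", "arg_driver", 0.3)])
    # per-APOE-group abundance multipliers for one species
    apoe_shift: Tuple[str, Dict[str, float]] = (
        "bile_driver", None)
    sex_fraction: float = FEMALE_FRACTION

    # abundance model
    log_abundance_sd: float = 0.6
    species_coverage_mean: float = 0.495
    species_coverage_sd: float = 0.097
    mapped_of_species_mean: float = 0.64
    mapped_of_species_sd: float = 0.116

    # metabolomics
    metabolomics_batches: int = 2
    batch_scale_factors: Tuple[float, ...] = (1.0, 2.5)
    missingness_rate: float = 0.05
    n_serum_metabolites: int = 60
    n_aliquot_groups: int = 6
    aliquots_per_group: int = 2
    plant_missing_outlier: bool = True
    plant_high_missing_met: bool = True
    plant_high_cv_met: bool = True
    # (metabolite, APOE group, log2 shift)
    planted_group_difference: Tuple[str, str, float] = ("dca_serum", "E4", 1.0)

    # cognition and genetics
    cognition_loading: float = COGNITION_LOADING
    cognition_age_slope: float = -0.2
    cognition_sex_shift: float = 0.4  # female minus male, on the factor
    n_snps: int = 28

    diet_flux: float = 1000.0

    def __post_init__(self) -> None:
        if self.apoe_shift[1] is None:
            self.apoe_shift = (self.apoe_shift[0],
                               {"E2": 0.6, "E3": 1.0, "E4": 1.5})
        self.validate()

    # -- derived -------------------------------------------------------
    @property
    def mapped_species(self) -> List[str]:
        return list(self.driver_species) + list(self.nonproducer_species)

    @property
    def target_metabolites(self) -> List[str]:
        mets = [m for m, _ in self.driver_species.values()]
        if self.chain and self.chain[1] not in mets:
            mets.append(self.chain[1])
        mets.append(HOST_ONLY_METABOLITE)
        return mets

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ConfigError("n_samples must be >= 2")
        for p, nm in [(self.sex_fraction, "sex_fraction"),
                      (self.missingness_rate, "missingness_rate")]:
            if not 0 <= p <= 1:
                raise ConfigError(f"{nm} must be in [0, 1]")
        if len(self.mapped_species) < 2:
            raise ConfigError("need at least two mapped species")
        known = set(self.mapped_species)
        for cov, sp, slope in self.covariate_effects:
            if sp not in known:
                raise ConfigError(f"covariate effect references undefined "
                                  f"species {sp!r}")
            if not -1 < slope < 1:
                raise ConfigError("standardized slopes must lie in (-1, 1)")
        if self.apoe_shift[0] not in known:
            raise ConfigError(f"apoe_shift references undefined species "
                              f"{self.apoe_shift[0]!r}")
        if self.chain:
            prec, prod, conv = self.chain
            producers = {m for m, _ in self.driver_species.values()}
            if prec not in producers:
                raise ConfigError(f"chain precursor {prec!r} has no producer "
                                  "species")
            if conv <= 0:
                raise ConfigError("chain yield must be positive")
        if len(self.batch_scale_factors) < self.metabolomics_batches:
            raise ConfigError("need one scale factor per metabolomics batch")


def substream(config_or_seed, name: str) -> np.random.Generator:
    """A named random substream derived from the master seed."""
    seed = (config_or_seed.seed if isinstance(config_or_seed, EffectConfig)
            else int(config_or_seed))
    key = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


# ---------------------------------------------------------------------------
# toy reconstructions
# ---------------------------------------------------------------------------

def _species_reactions(config: EffectConfig, species: str) -> Dict[str, dict]:
    """Reaction set of one toy species: lumen uptakes, biomass, and (for
    producers) a production + secretion route per target metabolite.

    Biomass draws on a dedicated uptake so growth never competes with
    production for the same coupled uptake reaction; the coupling constraint
    is then the unique active bound on a sole producer's secretion route.
    """
    rxns: Dict[str, dict] = {
        "UPT_bio": dict(metabolites={"diet_sub[luM]": -1.0, "bio_sub[c]": 1.0},
                        lb=0.0, ub=DEFAULT_BOUND),
        "BIO": dict(metabolites={"bio_sub[c]": -1.0, "biomass[c]": 1.0},
                    lb=0.0, ub=DEFAULT_BOUND),
    }
    target = dict(config.driver_species).get(species, (None, None))[0]
    if target is not None:
        rxns["UPT_sub"] = dict(
            metabolites={"diet_sub[luM]": -1.0, "diet_sub[c]": 1.0},
            lb=0.0, ub=DEFAULT_BOUND)
        rxns[f"PROD_{target}"] = dict(
            metabolites={"diet_sub[c]": -1.0, f"{target}[c]": 1.0},
            lb=0.0, ub=DEFAULT_BOUND)
        rxns[f"SEC_{target}"] = dict(
            metabolites={f"{target}[c]": -1.0, f"{target}[luM]": 1.0},
            lb=0.0, ub=DEFAULT_BOUND)
        if config.chain and config.chain[0] == target:
            prec, prod, conv = config.chain
            rxns[f"CONV_{prec}_{prod}"] = dict(
                metabolites={f"{prec}[c]": -1.0, f"{prod}[c]": conv},
                lb=0.0, ub=DEFAULT_BOUND)
            rxns[f"SEC_{prod}"] = dict(
                metabolites={f"{prod}[c]": -1.0, f"{prod}[luM]": 1.0},
                lb=0.0, ub=DEFAULT_BOUND)
    if species == "null_sp_1" and "arg_driver" in config.driver_species:
        # an L-arginine *exchanger* (uptake/degradation route, no production):
        # a candidate in driver attribution that is not the true driver
        arg = config.driver_species["arg_driver"][0]
        rxns[f"DEG_{arg}"] = dict(
            metabolites={f"{arg}[luM]": -1.0, "diet_sub[luM]": 0.5},
            lb=0.0, ub=DEFAULT_BOUND)
    return rxns


def generate_toy_reconstructions(
    config: EffectConfig,
) -> Dict[str, List[StoichiometricModel]]:
    """Strain-level toy reconstructions per mapped species.

    Producer species get two strains whose reaction sets overlap but only
    union to the full route (exercising pan-species union and widest-bound
    merging); non-producers get a single strain.  Construction is fully
    deterministic, so fixed seeds trivially give byte-identical model files.
    """
    out: Dict[str, List[StoichiometricModel]] = {}
    for sp in config.mapped_species:
        rxns = _species_reactions(config, sp)
        strains: List[StoichiometricModel] = []
        is_producer = sp in config.driver_species
        n_strains = 2 if is_producer else 1
        for k in range(n_strains):
            strain = StoichiometricModel(f"{sp}_strain{k + 1}")
            for rid, spec in rxns.items():
                # strain 2 misses the secretion routes; strain 1 carries a
                # tighter uptake bound so the pan union widens it again
                if n_strains == 2 and k == 1 and rid.startswith("SEC_"):
                    continue
                ub = spec["ub"]
                if n_strains == 2 and k == 0 and rid == "UPT_bio":
                    ub = 1000.0
                strain.add_reaction(rid, spec["metabolites"], spec["lb"], ub)
            strain.biomass_reaction = "BIO"
            strains.append(strain)
        out[sp] = strains
    return out


def generate_host_model(config: EffectConfig, sex: str) -> StoichiometricModel:
    """A minimal multi-compartment whole-body host for one sex.

    Diet enters through ``EX_diet_sub[d]``, is transported to the
    large-intestinal lumen, absorbed into blood, and consumed by the pinned
    whole-body objective.  One host-only metabolite is synthesised by the
    host at a capped rate, identically with and without a microbiome, so its
    scaled flux is exactly zero.  Target metabolites have absorption routes
    from the LI lumen into blood but no host production.
    """
    host = StoichiometricModel(f"host_{sex}", sex=sex)
    host.add_reaction("EX_diet_sub[d]", {"diet_sub[d]": -1.0})
    host.add_reaction("TR_diet_sub", {"diet_sub[d]": -1.0,
                                      "diet_sub[luLI]": 1.0}, 0.0)
    host.add_reaction("ABS_diet_sub", {"diet_sub[luLI]": -1.0,
                                       "diet_sub[bc]": 1.0}, 0.0)
    host.add_reaction("HOST_BIO", {"diet_sub[bc]": -1.0,
                                   "host_bio[bc]": 1.0}, 0.0)
    host.add_reaction("Whole_body_objective_rxn", {"host_bio[bc]": -1.0},
                      1.0, 1.0)
    host.add_reaction(f"SYN_{HOST_ONLY_METABOLITE}",
                      {"diet_sub[bc]": -1.0,
                       f"{HOST_ONLY_METABOLITE}[bc]": 1.0}, 0.0, 50.0)
    for met in config.target_metabolites:
        if met == HOST_ONLY_METABOLITE:
            continue
        host.add_reaction(f"ABS_{met}", {f"{met}[luLI]": -1.0,
                                         f"{met}[bc]": 1.0}, 0.0)
    return host


def default_diet(config: EffectConfig) -> Dict[str, float]:
    return {"diet_sub": config.diet_flux}


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def generate_covariates(config: EffectConfig) -> pd.DataFrame:
    """Cohort table: demographics, APOE genotype, cognitive subtests, SNP
    dosages.  Always drawn from the 'covariates' substream so other
    generators can regenerate the identical table."""
    rng = substream(config, "covariates")
    n = config.n_samples
    idx = [f"S{i + 1:04d}" for i in range(n)]
    age = np.clip(rng.normal(AGE_MEAN, AGE_SD, n), AGE_MIN, AGE_MAX)
    sex = np.where(rng.random(n) < config.sex_fraction, "female", "male")
    bmi = np.clip(rng.normal(BMI_MEAN, BMI_SD, n), 15.0, 50.0)
    education = rng.choice([1, 2, 3, 4], size=n, p=EDUCATION_PROBS)
    apoe = rng.choice(APOE_GENOTYPES, size=n, p=APOE_PROBS)

    z_age = (age - AGE_MEAN) / AGE_SD
    sex_c = np.where(sex == "female", 0.5, -0.5)
    factor = (config.cognition_age_slope * z_age
              + config.cognition_sex_shift * sex_c
              + rng.normal(0.0, 1.0, n))
    subtests = {
        f"subtest_{j + 1}": config.cognition_loading * factor
        + rng.normal(0.0, 1.0, n)
        for j in range(5)
    }

    uni = substream(config, "universe")
    mafs = uni.uniform(0.05, 0.5, config.n_snps)
    snps = {f"snp_{i + 1:02d}": rng.binomial(2, mafs[i], n).astype(float)
            for i in range(config.n_snps)}

    df = pd.DataFrame({"age": age, "sex": sex, "bmi": bmi,
                       "education": education, "apoe_genotype": apoe,
                       **subtests, **snps}, index=pd.Index(idx, name="sample_id"))
    return df


def prs_weights(config: EffectConfig) -> pd.Series:
    """Published-style per-SNP effect weights (fixed by the master seed)."""
    uni = substream(config, "universe")
    uni.uniform(0.05, 0.5, config.n_snps)  # skip the MAF draw
    w = uni.normal(0.0, 0.12, config.n_snps)
    return pd.Series(w, index=[f"snp_{i + 1:02d}" for i in range(config.n_snps)],
                     name="weight")


# ---------------------------------------------------------------------------
# abundances
# ---------------------------------------------------------------------------

def _apoe_group_of(genotype: str) -> str:
    if genotype in ("E2/E2", "E2/E3"):
        return "E2"
    if genotype == "E3/E3":
        return "E3"
    if genotype in ("E3/E4", "E4/E4"):
        return "E4"
    return "excluded"


def generate_abundance_table(
    config: EffectConfig,
    models: Optional[Mapping[str, List[StoichiometricModel]]] = None,
    cohort: Optional[pd.DataFrame] = None,
) -> AbundanceTable:
    """Relative-abundance table with mapped species, unmapped species, and
    higher-rank pseudo-taxa; rows sum to one.

    Mapped-species weights follow a log-normal model: per-species base
    weights, planted covariate effects added on the log scale (coefficient
    ``slope / sqrt(1 - slope^2) * sd`` so the *standardized* log-abundance
    slope equals the configured value), APOE-group multipliers, then closure
    to the simplex within the mapped block.  The mapped block's share of the
    species reads and the species share of all reads are drawn per sample
    around the configured coverage means.
    """
    if cohort is None:
        cohort = generate_covariates(config)
    rng = substream(config, "abundance")
    n = config.n_samples
    sp_names = config.mapped_species
    uni = substream(config, "universe_abund")
    base = uni.normal(0.0, 0.2, len(sp_names))
    # species carrying planted covariate effects get a smaller base share so
    # that simplex closure leaks only a negligible anti-correlation onto the
    # null species (compositional artifacts would otherwise break the
    # planted-null ground truth)
    effect_species = {sp for _, sp, _ in config.covariate_effects}
    for j, sp in enumerate(sp_names):
        if sp in effect_species:
            base[j] += np.log(0.3)

    sd = config.log_abundance_sd
    logw = np.tile(base, (n, 1)) + rng.normal(0.0, sd, (n, len(sp_names)))
    z = {
        "age": ((cohort["age"] - AGE_MEAN) / AGE_SD).to_numpy(),
        "bmi": ((cohort["bmi"] - BMI_MEAN) / BMI_SD).to_numpy(),
        "sex": np.where(cohort["sex"] == "female", 0.5, -0.5) / 0.5,
        "education": ((cohort["education"] - 2.87) / 0.93).to_numpy(),
    }
    for cov, sp, slope in config.covariate_effects:
        beta = slope / np.sqrt(1.0 - slope ** 2) * sd
        logw[:, sp_names.index(sp)] += beta * z[cov]
    shift_sp, multipliers = config.apoe_shift
    groups = cohort["apoe_genotype"].map(_apoe_group_of).to_numpy()
    mult = np.array([multipliers.get(g, 1.0) for g in groups])
    logw[:, sp_names.index(shift_sp)] += np.log(mult)

    w = np.exp(logw)
    mapped_block = w / w.sum(axis=1, keepdims=True)

    species_share = np.clip(
        rng.normal(config.species_coverage_mean, config.species_coverage_sd, n),
        0.05, 1.0)
    mapped_within = np.clip(
        rng.normal(config.mapped_of_species_mean, config.mapped_of_species_sd, n),
        0.05, 1.0)

    cols: Dict[str, np.ndarray] = {}
    for j, sp in enumerate(sp_names):
        cols[sp] = mapped_block[:, j] * species_share * mapped_within
    n_un = len(config.unmapped_species)
    if n_un:
        wu = rng.dirichlet(np.ones(n_un) * 3.0, size=n)
        for j, sp in enumerate(config.unmapped_species):
            cols[sp] = wu[:, j] * species_share * (1.0 - mapped_within)
    else:
        # fold the unmapped share back into the mapped species
        for sp in sp_names:
            cols[sp] = cols[sp] / mapped_within
    n_hi = len(config.higher_rank_taxa)
    if n_hi:
        wh = rng.dirichlet(np.ones(n_hi) * 3.0, size=n)
        for j, tx in enumerate(config.higher_rank_taxa):
            cols[tx] = wh[:, j] * (1.0 - species_share)
    else:
        total = species_share
        for c in cols:
            cols[c] = cols[c] / total

    data = pd.DataFrame(cols, index=cohort.index)
    data = data.div(data.sum(axis=1), axis=0)  # close exactly to the simplex
    ranks = {sp: RANK_SPECIES
             for sp in list(sp_names) + list(config.unmapped_species)}
    ranks.update({tx: RANK_HIGHER for tx in config.higher_rank_taxa})
    return AbundanceTable(data, ranks)


# ---------------------------------------------------------------------------
# metabolomics
# ---------------------------------------------------------------------------

QC_HIGH_MISSING_MET = "qc_high_missing_met"
QC_HIGH_CV_MET = "qc_high_cv_met"
#: aliquot ratio 1:1.65 gives a between-aliquot CV of 0.347 (> the 0.30 cut)
HIGH_CV_RATIO = 1.65


def generate_metabolomics(
    config: EffectConfig,
    cohort: Optional[pd.DataFrame] = None,
) -> MetabolomicsTable:
    """Raw peak-intensity table with batch scale factors, missingness and
    replicate aliquots.

    Plants (when enabled): one sample with ~10x the missingness rate (to be
    caught by the mean + 5 SD sample filter), one metabolite missing in 85%
    of samples (70% filter), and one metabolite whose replicate aliquots
    disagree by the 1:1.65 ratio (CV 0.347, caught by the 30% CV filter).
    A log2 group difference is planted on one metabolite for one APOE group.
    """
    if cohort is None:
        cohort = generate_covariates(config)
    rng = substream(config, "metabolomics")
    n = config.n_samples
    met_names = [f"met_{i + 1:03d}" for i in range(config.n_serum_metabolites)]
    met_names[0] = "dca_serum"
    met_names[1] = "arg_serum"
    if config.plant_high_missing_met:
        met_names[-2] = QC_HIGH_MISSING_MET
    if config.plant_high_cv_met:
        met_names[-1] = QC_HIGH_CV_MET
    m = len(met_names)

    uni = substream(config, "universe_metab")
    met_scale = 10.0 ** uni.uniform(3.0, 6.0, m)

    batches = rng.integers(0, config.metabolomics_batches, n)
    factors = np.asarray(config.batch_scale_factors[:config.metabolomics_batches])

    log2_vals = (np.log2(met_scale)[None, :]
                 + rng.normal(0.0, 0.45, (n, m)))
    shift_met, shift_group, shift = config.planted_group_difference
    if shift_met in met_names:
        groups = cohort["apoe_genotype"].map(_apoe_group_of).to_numpy()
        log2_vals[:, met_names.index(shift_met)] += np.where(
            groups == shift_group, shift, 0.0)
    values = 2.0 ** log2_vals * factors[batches][:, None]

    miss_rate = np.full(n, config.missingness_rate)
    outlier_sample = None
    if config.plant_missing_outlier and config.missingness_rate > 0:
        outlier_sample = cohort.index[0]
        miss_rate[0] = min(10.0 * config.missingness_rate, 0.9)
    miss = rng.random((n, m)) < miss_rate[:, None]
    if config.plant_high_missing_met:
        jm = met_names.index(QC_HIGH_MISSING_MET)
        miss[:, jm] = rng.random(n) < 0.85
    values[miss] = np.nan

    data = pd.DataFrame(values, index=cohort.index, columns=met_names)
    batch_series = pd.Series(
        [f"batch_{b + 1}" for b in batches], index=cohort.index, name="batch")
    aliquot = pd.Series(pd.NA, index=cohort.index, name="aliquot_group",
                        dtype=object)

    # replicate aliquot rows for CV estimation
    rows, labels, arow_batches = [], [], []
    for g in range(config.n_aliquot_groups):
        b = g % config.metabolomics_batches
        base = 2.0 ** (np.log2(met_scale) + rng.normal(0.0, 0.45, m))
        for r in range(config.aliquots_per_group):
            v = base * np.exp(rng.normal(0.0, 0.03, m))
            if config.plant_high_cv_met:
                jc = met_names.index(QC_HIGH_CV_MET)
                v[jc] = base[jc] * (HIGH_CV_RATIO if r % 2 else 1.0)
            rows.append(v * factors[b])
            labels.append((f"QC_g{g + 1}_r{r + 1}", f"aliquot_{g + 1}",
                           f"batch_{b + 1}"))
    if rows:
        qc_idx = [lbl[0] for lbl in labels]
        qc_df = pd.DataFrame(np.array(rows), index=qc_idx, columns=met_names)
        data = pd.concat([data, qc_df])
        batch_series = pd.concat([
            batch_series,
            pd.Series([lbl[2] for lbl in labels], index=qc_idx, name="batch")])
        aliquot = pd.concat([
            aliquot,
            pd.Series([lbl[1] for lbl in labels], index=qc_idx,
                      name="aliquot_group", dtype=object)])

    return MetabolomicsTable(data=data, batches=batch_series,
                             aliquot_groups=aliquot)


def generate_covariates_and_metabolomics(
    config: EffectConfig,
) -> Tuple[pd.DataFrame, MetabolomicsTable]:
    cohort = generate_covariates(config)
    return cohort, generate_metabolomics(config, cohort)


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def build_manifest(config: EffectConfig) -> dict:
    """Machine-readable record of every planted ground-truth fact."""
    prec, prod, conv = config.chain
    producers = {met: sp for sp, (met, _) in config.driver_species.items()}
    producers[prod] = [sp for sp, (met, _) in config.driver_species.items()
                       if met == prec][0]
    manifest = {
        "seed": config.seed,
        "n_samples": config.n_samples,
        "mapped_species": config.mapped_species,
        "resource_names": config.mapped_species,
        "unmapped_species": list(config.unmapped_species),
        "higher_rank_taxa": list(config.higher_rank_taxa),
        "target_metabolites": config.target_metabolites,
        "host_only_metabolite": HOST_ONLY_METABOLITE,
        "producers": producers,
        "precursors": {prod: prec},
        "chain": {"members": [prec, prod], "yield": conv,
                  "expected_representative": prod if conv < 1.0 else prec},
        "covariate_effects": [
            {"covariate": c, "species": s, "standardized_slope": b}
            for c, s, b in config.covariate_effects],
        "apoe_shift": {"species": config.apoe_shift[0],
                       "multipliers": config.apoe_shift[1]},
        "planted_group_difference": {
            "metabolite": config.planted_group_difference[0],
            "group": config.planted_group_difference[1],
            "log2_shift": config.planted_group_difference[2]},
        "species_coverage_mean": config.species_coverage_mean,
        "mapped_of_species_mean": config.mapped_of_species_mean,
        "batch_scale_factors": list(
            config.batch_scale_factors[:config.metabolomics_batches]),
        "missingness_rate": config.missingness_rate,
        "qc_plants": {
            "missing_outlier_sample": ("S0001" if config.plant_missing_outlier
                                       and config.missingness_rate > 0 else None),
            "high_missing_metabolite": (QC_HIGH_MISSING_MET
                                        if config.plant_high_missing_met else None),
            "high_cv_metabolite": (QC_HIGH_CV_MET
                                   if config.plant_high_cv_met else None),
            "planted_cv": 0.347,
        },
        "cognition": {"loading": config.cognition_loading,
                      "expected_variance_explained": 0.47},
        "prs_weights": prs_weights(config).to_dict(),
        "diet": default_diet(config),
        "coupling_factor": 400.0,
    }
    return manifest


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# one-call simulation
# ---------------------------------------------------------------------------

def simulate(config: EffectConfig) -> dict:
    """Generate every pipeline input; returns a dict of artifacts."""
    models = generate_toy_reconstructions(config)
    cohort = generate_covariates(config)
    abundances = generate_abundance_table(config, models, cohort)
    metabolomics = generate_metabolomics(config, cohort)
    hosts = {sex: generate_host_model(config, sex)
             for sex in ("female", "male")}
    return {
        "config": config,
        "models": models,
        "cohort": cohort,
        "abundances": abundances,
        "metabolomics": metabolomics,
        "hosts": hosts,
        "diet": default_diet(config),
        "manifest": build_manifest(config),
    }
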