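"""Derived scores and the association battery against AD risk factors.

Covers: the global cognition score (first principal component of the
standardized cognitive subtests), weighted polygenic risk scores
(PRS = sum_i D_i * E_i over SNP dosages D and published weights E), APOE
risk groups (E2 = {E2/E2, E2/E3}, E3 = {E3/E3}, E4 = {E3/E4, E4/E4},
E2/E4 excluded), and the statistical battery linking predicted blood fluxes,
species abundances and serum metabolomics to age, APOE group, global
cognition and sex:

* standardized linear regressions (OLS, two-sided Wald p on the focal
  coefficient, Benjamini-Hochberg FDR across the metabolite family per
  analysis);
* Kruskal-Wallis with tie correction plus post-hoc Dunn pairwise z tests
  (exact permutation p for small enumerable instances);
* Wilcoxon rank-sum for sex differences;
* flux-by-sex interaction regressions with per-sex stratified follow-ups;
* exact Fisher tests on 2 x C contingency tables by full enumeration of the
  conditional (multivariate hypergeometric) distribution;
* Welch two-sample t tests, from values or from (mean, SD, n) summaries;
* driver-species attribution: per metabolite, candidate species (those whose
  reconstruction can produce or exchange the metabolite, or produce a
  declared precursor) ranked by the R-squared of a simple regression of the
  log2-standardized abundance against the predicted flux.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .errors import InputError
from .model_assembly import StoichiometricModel

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    """One outcome x predictor test result."""

    outcome: str
    predictor: str
    test: str  # linear | kruskal_wallis | dunn | wilcoxon | interaction |
    #            fisher_rxc | t_two_sample
    estimate: Optional[float]
    statistic: Optional[float]
    p: float
    fdr_p: Optional[float] = None
    n: int = 0
    covariates: Tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "outcome": self.outcome, "predictor": self.predictor,
            "test": self.test, "estimate": self.estimate,
            "statistic": self.statistic, "p": self.p, "fdr_p": self.fdr_p,
            "n": self.n, "covariates": ";".join(self.covariates),
        }


def results_frame(results: Iterable[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])


# ---------------------------------------------------------------------------
# derived scores
# ---------------------------------------------------------------------------

def apoe_groups(genotypes: pd.Series) -> pd.Series:
    """Collapse APOE genotypes into risk groups; E2/E4 is excluded because
    the protective and risk alleles cannot be separated."""
    mapping = {"E2/E2": "E2", "E2/E3": "E2", "E3/E3": "E3",
               "E3/E4": "E4", "E4/E4": "E4", "E2/E4": "excluded"}
    unknown = set(genotypes.dropna().unique()) - set(mapping)
    if unknown:
        raise InputError(f"unknown APOE genotypes: {sorted(unknown)}")
    return genotypes.map(mapping)


def global_cognition(subtests: pd.DataFrame) -> Tuple[pd.Series, float]:
    """Global cognition score: first principal component of the standardized
    subtests, oriented to correlate positively with the mean standardized
    subtest; also returns the fraction of variance explained."""
    from sklearn.decomposition import PCA

    if subtests.shape[1] < 2:
        raise InputError("need at least two cognitive subtests")
    complete = subtests.dropna()
    sd = complete.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = sd.index[sd == 0].tolist()
        raise InputError(f"constant subtest column(s): {bad}")
    z = (complete - complete.mean(axis=0)) / sd
    pca = PCA(n_components=1)
    score = pd.Series(pca.fit_transform(z.to_numpy())[:, 0], index=z.index,
                      name="global_cognition")
    if np.corrcoef(score, z.mean(axis=1))[0, 1] < 0:
        score = -score
    return score, float(pca.explained_variance_ratio_[0])


def compute_prs(dosages: pd.DataFrame, weights: pd.Series) -> pd.Series:
    """PRS = sum_i D_i * E_i.  Samples with any missing dosage get a missing
    PRS (no zero-fill)."""
    missing = weights.index.difference(dosages.columns)
    if len(missing):
        raise InputError(f"dosage table lacks SNPs: {list(missing)[:5]}")
    D = dosages[weights.index]
    if ((D < 0) | (D > 2)).any().any():
        raise InputError("allelic dosages must lie in [0, 2]")
    return (D * weights).sum(axis=1, skipna=False).rename("prs")


def log2_standardize(x: pd.Series) -> pd.Series:
    """log2 then z-transform, the preprocessing used for relative abundances
    and serum intensities in the regressions; zeros become missing."""
    pos = x.where(x > 0)
    lg = np.log2(pos)
    return (lg - lg.mean()) / lg.std(ddof=1)


def zscore(x: pd.Series) -> pd.Series:
    return (x - x.mean()) / x.std(ddof=1)


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------

def _encode_covariates(covariates: Optional[pd.DataFrame]) -> pd.DataFrame:
    if covariates is None:
        return pd.DataFrame()
    enc = {}
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(s.dropna().unique())
            if len(levels) > 2:
                raise InputError(
                    f"covariate {col!r} has {len(levels)} levels; encode it "
                    "explicitly")
            enc[col] = (s == levels[-1]).astype(float) if len(levels) == 2 \
                else pd.Series(0.0, index=s.index)
        else:
            enc[col] = s.astype(float)
    return pd.DataFrame(enc)


def regress_outcome(
    y: pd.Series,
    x: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
    standardize: bool = True,
    outcome: str = "y",
    predictor: str = "x",
) -> AssociationResult:
    """OLS of ``y`` on ``x`` plus covariates; two-sided Wald p for the focal
    coefficient.  With ``standardize`` the focal predictor and a continuous
    outcome are z-scored first, so the estimate is a standardized slope."""
    import statsmodels.api as sm

    cov = _encode_covariates(covariates)
    parts = [y.rename("__y"), x.rename("__x")]
    if not cov.empty:
        parts.append(cov)
    frame = pd.concat(parts, axis=1).dropna()
    if len(frame) < len(frame.columns) + 2:
        raise InputError("too few complete cases for regression")
    yv = frame["__y"]
    xv = frame["__x"]
    if standardize:
        xv = zscore(xv)
        yv = zscore(yv)
    X = sm.add_constant(pd.concat([xv.rename("__x"), frame[cov.columns]],
                                  axis=1))
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax() if corr.size else ("?", "?")
        raise InputError(f"rank-deficient design; near-collinear columns "
                         f"{worst}")
    fit = sm.OLS(yv.to_numpy(), X.to_numpy()).fit()
    j = list(X.columns).index("__x")
    return AssociationResult(
        outcome=outcome, predictor=predictor, test="linear",
        estimate=float(fit.params[j]), statistic=float(fit.tvalues[j]),
        p=float(fit.pvalues[j]), n=len(frame),
        covariates=tuple(cov.columns))


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def _kw_statistic(ranks: np.ndarray, labels: np.ndarray,
                  tie_correction: float) -> float:
    N = len(ranks)
    h = 0.0
    for g in np.unique(labels):
        r = ranks[labels == g]
        h += r.sum() ** 2 / len(r)
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    return h / tie_correction if tie_correction > 0 else np.nan


def _tie_correction(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    N = len(values)
    return 1.0 - (counts ** 3 - counts).sum() / (N ** 3 - N)


#: enumeration cap for the exact Kruskal-Wallis permutation distribution
KW_EXACT_MAX = 50_000


def kruskal_dunn(
    y: pd.Series,
    groups: pd.Series,
    method: str = "auto",
    outcome: str = "y",
    predictor: str = "group",
) -> List[AssociationResult]:
    """Kruskal-Wallis (tie-corrected) plus post-hoc Dunn pairwise tests.

    Returns the KW result followed by one Dunn result per group pair
    (two-sided z from pooled ranks, reported unadjusted).  Groups with fewer
    than two members are dropped with a warning.  ``method='exact'`` (or
    'auto' on small instances) replaces the chi-square p of the KW test with
    the exact permutation p over all distinct assignments of the pooled
    values to the group sizes.
    """
    frame = pd.concat([y.rename("y"), groups.rename("g")], axis=1).dropna()
    sizes = frame["g"].value_counts()
    small = sizes.index[sizes < 2]
    for g in small:
        logger.warning("group %r has fewer than two members; dropped", g)
    frame = frame[~frame["g"].isin(small)]
    labels = frame["g"].to_numpy()
    values = frame["y"].to_numpy(dtype=float)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise InputError("need at least two groups of size >= 2")
    N = len(values)
    ranks = stats.rankdata(values)
    tie = _tie_correction(values)
    h = _kw_statistic(ranks, labels, tie)

    n_perm = math.factorial(N)
    for g in uniq:
        n_perm //= math.factorial(int((labels == g).sum()))
    use_exact = method == "exact" or (method == "auto" and n_perm <= KW_EXACT_MAX)
    if use_exact:
        p_kw = _kw_exact_p(ranks, labels, tie, h)
    else:
        if method == "exact":
            raise InputError(f"{n_perm} assignments exceed the exact "
                             f"enumeration cap {KW_EXACT_MAX}")
        p_kw = float(stats.chi2.sf(h, df=len(uniq) - 1))
    results = [AssociationResult(
        outcome=outcome, predictor=predictor, test="kruskal_wallis",
        estimate=None, statistic=float(h), p=p_kw, n=N)]

    # Dunn pairwise z statistics from the pooled ranks
    _, counts = np.unique(values, return_counts=True)
    T = (counts ** 3 - counts).sum() / (12.0 * (N - 1))
    for a, b in itertools.combinations(uniq, 2):
        ra = ranks[labels == a]
        rb = ranks[labels == b]
        var = (N * (N + 1) / 12.0 - T) * (1.0 / len(ra) + 1.0 / len(rb))
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = (ra.mean() - rb.mean()) / math.sqrt(var)
            p = float(2.0 * stats.norm.sf(abs(z)))
        results.append(AssociationResult(
            outcome=outcome, predictor=f"{a} vs {b}", test="dunn",
            estimate=float(ra.mean() - rb.mean()), statistic=float(z), p=p,
            n=len(ra) + len(rb)))
    return results


def _kw_exact_p(ranks: np.ndarray, labels: np.ndarray, tie: float,
                h_obs: float) -> float:
    """Exact permutation p of the KW statistic: enumerate all distinct
    assignments of the pooled ranks to the observed group sizes."""
    uniq = np.unique(labels)
    sizes = [int((labels == g).sum()) for g in uniq]
    idx = np.arange(len(ranks))

    count = 0
    at_least = 0

    def recurse(remaining: np.ndarray, gi: int, chosen: List[np.ndarray]):
        nonlocal count, at_least
        if gi == len(sizes) - 1:
            assignment = chosen + [remaining]
            lab = np.empty(len(ranks), dtype=int)
            for k, members in enumerate(assignment):
                lab[members] = k
            h = _kw_statistic(ranks, lab, tie)
            count += 1
            if h >= h_obs - 1e-12:
                at_least += 1
            return
        for combo in itertools.combinations(range(len(remaining)), sizes[gi]):
            members = remaining[list(combo)]
            rest = np.delete(remaining, list(combo))
            recurse(rest, gi + 1, chosen + [members])

    recurse(idx, 0, [])
    return at_least / count


def wilcoxon_sex(
    y: pd.Series,
    sex: pd.Series,
    outcome: str = "y",
) -> AssociationResult:
    """Two-sided Wilcoxon rank-sum test for a sex difference (tie-corrected;
    exact when sample sizes are small and tie-free)."""
    frame = pd.concat([y.rename("y"), sex.rename("s")], axis=1).dropna()
    levels = sorted(frame["s"].unique())
    if len(levels) != 2:
        raise InputError(f"need exactly two sex groups, got {levels}")
    a = frame.loc[frame["s"] == levels[0], "y"].to_numpy(dtype=float)
    b = frame.loc[frame["s"] == levels[1], "y"].to_numpy(dtype=float)
    if np.ptp(np.concatenate([a, b])) == 0:
        # all observations identical: no evidence of a shift
        return AssociationResult(outcome=outcome, predictor="sex",
                                 test="wilcoxon", estimate=0.0, statistic=None,
                                 p=1.0, n=len(frame))
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return AssociationResult(
        outcome=outcome, predictor=f"{levels[0]} vs {levels[1]}",
        test="wilcoxon", estimate=float(np.median(a) - np.median(b)),
        statistic=float(res.statistic), p=float(res.pvalue), n=len(frame))


# ---------------------------------------------------------------------------
# interaction models
# ---------------------------------------------------------------------------

def interaction_analysis(
    y: pd.Series,
    flux: pd.Series,
    sex: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
    stratify_alpha: float = 0.05,
    outcome: str = "y",
    predictor: str = "flux",
) -> List[AssociationResult]:
    """Model y ~ flux + sex + flux:sex + covariates; when the interaction is
    significant, fit per-sex models (without the sex term) and report all
    three results (interaction first)."""
    import statsmodels.api as sm

    levels = sorted(sex.dropna().unique())
    if len(levels) != 2:
        raise InputError(f"need both sexes, got {levels}")
    cov = _encode_covariates(covariates)
    parts = [y.rename("__y"), flux.rename("__f"),
             (sex == levels[-1]).astype(float).rename("__s")]
    if not cov.empty:
        parts.append(cov)
    frame = pd.concat(parts, axis=1).dropna()
    f = zscore(frame["__f"])
    inter = (f * frame["__s"]).rename("__fs")
    X = sm.add_constant(pd.concat(
        [f.rename("__f"), frame["__s"], inter, frame[cov.columns]], axis=1))
    fit = sm.OLS(frame["__y"].to_numpy(), X.to_numpy()).fit()
    j = list(X.columns).index("__fs")
    results = [AssociationResult(
        outcome=outcome, predictor=f"{predictor} x sex", test="interaction",
        estimate=float(fit.params[j]), statistic=float(fit.tvalues[j]),
        p=float(fit.pvalues[j]), n=len(frame), covariates=tuple(cov.columns))]
    if results[0].p < stratify_alpha:
        for level in levels:
            sel = sex == level
            res = regress_outcome(
                y[sel], flux[sel],
                None if covariates is None else covariates[sel],
                standardize=True, outcome=outcome,
                predictor=f"{predictor} ({level})")
            results.append(res)
    return results


# ---------------------------------------------------------------------------
# exact tests
# ---------------------------------------------------------------------------

#: ties in table probabilities are accepted within this relative slack
FISHER_TIE_EPS = 1e-7
FISHER_MAX_TABLES = 2e7


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_rxc(
    table,
    method: str = "auto",
    max_tables: float = FISHER_MAX_TABLES,
    n_mc: int = 500_000,
    seed: int = 0,
) -> float:
    """Exact two-sided Fisher test of independence for a 2 x C table.

    p = sum of the conditional (multivariate hypergeometric) probabilities
    of all tables with the observed margins whose probability does not
    exceed the observed table's (within a 1e-7 relative tie slack).  Full
    enumeration over the C-1 free cells; ``method='monte-carlo'`` (or
    'auto' beyond ``max_tables``) estimates the same sum by sampling from
    the conditional distribution.
    """
    obs = np.asarray(table, dtype=int)
    if obs.ndim != 2 or obs.shape[0] != 2:
        raise InputError("fisher_exact_rxc expects a 2 x C table")
    if (obs < 0).any():
        raise InputError("counts must be non-negative")
    cols = obs.sum(axis=0)
    r1 = int(obs[0].sum())
    N = int(obs.sum())
    if N == 0:
        return 1.0
    log_denom = _log_binom(N, r1)
    logp_obs = sum(_log_binom(cols[j], obs[0, j]) for j in range(len(cols)))
    logp_obs -= log_denom
    cutoff = logp_obs + math.log1p(FISHER_TIE_EPS)

    n_tables = float(np.prod(cols[:-1] + 1.0))
    if method == "auto":
        method = "enumerate" if n_tables <= max_tables else "monte-carlo"
    if method == "enumerate":
        if n_tables > max_tables:
            raise InputError(
                f"enumeration would visit ~{n_tables:.3g} tables (cap "
                f"{max_tables:.3g}); use method='monte-carlo'")
        grids = np.ix_(*[np.arange(c + 1) for c in cols[:-1]])
        logp = sum(_log_binom(cols[j], grids[j]) for j in range(len(cols) - 1))
        last = r1 - sum(grids[j] for j in range(len(cols) - 1))
        valid = (last >= 0) & (last <= cols[-1])
        logp = logp + _log_binom(cols[-1], np.clip(last, 0, cols[-1]))
        logp = logp - log_denom
        mask = valid & (logp <= cutoff)
        return float(np.exp(logp[mask]).sum())
    if method == "monte-carlo":
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_hypergeometric(cols, r1, size=n_mc)
        logp = (_log_binom(cols[None, :], draws).sum(axis=1) - log_denom)
        return float(np.mean(logp <= cutoff))
    raise InputError(f"unknown method {method!r}")


def t_two_sample(
    a, b,
    outcome: str = "y",
    predictor: str = "group",
) -> AssociationResult:
    """Welch two-sample t test, from raw values or (mean, sd, n) summaries."""
    if isinstance(a, tuple) and isinstance(b, tuple):
        (m1, s1, n1), (m2, s2, n2) = a, b
        if n1 < 2 or n2 < 2:
            raise InputError("need n >= 2 per group")
        if s1 == 0 and s2 == 0:
            t, p = (0.0, 1.0) if m1 == m2 else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2,
                                              equal_var=False)
        est = m1 - m2
        n = int(n1 + n2)
    else:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise InputError("need n >= 2 per group")
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        est = float(a.mean() - b.mean())
        n = len(a) + len(b)
    return AssociationResult(outcome=outcome, predictor=predictor,
                             test="t_two_sample", estimate=float(est),
                             statistic=float(t), p=float(p), n=n)


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(list(pvals), dtype=float)
    if len(p) == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_fdr(results: List[AssociationResult]) -> List[AssociationResult]:
    """BH-FDR across one family of results, in place."""
    adj = bh_fdr([r.p for r in results])
    for r, q in zip(results, adj):
        r.fdr_p = float(q)
    return results


# ---------------------------------------------------------------------------
# driver attribution
# ---------------------------------------------------------------------------

def candidate_species(
    models: Mapping[str, StoichiometricModel],
    metabolite: str,
    precursors: Optional[Mapping[str, str]] = None,
) -> List[str]:
    """Species whose reconstruction can produce the metabolite, exchange it
    with the shared lumen, or produce a declared precursor."""
    mets = [metabolite]
    if precursors and metabolite in precursors:
        mets.append(precursors[metabolite])
    out = []
    for sp, model in models.items():
        hit = False
        for met in mets:
            lum = f"{met}[luM]"
            if any(lum in rxn.metabolites for rxn in model.reactions.values()):
                hit = True
            if model.producers_of(f"{met}[c]"):
                hit = True
        if hit:
            out.append(sp)
    return out


def driver_attribution(
    flux_values: pd.DataFrame,
    abundances: pd.DataFrame,
    models: Mapping[str, StoichiometricModel],
    precursors: Optional[Mapping[str, str]] = None,
) -> Dict[str, List[Tuple[str, float]]]:
    """Rank candidate driver species per metabolite by explained variance.

    For each metabolite column of ``flux_values`` (NaN = masked) the
    candidate species' log2-standardized abundances are regressed against
    the flux; species are returned sorted by decreasing R-squared.
    Metabolite group names ("a/b") attribute against their member list.
    """
    rankings: Dict[str, List[Tuple[str, float]]] = {}
    for met in flux_values.columns:
        member_mets = met.split("/")
        cands: List[str] = []
        for m in member_mets:
            for sp in candidate_species(models, m, precursors):
                if sp not in cands:
                    cands.append(sp)
        if not cands:
            logger.warning("metabolite %r has no candidate species", met)
            rankings[met] = []
            continue
        y = flux_values[met]
        scored: List[Tuple[str, float]] = []
        for sp in cands:
            if sp not in abundances.columns:
                continue
            x = log2_standardize(abundances[sp])
            both = pd.concat([x, y], axis=1).dropna()
            if len(both) < 3 or both.iloc[:, 0].std() == 0 \
                    or both.iloc[:, 1].std() == 0:
                continue
            r = np.corrcoef(both.iloc[:, 0], both.iloc[:, 1])[0, 1]
            scored.append((sp, float(r * r)))
        scored.sort(key=lambda t: (-t[1], t[0]))
        rankings[met] = scored
    return rankings


# ---------------------------------------------------------------------------
# battery over a flux matrix
# ---------------------------------------------------------------------------

def flux_age_battery(values: pd.DataFrame, cohort: pd.DataFrame
                     ) -> List[AssociationResult]:
    """Per metabolite: standardized regression of flux on age with a sex
    control; BH-FDR across the metabolite family."""
    results = []
    cov = pd.DataFrame({"sex": cohort["sex"]})
    for met in values.columns:
        results.append(regress_outcome(
            values[met], cohort["age"], cov, standardize=True,
            outcome=met, predictor="age"))
    return attach_fdr(results)


def flux_cognition_battery(values: pd.DataFrame, cohort: pd.DataFrame,
                           cognition: pd.Series) -> List[AssociationResult]:
    """Per metabolite: regression of global cognition on the standardized
    flux, controlling age, sex, BMI and education; BH-FDR across the family."""
    results = []
    cov = cohort[["age", "sex", "bmi", "education"]]
    for met in values.columns:
        results.append(regress_outcome(
            cognition, values[met], cov, standardize=True,
            outcome="global_cognition", predictor=met))
    return attach_fdr(results)


def flux_sex_battery(values: pd.DataFrame, cohort: pd.DataFrame
                     ) -> List[AssociationResult]:
    results = []
    for met in values.columns:
        r = wilcoxon_sex(values[met], cohort["sex"], outcome=met)
        results.append(r)
    return attach_fdr(results)


def flux_apoe_battery(values: pd.DataFrame, cohort: pd.DataFrame
                      ) -> Dict[str, List[AssociationResult]]:
    """Per metabolite: Kruskal-Wallis across APOE risk groups plus Dunn
    pairwise follow-ups (E2/E4 carriers excluded)."""
    groups = apoe_groups(cohort["apoe_genotype"])
    keep = groups != "excluded"
    out: Dict[str, List[AssociationResult]] = {}
    for met in values.columns:
        try:
            out[met] = kruskal_dunn(values[met][keep], groups[keep],
                                    outcome=met, predictor="apoe_group")
        except InputError as exc:
            logger.warning("APOE test skipped for %r: %s", met, exc)
    kw = [res[0] for res in out.values()]
    attach_fdr(kw)
    return out


def flux_sex_interaction_battery(
    values: pd.DataFrame, cohort: pd.DataFrame, cognition: pd.Series,
) -> Dict[str, List[AssociationResult]]:
    """Flux-by-sex interaction on global cognition (age, BMI, education
    controls) with per-sex stratified follow-ups (BMI, education controls)
    when the interaction is significant."""
    out: Dict[str, List[AssociationResult]] = {}
    for met in values.columns:
        try:
            inter = interaction_analysis(
                cognition, values[met], cohort["sex"],
                cohort[["age", "bmi", "education"]],
                outcome="global_cognition", predictor=met)
        except InputError as exc:
            logger.warning("interaction test skipped for %r: %s", met, exc)
            continue
        if len(inter) > 1:
            # refit the stratified models with the stated covariate set
            inter = inter[:1]
            for level in sorted(cohort["sex"].dropna().unique()):
                sel = cohort["sex"] == level
                inter.append(regress_outcome(
                    cognition[sel], values[met][sel],
                    cohort.loc[sel, ["bmi", "education"]], standardize=True,
                    outcome="global_cognition",
                    predictor=f"{met} ({level})"))
        out[met] = inter
    return out
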