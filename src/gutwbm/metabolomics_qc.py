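"""Untargeted-metabolomics QC: batch normalization, sample/metabolite
filters, CV filter, log2 transform, KNN imputation.

The QC chain mirrors standard platform post-processing for peak-intensity
tables:

1. divide each intensity by the median of its metabolite within its batch;
2. drop samples whose missing-value count exceeds the cohort mean plus five
   standard deviations of the per-sample missing counts;
3. drop metabolites missing in more than 70% of samples, and metabolites
   whose between-aliquot coefficient of variation (SD/mean over replicate
   aliquots, averaged over replicate groups) exceeds 30%;
4. log2-transform and impute remaining missing values by K-nearest-neighbour
   imputation over samples (Euclidean distance on co-present metabolites,
   columns standardized for the distance computation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

MISSING_SD_FACTOR = 5.0
MET_MISSING_FRAC = 0.7
CV_MAX = 0.30
KNN_NEIGHBOURS = 10


@dataclass
class MetabolomicsTable:
    """Sample x metabolite peak intensities with batch and aliquot labels.

    ``aliquot_groups`` labels replicate-aliquot rows used for CV estimation
    (NA for ordinary cohort samples).  ``dropped_samples`` and
    ``dropped_metabolites`` accumulate QC exclusions with reasons.
    """

    data: pd.DataFrame
    batches: pd.Series
    aliquot_groups: Optional[pd.Series] = None
    dropped_samples: Dict[str, str] = field(default_factory=dict)
    dropped_metabolites: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.batches.index.equals(self.data.index):
            self.batches = self.batches.reindex(self.data.index)
        if self.batches.isna().any():
            raise InputError("every sample needs a batch label")
        if (self.data.to_numpy(dtype=float, na_value=np.nan) <= 0).any():
            raise InputError("peak intensities must be positive where present")

    def copy(self) -> "MetabolomicsTable":
        return MetabolomicsTable(
            self.data.copy(), self.batches.copy(),
            None if self.aliquot_groups is None else self.aliquot_groups.copy(),
            dict(self.dropped_samples), dict(self.dropped_metabolites))

    def cohort_samples(self) -> pd.Index:
        """Samples that are not replicate aliquots."""
        if self.aliquot_groups is None:
            return self.data.index
        return self.data.index[self.aliquot_groups.reindex(self.data.index).isna()]


def batch_normalize(t: MetabolomicsTable) -> MetabolomicsTable:
    """Divide each intensity by the median of its metabolite in its batch
    (missing values ignored in the median)."""
    out = t.copy()
    for batch, rows in out.data.groupby(out.batches):
        med = rows.median(axis=0, skipna=True)
        fully_missing = med.index[med.isna()]
        for metab in fully_missing:
            logger.warning("metabolite %r fully missing in batch %r; left "
                           "missing", metab, batch)
        out.data.loc[rows.index] = rows.div(med, axis=1)
    return out


def exclude_samples_by_missingness(
    t: MetabolomicsTable, k: float = MISSING_SD_FACTOR,
) -> MetabolomicsTable:
    """Drop samples whose missing count exceeds mean + k*SD of the
    per-sample missing counts."""
    out = t.copy()
    counts = out.data.isna().sum(axis=1)
    threshold = counts.mean() + k * counts.std(ddof=1)
    if np.isnan(threshold):  # single sample: SD undefined, keep everything
        return out
    drop = counts.index[counts > threshold]
    for s in drop:
        out.dropped_samples[str(s)] = (
            f"missing_count {counts[s]} > mean+{k:g}*SD ({threshold:.2f})")
    out.data = out.data.drop(index=drop)
    out.batches = out.batches.drop(index=drop)
    if out.aliquot_groups is not None:
        out.aliquot_groups = out.aliquot_groups.drop(index=drop,
                                                     errors="ignore")
    return out


def aliquot_cv(t: MetabolomicsTable) -> Optional[pd.Series]:
    """Between-aliquot CV per metabolite: SD/mean within each replicate
    group, averaged across groups.  None when no replicate groups exist."""
    if t.aliquot_groups is None or t.aliquot_groups.dropna().empty:
        return None
    groups = t.aliquot_groups.dropna()
    cvs: List[pd.Series] = []
    for _, idx in groups.groupby(groups):
        rows = t.data.loc[idx.index]
        if len(rows) < 2:
            continue
        cv = rows.std(axis=0, ddof=1) / rows.mean(axis=0)
        cvs.append(cv)
    if not cvs:
        return None
    return pd.concat(cvs, axis=1).mean(axis=1)


def filter_metabolites(
    t: MetabolomicsTable,
    missing_frac: float = MET_MISSING_FRAC,
    cv_max: float = CV_MAX,
) -> MetabolomicsTable:
    """Drop metabolites missing in > ``missing_frac`` of samples and
    metabolites with between-aliquot CV > ``cv_max``."""
    out = t.copy()
    frac = out.data.isna().mean(axis=0)
    drop_missing = frac.index[frac > missing_frac]
    for metab in drop_missing:
        out.dropped_metabolites[str(metab)] = (
            f"missing_fraction {frac[metab]:.3f} > {missing_frac:g}")

    cv = aliquot_cv(out)
    if cv is None:
        logger.warning("no replicate aliquot groups; CV filter skipped")
        drop_cv = pd.Index([])
    else:
        drop_cv = cv.index[cv > cv_max].difference(drop_missing)
        for metab in drop_cv:
            out.dropped_metabolites[str(metab)] = (
                f"aliquot_cv {cv[metab]:.3f} > {cv_max:g}")
    drop = drop_missing.union(drop_cv)
    out.data = out.data.drop(columns=drop)
    return out


def log2_and_impute(
    t: MetabolomicsTable, k_neighbors: int = KNN_NEIGHBOURS,
) -> MetabolomicsTable:
    """Log2-transform and KNN-impute missing values.

    Neighbours are samples; distances are Euclidean over co-present
    metabolites on the column-standardized log2 matrix.  The imputed values
    are mapped back to the unstandardized log2 scale.
    """
    from sklearn.impute import KNNImputer

    out = t.copy()
    if out.data.isna().all(axis=0).any():
        bad = out.data.columns[out.data.isna().all(axis=0)].tolist()
        raise InputError(
            f"metabolites missing everywhere (should have been filtered): {bad}")
    log2 = np.log2(out.data.astype(float))
    if not log2.isna().any().any():
        out.data = log2
        return out
    mu = log2.mean(axis=0)
    sd = log2.std(axis=0, ddof=0).replace(0.0, 1.0)
    z = (log2 - mu) / sd
    imputer = KNNImputer(n_neighbors=min(k_neighbors, len(z) - 1),
                         weights="uniform")
    imputed = pd.DataFrame(imputer.fit_transform(z.to_numpy()),
                           index=z.index, columns=z.columns)
    out.data = imputed * sd + mu
    return out


def run_qc(
    t: MetabolomicsTable,
    k_sd: float = MISSING_SD_FACTOR,
    missing_frac: float = MET_MISSING_FRAC,
    cv_max: float = CV_MAX,
    k_neighbors: int = KNN_NEIGHBOURS,
) -> MetabolomicsTable:
    """Full QC chain: batch normalize -> sample filter -> metabolite filters
    -> log2 + KNN imputation."""
    t = batch_normalize(t)
    t = exclude_samples_by_missingness(t, k=k_sd)
    t = filter_metabolites(t, missing_frac=missing_frac, cv_max=cv_max)
    return log2_and_impute(t, k_neighbors=k_neighbors)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_metabolomics(data_tsv, labels_tsv) -> MetabolomicsTable:
    data = pd.read_csv(data_tsv, sep="\t", index_col=0)
    labels = pd.read_csv(labels_tsv, sep="\t", index_col=0)
    aliquot = labels["aliquot_group"] if "aliquot_group" in labels else None
    return MetabolomicsTable(data, labels["batch"], aliquot)


def write_metabolomics(t: MetabolomicsTable, data_tsv, labels_tsv) -> None:
    t.data.to_csv(data_tsv, sep="\t", index_label="sample_id")
    labels = pd.DataFrame({"batch": t.batches})
    if t.aliquot_groups is not None:
        labels["aliquot_group"] = t.aliquot_groups
    labels.to_csv(labels_tsv, sep="\t", index_label="sample_id")
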