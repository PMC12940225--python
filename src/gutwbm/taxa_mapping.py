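"""Species-level filtering, resource mapping, renormalization, coverage stats.

This stage turns a raw relative-abundance table (samples x taxa, mixed
taxonomic ranks) into the species-level table used to parameterise
community models:

1. drop taxa of lower-than-species taxonomic resolution;
2. map species names onto the reconstruction resource (exact match on a
   canonicalised name) and drop unmatched species;
3. renormalize rows to the simplex, zero entries below the 1e-6 relative
   abundance floor, and renormalize again.

Coverage statistics (mean per-sample read coverage at each stage, richness
counts) mirror the usual mapping reports for 16S cohorts; taxa below the
1e-6 floor are excluded from both the coverage and the richness counts.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

#: relative-abundance floor (0.0001%) used for zeroing and for the
#: richness/coverage counts
ABUNDANCE_FLOOR = 1e-6

RANK_SPECIES = "species"
RANK_HIGHER = "higher"


@dataclass
class AbundanceTable:
    """Relative abundances (samples x taxa) with per-taxon rank labels.

    ``ranks`` maps taxon name to ``"species"`` or ``"higher"``; all columns
    of ``data`` must be labelled.  ``flagged_samples`` records samples whose
    rows became all-zero during filtering (they are excluded downstream, not
    silently kept).
    """

    data: pd.DataFrame
    ranks: Dict[str, str]
    flagged_samples: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in self.data.columns if c not in self.ranks]
        if missing:
            raise InputError(
                f"taxa without rank metadata: {missing[:5]}"
                + ("..." if len(missing) > 5 else ""))
        if (self.data.values < 0).any():
            raise InputError("abundance table contains negative values")

    def copy(self) -> "AbundanceTable":
        return AbundanceTable(self.data.copy(), dict(self.ranks),
                              list(self.flagged_samples))


@dataclass
class MappingReport:
    """Per-cohort mapping statistics in the style of a 16S coverage table."""

    n_named_taxa: int
    n_named_species: int
    n_mapped_species: int
    mean_richness_taxa: float
    sd_richness_taxa: float
    mean_richness_species: float
    sd_richness_species: float
    mean_richness_mapped: float
    sd_richness_mapped: float
    mean_species_coverage: float
    sd_species_coverage: float
    mean_mapped_coverage: float
    sd_mapped_coverage: float
    mean_mapped_of_species: float
    sd_mapped_of_species: float
    per_sample: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("total_named_taxa", self.n_named_taxa, np.nan),
            ("total_named_species", self.n_named_species, np.nan),
            ("total_mapped_species", self.n_mapped_species, np.nan),
            ("mean_richness_named_taxa", self.mean_richness_taxa,
             self.sd_richness_taxa),
            ("mean_richness_species", self.mean_richness_species,
             self.sd_richness_species),
            ("mean_richness_mapped_species", self.mean_richness_mapped,
             self.sd_richness_mapped),
            ("mean_read_coverage_species", self.mean_species_coverage,
             self.sd_species_coverage),
            ("mean_read_coverage_mapped", self.mean_mapped_coverage,
             self.sd_mapped_coverage),
            ("mean_mapping_coverage_of_species_reads",
             self.mean_mapped_of_species, self.sd_mapped_of_species),
        ]
        return pd.DataFrame(rows, columns=["statistic", "value", "sd"])


_CANON_RE = re.compile(r"[\s_]+")


def canonical_name(name: str) -> str:
    """Canonicalise a taxon name: lowercase, runs of spaces/underscores
    collapsed to single underscores."""
    return _CANON_RE.sub("_", name.strip().lower())


def filter_species_level(raw: AbundanceTable) -> AbundanceTable:
    """Keep only species-rank columns; abundances are *not* renormalized
    (coverage statistics need the pre-normalization values)."""
    species_cols = [c for c in raw.data.columns
                    if raw.ranks[c] == RANK_SPECIES]
    data = raw.data[species_cols].copy()
    flagged = list(raw.flagged_samples)
    zero_rows = data.index[(data.sum(axis=1) == 0)].tolist()
    for s in zero_rows:
        if s not in flagged:
            flagged.append(s)
            logger.warning("sample %r has no species-level taxa; flagged", s)
    return AbundanceTable(data, {c: RANK_SPECIES for c in species_cols}, flagged)


def map_to_resource(
    species: AbundanceTable,
    resource_names: Iterable[str],
    raw: Optional[AbundanceTable] = None,
    floor: float = ABUNDANCE_FLOOR,
) -> tuple[AbundanceTable, MappingReport]:
    """Map species columns onto the reconstruction resource and report
    coverage statistics.

    Matching is exact string equality on the canonicalised name.  Unmatched
    species are dropped.  ``raw`` (the unfiltered table, if given) supplies
    the named-taxa richness and total-read denominator for the report;
    without it the species table doubles as the raw table.  Taxa below
    ``floor`` are excluded from all richness and coverage counts.
    """
    resource = {canonical_name(n) for n in resource_names}
    if not resource:
        raise InputError("resource name set is empty")
    mapped_cols = [c for c in species.data.columns
                   if canonical_name(c) in resource]
    mapped = species.data[mapped_cols].copy()

    base = raw if raw is not None else species
    above = base.data.where(base.data >= floor, 0.0)
    sp_above = species.data.where(species.data >= floor, 0.0)
    mp_above = mapped.where(mapped >= floor, 0.0)

    per_sample = pd.DataFrame({
        "richness_taxa": (above > 0).sum(axis=1),
        "richness_species": (sp_above > 0).sum(axis=1),
        "richness_mapped": (mp_above > 0).sum(axis=1),
        "species_coverage": sp_above.sum(axis=1),
        "mapped_coverage": mp_above.sum(axis=1),
    })
    with np.errstate(invalid="ignore", divide="ignore"):
        per_sample["mapped_of_species"] = (
            per_sample["mapped_coverage"] / per_sample["species_coverage"])

    flagged = list(species.flagged_samples)
    zero = mapped.index[mapped.sum(axis=1) == 0].tolist()
    for s in zero:
        if s not in flagged:
            flagged.append(s)
            logger.warning("sample %r has zero mapped species; flagged for "
                           "exclusion downstream", s)

    report = MappingReport(
        n_named_taxa=int((above > 0).any(axis=0).sum()),
        n_named_species=int((sp_above > 0).any(axis=0).sum()),
        n_mapped_species=int((mp_above > 0).any(axis=0).sum()),
        mean_richness_taxa=float(per_sample["richness_taxa"].mean()),
        sd_richness_taxa=float(per_sample["richness_taxa"].std()),
        mean_richness_species=float(per_sample["richness_species"].mean()),
        sd_richness_species=float(per_sample["richness_species"].std()),
        mean_richness_mapped=float(per_sample["richness_mapped"].mean()),
        sd_richness_mapped=float(per_sample["richness_mapped"].std()),
        mean_species_coverage=float(per_sample["species_coverage"].mean()),
        sd_species_coverage=float(per_sample["species_coverage"].std()),
        mean_mapped_coverage=float(per_sample["mapped_coverage"].mean()),
        sd_mapped_coverage=float(per_sample["mapped_coverage"].std()),
        mean_mapped_of_species=float(per_sample["mapped_of_species"].mean()),
        sd_mapped_of_species=float(per_sample["mapped_of_species"].std()),
        per_sample=per_sample,
    )
    table = AbundanceTable(mapped, {c: RANK_SPECIES for c in mapped_cols},
                           flagged)
    return table, report


def renormalize(table: AbundanceTable,
                threshold: float = ABUNDANCE_FLOOR) -> AbundanceTable:
    """Two-pass renormalization: normalize rows to sum 1, zero entries below
    ``threshold``, normalize again.  Rows summing to zero are flagged."""
    data = table.data.copy().astype(float)
    flagged = list(table.flagged_samples)

    def _norm(df: pd.DataFrame) -> pd.DataFrame:
        sums = df.sum(axis=1)
        zero = sums.index[sums == 0]
        for s in zero:
            if s not in flagged:
                flagged.append(s)
                logger.warning("sample %r sums to zero; flagged", s)
        safe = sums.replace(0, np.nan)
        return df.div(safe, axis=0).fillna(0.0)

    data = _norm(data)
    data = data.where(data >= threshold, 0.0)
    data = _norm(data)
    return AbundanceTable(data, dict(table.ranks), flagged)


def community_abundances(table: AbundanceTable) -> Dict[str, Dict[str, float]]:
    """Per-sample nonzero species abundances (input to community assembly),
    excluding flagged samples."""
    out: Dict[str, Dict[str, float]] = {}
    for sample, row in table.data.iterrows():
        if sample in table.flagged_samples:
            continue
        nz = row[row > 0]
        out[str(sample)] = nz.to_dict()
    return out


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_abundance_table(abundance_tsv, ranks_tsv=None) -> AbundanceTable:
    """Read a samples x taxa TSV; ranks from a companion TSV
    (taxon, rank) or assumed species-level when absent."""
    data = pd.read_csv(abundance_tsv, sep="\t", index_col=0)
    if ranks_tsv is not None:
        rk = pd.read_csv(ranks_tsv, sep="\t", index_col=0)["rank"]
        ranks = {t: str(r) for t, r in rk.items()}
    else:
        ranks = {c: RANK_SPECIES for c in data.columns}
    return AbundanceTable(data, ranks)


def write_abundance_table(table: AbundanceTable, abundance_tsv,
                          ranks_tsv=None) -> None:
    table.data.to_csv(abundance_tsv, sep="\t", index_label="sample_id")
    if ranks_tsv is not None:
        pd.Series(table.ranks, name="rank").to_csv(
            ranks_tsv, sep="\t", index_label="taxon")
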