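"""Flux post-processing: masking, metabolite refinement, dependency grouping.

The pipeline order is fixed and matches the order the quantities are
produced: fluxes are rounded to six decimals and scaled (microbiome minus
germ-free) when the flux matrix is built; then

1. scaled values of zero are masked (no microbial contribution);
2. per metabolite, samples attaining the metabolite's maximum scaled value
   two or more times are masked (the optimum hit a host or dietary bound,
   not a microbial constraint);
3. metabolites are dropped when masked/zero in more than 90% of samples, or
   when one tolerance-binned value covers 90% or more of samples;
4. metabolites with pairwise R-squared above 0.999 are collected into
   linearly dependent groups (connected components); each group is
   represented by its member with the smallest maximal flux and renamed by
   concatenation (e.g. ``ba_a/ba_b``).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .fba_engine import (
    FLUX_DECIMALS,
    MASK_BOUND,
    MASK_NONE,
    MASK_ZERO,
    FluxMatrix,
)

logger = logging.getLogger(__name__)

ZERO_FRAC = 0.9
IDENT_FRAC = 0.9
FLUX_TOL = 1e-6
R2_THRESHOLD = 0.999
MIN_SHARED_SAMPLES = 3


@dataclass
class MetaboliteGroup:
    """A set of stoichiometrically dependent metabolites (pairwise R^2 above
    the threshold), represented by the member with the smallest maximum."""

    members: List[str]
    representative: str
    name: str
    r2: pd.DataFrame = field(repr=False, default=None)


def mask_zero_and_bound_limited(fm: FluxMatrix) -> FluxMatrix:
    """Mask zero scaled fluxes and bound-limited maxima.

    A scaled flux of exactly zero (after 6-decimal rounding) indicates no
    microbial contribution.  If the maximal scaled value of a metabolite is
    attained by two or more samples, those samples' optima were limited by a
    shared (host or dietary) bound rather than by the sample's community, so
    the attaining samples are masked.
    """
    out = fm.copy()
    values = out.scaled.round(FLUX_DECIMALS)
    free = out.mask == MASK_NONE
    zero = free & (values == 0.0)
    out.mask = out.mask.mask(zero, MASK_ZERO)
    free = out.mask == MASK_NONE
    for met in values.columns:
        col = values[met].where(free[met])
        if col.dropna().empty:
            continue
        colmax = col.max()
        attaining = col == colmax
        if attaining.sum() >= 2:
            out.mask.loc[attaining.fillna(False), met] = MASK_BOUND
    return out


def refine_metabolites(
    fm: FluxMatrix,
    zero_frac: float = ZERO_FRAC,
    ident_frac: float = IDENT_FRAC,
    tol: float = FLUX_TOL,
) -> FluxMatrix:
    """Drop metabolites that are uninformative across the cohort.

    A metabolite is dropped when masked or zero entries cover more than
    ``zero_frac`` of samples, or when a single tolerance-binned flux value
    covers at least ``ident_frac`` of samples.  Values are considered
    identical when they chain within ``tol`` (single-linkage binning on the
    sorted values), the declared reading of an identity tolerance of 1e-6
    mmol/day/person.
    """
    drop: List[str] = []
    n = len(fm.scaled.index)
    usable = fm.analysis_values()
    for met in fm.scaled.columns:
        col = usable[met]
        n_missing = int(col.isna().sum())
        if n_missing > zero_frac * n:
            drop.append(met)
            logger.info("metabolite %r dropped: %d/%d samples without a "
                        "usable flux", met, n_missing, n)
            continue
        vals = np.sort(col.dropna().to_numpy())
        if vals.size == 0:
            drop.append(met)
            continue
        # tolerance binning: union values whose gap is <= tol, take the
        # modal bin
        boundaries = np.nonzero(np.diff(vals) > tol)[0]
        sizes = np.diff(np.concatenate(([0], boundaries + 1, [vals.size])))
        if sizes.max() >= ident_frac * n:
            drop.append(met)
            logger.info("metabolite %r dropped: modal value covers %d/%d "
                        "samples", met, int(sizes.max()), n)
    return fm.drop_metabolites(drop)


def _pairwise_r2(values: pd.DataFrame, min_shared: int = MIN_SHARED_SAMPLES
                 ) -> pd.DataFrame:
    mets = list(values.columns)
    r2 = pd.DataFrame(np.nan, index=mets, columns=mets)
    for a, b in itertools.combinations(mets, 2):
        both = values[[a, b]].dropna()
        if len(both) < min_shared:
            logger.warning("pair (%s, %s): only %d shared samples; skipped",
                           a, b, len(both))
            continue
        xa, xb = both[a].to_numpy(), both[b].to_numpy()
        if xa.std() == 0 or xb.std() == 0:
            continue
        r = np.corrcoef(xa, xb)[0, 1]
        r2.loc[a, b] = r2.loc[b, a] = r * r
    np.fill_diagonal(r2.values, 1.0)
    return r2


def group_dependent_metabolites(
    fm: FluxMatrix,
    r2_threshold: float = R2_THRESHOLD,
    min_shared: int = MIN_SHARED_SAMPLES,
) -> Tuple[FluxMatrix, List[MetaboliteGroup]]:
    """Collapse linearly dependent metabolites into groups.

    Metabolites are nodes; an edge joins pairs with R^2 above the threshold
    over complete-case samples.  Connected components of size >= 2 become
    groups; the member with the smallest maximal flux represents the group
    (its flux distribution is kept) and the group is renamed by
    concatenating the member names.
    """
    import networkx as nx

    values = fm.analysis_values()
    r2 = _pairwise_r2(values, min_shared)
    graph = nx.Graph()
    graph.add_nodes_from(values.columns)
    for a, b in itertools.combinations(values.columns, 2):
        if r2.loc[a, b] > r2_threshold:
            graph.add_edge(a, b)

    groups: List[MetaboliteGroup] = []
    out = fm.copy()
    rename: Dict[str, str] = {}
    drop: List[str] = []
    for comp in sorted(nx.connected_components(graph), key=sorted):
        if len(comp) < 2:
            continue
        members = sorted(comp)
        maxima = {m: values[m].max() for m in members}
        representative = min(members, key=lambda m: (maxima[m], m))
        name = "/".join(members)
        groups.append(MetaboliteGroup(
            members=members, representative=representative, name=name,
            r2=r2.loc[members, members]))
        rename[representative] = name
        drop.extend(m for m in members if m != representative)
    out = out.drop_metabolites(drop)
    out.raw = out.raw.rename(columns=rename)
    out.germ_free = out.germ_free.rename(columns=rename)
    out.scaled = out.scaled.rename(columns=rename)
    out.mask = out.mask.rename(columns=rename)
    return out, groups


def process_fluxes(
    fm: FluxMatrix,
    zero_frac: float = ZERO_FRAC,
    ident_frac: float = IDENT_FRAC,
    tol: float = FLUX_TOL,
    r2_threshold: float = R2_THRESHOLD,
) -> Tuple[FluxMatrix, List[MetaboliteGroup]]:
    """The full fixed-order post-processing chain."""
    fm = mask_zero_and_bound_limited(fm)
    fm = refine_metabolites(fm, zero_frac=zero_frac, ident_frac=ident_frac,
                            tol=tol)
    return group_dependent_metabolites(fm, r2_threshold=r2_threshold)


def write_groups(groups: List[MetaboliteGroup], path) -> None:
    rows = [
        {"group": g.name, "representative": g.representative,
         "members": ";".join(g.members)}
        for g in groups
    ]
    pd.DataFrame(rows, columns=["group", "representative", "members"]).to_csv(
        path, sep="\t", index=False)
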