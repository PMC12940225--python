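"""Flux balance analysis: LP formulation, demand reactions, blood-flux grids.

FBA solves  max c'v  subject to  S.v = 0,  lb <= v <= ub,  plus the coupling
inequality rows |v_j| <= C * v_biomass,k for microbial reactions.  The LP is
solved with the HiGHS dual simplex through scipy.  Only objective values are
retained for downstream analysis (LP degeneracy can change the flux vector
but never the optimum).

The blood-flux prediction adds an artificial demand reaction
``DM_<met>[bc]: 1 met[bc] -> 0`` for each target metabolite, maximizes it in
every personalised microbiome-WBM and in the matching sex's germ-free host,
and reports the difference ("scaled flux") as the net microbial contribution
in mmol/day/person.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .errors import SolverError, StructuralError
from .model_assembly import (
    DEFAULT_BOUND,
    MicrobiomeWBM,
    StoichiometricModel,
)

logger = logging.getLogger(__name__)

#: decimals kept when storing flux values (mmol/day/person)
FLUX_DECIMALS = 6

#: tolerance asserted on optimal solutions (mass balance, bounds, coupling)
SOLUTION_TOL = 1e-6

_SOLVER_OPTIONS = {
    "primal_feasibility_tolerance": 1e-9,
    "dual_feasibility_tolerance": 1e-9,
}


@dataclass
class FluxSolution:
    """Outcome of one FBA maximization."""

    objective_value: Optional[float]
    status: str  # optimal | infeasible | unbounded | failed
    fluxes: Optional[pd.Series] = None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


class LinearProblem:
    """Dense LP arrays for one model, reusable across objective choices."""

    def __init__(self, model: StoichiometricModel):
        self.reaction_ids: List[str] = list(model.reactions)
        self.rxn_index = {rid: j for j, rid in enumerate(self.reaction_ids)}
        met_index = {m: i for i, m in enumerate(model.metabolites)}
        n_met, n_rxn = len(met_index), len(self.reaction_ids)
        S = np.zeros((n_met, n_rxn))
        for j, rid in enumerate(self.reaction_ids):
            for met, coef in model.reactions[rid].metabolites.items():
                S[met_index[met], j] = coef
        self.S = S
        self.b_eq = np.zeros(n_met)
        self.bounds = [
            (model.reactions[rid].lower_bound, model.reactions[rid].upper_bound)
            for rid in self.reaction_ids
        ]
        # coupling rows: v_j - C v_bio <= 0  and  -v_j - C v_bio <= 0
        n_cc = len(model.coupling)
        if n_cc:
            A_ub = np.zeros((2 * n_cc, n_rxn))
            for k, cc in enumerate(model.coupling):
                j = self.rxn_index[cc.reaction]
                b = self.rxn_index[cc.biomass_reaction]
                A_ub[2 * k, j] = 1.0
                A_ub[2 * k, b] = -cc.factor
                A_ub[2 * k + 1, j] = -1.0
                A_ub[2 * k + 1, b] = -cc.factor
            self.A_ub: Optional[np.ndarray] = A_ub
            self.b_ub: Optional[np.ndarray] = np.zeros(2 * n_cc)
        else:
            self.A_ub = None
            self.b_ub = None

    def maximize(self, objective_reaction_id: str,
                 return_fluxes: bool = False) -> FluxSolution:
        try:
            j = self.rxn_index[objective_reaction_id]
        except KeyError:
            raise StructuralError(
                f"objective reaction {objective_reaction_id!r} not in model")
        c = np.zeros(len(self.reaction_ids))
        c[j] = -1.0  # linprog minimizes
        res = linprog(c, A_ub=self.A_ub, b_ub=self.b_ub, A_eq=self.S,
                      b_eq=self.b_eq, bounds=self.bounds, method="highs-ds",
                      options=_SOLVER_OPTIONS)
        if res.status == 0:
            v = np.asarray(res.x)
            self._check_solution(v)
            fluxes = (pd.Series(v, index=self.reaction_ids)
                      if return_fluxes else None)
            return FluxSolution(float(v[j]), "optimal", fluxes)
        if res.status == 2:
            return FluxSolution(None, "infeasible")
        if res.status == 3:
            return FluxSolution(None, "unbounded")
        raise SolverError(f"LP solver failed (status {res.status}): {res.message}")

    def _check_solution(self, v: np.ndarray) -> None:
        resid = float(np.max(np.abs(self.S @ v))) if self.S.size else 0.0
        if resid > SOLUTION_TOL:
            raise SolverError(f"mass-balance residual {resid:.3g} exceeds "
                              f"{SOLUTION_TOL}")
        for (lb, ub), x in zip(self.bounds, v):
            if x < lb - SOLUTION_TOL or x > ub + SOLUTION_TOL:
                raise SolverError("flux bound violated beyond tolerance")
        if self.A_ub is not None:
            viol = float(np.max(self.A_ub @ v - self.b_ub))
            if viol > SOLUTION_TOL:
                raise SolverError(f"coupling violated by {viol:.3g}")


def fba_max(model: StoichiometricModel, objective_reaction_id: str,
            return_fluxes: bool = False) -> FluxSolution:
    """Maximize the flux through one reaction under steady state and bounds."""
    return LinearProblem(model).maximize(objective_reaction_id, return_fluxes)


# ---------------------------------------------------------------------------
# demand reactions
# ---------------------------------------------------------------------------

def demand_reaction_id(metabolite: str, compartment: str = "bc") -> str:
    from .model_assembly import strip_compartment
    return f"DM_{strip_compartment(metabolite)}[{compartment}]"


def add_demand_reaction(model: StoichiometricModel, metabolite: str,
                        compartment: str = "bc") -> StoichiometricModel:
    """Add an unbalanced sink ``DM_<met>[comp]: 1 met[comp] -> 0``.

    Idempotent: calling twice leaves a single reaction.  Raises if the
    metabolite does not exist in the named compartment.
    """
    from .model_assembly import strip_compartment
    met_id = f"{strip_compartment(metabolite)}[{compartment}]"
    if met_id not in model.metabolites:
        raise StructuralError(
            f"metabolite {met_id!r} absent from model {model.id!r}")
    rid = demand_reaction_id(metabolite, compartment)
    if rid in model.reactions:
        return model
    model.add_reaction(rid, {met_id: -1.0}, 0.0, DEFAULT_BOUND)
    return model


# ---------------------------------------------------------------------------
# flux matrix
# ---------------------------------------------------------------------------

#: reason codes for masked entries
MASK_NONE = ""
MASK_INFEASIBLE = "infeasible"
MASK_ZERO = "zero_contribution"
MASK_BOUND = "bound_limited"


@dataclass
class FluxMatrix:
    """Samples x metabolites grid of maximal blood fluxes (mmol/day/person).

    Layers: raw microbiome-WBM flux, sex-matched germ-free flux, and the
    scaled (raw - germ-free) microbial contribution.  The mask layer holds
    reason codes for entries excluded from analysis.
    """

    raw: pd.DataFrame
    germ_free: pd.DataFrame
    scaled: pd.DataFrame
    mask: pd.DataFrame
    sexes: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def copy(self) -> "FluxMatrix":
        return FluxMatrix(self.raw.copy(), self.germ_free.copy(),
                          self.scaled.copy(), self.mask.copy(),
                          self.sexes.copy())

    def analysis_values(self) -> pd.DataFrame:
        """Scaled fluxes with masked entries set to NaN."""
        return self.scaled.where(self.mask == MASK_NONE)

    def drop_metabolites(self, metabolites: Iterable[str]) -> "FluxMatrix":
        cols = [c for c in self.scaled.columns if c not in set(metabolites)]
        return FluxMatrix(self.raw[cols], self.germ_free[cols],
                          self.scaled[cols], self.mask[cols], self.sexes)


def predict_blood_fluxes(
    sample_models: Mapping[str, MicrobiomeWBM],
    germfree: Mapping[str, StoichiometricModel],
    metabolites: Sequence[str],
    compartment: str = "bc",
) -> FluxMatrix:
    """Maximal blood demand fluxes for every sample and target metabolite.

    ``germfree`` maps sex tag to the diet-constrained germ-free host; the
    germ-free layer is computed once per sex and metabolite.  Infeasible
    sample models mask the whole row with reason ``infeasible`` and the
    pipeline continues.
    """
    if not metabolites:
        raise StructuralError("metabolite list is empty")
    gf_flux: Dict[str, Dict[str, float]] = {}
    for sex, host in germfree.items():
        model = host.copy()
        for met in metabolites:
            add_demand_reaction(model, met, compartment)
        lp = LinearProblem(model)
        gf_flux[sex] = {}
        for met in metabolites:
            sol = lp.maximize(demand_reaction_id(met, compartment))
            if not sol.ok:
                raise SolverError(
                    f"germ-free model for sex {sex!r} is {sol.status} for "
                    f"metabolite {met!r}")
            gf_flux[sex][met] = round(sol.objective_value, FLUX_DECIMALS)

    samples = list(sample_models)
    mets = list(metabolites)
    raw_arr = np.full((len(samples), len(mets)), np.nan)
    gf_arr = np.full_like(raw_arr, np.nan)
    mask_arr = np.full(raw_arr.shape, MASK_NONE, dtype=object)
    sexes = pd.Series({s: sample_models[s].sex for s in samples})

    for i, (sample, wbm) in enumerate(sample_models.items()):
        sex = wbm.sex
        if sex not in gf_flux:
            raise StructuralError(
                f"sample {sample!r} has sex {sex!r} without a germ-free model")
        model = wbm.model.copy()
        for met in mets:
            add_demand_reaction(model, met, compartment)
        lp = LinearProblem(model)
        for j, met in enumerate(mets):
            sol = lp.maximize(demand_reaction_id(met, compartment))
            if sol.status == "infeasible":
                logger.warning("sample %r: model infeasible; row masked", sample)
                raw_arr[i, :] = np.nan
                gf_arr[i, :] = np.nan
                mask_arr[i, :] = MASK_INFEASIBLE
                break
            if not sol.ok:
                raise SolverError(
                    f"sample {sample!r}, metabolite {met!r}: LP {sol.status}")
            raw_arr[i, j] = round(sol.objective_value, FLUX_DECIMALS)
            gf_arr[i, j] = gf_flux[sex][met]

    raw = pd.DataFrame(raw_arr, index=samples, columns=mets)
    gf = pd.DataFrame(gf_arr, index=samples, columns=mets)
    mask = pd.DataFrame(mask_arr, index=samples, columns=mets)
    scaled = (raw - gf).round(FLUX_DECIMALS)
    return FluxMatrix(raw=raw, germ_free=gf, scaled=scaled, mask=mask,
                      sexes=sexes)


def write_flux_matrix(fm: FluxMatrix, outdir) -> None:
    """Write one TSV per layer plus the mask."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fm.raw.to_csv(out / "flux_raw.tsv", sep="\t", index_label="sample_id")
    fm.germ_free.to_csv(out / "flux_germfree.tsv", sep="\t",
                        index_label="sample_id")
    fm.scaled.to_csv(out / "flux_scaled.tsv", sep="\t", index_label="sample_id")
    fm.mask.to_csv(out / "flux_mask.tsv", sep="\t", index_label="sample_id")
    fm.sexes.rename("sex").to_csv(out / "flux_sexes.tsv", sep="\t",
                                  index_label="sample_id")


def read_flux_matrix(indir) -> FluxMatrix:
    from pathlib import Path
    ind = Path(indir)
    kw = dict(sep="\t", index_col="sample_id")
    raw = pd.read_csv(ind / "flux_raw.tsv", **kw)
    gf = pd.read_csv(ind / "flux_germfree.tsv", **kw)
    scaled = pd.read_csv(ind / "flux_scaled.tsv", **kw)
    mask = pd.read_csv(ind / "flux_mask.tsv", keep_default_na=False, **kw)
    sexes = pd.read_csv(ind / "flux_sexes.tsv", **kw)["sex"]
    return FluxMatrix(raw, gf, scaled.astype(float), mask.astype(str), sexes)
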