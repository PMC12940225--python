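"""Constraint-based model containers and community/host assembly.

The data model follows the COBRA convention: a metabolic network is a
stoichiometric matrix S (metabolites x reactions, substrates negative,
products positive) with per-reaction flux bounds in mmol/day/person.
Compartments are tagged with bracket suffixes on the metabolite id,
e.g. ``glc[bc]`` (blood), ``glc[luLI]`` (large-intestinal lumen),
``glc[luM]`` (shared microbiota lumen), ``x[fe]`` (feces), ``x[d]`` (diet).

Community assembly mirrors the microbiome-modelling workflow used for
personalised host-microbiome models:

1. strain reconstructions of one species are merged into a pan-species
   model (union of reactions, widest bounds);
2. pan-species models are connected to a shared microbiota lumen and tied
   together by a ``communityBiomass`` reaction whose stoichiometric
   coefficients are the species' relative abundances;
3. every microbial reaction is coupled to its species' biomass reaction
   (|v_j| <= C * v_biomass,k with C = 400 by default), so that taxa that do
   not grow cannot carry flux;
4. the community is joined to a sex-matched whole-body host model through
   the large-intestinal lumen, and the community biomass excretion and the
   whole-body objective are both pinned to 1 mmol/day/person.

Coupling constraints are kept as explicit inequality rows next to S (not
folded into bounds), matching the flux-capacity-constraint semantics of the
COBRA toolbox.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

from .errors import AssemblyError, InputError, StructuralError

logger = logging.getLogger(__name__)

#: Default flux bound (mmol/person/day) for otherwise unconstrained reactions.
DEFAULT_BOUND = 1_000_000.0

#: Default flux-capacity coupling factor tying microbial reactions to growth.
DEFAULT_COUPLING_FACTOR = 400.0

_COMPARTMENT_RE = re.compile(r"\[([A-Za-z0-9_]+)\]$")


def compartment_of(metabolite_id: str) -> str:
    """Return the bracket-suffix compartment tag of a metabolite id."""
    m = _COMPARTMENT_RE.search(metabolite_id)
    if m is None:
        raise InputError(f"metabolite id {metabolite_id!r} has no [compartment] suffix")
    return m.group(1)


def strip_compartment(metabolite_id: str) -> str:
    """Return the metabolite id without its compartment suffix."""
    return _COMPARTMENT_RE.sub("", metabolite_id)


@dataclass
class Reaction:
    """A reaction column of S: signed stoichiometry plus flux bounds."""

    id: str
    metabolites: Dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    objective_coefficient: float = 0.0

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise InputError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        for met, coef in self.metabolites.items():
            if coef == 0:
                raise InputError(f"reaction {self.id}: zero coefficient for {met}")

    def copy(self) -> "Reaction":
        return Reaction(
            self.id,
            dict(self.metabolites),
            self.lower_bound,
            self.upper_bound,
            self.objective_coefficient,
        )


@dataclass(frozen=True)
class CouplingConstraint:
    """|v_reaction| <= factor * v_biomass, encoded as two LP inequality rows."""

    reaction: str
    biomass_reaction: str
    factor: float = DEFAULT_COUPLING_FACTOR

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise InputError("coupling factor must be positive")


class StoichiometricModel:
    """A metabolic network: metabolites, reactions, bounds, coupling rows.

    The implicit concentration vector is never simulated; flux analysis
    assumes steady state (S.v = 0).
    """

    def __init__(self, model_id: str, sex: Optional[str] = None):
        self.id = model_id
        self.sex = sex
        self.metabolites: Dict[str, str] = {}  # id -> compartment tag
        self.reactions: Dict[str, Reaction] = {}
        self.coupling: List[CouplingConstraint] = []
        self.biomass_reaction: Optional[str] = None

    # -- construction ---------------------------------------------------
    def add_metabolite(self, met_id: str) -> None:
        if met_id not in self.metabolites:
            self.metabolites[met_id] = compartment_of(met_id)

    def add_reaction(
        self,
        rxn_id: str,
        metabolites: Mapping[str, float],
        lower_bound: float = -DEFAULT_BOUND,
        upper_bound: float = DEFAULT_BOUND,
        objective_coefficient: float = 0.0,
    ) -> Reaction:
        if rxn_id in self.reactions:
            raise AssemblyError(f"duplicate reaction id {rxn_id!r} in model {self.id}")
        rxn = Reaction(rxn_id, dict(metabolites), lower_bound, upper_bound,
                       objective_coefficient)
        for met in rxn.metabolites:
            self.add_metabolite(met)
        self.reactions[rxn_id] = rxn
        return rxn

    def add_coupling(self, reaction: str, biomass_reaction: str,
                     factor: float = DEFAULT_COUPLING_FACTOR) -> None:
        for rid in (reaction, biomass_reaction):
            if rid not in self.reactions:
                raise AssemblyError(
                    f"coupling references unknown reaction {rid!r} in model {self.id}")
        self.coupling.append(CouplingConstraint(reaction, biomass_reaction, factor))

    def copy(self, model_id: Optional[str] = None) -> "StoichiometricModel":
        new = StoichiometricModel(model_id or self.id, self.sex)
        new.metabolites = dict(self.metabolites)
        new.reactions = {rid: r.copy() for rid, r in self.reactions.items()}
        new.coupling = list(self.coupling)
        new.biomass_reaction = self.biomass_reaction
        return new

    # -- introspection --------------------------------------------------
    def compartments(self) -> Set[str]:
        return set(self.metabolites.values())

    def producers_of(self, met_id: str) -> List[str]:
        """Reactions that can produce ``met_id`` (positive coefficient with
        positive upper bound, or negative coefficient with negative lower bound)."""
        out = []
        for rid, rxn in self.reactions.items():
            coef = rxn.metabolites.get(met_id)
            if coef is None:
                continue
            if (coef > 0 and rxn.upper_bound > 0) or (coef < 0 and rxn.lower_bound < 0):
                out.append(rid)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StoichiometricModel):
            return NotImplemented
        return (
            self.metabolites == other.metabolites
            and set(self.reactions) == set(other.reactions)
            and all(
                self.reactions[r].metabolites == other.reactions[r].metabolites
                and self.reactions[r].lower_bound == other.reactions[r].lower_bound
                and self.reactions[r].upper_bound == other.reactions[r].upper_bound
                for r in self.reactions
            )
            and set(self.coupling) == set(other.coupling)
        )

    # -- I/O: COBRA-style JSON ------------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "id": self.id,
            "version": "1",
            "metabolites": [
                {"id": m, "name": strip_compartment(m), "compartment": c}
                for m, c in sorted(self.metabolites.items())
            ],
            "reactions": [
                {
                    "id": r.id,
                    "name": r.id,
                    "metabolites": dict(sorted(r.metabolites.items())),
                    "lower_bound": r.lower_bound,
                    "upper_bound": r.upper_bound,
                    "gene_reaction_rule": "",
                    "objective_coefficient": r.objective_coefficient,
                }
                for r in (self.reactions[k] for k in sorted(self.reactions))
            ],
            "genes": [],
            "compartments": {c: c for c in sorted(self.compartments())},
            # extension keys (ignored by cobrapy readers)
            "coupling_constraints": [
                {"reaction": cc.reaction, "biomass_reaction": cc.biomass_reaction,
                 "factor": cc.factor}
                for cc in self.coupling
            ],
            "biomass_reaction": self.biomass_reaction,
            "sex": self.sex,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "StoichiometricModel":
        model = cls(d["id"], d.get("sex"))
        for rxn in d["reactions"]:
            model.add_reaction(
                rxn["id"], rxn["metabolites"],
                rxn.get("lower_bound", -DEFAULT_BOUND),
                rxn.get("upper_bound", DEFAULT_BOUND),
                rxn.get("objective_coefficient", 0.0),
            )
        for met in d.get("metabolites", []):
            model.add_metabolite(met["id"])
        for cc in d.get("coupling_constraints", []):
            model.add_coupling(cc["reaction"], cc["biomass_reaction"], cc["factor"])
        model.biomass_reaction = d.get("biomass_reaction")
        return model

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load_json(cls, path) -> "StoichiometricModel":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


@dataclass
class CommunityModel:
    """A per-sample microbial community: namespaced pan-species models wired
    to a shared lumen, with communityBiomass and coupling constraints."""

    model: StoichiometricModel
    members: Dict[str, Tuple[str, float]]  # species -> (biomass reaction id, a_k)
    lumen_metabolites: Set[str] = field(default_factory=set)

    @property
    def abundances(self) -> Dict[str, float]:
        return {sp: a for sp, (_, a) in self.members.items()}


@dataclass
class MicrobiomeWBM:
    """A whole-body host model joined to a microbial community."""

    model: StoichiometricModel
    host: StoichiometricModel  # pristine copy of the host used in the join
    community: CommunityModel
    added_reactions: Set[str] = field(default_factory=set)
    added_metabolites: Set[str] = field(default_factory=set)

    @property
    def sex(self) -> Optional[str]:
        return self.model.sex

    def germ_free(self) -> StoichiometricModel:
        """Remove the community and its junction reactions, recovering the host."""
        return self.host.copy()


# ---------------------------------------------------------------------------
# pan-species construction
# ---------------------------------------------------------------------------

def build_pan_species(strain_models: Iterable[StoichiometricModel],
                      pan_id: Optional[str] = None) -> StoichiometricModel:
    """Merge strain-level reconstructions of one species into a pan model.

    The pan reaction set is the union by reaction id.  Reactions sharing an
    id must have identical stoichiometry; their bounds are widened to the
    union of the observed flux intervals.  A single biomass reaction is
    designated from the strains' flagged biomass reactions.
    """
    strains = list(strain_models)
    if not strains:
        raise AssemblyError("build_pan_species requires at least one strain model")
    pan = StoichiometricModel(pan_id or f"pan_{strains[0].id}")
    origin: Dict[str, str] = {}
    for strain in strains:
        for rid, rxn in strain.reactions.items():
            if rid not in pan.reactions:
                pan.add_reaction(rid, rxn.metabolites, rxn.lower_bound,
                                 rxn.upper_bound, rxn.objective_coefficient)
                origin[rid] = strain.id
            else:
                existing = pan.reactions[rid]
                if existing.metabolites != rxn.metabolites:
                    raise AssemblyError(
                        f"reaction {rid!r} has conflicting stoichiometry between "
                        f"strains {origin[rid]!r} and {strain.id!r}")
                existing.lower_bound = min(existing.lower_bound, rxn.lower_bound)
                existing.upper_bound = max(existing.upper_bound, rxn.upper_bound)
        for met in strain.metabolites:
            pan.add_metabolite(met)
        if strain.biomass_reaction is not None:
            if pan.biomass_reaction is None:
                pan.biomass_reaction = strain.biomass_reaction
            elif pan.biomass_reaction != strain.biomass_reaction:
                raise AssemblyError(
                    f"strains of {pan.id} designate different biomass reactions: "
                    f"{pan.biomass_reaction!r} vs {strain.biomass_reaction!r}")
    return pan


# ---------------------------------------------------------------------------
# community construction
# ---------------------------------------------------------------------------

COMMUNITY_BIOMASS_ID = "communityBiomass"
COMMUNITY_BIOMASS_MET = "microbiota_LI_biomass[luM]"
ABUNDANCE_SUM_TOL = 1e-9


def _namespace_met(species: str, met_id: str) -> str:
    """Species-tag a metabolite id; shared-lumen metabolites stay global."""
    if compartment_of(met_id) == "luM":
        return met_id
    return f"{species}__{met_id}"


def build_community(
    pan_models: Mapping[str, StoichiometricModel],
    abundances: Mapping[str, float],
    coupling_factor: float = DEFAULT_COUPLING_FACTOR,
    community_id: str = "community",
) -> CommunityModel:
    """Assemble a community model from pan-species models and abundances.

    Species with zero abundance are excluded; the remaining relative
    abundances must already sum to one (no silent renormalization here —
    normalization belongs to the taxa-mapping stage).  Every microbial
    reaction is coupled to its species' biomass reaction with the given
    flux-capacity factor.
    """
    kept = {sp: a for sp, a in abundances.items() if a != 0}
    for sp, a in kept.items():
        if a < 0:
            raise InputError(f"negative abundance for species {sp!r}")
        if sp not in pan_models:
            raise InputError(f"no pan-species model for {sp!r}")
    total = sum(kept.values())
    if abs(total - 1.0) > 1e-6:
        raise InputError(
            f"species abundances must sum to 1 (got {total:.6g}); renormalize "
            "in the taxa-mapping stage first")
    if not kept:
        raise InputError("community has no members (all abundances zero)")

    model = StoichiometricModel(community_id)
    members: Dict[str, Tuple[str, float]] = {}
    for sp, a in sorted(kept.items()):
        pan = pan_models[sp]
        if pan.biomass_reaction is None:
            raise AssemblyError(
                f"species {sp!r} has abundance {a} but its model lacks a "
                "biomass reaction; community biomass is undefined")
        for rid, rxn in pan.reactions.items():
            ns_id = f"{sp}__{rid}"
            ns_mets = {_namespace_met(sp, m): c for m, c in rxn.metabolites.items()}
            model.add_reaction(ns_id, ns_mets, rxn.lower_bound, rxn.upper_bound)
        biomass_id = f"{sp}__{pan.biomass_reaction}"
        for rid in pan.reactions:
            ns_id = f"{sp}__{rid}"
            if ns_id != biomass_id:
                model.add_coupling(ns_id, biomass_id, coupling_factor)
        members[sp] = (biomass_id, a)

    # communityBiomass: consume each species biomass metabolite in proportion
    # to its relative abundance, produce one unit of community biomass.
    stoich: Dict[str, float] = {}
    for sp, (biomass_id, a) in members.items():
        biomass_rxn = model.reactions[biomass_id]
        products = [m for m, c in biomass_rxn.metabolites.items() if c > 0]
        if len(products) != 1:
            raise AssemblyError(
                f"biomass reaction {biomass_id!r} must produce exactly one "
                f"species-biomass metabolite (got {products})")
        stoich[products[0]] = -a
    stoich[COMMUNITY_BIOMASS_MET] = 1.0
    model.add_reaction(COMMUNITY_BIOMASS_ID, stoich, 0.0, DEFAULT_BOUND)

    lumen = {m for m, c in model.metabolites.items() if c == "luM"}
    return CommunityModel(model=model, members=members, lumen_metabolites=lumen)


# ---------------------------------------------------------------------------
# host-microbiome join
# ---------------------------------------------------------------------------

WBM_OBJECTIVE_ID = "Whole_body_objective_rxn"
BIOMASS_EXCRETION_ID = "Excretion_EX_microbiota_LI_biomass[fe]"
BIOMASS_FE_MET = "microbiota_LI_biomass[fe]"


def join_host_microbiome(
    host: StoichiometricModel,
    community: CommunityModel,
    sample_sex: Optional[str] = None,
) -> MicrobiomeWBM:
    """Join a community to a whole-body host via the large-intestinal lumen.

    Adds reversible lumen<->LI transport for every shared-lumen metabolite,
    routes the community biomass to feces, and pins both the community
    biomass excretion and the whole-body objective to 1 mmol/day/person.
    """
    if sample_sex is not None and host.sex is not None and host.sex != sample_sex:
        raise StructuralError(
            f"host sex {host.sex!r} does not match sample sex {sample_sex!r}")
    if "luLI" not in host.compartments():
        raise StructuralError(
            f"host model {host.id!r} lacks a large-intestinal lumen ([luLI]) "
            "compartment")
    if WBM_OBJECTIVE_ID not in host.reactions:
        raise StructuralError(
            f"host model {host.id!r} lacks {WBM_OBJECTIVE_ID}")

    joined = host.copy(f"{host.id}__microbiome")
    added_rxns: Set[str] = set()
    added_mets: Set[str] = set()

    host_mets = set(host.metabolites)
    for rid, rxn in community.model.reactions.items():
        joined.add_reaction(rid, rxn.metabolites, rxn.lower_bound, rxn.upper_bound)
        added_rxns.add(rid)
    for met in community.model.metabolites:
        if met not in host_mets:
            added_mets.add(met)
    joined.coupling.extend(community.model.coupling)

    # junction reactions lumen <-> large-intestinal lumen (1:1 transport)
    for lum_met in sorted(community.lumen_metabolites):
        if lum_met == COMMUNITY_BIOMASS_MET:
            continue
        li_met = f"{strip_compartment(lum_met)}[luLI]"
        rid = f"LI_{strip_compartment(lum_met)}"
        joined.add_reaction(rid, {li_met: -1.0, lum_met: 1.0})
        added_rxns.add(rid)
        if li_met not in host_mets:
            added_mets.add(li_met)

    # community biomass excretion route, pinned to 1 mmol/day/person
    tr_id = "TR_microbiota_LI_biomass"
    joined.add_reaction(tr_id, {COMMUNITY_BIOMASS_MET: -1.0, BIOMASS_FE_MET: 1.0},
                        0.0, DEFAULT_BOUND)
    joined.add_reaction(BIOMASS_EXCRETION_ID, {BIOMASS_FE_MET: -1.0}, 1.0, 1.0)
    added_rxns.update({tr_id, BIOMASS_EXCRETION_ID})
    added_mets.add(BIOMASS_FE_MET)

    obj = joined.reactions[WBM_OBJECTIVE_ID]
    obj.lower_bound = 1.0
    obj.upper_bound = 1.0

    return MicrobiomeWBM(
        model=joined,
        host=host.copy(),
        community=community,
        added_reactions=added_rxns,
        added_metabolites=added_mets,
    )


def strip_community(wbm: MicrobiomeWBM) -> StoichiometricModel:
    """Remove the community and its junctions, recovering the germ-free host."""
    model = wbm.model.copy(wbm.host.id)
    for rid in wbm.added_reactions:
        model.reactions.pop(rid, None)
    for met in wbm.added_metabolites:
        model.metabolites.pop(met, None)
    model.coupling = [cc for cc in model.coupling
                      if cc.reaction not in wbm.added_reactions]
    obj = model.reactions[WBM_OBJECTIVE_ID]
    host_obj = wbm.host.reactions[WBM_OBJECTIVE_ID]
    obj.lower_bound = host_obj.lower_bound
    obj.upper_bound = host_obj.upper_bound
    return model


# ---------------------------------------------------------------------------
# diet
# ---------------------------------------------------------------------------

def apply_diet(model: StoichiometricModel, diet: Mapping[str, float]
               ) -> StoichiometricModel:
    """Constrain dietary exchange reactions to a diet.

    ``diet`` maps metabolite names to maximal uptake fluxes in
    mmol/person/day.  Dietary exchanges follow the uptake-negative
    convention (EX_x[d]: x[d] -> 0), so a diet entry of f sets bounds
    (-f, 0).  Dietary exchanges for metabolites absent from the diet are
    closed from below (lb = 0).  Diet entries without a matching dietary
    exchange reaction are skipped with a logged warning.
    """
    exchanges = {rid: rid[len("EX_"):] for rid in model.reactions
                 if rid.startswith("EX_") and rid.endswith("[d]")}
    by_name = {strip_compartment(name): rid for rid, name in exchanges.items()}
    matched = set()
    for met, flux in diet.items():
        rid = by_name.get(strip_compartment(met))
        if rid is None:
            logger.warning("diet metabolite %r has no dietary exchange reaction; "
                           "skipped", met)
            continue
        rxn = model.reactions[rid]
        rxn.lower_bound = -float(flux)
        rxn.upper_bound = 0.0
        matched.add(rid)
    for rid in exchanges:
        if rid not in matched:
            model.reactions[rid].lower_bound = 0.0
    return model


def read_diet_tsv(path) -> Dict[str, float]:
    """Read a diet file: two tab-separated columns, metabolite id and flux."""
    diet: Dict[str, float] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if i == 0 and parts[0].lower() in {"metabolite", "metabolite_id"}:
                continue
            if len(parts) < 2:
                raise InputError(f"malformed diet line: {line!r}")
            diet[parts[0]] = float(parts[1])
    return diet


def write_diet_tsv(diet: Mapping[str, float], path) -> None:
    with open(path, "w") as fh:
        fh.write("metabolite_id\tflux_mmol_per_day\n")
        for met, flux in diet.items():
            fh.write(f"{met}\t{flux:g}\n")
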