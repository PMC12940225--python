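"""Pan-species union, community assembly, host joining, and diet bounds."""

import pytest

from gutwbm import (
    AssemblyError,
    DEFAULT_BOUND,
    InputError,
    StructuralError,
    StoichiometricModel,
    apply_diet,
    build_community,
    build_pan_species,
    fba_max,
    join_host_microbiome,
    strip_community,
)
from gutwbm.model_assembly import COMMUNITY_BIOMASS_ID
from gutwbm.synthetic_cohort import (
    EffectConfig,
    default_diet,
    generate_host_model,
    generate_toy_reconstructions,
)


def _strain(model_id, reactions, biomass=None):
    m = StoichiometricModel(model_id)
    for rid, (mets, lb, ub) in reactions.items():
        m.add_reaction(rid, mets, lb, ub)
    m.biomass_reaction = biomass
    return m


class TestPanSpecies:
    def test_union_of_reaction_sets(self):
        s1 = _strain("s1", {"R1": ({"a[c]": -1.0, "b[c]": 1.0}, 0, 10),
                            "R2": ({"b[c]": -1.0, "c[c]": 1.0}, 0, 10)})
        s2 = _strain("s2", {"R2": ({"b[c]": -1.0, "c[c]": 1.0}, 0, 10),
                            "R3": ({"c[c]": -1.0, "d[c]": 1.0}, 0, 10)})
        pan = build_pan_species([s1, s2])
        assert set(pan.reactions) == {"R1", "R2", "R3"}

    def test_single_strain_is_identity(self):
        s1 = _strain("s1", {"R1": ({"a[c]": -1.0, "b[c]": 1.0}, -2, 7)},
                     biomass="R1")
        pan = build_pan_species([s1])
        assert set(pan.reactions) == {"R1"}
        assert pan.reactions["R1"].lower_bound == -2
        assert pan.reactions["R1"].upper_bound == 7
        assert pan.biomass_reaction == "R1"

    def test_widest_bounds_match_interval_union(self):
        intervals = [(0.0, 10.0), (-5.0, 8.0)]
        strains = [
            _strain(f"s{i}", {"R2": ({"a[c]": -1.0, "b[c]": 1.0}, lb, ub)})
            for i, (lb, ub) in enumerate(intervals)
        ]
        pan = build_pan_species(strains)
        # oracle: the smallest interval containing every strain's interval
        lo = min(lb for lb, _ in intervals)
        hi = max(ub for _, ub in intervals)
        assert (pan.reactions["R2"].lower_bound,
                pan.reactions["R2"].upper_bound) == (lo, hi) == (-5.0, 10.0)

    def test_conflicting_stoichiometry_names_both_strains(self):
        s1 = _strain("alpha", {"R1": ({"a[c]": -1.0, "b[c]": 1.0}, 0, 10)})
        s2 = _strain("beta", {"R1": ({"a[c]": -2.0, "b[c]": 1.0}, 0, 10)})
        with pytest.raises(AssemblyError, match="alpha.*beta"):
            build_pan_species([s1, s2])


def _producer_species(name="sp1", met="x"):
    return _strain(name, {
        "UPT_bio": ({"diet_sub[luM]": -1.0, "bio_sub[c]": 1.0}, 0, DEFAULT_BOUND),
        "BIO": ({"bio_sub[c]": -1.0, "biomass[c]": 1.0}, 0, DEFAULT_BOUND),
        "UPT": ({"diet_sub[luM]": -1.0, "diet_sub[c]": 1.0}, 0, DEFAULT_BOUND),
        "PROD": ({"diet_sub[c]": -1.0, f"{met}[c]": 1.0}, 0, DEFAULT_BOUND),
        "SEC": ({f"{met}[c]": -1.0, f"{met}[luM]": 1.0}, 0, DEFAULT_BOUND),
    }, biomass="BIO")


def _nonproducer_species(name="sp2"):
    return _strain(name, {
        "UPT_bio": ({"diet_sub[luM]": -1.0, "bio_sub[c]": 1.0}, 0, DEFAULT_BOUND),
        "BIO": ({"bio_sub[c]": -1.0, "biomass[c]": 1.0}, 0, DEFAULT_BOUND),
    }, biomass="BIO")


class TestCommunity:
    def test_community_biomass_stoichiometry_and_coupling(self):
        pans = {"sp1": _producer_species(), "sp2": _nonproducer_species()}
        community = build_community(pans, {"sp1": 0.25, "sp2": 0.75}, 400.0)
        cb = community.model.reactions[COMMUNITY_BIOMASS_ID]
        assert cb.metabolites["sp1__biomass[c]"] == -0.25
        assert cb.metabolites["sp2__biomass[c]"] == -0.75
        assert cb.metabolites["microbiota_LI_biomass[luM]"] == 1.0
        coupled = {cc.reaction for cc in community.model.coupling}
        # every namespaced microbial reaction except the biomass reactions
        assert "sp1__PROD" in coupled and "sp2__UPT_bio" in coupled
        assert "sp1__BIO" not in coupled
        assert all(cc.factor == 400.0 for cc in community.model.coupling)

    def test_zero_abundance_species_excluded(self):
        pans = {"sp1": _producer_species(), "sp2": _nonproducer_species()}
        community = build_community(pans, {"sp1": 1.0, "sp2": 0.0})
        assert set(community.members) == {"sp1"}

    def test_unnormalized_abundances_rejected(self):
        pans = {"sp1": _producer_species(), "sp2": _nonproducer_species()}
        with pytest.raises(InputError, match="sum to 1"):
            build_community(pans, {"sp1": 0.5, "sp2": 0.2})

    def test_member_without_biomass_reaction_is_hard_error(self):
        bad = _producer_species("sp1")
        bad.biomass_reaction = None
        with pytest.raises(AssemblyError, match="biomass"):
            build_community({"sp1": bad}, {"sp1": 1.0})


def _joined_toy(abundances, config=None, diet=True):
    config = config or EffectConfig(n_samples=2, seed=0)
    strains = generate_toy_reconstructions(config)
    pans = {sp: build_pan_species(s, pan_id=sp) for sp, s in strains.items()}
    community = build_community(pans, abundances)
    host = generate_host_model(config, "female")
    wbm = join_host_microbiome(host, community, sample_sex="female")
    if diet:
        apply_diet(wbm.model, default_diet(config))
    return wbm, host, config


class TestJoin:
    def test_germ_free_round_trip(self):
        wbm, host, _ = _joined_toy({"arg_driver": 0.5, "null_sp_2": 0.5},
                                   diet=False)
        stripped = strip_community(wbm)
        assert stripped == host

    def test_sex_mismatch_rejected(self):
        config = EffectConfig(n_samples=2, seed=0)
        strains = generate_toy_reconstructions(config)
        pans = {sp: build_pan_species(s, pan_id=sp) for sp, s in strains.items()}
        community = build_community(pans, {"arg_driver": 1.0})
        host = generate_host_model(config, "male")
        with pytest.raises(StructuralError, match="sex"):
            join_host_microbiome(host, community, sample_sex="female")
        assert join_host_microbiome(host, community,
                                    sample_sex="male").sex == "male"

    def test_missing_li_compartment_rejected(self):
        config = EffectConfig(n_samples=2, seed=0)
        strains = generate_toy_reconstructions(config)
        pans = {sp: build_pan_species(s, pan_id=sp) for sp, s in strains.items()}
        community = build_community(pans, {"arg_driver": 1.0})
        host = StoichiometricModel("hostless", sex="female")
        host.add_reaction("Whole_body_objective_rxn", {"x[bc]": -1.0}, 1, 1)
        with pytest.raises(StructuralError, match="luLI"):
            join_host_microbiome(host, community)

    def test_pinned_reactions_are_unit_fixed(self):
        wbm, _, _ = _joined_toy({"arg_driver": 1.0})
        for rid in ("Excretion_EX_microbiota_LI_biomass[fe]",
                    "Whole_body_objective_rxn"):
            rxn = wbm.model.reactions[rid]
            assert rxn.lower_bound == rxn.upper_bound == 1.0

    def test_host_only_metabolite_unchanged_by_join(self):
        from gutwbm import add_demand_reaction
        wbm, host, config = _joined_toy({"arg_driver": 0.5, "null_sp_2": 0.5})
        gf = host.copy()
        apply_diet(gf, default_diet(config))
        for model in (wbm.model, gf):
            add_demand_reaction(model, "host_only_met")
        joined_max = fba_max(wbm.model, "DM_host_only_met[bc]").objective_value
        gf_max = fba_max(gf, "DM_host_only_met[bc]").objective_value
        assert joined_max == pytest.approx(gf_max, abs=1e-6)


class TestDiet:
    def test_diet_bounds_and_closure(self):
        m = StoichiometricModel("h")
        m.add_reaction("EX_glc[d]", {"glc[d]": -1.0})
        m.add_reaction("EX_fru[d]", {"fru[d]": -1.0})
        m.add_reaction("R1", {"glc[d]": -1.0, "glc[bc]": 1.0})
        apply_diet(m, {"glc": 10.0})
        assert (m.reactions["EX_glc[d]"].lower_bound,
                m.reactions["EX_glc[d]"].upper_bound) == (-10.0, 0.0)
        # non-diet dietary exchange closed from below
        assert m.reactions["EX_fru[d]"].lower_bound == 0.0
        # internal reactions keep the unconstrained default
        assert (m.reactions["R1"].lower_bound,
                m.reactions["R1"].upper_bound) == (-1_000_000.0, 1_000_000.0)

    def test_unknown_diet_metabolite_warns_and_skips(self, caplog):
        m = StoichiometricModel("h")
        m.add_reaction("EX_glc[d]", {"glc[d]": -1.0})
        with caplog.at_level("WARNING"):
            apply_diet(m, {"ribose": 5.0})
        assert "ribose" in caplog.text
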