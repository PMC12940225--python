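"""FBA correctness: demand reactions, LP optima vs enumeration oracle,
blood-flux grids and their invariants."""

import numpy as np
import pandas as pd
import pytest

from gutwbm import (
    StoichiometricModel,
    StructuralError,
    add_demand_reaction,
    fba_max,
    predict_blood_fluxes,
)
from gutwbm.fba_engine import MASK_INFEASIBLE, demand_reaction_id
from oracles import oracle_fba_max, random_toy_model


class TestDemandReaction:
    def test_blood_demand_shape(self):
        m = StoichiometricModel("toy")
        m.add_reaction("T", {"dchac[luLI]": -1.0, "dchac[bc]": 1.0})
        add_demand_reaction(m, "dchac")
        rxn = m.reactions["DM_dchac[bc]"]
        assert rxn.metabolites == {"dchac[bc]": -1.0}
        assert (rxn.lower_bound, rxn.upper_bound) == (0.0, 1_000_000.0)

    def test_idempotent(self):
        m = StoichiometricModel("toy")
        m.add_reaction("T", {"x[bc]": 1.0, "x[c]": -1.0})
        add_demand_reaction(m, "x")
        add_demand_reaction(m, "x")
        assert sum(r.startswith("DM_x") for r in m.reactions) == 1

    def test_wrong_compartment_rejected(self):
        m = StoichiometricModel("toy")
        m.add_reaction("T", {"x[luM]": 1.0, "y[luM]": -1.0})
        with pytest.raises(StructuralError):
            add_demand_reaction(m, "x", "bc")


class TestFbaMax:
    def test_single_bottleneck_chain(self):
        m = StoichiometricModel("chain")
        m.add_reaction("SRC", {"a[c]": 1.0}, 0.0, 5.0)
        m.add_reaction("DM_a[c]", {"a[c]": -1.0}, 0.0, 1_000_000.0)
        sol = fba_max(m, "DM_a[c]")
        assert sol.ok and sol.objective_value == pytest.approx(5.0)

    def test_coupling_bound_value(self):
        # producer coupled at C=400 to a biomass reaction forced to 0.25
        m = StoichiometricModel("coupled")
        m.add_reaction("BIO", {"b[c]": 1.0}, 0.25, 0.25)
        m.add_reaction("DM_b[c]", {"b[c]": -1.0}, 0.0, 1_000_000.0)
        m.add_reaction("PROD", {"x[c]": 1.0}, 0.0, 1_000_000.0)
        m.add_reaction("DM_x[c]", {"x[c]": -1.0}, 0.0, 1_000_000.0)
        m.add_coupling("PROD", "BIO", 400.0)
        sol = fba_max(m, "DM_x[c]")
        assert sol.objective_value == pytest.approx(100.0, abs=1e-6)

    def test_status_reported_not_fabricated(self):
        m = StoichiometricModel("infeasible")
        m.add_reaction("A", {"x[c]": 1.0}, 2.0, 5.0)   # forces production
        m.add_reaction("B", {"x[c]": -1.0}, 0.0, 1.0)  # cannot drain enough
        sol = fba_max(m, "B")
        assert sol.status == "infeasible"
        assert sol.objective_value is None

    def test_matches_vertex_enumeration_oracle_on_random_toys(self):
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 25:
            model = random_toy_model(rng, n_reactions=int(rng.integers(4, 9)))
            rid = f"r{int(rng.integers(0, len(model.reactions)))}"
            if rid not in model.reactions:
                continue
            sol = fba_max(model, rid)
            expected = oracle_fba_max(model, rid)
            assert sol.ok and expected is not None
            assert sol.objective_value == pytest.approx(expected, abs=1e-6)
            checked += 1

    def test_matches_cobra_on_uncoupled_toy(self, tmp_path):
        # independent solver route: cobrapy reads our COBRA-style JSON
        cobra_io = pytest.importorskip("cobra.io")
        m = StoichiometricModel("toy")
        m.add_reaction("EX_a[d]", {"a[d]": -1.0}, -7.0, 0.0)
        m.add_reaction("T", {"a[d]": -1.0, "a[bc]": 1.0}, 0.0, 4.0)
        m.add_reaction("DM_a[bc]", {"a[bc]": -1.0}, 0.0, 1_000_000.0)
        path = tmp_path / "toy.json"
        m.save_json(path)
        cm = cobra_io.load_json_model(str(path))
        cm.objective = "DM_a[bc]"
        assert cm.optimize().objective_value == pytest.approx(
            fba_max(m, "DM_a[bc]").objective_value, abs=1e-6)

    def test_monotone_in_bounds(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            model = random_toy_model(rng, n_reactions=6)
            rid = "r0"
            base = fba_max(model, rid).objective_value
            widened = model.copy()
            for rxn in widened.reactions.values():
                rxn.lower_bound -= 1.0
                rxn.upper_bound += 1.0
            assert fba_max(widened, rid).objective_value >= base - 1e-9


class TestPredictBloodFluxes:
    def test_scaled_equals_naive_recompute(self, small_study):
        fm = small_study["flux_matrix"]
        models = small_study["sample_models"]
        germfree = small_study["germfree"]
        rng = np.random.default_rng(0)
        samples = rng.choice(fm.raw.index, size=5, replace=False)
        for sample in samples:
            model = models[sample].model.copy()
            gf = germfree[models[sample].sex].copy()
            for met in fm.raw.columns:
                add_demand_reaction(model, met)
                add_demand_reaction(gf, met)
            for met in fm.raw.columns:
                raw = fba_max(model, demand_reaction_id(met)).objective_value
                base = fba_max(gf, demand_reaction_id(met)).objective_value
                assert fm.scaled.loc[sample, met] == pytest.approx(
                    round(raw, 6) - round(base, 6), abs=1e-6)

    def test_sex_consistency_of_germ_free_layer(self, small_study):
        fm = small_study["flux_matrix"]
        germfree = small_study["germfree"]
        from gutwbm.fba_engine import LinearProblem
        per_sex = {}
        for sex, host in germfree.items():
            model = host.copy()
            for met in fm.raw.columns:
                add_demand_reaction(model, met)
            lp = LinearProblem(model)
            per_sex[sex] = {
                met: round(lp.maximize(demand_reaction_id(met)).objective_value, 6)
                for met in fm.raw.columns}
        for sample in fm.raw.index:
            sex = fm.sexes[sample]
            for met in fm.raw.columns:
                assert fm.germ_free.loc[sample, met] == per_sex[sex][met]

    def test_sole_producer_flux_proportional_to_abundance(self):
        from gutwbm.model_assembly import (apply_diet, build_community,
                                           build_pan_species,
                                           join_host_microbiome)
        from gutwbm.synthetic_cohort import (EffectConfig, default_diet,
                                             generate_host_model,
                                             generate_toy_reconstructions)
        config = EffectConfig(n_samples=2, seed=0)
        strains = generate_toy_reconstructions(config)
        pans = {sp: build_pan_species(s, pan_id=sp)
                for sp, s in strains.items()}
        host = generate_host_model(config, "female")
        gf = host.copy()
        apply_diet(gf, default_diet(config))
        models = {}
        for name, a in [("s_lo", 0.1), ("s_hi", 0.2)]:
            community = build_community(
                pans, {"arg_driver": a, "null_sp_2": 1.0 - a})
            wbm = join_host_microbiome(host, community, sample_sex="female")
            apply_diet(wbm.model, default_diet(config))
            models[name] = wbm
        fm = predict_blood_fluxes(models, {"female": gf}, ["arg_like"])
        ratio = (fm.scaled.loc["s_hi", "arg_like"]
                 / fm.scaled.loc["s_lo", "arg_like"])
        assert ratio == pytest.approx(2.0, rel=1e-6)

    def test_infeasible_sample_masks_row_and_continues(self):
        from gutwbm import EffectConfig
        from gutwbm.pipeline import run_flux_study as rfs
        study = rfs(EffectConfig(n_samples=4, seed=3))
        models = dict(list(study["sample_models"].items())[:2])
        broken = list(models)[0]
        model = models[broken].model
        # conflicting pin makes the model infeasible
        model.reactions["Whole_body_objective_rxn"].lower_bound = 2.0
        model.reactions["Whole_body_objective_rxn"].upper_bound = 2.0
        model.reactions["EX_diet_sub[d]"].lower_bound = -1.0
        fm = predict_blood_fluxes(models, study["germfree"], ["arg_like"])
        assert (fm.mask.loc[broken] == MASK_INFEASIBLE).all()
        other = [s for s in models if s != broken][0]
        assert np.isfinite(fm.raw.loc[other, "arg_like"])

    def test_deterministic(self, small_config, small_study):
        from gutwbm.pipeline import run_flux_study
        again = run_flux_study(small_config)
        pd.testing.assert_frame_equal(again["flux_matrix"].scaled,
                                      small_study["flux_matrix"].scaled)
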