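"""Model representation, rate evaluation, and SBML exchange."""

import numpy as np
import pytest

from gshflux.model import (
    IRREVERSIBLE_MM,
    MASS_ACTION,
    REVERSIBLE_MM,
    KineticModel,
    ModelError,
    ModelParseError,
    RateLaw,
    ReactionDef,
    SpeciesState,
    UnsupportedModelError,
    build_default_gsh_model,
    evaluate_rates,
    load_builtin,
    load_model,
    ode_rhs,
    save_model,
    structurally_equal,
)
from gshflux.synthetic import chain_model, gen_toy_models, redox_model


def one_reaction_model(law, stoich=None, extra_species=()):
    species = [
        SpeciesState("S", concentration=1.0),
        SpeciesState("P", concentration=0.5),
    ] + list(extra_species)
    rxn = ReactionDef("r1", stoichiometry=stoich or {"S": -1, "P": 1}, rate_law=law)
    return KineticModel(species, [rxn])


class TestRateEvaluation:
    def test_irreversible_mm_half_saturation(self):
        law = RateLaw(IRREVERSIBLE_MM, vmax=10.0, km_substrate={"S": 1.0},
                      substrate_refs=["S"], product_refs=["P"])
        m = one_reaction_model(law)
        rates = evaluate_rates(m, np.array([1.0, 0.5]))
        assert rates[0] == pytest.approx(5.0)

    def test_irreversible_mm_zero_at_zero_substrate(self):
        law = RateLaw(IRREVERSIBLE_MM, vmax=10.0, km_substrate={"S": 1.0},
                      substrate_refs=["S"], product_refs=["P"])
        m = one_reaction_model(law)
        assert evaluate_rates(m, np.array([0.0, 0.5]))[0] == 0.0

    def test_zero_vmax_gives_zero_rates(self, gsh_model):
        conc = gsh_model.initial_concentrations()
        zeroed = {rid: 0.0 for rid in gsh_model.reference_vmax()}
        rates = evaluate_rates(gsh_model, conc, vmax_override=zeroed)
        mm_idx = [j for j, r in enumerate(gsh_model.reactions)
                  if r.rate_law.form != MASS_ACTION]
        assert np.all(rates[mm_idx] == 0.0)

    def test_reversible_mm_zero_at_equilibrium(self):
        """Net rate vanishes when the mass-action ratio equals Keq.

        Cross-checked against a direct arithmetic evaluation of the
        reversible-MM formula at an off-equilibrium point.
        """
        vmax, kms, kmp, keq = 3.0, 0.4, 1.5, 2.0
        law = RateLaw(REVERSIBLE_MM, vmax=vmax, km_substrate={"S": kms},
                      km_product={"P": kmp}, keq=keq,
                      substrate_refs=["S"], product_refs=["P"])
        m = one_reaction_model(law)
        s = 0.7
        at_eq = evaluate_rates(m, np.array([s, keq * s]))
        assert at_eq[0] == pytest.approx(0.0, abs=1e-14)
        s, p = 0.7, 0.2
        expected = vmax / kms * (s - p / keq) / (1 + s / kms + p / kmp)
        assert evaluate_rates(m, np.array([s, p]))[0] == pytest.approx(expected)

    def test_irreversible_rates_nonnegative(self, gsh_model, rng):
        for _ in range(20):
            conc = rng.uniform(0.0, 5.0, size=len(gsh_model.species))
            rates = evaluate_rates(gsh_model, conc)
            for j, r in enumerate(gsh_model.reactions):
                if r.rate_law.form == IRREVERSIBLE_MM:
                    assert rates[j] >= 0.0

    def test_negative_concentration_rejected(self, gsh_model):
        conc = gsh_model.initial_concentrations()
        conc[5] = -0.1
        with pytest.raises(ModelError, match="negative concentration"):
            evaluate_rates(gsh_model, conc)


class TestOdeRhs:
    def test_rhs_is_stoichiometry_times_rates(self, gsh_model, rng):
        """dc/dt equals N.v element-wise on dynamic rows, zero on boundary."""
        conc = rng.uniform(0.01, 3.0, size=len(gsh_model.species))
        rhs = ode_rhs(gsh_model, conc)
        nv = gsh_model.stoich_matrix @ evaluate_rates(gsh_model, conc)
        dyn = gsh_model.dynamic_index
        np.testing.assert_allclose(rhs[dyn], nv[dyn], rtol=1e-12)
        boundary = [i for i in range(len(gsh_model.species)) if i not in dyn]
        assert np.all(rhs[boundary] == 0.0)

    def test_all_vmax_zero_chain_rhs(self):
        m = chain_model(k1=0.0, vmax=4.0, km=2.0)
        rhs = ode_rhs(m, m.initial_concentrations(),
                      vmax_override={"vdrain": 0.0})
        assert np.all(rhs == 0.0)

    def test_linear_chain_intermediate_balance(self):
        m = chain_model(k1=1.0, vmax=4.0, km=2.0)
        conc = m.initial_concentrations()
        rhs = ode_rhs(m, conc)
        rates = evaluate_rates(m, conc)
        assert rhs[m.species_idx("S")] == pytest.approx(rates[0] - rates[1])


class TestSbmlExchange:
    @pytest.mark.parametrize("name", ["chain", "branch", "redox", "supply"])
    def test_round_trip_toy_fixtures(self, name):
        m = gen_toy_models()[name]
        assert structurally_equal(m, load_model(save_model(m)))

    def test_round_trip_surrogate(self, gsh_model):
        m2 = load_model(save_model(gsh_model))
        assert structurally_equal(gsh_model, m2)
        assert len(m2.species) == len(gsh_model.species)
        assert m2.reaction_ids == gsh_model.reaction_ids

    def test_builtin_file_matches_builder(self, gsh_model):
        assert structurally_equal(gsh_model, load_builtin())

    def test_boundary_flag_round_trips(self):
        m = chain_model()
        m2 = load_model(save_model(m))
        flags = {s.species_id: s.is_boundary for s in m2.species}
        assert flags == {"SRC": True, "S": False, "OUT": True}

    def test_single_reaction_identity_read_back(self):
        law = RateLaw(IRREVERSIBLE_MM, vmax=7.5, km_substrate={"S": 0.3},
                      substrate_refs=["S"], product_refs=["P"])
        m2 = load_model(save_model(one_reaction_model(law)))
        loaded = m2.reaction("r1").rate_law
        assert loaded.form == IRREVERSIBLE_MM
        assert loaded.vmax == pytest.approx(7.5)
        assert loaded.km_substrate["S"] == pytest.approx(0.3)

    def test_empty_model_rejected(self):
        m = build_default_gsh_model()
        m.reactions = []
        with pytest.raises(ModelError, match="no reactions"):
            save_model(m)

    def test_undeclared_species_rejected(self, gsh_model):
        doc = save_model(gsh_model).replace("GSSG", "GHOST_SPECIES", 1)
        with pytest.raises((ModelParseError, ModelError)):
            load_model(doc)

    def test_malformed_document_rejected(self):
        with pytest.raises(ModelParseError):
            load_model("<sbml><model><broken")

    def test_reaction_without_kinetic_law_rejected(self, gsh_model):
        import re

        doc = save_model(gsh_model)
        doc = re.sub(r"<kineticLaw>.*?</kineticLaw>", "", doc, count=1,
                     flags=re.DOTALL)
        with pytest.raises(UnsupportedModelError, match="kinetic law"):
            load_model(doc)


class TestSurrogateModel:
    def test_contains_required_reactions(self, gsh_model):
        rids = set(gsh_model.reaction_ids)
        assert {"v11", "v27", "vGS", "vGCS", "vGPX", "vGST"} <= rids

    def test_build_is_deterministic(self, gsh_model):
        assert structurally_equal(gsh_model, build_default_gsh_model())
        assert gsh_model.content_hash() == build_default_gsh_model().content_hash()

    def test_moiety_conservation_under_integration(self):
        """Redox-couple total (RED + 2*OX) drifts < 1e-6 relative."""
        from gshflux.steadystate import integrate_trajectory

        m = redox_model()
        x0 = m.initial_concentrations()
        x0[0], x0[1] = 1.7, 0.65  # arbitrary positive start, total 3.0
        _t, conc = integrate_trajectory(m, 200.0, x0=x0, n_points=40)
        totals = conc[:, 0] + 2.0 * conc[:, 1]
        assert np.max(np.abs(totals - totals[0])) / totals[0] < 1e-6

    def test_invariant_validation_catches_bad_refs(self):
        law = RateLaw(IRREVERSIBLE_MM, vmax=1.0, km_substrate={"MISSING": 1.0},
                      substrate_refs=["MISSING"], product_refs=[])
        with pytest.raises(ModelError, match="undeclared species"):
            KineticModel([SpeciesState("S", concentration=1.0)],
                         [ReactionDef("r", stoichiometry={"S": -1}, rate_law=law)])
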