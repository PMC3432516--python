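"""Synthetic expression generator and fixture ground truth."""

import math

import numpy as np
import pytest

from gshflux.expression import fold_change
from gshflux.synthetic import (
    STUDY_FOLD_CHANGES,
    SyntheticSpec,
    gen_expression,
    gen_toy_models,
    study_gene_map,
    study_scenario_spec,
)


def spec_with(noise_cv=0.0, seed=0, fold=1.86, gene="GENEA"):
    return SyntheticSpec(
        genes=[gene, "GENEB"],
        subjects=["CTRL", "P"],
        control_subject="CTRL",
        fold_changes={"P": {gene: fold}},
        noise_cv=noise_cv,
        seed=seed,
    )


class TestGenExpression:
    def test_zero_noise_exact_recovery(self):
        """Programmed 1.86x fold change recovered exactly without noise."""
        expr = gen_expression(spec_with(noise_cv=0.0))
        ratio, per_rep = fold_change(expr, "GENEA", "P", "CTRL")
        assert ratio == pytest.approx(1.86)
        assert per_rep == pytest.approx([1.86, 1.86])
        assert fold_change(expr, "GENEB", "P", "CTRL")[0] == pytest.approx(1.0)

    def test_same_seed_identical(self):
        a = gen_expression(spec_with(noise_cv=0.1, seed=5))
        b = gen_expression(spec_with(noise_cv=0.1, seed=5))
        assert a.df.equals(b.df)
        c = gen_expression(spec_with(noise_cv=0.1, seed=6))
        assert not a.df.equals(c.df)

    def test_empirical_cv_matches_lognormal_formula(self):
        """Across many replicate draws the multiplicative CV hits noise_cv."""
        spec = SyntheticSpec(
            genes=["G"], subjects=["CTRL"], control_subject="CTRL",
            replicates_per_subject=200, noise_cv=0.1, seed=3,
        )
        vals = gen_expression(spec).intensities("G", "CTRL")
        cv = vals.std(ddof=1) / vals.mean()
        assert abs(cv - 0.1) / 0.1 < 0.2

    def test_control_fold_change_must_be_one(self):
        with pytest.raises(ValueError, match="control fold change"):
            SyntheticSpec(genes=["G"], subjects=["C"], control_subject="C",
                          fold_changes={"C": {"G": 2.0}})

    def test_ground_truth_recovery_bias_under_noise(self):
        """Mean recovered fold change over 100 seeds biased < 1% at CV 5%."""
        ratios = [
            fold_change(gen_expression(spec_with(noise_cv=0.05, seed=s)),
                        "GENEA", "P", "CTRL")[0]
            for s in range(100)
        ]
        assert abs(np.mean(ratios) / 1.86 - 1.0) < 0.01

    def test_study_scenario_shape(self):
        spec = study_scenario_spec(seed=0)
        expr = gen_expression(spec)
        assert expr.subjects == ["H0002", "H0007", "H0008"]
        assert all(expr.replicate_count(s) == 2 for s in expr.subjects)
        ratio, _ = fold_change(
            gen_expression(study_scenario_spec(seed=0, noise_cv=0.0)),
            "OPLAH", "H0008", "H0002",
        )
        assert ratio == pytest.approx(STUDY_FOLD_CHANGES["H0008"]["OPLAH"])

    def test_study_gene_map_covers_model(self, gsh_model):
        study_gene_map().validate_against(gsh_model)


class TestToyFixtures:
    def test_fixture_set_complete(self):
        models = gen_toy_models()
        assert set(models) == {"chain", "branch", "redox", "supply"}

    def test_chain_closed_form_documented_and_matched(self):
        from gshflux.steadystate import solve_steady_state
        from gshflux.synthetic import chain_model, chain_steady_conc

        state = solve_steady_state(chain_model(0.7, 3.0, 1.5))
        assert state.concentrations["S"] == pytest.approx(
            chain_steady_conc(0.7, 3.0, 1.5), rel=1e-7
        )

    def test_chain_closed_form_guards(self):
        from gshflux.synthetic import chain_steady_conc

        with pytest.raises(ValueError):
            chain_steady_conc(1.0, 0.5, 2.0)

    def test_branch_split_closed_form(self):
        from gshflux.steadystate import solve_steady_state
        from gshflux.synthetic import branch_model

        k1, v1, v2, km = 1.2, 2.0, 4.0, 0.7
        state = solve_steady_state(branch_model(k1, v1, v2, km))
        assert state.fluxes["vb1"] == pytest.approx(v1 * k1 / (v1 + v2), rel=1e-7)
        assert state.concentrations["S"] == pytest.approx(
            km * k1 / (v1 + v2 - k1), rel=1e-7
        )

    def test_redox_total_conserved(self):
        from gshflux.steadystate import integrate_trajectory
        from gshflux.synthetic import redox_model

        m = redox_model(total=3.0)
        _t, conc = integrate_trajectory(m, 50.0, n_points=25)
        totals = conc[:, 0] + 2 * conc[:, 1]
        np.testing.assert_allclose(totals, 3.0, rtol=1e-7)


class TestEndToEndRecovery:
    def test_neutral_fold_change_gives_unit_ratio(self):
        """f = 1 everywhere: flux ratios 1 within combined ensemble spread."""
        from gshflux.synthetic import end_to_end_recovery, supply_model

        spec = SyntheticSpec(
            genes=["SUPPLY1"], subjects=["CTRL", "P"], control_subject="CTRL",
            fold_changes={}, noise_cv=0.05, seed=2,
        )
        from gshflux.expression import GeneEnzymeMap

        rep = end_to_end_recovery(spec, supply_model(), GeneEnzymeMap(
            {"SUPPLY1": ["vin"]}), "P", n_samples=400, seed=0)
        vin = next(c for c in rep["comparisons"] if c.reaction_id == "vin")
        tol = 3 * (vin.flux_sd_case + vin.flux_sd_control) / vin.flux_mean_control
        assert abs(vin.flux_ratio - 1.0) < max(tol, 0.05)

    def test_flux_proportional_fixture_recovers_f(self):
        from gshflux.expression import GeneEnzymeMap
        from gshflux.synthetic import end_to_end_recovery, supply_model

        spec = SyntheticSpec(
            genes=["SUPPLY1"], subjects=["CTRL", "P"], control_subject="CTRL",
            fold_changes={"P": {"SUPPLY1": 2.0}}, noise_cv=0.05, seed=4,
        )
        rep = end_to_end_recovery(spec, supply_model(), GeneEnzymeMap(
            {"SUPPLY1": ["vin"]}), "P", n_samples=400, seed=0)
        vin = next(c for c in rep["comparisons"] if c.reaction_id == "vin")
        assert vin.flux_ratio == pytest.approx(2.0, rel=0.1)

    def test_input_limited_fixture_flux_ratio_one(self):
        from gshflux.expression import GeneEnzymeMap
        from gshflux.synthetic import chain_model, end_to_end_recovery

        spec = SyntheticSpec(
            genes=["DRAIN1"], subjects=["CTRL", "P"], control_subject="CTRL",
            fold_changes={"P": {"DRAIN1": 2.0}}, noise_cv=0.05, seed=4,
        )
        rep = end_to_end_recovery(spec, chain_model(1.0, 4.0, 2.0),
                                  GeneEnzymeMap({"DRAIN1": ["vdrain"]}),
                                  "P", n_samples=400, seed=0)
        drain = next(c for c in rep["comparisons"] if c.reaction_id == "vdrain")
        assert drain.flux_ratio == pytest.approx(1.0, abs=1e-6)
        assert drain.agreement == pytest.approx(-math.log(2.0), abs=0.1)
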