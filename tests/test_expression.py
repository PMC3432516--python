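"""Expression fold changes and Vmax-range construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gshflux.expression import (
    ExpressionError,
    ExpressionMatrix,
    GeneEnzymeMap,
    VmaxRange,
    fold_change,
    vmax_ranges,
)
from gshflux.synthetic import chain_model


def make_matrix(case_vals, ctrl_vals, gene="GENEA"):
    cols = {f"CTRL_{i+1}": [v] for i, v in enumerate(ctrl_vals)}
    cols.update({f"CASE_{i+1}": [v] for i, v in enumerate(case_vals)})
    return ExpressionMatrix(pd.DataFrame(cols, index=[gene]))


class TestFoldChange:
    def test_hand_arithmetic(self, toy_expression):
        ratio, per_rep = fold_change(toy_expression, "GENEA", "CASE", "CTRL")
        assert ratio == pytest.approx(1.0)
        assert per_rep == pytest.approx([0.8, 1.2])

    def test_identity(self, toy_expression):
        ratio, per_rep = fold_change(toy_expression, "GENEB", "CASE", "CTRL")
        assert ratio == pytest.approx(1.0)
        assert per_rep == pytest.approx([1.0, 1.0])

    def test_programmed_1_86(self):
        expr = make_matrix([186.0, 186.0], [100.0, 100.0])
        ratio, _ = fold_change(expr, "GENEA", "CASE", "CTRL")
        assert ratio == pytest.approx(1.86)

    def test_missing_gene_and_subject(self, toy_expression):
        with pytest.raises(ExpressionError, match="unknown gene"):
            fold_change(toy_expression, "NOPE", "CASE", "CTRL")
        with pytest.raises(ExpressionError, match="unknown subject"):
            fold_change(toy_expression, "GENEA", "CASE", "NOPE")

    def test_nonpositive_intensity_rejected(self):
        df = pd.DataFrame({"A_1": [1.0], "B_1": [0.0]}, index=["G"])
        with pytest.raises(ExpressionError, match="> 0"):
            ExpressionMatrix(df)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, scale):
        """A common multiplicative factor on all samples changes nothing."""
        base = make_matrix([8.0, 12.0], [10.0, 10.0])
        scaled = ExpressionMatrix(base.df * scale)
        r1, p1 = fold_change(base, "GENEA", "CASE", "CTRL")
        r2, p2 = fold_change(scaled, "GENEA", "CASE", "CTRL")
        assert r2 == pytest.approx(r1)
        assert p2 == pytest.approx(p1)


class TestVmaxRanges:
    @pytest.fixture
    def chain(self):
        return chain_model(1.0, 10.0, 2.0)  # reference Vmax 10 on the drain

    @pytest.fixture
    def gmap(self):
        return GeneEnzymeMap({"GENEA": ["vdrain"]})

    def test_degenerate_when_equal_to_control_mean(self, chain, gmap):
        expr = make_matrix([10.0], [10.0, 10.0])
        (rng,) = vmax_ranges(expr, gmap, chain, "CASE", "CTRL")
        assert (rng.low, rng.high) == (10.0, 10.0)

    def test_hand_arithmetic_range(self, chain, gmap):
        expr = make_matrix([8.0, 12.0], [10.0, 10.0])
        (rng,) = vmax_ranges(expr, gmap, chain, "CASE", "CTRL")
        assert rng.low == pytest.approx(8.0)
        assert rng.high == pytest.approx(12.0)
        assert rng.per_replicate_vmax == pytest.approx([8.0, 12.0])

    def test_control_uses_own_replicate_spread(self, chain, gmap):
        expr = make_matrix([8.0, 12.0], [9.0, 11.0])
        (rng,) = vmax_ranges(expr, gmap, chain, "CTRL", "CTRL")
        assert rng.low == pytest.approx(9.0)
        assert rng.high == pytest.approx(11.0)

    def test_unmapped_reaction_degenerate_at_reference(self, chain):
        expr = make_matrix([8.0, 12.0], [10.0, 10.0])
        (rng,) = vmax_ranges(expr, GeneEnzymeMap({}), chain, "CASE", "CTRL")
        assert (rng.low, rng.high) == (10.0, 10.0)

    def test_multiple_genes_geometric_mean(self, chain):
        gmap = GeneEnzymeMap({"GENEA": ["vdrain"], "GENEB": ["vdrain"]})
        df = pd.DataFrame(
            {"CTRL_1": [10.0, 10.0], "CASE_1": [20.0, 5.0]},
            index=["GENEA", "GENEB"],
        )
        (rng,) = vmax_ranges(ExpressionMatrix(df), gmap, chain, "CASE", "CTRL")
        assert rng.low == pytest.approx(10.0)  # geomean(2, 0.5) = 1

    def test_gene_mapped_to_absent_reaction_errors(self, chain):
        expr = make_matrix([8.0], [10.0])
        gmap = GeneEnzymeMap({"GENEA": ["not_a_reaction"]})
        with pytest.raises(ExpressionError, match="absent from the model"):
            vmax_ranges(expr, gmap, chain, "CASE", "CTRL")

    def test_gene_mapped_to_mass_action_errors(self, chain):
        expr = make_matrix([8.0], [10.0])
        gmap = GeneEnzymeMap({"GENEA": ["vin"]})
        with pytest.raises(ExpressionError, match="no Vmax"):
            vmax_ranges(expr, gmap, chain, "CASE", "CTRL")

    def test_proportionality_zero_disables_scaling(self, chain, gmap):
        expr = make_matrix([8.0, 12.0], [10.0, 10.0])
        (rng,) = vmax_ranges(expr, gmap, chain, "CASE", "CTRL",
                             proportionality=0.0)
        assert (rng.low, rng.high) == (10.0, 10.0)

    @given(bump=st.floats(min_value=1.01, max_value=5.0))
    @settings(max_examples=25, deadline=None)
    def test_monotonicity_in_case_replicate(self, bump):
        """Raising one case replicate never lowers the range maximum."""
        chain = chain_model(1.0, 10.0, 2.0)
        gmap = GeneEnzymeMap({"GENEA": ["vdrain"]})
        base = make_matrix([8.0, 12.0], [10.0, 10.0])
        bumped = make_matrix([8.0, 12.0 * bump], [10.0, 10.0])
        (r0,) = vmax_ranges(base, gmap, chain, "CASE", "CTRL")
        (r1,) = vmax_ranges(bumped, gmap, chain, "CASE", "CTRL")
        assert r1.per_replicate_vmax[1] > r0.per_replicate_vmax[1]
        assert r1.high >= r0.high

    def test_range_invariants(self):
        rng = VmaxRange("r", "c", [3.0, 1.0, 2.0])
        assert rng.low == 1.0 and rng.high == 3.0 and rng.midpoint == 2.0
        with pytest.raises(ExpressionError):
            VmaxRange("r", "c", [0.0, 1.0])


class TestIoFormats:
    def test_expression_tsv_round_trip(self, toy_expression, tmp_path):
        path = tmp_path / "expr.tsv"
        toy_expression.to_tsv(str(path))
        back = ExpressionMatrix.from_tsv(str(path))
        pd.testing.assert_frame_equal(back.df, toy_expression.df)

    def test_gene_map_tsv_round_trip(self, tmp_path):
        gmap = GeneEnzymeMap({"GSS": ["vGS"], "GSTA4": ["vGST"],
                              "GSTM1": ["vGST"]})
        path = tmp_path / "map.tsv"
        gmap.to_tsv(str(path))
        assert GeneEnzymeMap.from_tsv(str(path)).entries == gmap.entries
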