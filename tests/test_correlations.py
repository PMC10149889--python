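import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psyvalid.correlations import (
    CorrelationMatrix,
    average_absolute_correlation,
    correlation_ci,
    disattenuate,
    fisher_z,
    inverse_fisher,
    matrix_equality_test,
    matrix_mad,
    pairwise_correlations,
)
from tests.conftest import make_symmetric


class TestFisherZ:
    @pytest.mark.parametrize(
        "r,expected",
        [(0.0, 0.0), (0.55, math.atanh(0.55)), (-0.3, math.atanh(-0.3))],
    )
    def test_matches_atanh(self, r, expected):
        assert fisher_z(r) == pytest.approx(expected, abs=1e-12)
        assert fisher_z(0.55) == pytest.approx(0.6184, abs=5e-4)

    @given(st.floats(-0.999999, 0.999999))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_identity(self, r):
        assert inverse_fisher(fisher_z(r)) == pytest.approx(r, abs=1e-9)

    def test_unit_correlation_is_clipped_finite(self):
        assert np.isfinite(fisher_z(1.0)) and np.isfinite(fisher_z(-1.0))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.5)


class TestPairwiseCorrelations:
    def test_self_and_negation(self, rng):
        x = rng.standard_normal(50)
        table = pd.DataFrame({"x": x, "y": -x, "z": rng.standard_normal(50)})
        m = pairwise_correlations(table)
        assert m.values.loc["x", "x"] == pytest.approx(1.0)
        assert m.values.loc["x", "y"] == pytest.approx(-1.0)
        assert m.pair_n.loc["x", "z"] == 50

    def test_matches_hand_computed_pearson(self):
        # 6-row fixture; Pearson from explicit sums, no library shortcut
        x = np.array([1.0, 2.0, 4.0, 4.5, 6.0, 9.0])
        y = np.array([2.0, 1.0, 3.0, 5.0, 5.5, 8.0])
        n = 6
        sxy = np.sum(x * y) - np.sum(x) * np.sum(y) / n
        sxx = np.sum(x * x) - np.sum(x) ** 2 / n
        syy = np.sum(y * y) - np.sum(y) ** 2 / n
        expected = sxy / np.sqrt(sxx * syy)
        m = pairwise_correlations(pd.DataFrame({"x": x, "y": y}))
        assert m.values.loc["x", "y"] == pytest.approx(expected, abs=1e-12)

    def test_pairwise_deletion_counts_and_min_pairs(self, rng):
        table = pd.DataFrame(rng.standard_normal((10, 2)), columns=["a", "b"])
        table.loc[:6, "b"] = np.nan  # only 3 complete pairs -> undefined
        m = pairwise_correlations(table)
        assert m.pair_n.loc["a", "b"] == 3
        assert np.isnan(m.values.loc["a", "b"])

    def test_constant_column_is_undefined(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0], "b": [2.0] * 5})
        m = pairwise_correlations(table)
        assert np.isnan(m.values.loc["a", "b"])


class TestAverageAbsoluteCorrelation:
    def test_network_block_single_item_column(self):
        # seven network-domain correlations of a direct-frequency single item
        vals = [-0.16, -0.03, -0.17, -0.21, -0.19, -0.02, -0.12]
        assert round(average_absolute_correlation(vals), 2) == 0.13

    def test_satisfaction_block_total_scale_column(self):
        vals = [-0.53, -0.36, -0.45, -0.66, -0.42, -0.34]
        assert round(average_absolute_correlation(vals), 2) == 0.47

    def test_constant_list_returns_magnitude(self):
        assert average_absolute_correlation([-0.4, -0.4, -0.4]) == pytest.approx(0.4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_absolute_correlation([])

    @given(
        st.lists(st.floats(-0.95, 0.95), min_size=2, max_size=12).filter(
            lambda v: len({round(abs(x), 6) for x in v}) > 1
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_z_average_dominates_plain_mean(self, vals):
        # convexity of atanh on [0, 1): the z-based average of heterogeneous
        # magnitudes exceeds the arithmetic mean of |r|
        assert average_absolute_correlation(vals) >= np.mean(np.abs(vals)) - 1e-12


class TestMatrixMad:
    def test_identical_matrices(self, study1_convergent):
        m = study1_convergent["self"]
        assert matrix_mad(m, m) == 0.0

    def test_single_cell(self):
        m1 = make_symmetric([[1, 0.5], [0.5, 1]], ["a", "b"])
        m2 = make_symmetric([[1, 0.3], [0.3, 1]], ["a", "b"])
        assert matrix_mad(m1, m2) == pytest.approx(0.2)

    def test_self_vs_informant_triangles(self, study1_convergent):
        # direct arithmetic on the printed triangles lands near the
        # published .08 (printed values are rounded; exact match impossible)
        mad = matrix_mad(study1_convergent["self"], study1_convergent["informant"])
        assert mad == pytest.approx(0.08, abs=0.02)

    def test_label_mismatch_requires_map(self):
        m1 = make_symmetric([[1, 0.5], [0.5, 1]], ["a", "b"])
        m2 = make_symmetric([[1, 0.5], [0.5, 1]], ["a", "c"])
        with pytest.raises(ValueError):
            matrix_mad(m1, m2)
        assert matrix_mad(m1, m2, relabel={"c": "b"}) == 0.0


class TestMatrixEqualityTest:
    def test_identical_matrices_give_zero(self, study1_convergent):
        m = study1_convergent["self"]
        res = matrix_equality_test(m, 300, m, 300)
        assert res.q_statistic == 0.0 and res.p_value == 1.0
        assert res.df == res.cells_compared == 28

    def test_single_cell_hand_arithmetic(self):
        # z difference .2 at n=103 each: Q = .04 / (2/100) = 2.0
        r1 = math.tanh(0.5)
        r2 = math.tanh(0.3)
        m1 = make_symmetric([[1, r1], [r1, 1]], ["a", "b"])
        m2 = make_symmetric([[1, r2], [r2, 1]], ["a", "b"])
        res = matrix_equality_test(m1, 103, m2, 103)
        assert res.q_statistic == pytest.approx(2.0, abs=1e-9)
        assert res.df == 1

    def test_symmetric_in_arguments(self, study1_convergent):
        m1, m2 = study1_convergent["self"], study1_convergent["informant"]
        a = matrix_equality_test(m1, 400, m2, 160)
        b = matrix_equality_test(m2, 160, m1, 400)
        assert a.q_statistic == pytest.approx(b.q_statistic)

    def test_q_scales_with_sample_size(self):
        m1 = make_symmetric([[1, 0.5], [0.5, 1]], ["a", "b"])
        m2 = make_symmetric([[1, 0.4], [0.4, 1]], ["a", "b"])
        small = matrix_equality_test(m1, 103, m2, 103).q_statistic
        large = matrix_equality_test(m1, 203, m2, 203).q_statistic
        assert large == pytest.approx(small * 200 / 100)

    def test_k_squared_df_compatibility_mode(self, study1_convergent):
        m1, m2 = study1_convergent["self"], study1_convergent["informant"]
        unique = matrix_equality_test(m1, 679, m2, 160)
        compat = matrix_equality_test(m1, 679, m2, 160, cell_set="kxk")
        assert compat.df == 64
        assert compat.q_statistic == pytest.approx(2 * unique.q_statistic)

    def test_dependent_samples_flagged(self, study1_convergent):
        m1, m2 = study1_convergent["self"], study1_convergent["informant"]
        res = matrix_equality_test(m1, 160, m2, 160, dependent_samples=True)
        assert "dependence ignored" in res.notes


class TestDisattenuate:
    @pytest.mark.parametrize(
        "r,rel1,rel2,expected",
        [
            (0.55, 0.80, 0.81, 0.68),  # short-scale partner agreement
            (0.61, 0.94, 0.93, 0.65),  # long-scale informant agreement
        ],
    )
    def test_published_corrections(self, r, rel1, rel2, expected):
        assert round(disattenuate(r, rel1, rel2), 2) == expected

    def test_zero_maps_to_zero(self):
        assert disattenuate(0.0, 0.5, 0.9) == 0.0

    def test_nonpositive_reliability_rejected(self):
        with pytest.raises(ValueError):
            disattenuate(0.5, 0.0, 0.9)

    @given(
        st.floats(0.05, 0.9),
        st.floats(0.3, 1.0),
        st.floats(0.3, 1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_r_and_reliabilities(self, r, rel1, rel2):
        base = disattenuate(r, rel1, rel2)
        assert disattenuate(r + 0.05, rel1, rel2) > base
        assert disattenuate(r, min(rel1 + 0.05, 1.0), rel2) <= base + 1e-12


class TestCorrelationCI:
    def test_null_interval_closed_form(self):
        lo, hi = correlation_ci(0.0, 403, 0.95)
        expected = math.tanh(1.959963985 / math.sqrt(400))
        assert hi == pytest.approx(expected, abs=1e-9)
        assert lo == pytest.approx(-expected, abs=1e-9)

    def test_full_coverage_limit(self):
        lo, hi = correlation_ci(0.3, 50, 1.0)
        assert lo == pytest.approx(-1.0, abs=1e-9)
        assert hi == pytest.approx(1.0, abs=1e-9)

    def test_interval_collapses_with_n(self):
        lo, hi = correlation_ci(0.42, 10**9)
        assert lo == pytest.approx(0.42, abs=1e-3)
        assert hi == pytest.approx(0.42, abs=1e-3)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            correlation_ci(0.5, 3)


class TestCorrelationMatrixContainer:
    def test_asymmetric_values_rejected(self):
        frame = pd.DataFrame([[1.0, 0.5], [0.4, 1.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            CorrelationMatrix(values=frame, symmetric=True)

    def test_cells_unique_triangle(self, study1_convergent):
        cells = study1_convergent["self"].cells()
        assert len(cells) == 28
        assert cells[("RTLS_Total", "RTLS_Emotional")] == pytest.approx(0.93)
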