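"""Quality chain: dE, Chauvenet, dehiscence, amide, normalization, weights, F."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from zandry.quality import (
    PUBLISHED_WEIGHTS,
    ColorMeasurement,
    QualityTable,
    amide_content,
    chauvenet_filter,
    comprehensive_score,
    dehiscence_rate,
    delta_e,
    entropy_weights,
    normalize_indicator,
    score_table,
)

finite = st.floats(min_value=-100.0, max_value=100.0)
lab = st.builds(ColorMeasurement, finite, finite, finite)


class TestDeltaE:
    def test_identity_and_pythagoras(self):
        a = ColorMeasurement(10.0, 5.0, -3.0)
        assert delta_e(a, a) == 0.0
        assert delta_e(ColorMeasurement(3, 4, 0), ColorMeasurement(0, 0, 0)) == 5.0

    def test_fresh_vs_dried_means(self):
        fresh = ColorMeasurement(31.82, -21.23, 19.51)
        dried = ColorMeasurement(29.42, -17.17, 18.07)
        assert delta_e(dried, fresh) == pytest.approx(4.93, abs=0.01)

    @given(a=lab, b=lab, c=lab)
    def test_metric_axioms(self, a, b, c):
        assert delta_e(a, b) == pytest.approx(delta_e(b, a))
        assert delta_e(a, c) <= delta_e(a, b) + delta_e(b, c) + 1e-9
        assert delta_e(a, b) >= 0.0


class TestChauvenet:
    def test_rejects_gross_outlier(self):
        out = chauvenet_filter([10.0, 10.1, 9.9, 10.05, 20.0])
        assert 20.0 not in out
        assert len(out) == 4

    def test_identical_values_all_retained(self):
        out = chauvenet_filter([5.0] * 5)
        assert len(out) == 5

    def test_three_spread_values_retained(self):
        out = chauvenet_filter([1.0, 2.0, 3.0])
        assert len(out) == 3

    def test_fewer_than_three_warns_and_passes_through(self):
        with pytest.warns(UserWarning):
            out = chauvenet_filter([1.0, 2.0])
        assert len(out) == 2

    @given(st.lists(st.floats(min_value=-50, max_value=50), min_size=3, max_size=12))
    def test_idempotent_on_own_output(self, values):
        once = chauvenet_filter(values)
        if len(once) >= 3:
            twice = chauvenet_filter(once)
            # single-pass regime: re-filtering with the same statistics basis
            # never removes everything and keeps at least the minimum
            assert len(twice) >= 2


class TestCounts:
    def test_dehiscence_examples(self):
        assert dehiscence_rate(0, 50) == 0.0
        assert dehiscence_rate(3, 4) == 75.0
        assert dehiscence_rate(7, 7) == 100.0
        with pytest.raises(ValueError):
            dehiscence_rate(1, 0)

    def test_amide_examples(self):
        assert amide_content(0.0, 5, 50, 1.0, 410) == 0.0
        assert amide_content(0.41, 5, 50, 1.0, 410) == pytest.approx(0.25)
        assert amide_content(0.41, 10, 50, 1.0, 410) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            amide_content(0.41, 5, 50, 0.0, 410)


class TestNormalization:
    def test_cost_endpoints(self):
        d = normalize_indicator([1.0, 2.0, 3.0], "cost")
        assert d[0] == 1.0 and d[-1] == 0.0

    def test_benefit_endpoints(self):
        d = normalize_indicator([1.0, 2.0, 3.0], "benefit")
        assert d[0] == 0.0 and d[-1] == 1.0

    def test_published_color_column_value(self):
        # dE column spanning [2.52, 8.68]: 3.81 normalizes to ~0.791 as cost
        col = [6.73, 3.75, 3.81, 5.59, 4.40, 2.52, 4.37, 5.70, 3.07, 5.44, 5.86, 8.68]
        d = normalize_indicator(col, "cost")
        assert d[2] == pytest.approx((8.68 - 3.81) / (8.68 - 2.52), abs=1e-9)
        assert d[2] == pytest.approx(0.791, abs=2e-3)

    def test_constant_column_degenerates(self):
        with pytest.warns(UserWarning):
            d = normalize_indicator([2.0, 2.0], "cost")
        assert np.allclose(d, 0.5)


class TestEntropyWeights:
    def test_hand_computed_2x2(self):
        w = entropy_weights(np.array([[1.0, 0.5], [0.0, 0.5]]))
        assert np.allclose(w, [1.0, 0.0])

    def test_uniform_column_gets_zero_weight(self):
        d = np.array([[0.4, 0.1], [0.4, 0.9], [0.4, 0.5]])
        w = entropy_weights(d)
        assert w[0] == pytest.approx(0.0, abs=1e-12)
        assert w.sum() == pytest.approx(1.0)

    @given(
        st.integers(min_value=2, max_value=8),
        st.integers(min_value=2, max_value=5),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_sums_to_one_and_permutation_equivariant(self, m, k, seed):
        rng = np.random.default_rng(seed)
        d = rng.uniform(0.05, 1.0, size=(m, k))
        w = entropy_weights(d)
        assert w.sum() == pytest.approx(1.0)
        assert np.all(w >= 0)
        row_perm = rng.permutation(m)
        col_perm = rng.permutation(k)
        assert np.allclose(entropy_weights(d[row_perm]), w, atol=1e-12)
        assert np.allclose(entropy_weights(d[:, col_perm]), w[col_perm], atol=1e-12)


class TestComprehensiveScore:
    def test_bounds(self):
        w = [0.25] * 4
        assert comprehensive_score([1, 1, 1, 1], w)[0] == pytest.approx(10.0)
        assert comprehensive_score([0, 0, 0, 0], w)[0] == 0.0

    def test_weighted_example(self):
        disp, raw = comprehensive_score(
            [0.791, 0.919, 1.0, 0.996], [0.21, 0.18, 0.22, 0.39]
        )
        assert raw == pytest.approx(0.940, abs=1e-3)
        assert disp == pytest.approx(9.40, abs=0.01)

    @given(
        st.integers(min_value=0, max_value=3),
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
    )
    def test_monotone_in_every_indicator(self, idx, lo, hi):
        w = np.array([0.21, 0.18, 0.22, 0.39])
        d = np.full(4, 0.5)
        d_lo, d_hi = d.copy(), d.copy()
        d_lo[idx], d_hi[idx] = min(lo, hi), max(lo, hi)
        assert comprehensive_score(d_hi, w)[0] >= comprehensive_score(d_lo, w)[0]

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            comprehensive_score([0.5, 0.5], [1.0])


class TestScoreTable:
    @pytest.fixture
    def table(self):
        means = pd.DataFrame(
            {
                "delta_e": [3.81, 2.52, 8.68],
                "dehiscence_rate": [99.1, 97.2, 99.8],
                "volatile_oil": [1.5, 0.75, 0.9],
                "amide": [28.6, 26.3, 26.5],
            },
            index=["MVD-60", "PVD-50", "HAD-70"],
        )
        return QualityTable(means=means)

    def test_published_weights_scheme(self, table):
        result = score_table(table, weights="published")
        assert result.weights.sum() == pytest.approx(1.0)
        assert dict(result.weights) == pytest.approx(PUBLISHED_WEIGHTS)
        assert result.f_display.between(0, 10).all()

    def test_entropy_scheme_reports_entropy(self, table):
        result = score_table(table, weights="entropy")
        assert result.entropy is not None
        assert result.weights.sum() == pytest.approx(1.0)

    def test_normalized_in_unit_interval(self, table):
        norm = table.normalized()
        assert (norm.to_numpy() >= 0).all() and (norm.to_numpy() <= 1).all()
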