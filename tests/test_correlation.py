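"""Variable classification, preprocessing, dispatch, FDR and rendering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gaitvar import (
    DegenerateDataError,
    InsufficientDataError,
    SmoothingConfig,
    VariableSpec,
    annotate_and_export,
    classify_variables,
    compute_correlation_matrix,
    dispatch_method,
    fdr_adjust,
    format_coefficient,
    pairwise_correlation,
    preprocess,
    star_annotation,
)
from gaitvar.correlation import KINDS, CorrelationResult

from oracles import bh_adjust


def spec(name, kind, values):
    return VariableSpec(name=name, kind=kind, values=np.asarray(values))


class TestClassifyVariables:
    def test_study_schema_classification(self):
        table = pd.DataFrame(
            {
                "subject_id": ["a", "b", "c", "d"],
                "gender": ["M", "F", "M", "M"],
                "score2": [0, 2, 3, 4],
                "height_cm": [150.5, 160.2, 171.0, 168.3],
                "duration": [9.1, 8.2, 7.7, 10.4],
            }
        )
        kinds = {s.name: s.kind for s in classify_variables(table)}
        assert kinds == {
            "gender": "binary",
            "score2": "ordinal",
            "height_cm": "continuous",
            "duration": "continuous",
        }

    def test_overrides_beat_autodetection(self):
        table = pd.DataFrame({"x": [0, 1, 2, 3], "y": [1.0, 2.0, 3.0, 4.0]})
        kinds = {s.name: s.kind
                 for s in classify_variables(table, overrides={"x": "continuous"})}
        assert kinds["x"] == "continuous"

    def test_constant_column_excluded_with_warning(self, caplog):
        table = pd.DataFrame({"c": [5, 5, 5], "x": [1.0, 2.0, 3.0]})
        with caplog.at_level("WARNING", logger="gaitvar.correlation"):
            specs = classify_variables(table)
        assert [s.name for s in specs] == ["x"]
        assert "constant" in caplog.text


class TestPreprocess:
    def test_ordinal_midranks_then_zscore(self):
        s = spec("o", "ordinal", [1, 2, 2, 4])
        z = preprocess(s)
        ranks = np.array([1.0, 2.5, 2.5, 4.0])
        expected = (ranks - ranks.mean()) / ranks.std(ddof=1)
        np.testing.assert_allclose(z, expected)
        assert z.sum() == pytest.approx(0.0, abs=1e-12)

    def test_smoothing_disabled_is_identity(self):
        values = [3.0, 1.0, 4.0, 1.0, 5.0]
        z = preprocess(spec("c", "continuous", values), SmoothingConfig(enabled=False))
        np.testing.assert_array_equal(z, values)

    def test_lowess_reproduces_constants(self):
        z = preprocess(spec("c", "continuous", [7.0] * 10),
                       SmoothingConfig(enabled=True, frac=0.5))
        np.testing.assert_allclose(z, 7.0)

    def test_lowess_shrinks_noise_around_a_trend(self):
        rng = np.random.default_rng(0)
        trend = np.linspace(0, 10, 60)
        noisy = trend + rng.normal(0, 1.0, 60)
        smooth = preprocess(spec("c", "continuous", noisy),
                            SmoothingConfig(enabled=True, frac=0.3))
        assert np.std(smooth - trend) < np.std(noisy - trend)

    def test_binary_becomes_zero_one(self):
        z = preprocess(spec("g", "binary", np.array(["M", "F", "M", "M"], object)))
        assert sorted(set(z)) == [0.0, 1.0]

    def test_all_tied_ordinal_is_degenerate(self):
        with pytest.raises(DegenerateDataError, match="tied"):
            preprocess(spec("o", "ordinal", [2, 2, 2, 2]))


class TestDispatch:
    @pytest.mark.parametrize(
        "ka, kb, expected",
        [
            ("binary", "binary", "undefined_default"),
            ("binary", "ordinal", "point_biserial"),
            ("binary", "continuous", "point_biserial"),
            ("ordinal", "ordinal", "kendall_tau"),
            ("continuous", "continuous", "pearson"),
            ("ordinal", "continuous", "spearman"),
        ],
    )
    def test_lookup_table_all_six_kind_pairs(self, ka, kb, expected):
        assert dispatch_method(ka, kb) == expected
        assert dispatch_method(kb, ka) == expected

    @given(st.sampled_from(KINDS), st.sampled_from(KINDS))
    def test_dispatch_is_total_and_symmetric(self, ka, kb):
        assert dispatch_method(ka, kb) == dispatch_method(kb, ka)


class TestPairwiseCorrelation:
    def test_continuous_self_correlation_is_one(self):
        x = spec("x", "continuous", [1.0, 2.0, 5.0, 3.0])
        r = pairwise_correlation(x, spec("y", "continuous", [1.0, 2.0, 5.0, 3.0]))
        assert r.coefficient == pytest.approx(1.0)
        assert r.method == "pearson"

    def test_point_biserial_hand_example(self):
        # Pearson of 0/1 coding vs (1,2,3,4): r = 0.5 / (0.5 * sqrt(1.25))
        b = spec("b", "binary", [0, 0, 1, 1])
        c = spec("c", "continuous", [1.0, 2.0, 3.0, 4.0])
        r = pairwise_correlation(b, c)
        assert r.method == "point_biserial"
        assert r.coefficient == pytest.approx(0.8944, abs=1e-4)

    def test_reversed_ordinals_give_kendall_minus_one(self):
        a = spec("a", "ordinal", [1, 2, 3, 4, 5])
        b = spec("b", "ordinal", [5, 4, 3, 2, 1])
        r = pairwise_correlation(a, b)
        assert r.method == "kendall_tau"
        assert r.coefficient == pytest.approx(-1.0)

    def test_binary_binary_has_no_coefficient(self):
        r = pairwise_correlation(spec("a", "binary", [0, 1, 0]),
                                 spec("b", "binary", [1, 1, 0]))
        assert r.method == "undefined_default"
        assert not r.defined

    def test_mixed_ordinal_continuous_uses_spearman(self):
        r = pairwise_correlation(spec("o", "ordinal", [1, 2, 3, 4]),
                                 spec("c", "continuous", [2.0, 4.0, 6.0, 9.0]))
        assert r.method == "spearman"
        assert r.coefficient == pytest.approx(1.0)

    def test_fewer_than_three_pairs_rejected(self):
        with pytest.raises(InsufficientDataError, match=">= 3"):
            pairwise_correlation(spec("a", "continuous", [1.0, 2.0]),
                                 spec("b", "continuous", [3.0, 4.0]))

    def test_zero_variance_flagged_not_crashed(self):
        r = pairwise_correlation(spec("a", "continuous", [1.0, 1.0, 1.0]),
                                 spec("b", "continuous", [1.0, 2.0, 3.0]))
        assert not r.defined and "zero variance" in r.note

    def test_missing_values_dropped_pairwise(self):
        a = spec("a", "continuous", [1.0, 2.0, np.nan, 4.0, 5.0])
        b = spec("b", "continuous", [2.0, 4.0, 6.0, 8.0, np.nan])
        r = pairwise_correlation(a, b)
        assert r.coefficient == pytest.approx(1.0)


class TestFdrAdjust:
    def _results(self, ps):
        return [CorrelationResult(pair=(f"v{i}", f"w{i}"), method="pearson",
                                  coefficient=0.5, p_raw=p)
                for i, p in enumerate(ps)]

    def test_single_p_unchanged(self):
        out = fdr_adjust(self._results([0.03]))
        assert out[0].p_adjusted == pytest.approx(0.03)

    def test_hand_stepup_example(self):
        out = fdr_adjust(self._results([0.01, 0.02, 0.03, 0.04]))
        assert [r.p_adjusted for r in out] == pytest.approx([0.04] * 4)

    def test_equal_ps_stay_equal(self):
        out = fdr_adjust(self._results([0.02, 0.02, 0.02]))
        assert len({round(r.p_adjusted, 12) for r in out}) == 1

    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=30))
    def test_matches_hand_bh_and_never_below_raw(self, ps):
        out = fdr_adjust(self._results(ps))
        expected = bh_adjust(ps)
        for r, p, e in zip(out, ps, expected):
            assert r.p_adjusted == pytest.approx(min(e, 1.0), rel=1e-9)
            assert r.p_adjusted >= p - 1e-15
            assert r.p_adjusted <= 1.0


class TestAnnotation:
    @pytest.mark.parametrize("p, stars", [
        (0.0005, "***"), (0.005, "**"), (0.03, "*"), (0.2, ""), (math.nan, ""),
    ])
    def test_star_thresholds(self, p, stars):
        assert star_annotation(p) == stars

    def test_coefficient_rendering_half_up(self):
        assert format_coefficient(-0.955, "***") == "-0.96***"
        assert format_coefficient(-0.954) == "-0.95"
        assert format_coefficient(float("nan"), "*") == ""


class TestCorrelationMatrix:
    def _matrix(self):
        rng = np.random.default_rng(5)
        n = 24
        x = rng.normal(size=n)
        table = pd.DataFrame(
            {
                "gender": np.where(rng.uniform(size=n) < 0.5, "M", "F"),
                "score": rng.integers(0, 5, n),
                "duration": 10 - 2 * x + rng.normal(0, 0.5, n),
                "var_mean": 5 + x,
            }
        )
        specs = classify_variables(table, overrides={"score": "ordinal"})
        return compute_correlation_matrix(specs)

    def test_symmetry_and_unit_diagonal(self):
        m = self._matrix()
        coef = m.coefficient_frame()
        assert np.allclose(coef.to_numpy(float), coef.to_numpy(float).T,
                           equal_nan=True)
        assert coef.loc["duration", "duration"] == 1.0
        assert math.isnan(coef.loc["gender", "gender"])  # binary self-pair

    def test_every_defined_coefficient_in_unit_interval(self):
        m = self._matrix()
        for r in m.results.values():
            if r.defined:
                assert -1.0 <= r.coefficient <= 1.0
            if math.isfinite(r.p_adjusted) and math.isfinite(r.p_raw):
                assert r.p_adjusted >= r.p_raw - 1e-15

    def test_methods_match_declared_kinds(self):
        m = self._matrix()
        assert m.get("gender", "score").method == "point_biserial"
        assert m.get("gender", "duration").method == "point_biserial"
        assert m.get("duration", "var_mean").method == "pearson"
        assert m.get("score", "duration").method == "spearman"

    def test_export_writes_csv_and_heatmap(self, tmp_path):
        m = self._matrix()
        written = annotate_and_export(m, tmp_path / "corr.csv",
                                      heatmap_path=tmp_path / "heat.png")
        table = pd.read_csv(written["csv"])
        assert set(table.columns) >= {"var_a", "var_b", "method", "coefficient",
                                      "p_raw", "p_adjusted", "stars"}
        assert written["heatmap"].stat().st_size > 0
        blank = m.annotation_frame().loc["gender", "gender"]
        assert blank == ""
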