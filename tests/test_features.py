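"""Feature-table parsing, coverage filtering, and metric scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spatiophylo.errors import DefinitionError, DegenerateInputError, IntegrityError
from spatiophylo.features import (
    FeatureMatrix,
    MetricDefinition,
    apply_coverage_filter,
    read_feature_table,
    score_metric,
    standardize,
)

from conftest import make_matrix

SINGLETONS = MetricDefinition.singleton("fusion", ["F1", "F2", "F3", "F4"])


class TestReadFeatureTable:
    def test_wide_csv_maps_states(self, tmp_path):
        p = tmp_path / "wide.csv"
        p.write_text("taxon,F1,F2,F3\na,1,0,?\nb,0,1,\n")
        m = read_feature_table(p, dialect="wide_csv")
        assert m.taxa == ["a", "b"]
        assert m.data.loc["a", "F1"] == 1.0
        assert m.data.loc["a", "F2"] == 0.0
        assert np.isnan(m.data.loc["a", "F3"])
        assert np.isnan(m.data.loc["b", "F3"])

    def test_long_equals_wide(self, tmp_path):
        wide = tmp_path / "wide.csv"
        wide.write_text("taxon,F1,F2\na,1,0\nb,?,1\n")
        long = tmp_path / "long.csv"
        long.write_text(
            "Language_ID,Parameter_ID,Value\n"
            "a,F1,1\na,F2,0\nb,F1,?\nb,F2,1\n"
        )
        mw = read_feature_table(wide, "wide_csv")
        ml = read_feature_table(long, "cldf_long")
        pd.testing.assert_frame_equal(
            mw.data.sort_index(), ml.data.sort_index(), check_names=False
        )

    def test_absent_long_rows_are_missing(self, tmp_path):
        long = tmp_path / "long.csv"
        long.write_text("Language_ID,Parameter_ID,Value\na,F1,1\nb,F2,0\n")
        m = read_feature_table(long, "cldf_long")
        assert np.isnan(m.data.loc["a", "F2"])

    def test_duplicate_pair_rejected(self, tmp_path):
        long = tmp_path / "dup.csv"
        long.write_text("Language_ID,Parameter_ID,Value\na,F1,1\na,F1,0\n")
        with pytest.raises(IntegrityError):
            read_feature_table(long, "cldf_long")

    def test_duplicate_taxon_row_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("taxon,F1\na,1\na,0\n")
        with pytest.raises(IntegrityError):
            read_feature_table(p, "wide_csv")

    def test_multistate_coerced_present(self, tmp_path):
        p = tmp_path / "multi.csv"
        p.write_text("taxon,F1\na,2\nb,0\n")
        m = read_feature_table(p, "wide_csv")
        assert m.data.loc["a", "F1"] == 1.0
        assert m.data.loc["b", "F1"] == 0.0


class TestCoverageFilter:
    def test_boundary_is_strict(self):
        # over the threshold removed; exactly at the threshold retained
        m = make_matrix(
            {
                "thirty": [1, 0, None, 1, 1, 1, None, 1, 0, None],  # 30%
                "quarter": [None, 1, 0, 1, None, 1, 0, 1, None, 0],  # 30% too
            },
            [f"F{i}" for i in range(10)],
        )
        assert apply_coverage_filter(m, 0.25).taxa == []
        m2 = make_matrix(
            {"at25": [None, 1, 1, 1], "at50": [None, None, 1, 1]},
            ["F1", "F2", "F3", "F4"],
        )
        kept = apply_coverage_filter(m2, max_missing=0.25)
        assert kept.taxa == ["at25"]  # 25% retained (strict "more than")

    def test_no_filter_identity(self, toy_matrix):
        assert apply_coverage_filter(toy_matrix, 1.0).taxa == toy_matrix.taxa

    def test_counts_all_features_not_only_metric_ones(self):
        # missingness outside the metric features still counts
        m = make_matrix(
            {"a": [1, None, None], "b": [1, 1, 1]}, ["F1", "X1", "X2"]
        )
        kept = apply_coverage_filter(m, 0.25)
        assert kept.taxa == ["b"]


class TestScoreMetric:
    @pytest.mark.parametrize(
        "values,expected,ngroups",
        [
            ([1, 0, 1, 1], 0.75, 4),
            ([1, 0, 1, None], 2 / 3, 3),
            ([1, 1, 1, 1], 1.0, 4),
            ([0, 0, 0, 0], 0.0, 4),
        ],
    )
    def test_singleton_groups(self, values, expected, ngroups):
        m = make_matrix({"t": values}, ["F1", "F2", "F3", "F4"])
        out = score_metric(m, SINGLETONS)
        assert out.loc[0, "raw_score"] == pytest.approx(expected)
        assert out.loc[0, "n_groups_coded"] == ngroups

    def test_or_rule_within_group(self):
        # fused and independent markers of one function count once
        defn = MetricDefinition("informativity", {"plural": ["fused", "indep"]})
        m = make_matrix({"t": [1, 0], "u": [0, 0], "v": [0, None]},
                        ["fused", "indep"])
        out = score_metric(m, defn).set_index("taxon")
        assert out.loc["t", "raw_score"] == 1.0
        assert out.loc["u", "raw_score"] == 0.0
        assert out.loc["v", "raw_score"] == 0.0

    def test_all_missing_taxon_dropped(self):
        m = make_matrix({"gone": [None, None], "here": [1, 0]}, ["F1", "F2"])
        out = score_metric(m, MetricDefinition.singleton("f", ["F1", "F2"]))
        assert list(out["taxon"]) == ["here"]

    def test_unknown_feature_rejected(self, toy_matrix):
        bad = MetricDefinition("f", {"g": ["NOPE"]})
        with pytest.raises(DefinitionError):
            score_metric(toy_matrix, bad)

    def test_order_invariance(self, toy_matrix):
        out1 = score_metric(toy_matrix, SINGLETONS).set_index("taxon")
        shuffled = FeatureMatrix(
            toy_matrix.data.iloc[::-1, ::-1]
        )
        out2 = score_metric(shuffled, SINGLETONS).set_index("taxon")
        pd.testing.assert_series_equal(
            out1["raw_score"].sort_index(), out2["raw_score"].sort_index()
        )

    def test_filter_score_commute(self, toy_matrix):
        a = score_metric(apply_coverage_filter(toy_matrix, 0.2), SINGLETONS)
        b = score_metric(toy_matrix, SINGLETONS)
        b = b[b["taxon"].isin(a["taxon"])].reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestMetricDefinition:
    def test_feature_in_two_groups_rejected(self):
        with pytest.raises(DefinitionError):
            MetricDefinition("m", {"g1": ["F1"], "g2": ["F1"]})

    def test_empty_group_rejected(self):
        with pytest.raises(DefinitionError):
            MetricDefinition("m", {"g1": []})

    def test_excluded_and_used_rejected(self):
        with pytest.raises(DefinitionError):
            MetricDefinition("m", {"g": ["F1"]}, excluded_features=["F1"])

    def test_bundled_toy_definitions_load(self):
        from spatiophylo.features import example_definition

        fusion = example_definition("fusion")
        info = example_definition("informativity")
        assert all(len(m) == 1 for m in fusion.groups.values())
        assert any(len(m) > 1 for m in info.groups.values())

    def test_json_roundtrip(self, tmp_path):
        p = tmp_path / "def.json"
        p.write_text(
            '{"name": "fusion", "groups": {"g1": ["F1"], "g2": ["F2"]},'
            ' "excluded_features": ["F9"]}'
        )
        d = MetricDefinition.from_json(p)
        assert d.name == "fusion" and d.groups["g2"] == ["F2"]


class TestStandardize:
    def test_known_values(self):
        s = pd.DataFrame({"taxon": list("abc"), "raw_score": [0.0, 0.5, 1.0]})
        out = standardize(s)
        assert out["z_score"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_rejected(self):
        s = pd.DataFrame({"taxon": list("ab"), "raw_score": [0.4, 0.4]})
        with pytest.raises(DegenerateInputError):
            standardize(s)

    def test_mean_zero_unit_variance(self, rng):
        s = pd.DataFrame(
            {"taxon": [str(i) for i in range(50)],
             "raw_score": rng.uniform(size=50)}
        )
        z = standardize(s)["z_score"]
        assert abs(z.mean()) < 1e-8
        assert abs(z.var(ddof=1) - 1.0) < 1e-8


@settings(max_examples=30, deadline=None)
@given(st.data())
def test_raw_scores_bounded(data):
    """Raw scores stay in [0, 1] for arbitrary binary/missing matrices."""
    n_taxa = data.draw(st.integers(2, 6))
    n_feat = data.draw(st.integers(1, 5))
    cells = data.draw(
        st.lists(
            st.sampled_from([0.0, 1.0, np.nan]),
            min_size=n_taxa * n_feat, max_size=n_taxa * n_feat,
        )
    )
    df = pd.DataFrame(
        np.array(cells).reshape(n_taxa, n_feat),
        index=[f"t{i}" for i in range(n_taxa)],
        columns=[f"F{j}" for j in range(n_feat)],
    )
    out = score_metric(
        FeatureMatrix(df),
        MetricDefinition.singleton("m", list(df.columns)),
    )
    assert ((out["raw_score"] >= 0) & (out["raw_score"] <= 1)).all()
    assert (out["n_groups_coded"] > 0).all()
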