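"""Correlation-cluster filtering and noise-benchmarked importance."""

import numpy as np
import pandas as pd
import pytest

from commstack import (CommunitySchema, CommunityTable, KeepPolicy, ModelSpec,
                       NOISE_FEATURE, build_model_frame,
                       grassland_feature_sets, noise_benchmark_importance,
                       select_features, spearman_cluster_filter)
from commstack.data import ModelFrame

from conftest import RF_SMALL


def table_with_features(columns: dict, species_counts: dict):
    species = tuple(species_counts)
    soil = tuple(columns)
    schema = CommunitySchema(species=species, soil_variables=soil)
    n = len(next(iter(columns.values())))
    df = pd.DataFrame({"plot": "P1", "subplot": [f"S{i}" for i in range(n)],
                       "year": 2015, "x": np.arange(n) % 10 * 1.0,
                       "y": np.arange(n) // 10 * 1.0})
    for name, vals in columns.items():
        df[name] = vals
    df["precipitation"] = 500.0
    for sp, vals in species_counts.items():
        df[sp] = vals
    return CommunityTable(df, schema)


class TestSpearmanClusterFilter:
    def test_default_survey_recovers_the_two_soil_clusters(self, default_table):
        table, _ = default_table
        report = spearman_cluster_filter(
            table, 0.7, KeepPolicy(prefer=("C", "salinity")))
        assert {"C", "organic_matter", "N", "cn_ratio"} in report.clusters
        assert {"salinity", "Na", "Cl", "K"} in report.clusters
        assert "C" in report.kept and "salinity" in report.kept
        for dropped in ["organic_matter", "N", "cn_ratio", "Na", "Cl", "K"]:
            assert report.dropped[dropped] == "correlation-cluster"

    def test_identical_columns_drop_exactly_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        table = table_with_features(
            {"a": x, "b": x.copy(), "c": rng.normal(size=60)},
            {"HOMA": rng.poisson(3, 60)})
        report = spearman_cluster_filter(table, 0.95)
        assert sorted(report.clusters[0]) == ["a", "b"]
        assert len(report.dropped) == 1

    def test_uncorrelated_features_all_kept(self):
        rng = np.random.default_rng(1)
        table = table_with_features(
            {k: rng.normal(size=80) for k in "abcd"},
            {"HOMA": rng.poisson(3, 80)})
        report = spearman_cluster_filter(table, 0.7)
        assert report.dropped == {}
        assert set(report.kept) == {"a", "b", "c", "d", "precipitation"}

    def test_constant_feature_flagged_and_kept(self):
        rng = np.random.default_rng(2)
        table = table_with_features(
            {"a": rng.normal(size=50), "flat": np.zeros(50)},
            {"HOMA": rng.poisson(3, 50)})
        report = spearman_cluster_filter(table, 0.7)
        assert "flat" in report.constant
        assert "flat" in report.kept

    def test_threshold_must_be_in_unit_interval(self, small_table):
        with pytest.raises(ValueError):
            spearman_cluster_filter(small_table[0], 1.5)


class TestNoiseBenchmark:
    def test_null_target_keeps_every_feature_near_noise(self):
        rng = np.random.default_rng(3)
        table = table_with_features(
            {k: rng.normal(size=120) for k in "abc"},
            {"HOMA": rng.poisson(3, 120), "LEMA": rng.poisson(3, 120)})
        frame = build_model_frame(table, ["a", "b", "c"],
                                  include_competitors=False)
        imp = noise_benchmark_importance(frame, RF_SMALL, seed=3)
        noise = imp.set_index("feature").loc[NOISE_FEATURE]
        for _, row in imp.iterrows():
            assert row["importance"] <= noise["importance"] \
                + 2 * (noise["se"] + row["se"]) + 0.05

    def test_strong_predictor_ranks_first_above_noise(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=300)
        counts = rng.poisson(np.exp(2 + 1.2 * x))
        table = table_with_features(
            {"driver": x, "bystander": rng.normal(size=300)},
            {"HOMA": counts})
        frame = build_model_frame(table, ["driver", "bystander"],
                                  include_competitors=False)
        imp = noise_benchmark_importance(frame, RF_SMALL, seed=4)
        assert imp.iloc[0]["feature"] == "driver"
        noise_val = imp.set_index("feature").loc[NOISE_FEATURE, "importance"]
        assert imp.iloc[0]["importance"] > noise_val

    def test_survey_ordering_matches_the_known_drivers(self, default_table):
        # precipitation is the dominant abiotic driver; the causally inert
        # soil variables (pH, Ca, Mg) rank far below the true drivers
        table, _ = default_table
        report = spearman_cluster_filter(
            table, 0.7, KeepPolicy(prefer=("C", "salinity")))
        frame = build_model_frame(table, report.kept,
                                  include_competitors=False)
        imp = noise_benchmark_importance(
            frame, ModelSpec("rf", n_estimators=60, max_samples=0.4,
                             max_features=1.0), seed=1)
        vals = dict(zip(imp["feature"], imp["importance"]))
        abiotic = {f: v for f, v in vals.items()
                   if f not in ("species", NOISE_FEATURE)}
        assert max(abiotic, key=abiotic.get) == "precipitation"
        # the causally inert soil variables never rival the strong drivers
        for null_feature in ["pH", "Ca", "Mg"]:
            for driver in ["precipitation", "salinity"]:
                assert vals[null_feature] < vals[driver]
        assert vals[NOISE_FEATURE] < min(vals["precipitation"],
                                         vals["salinity"])

    def test_single_row_frame_rejected(self):
        schema = CommunitySchema(species=("HOMA",))
        df = pd.DataFrame([{"plot": "P1", "subplot": "S1", "year": 2015,
                            "x": 0.0, "y": 0.0, "precipitation": 500.0,
                            **{v: 1.0 for v in schema.soil_variables},
                            "HOMA": 3}])
        frame = build_model_frame(CommunityTable(df, schema),
                                  include_competitors=False)
        with pytest.raises(ValueError, match="insufficient data"):
            noise_benchmark_importance(frame, RF_SMALL, seed=0)


class TestSelectFeatures:
    def _report(self):
        from commstack.features import SelectionReport
        candidates = ("a", "b", "c", "d")
        report = SelectionReport(candidates=candidates, kept=list(candidates))
        report.importance = pd.DataFrame({
            "feature": ["a", "b", NOISE_FEATURE, "c", "d"],
            "importance": [0.5, 0.2, 0.05, 0.01, -0.02],
            "se": [0.01] * 5})
        return report

    def test_below_noise_features_dropped(self):
        report = self._report()
        kept = select_features(report, drop_below_noise=True)
        assert kept == ["a", "b"]
        assert report.dropped == {"c": "below-noise", "d": "below-noise"}

    def test_manual_keep_overrides_below_noise(self):
        kept = select_features(self._report(), drop_below_noise=True,
                               manual_keep=("c",))
        assert kept == ["a", "b", "c"]

    def test_manual_drop_always_applies(self):
        kept = select_features(self._report(), manual_drop=("b",))
        assert kept == ["a", "c", "d"]

    def test_no_rules_is_identity(self):
        report = self._report()
        assert select_features(report) == list(report.candidates)

    def test_noise_feature_never_survives(self):
        report = self._report()
        report.kept = list(report.candidates) + [NOISE_FEATURE]
        report.candidates = tuple(report.kept)
        assert NOISE_FEATURE not in select_features(report, drop_below_noise=True)

    def test_unknown_override_rejected(self):
        with pytest.raises(ValueError, match="unknown feature"):
            select_features(self._report(), manual_drop=("zinc",))


class TestGrasslandSelection:
    def test_abiotic_model_keeps_exactly_six_features(self):
        sets = grassland_feature_sets()
        assert len(sets["abiotic"]) == 6
        assert set(sets["abiotic"]) == {"salinity", "carbonates", "C", "P",
                                        "Ca", "precipitation"}

    def test_full_model_keeps_eight_features(self):
        sets = grassland_feature_sets()
        assert len(sets["full"]) == 8
        assert set(sets["full"]) - set(sets["abiotic"]) == {"pH", "Mg"}

    def test_duplicated_column_does_not_enlarge_the_retained_set(self, small_table):
        table, _ = small_table
        base = spearman_cluster_filter(table, 0.99)
        dup = table.data.copy()
        dup["salinity_copy"] = dup["salinity"]
        schema = CommunitySchema(species=table.schema.species,
                                 soil_variables=table.schema.soil_variables
                                 + ("salinity_copy",))
        dup_report = spearman_cluster_filter(CommunityTable(dup, schema), 0.99)
        assert len(dup_report.kept) <= len(base.kept) + 1
        assert ("salinity_copy" in dup_report.dropped
                or "salinity" in dup_report.dropped)
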