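"""Metrics, fold schemes, evaluation loops, and Moran's I."""

import numpy as np
import pandas as pd
import pytest

from commstack import (AbundancePipeline, MetricsRecord, ModelSpec,
                       leave_one_year_out_eval, morans_i, per_species_metrics,
                       r_squared, random_kfold, repeated_random_split_eval,
                       rmse, spatial_block_kfold, spatial_cv_eval)
from commstack import generate_dataset

from conftest import small_config


class TestMetricOracles:
    def test_rmse_hand_examples(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
        assert rmse([0, 0, 3], [0, 0, 0]) == pytest.approx(np.sqrt(3))

    def test_r_squared_hand_examples(self):
        y = [1.0, 2.0, 3.0]
        assert r_squared(y, y) == pytest.approx(1.0)
        assert r_squared(y, [2.0, 2.0, 2.0]) == pytest.approx(0.0)
        assert r_squared(y, [1.0, 2.0, 5.0]) == pytest.approx(-1.0)

    def test_brute_force_equivalence_on_random_pairs(self):
        # independent arithmetic oracle, elementwise loops
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(2, 30)
            y = rng.normal(size=n)
            yhat = rng.normal(size=n)
            if np.allclose(y, y[0]):
                continue
            se = [(a - b) ** 2 for a, b in zip(y, yhat)]
            oracle_rmse = (sum(se) / n) ** 0.5
            ybar = sum(y) / n
            oracle_r2 = 1 - sum(se) / sum((a - ybar) ** 2 for a in y)
            assert abs(rmse(y, yhat) - oracle_rmse) < 1e-12
            assert abs(r_squared(y, yhat) - oracle_r2) < 1e-12

    def test_rmse_is_symmetric(self):
        rng = np.random.default_rng(1)
        y, yhat = rng.normal(size=20), rng.normal(size=20)
        assert rmse(y, yhat) == rmse(yhat, y)

    def test_error_conditions(self):
        with pytest.raises(ValueError, match="mismatch"):
            rmse([1, 2], [1])
        with pytest.raises(ValueError, match="empty"):
            rmse([], [])
        with pytest.raises(ValueError, match="zero-variance"):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_rse_is_one_minus_r2(self):
        rec = MetricsRecord(rmse=1.0, r2=0.37, n=10)
        assert rec.rse == 1.0 - 0.37
        flagged = MetricsRecord(rmse=1.0, r2=None, n=2, flagged=True)
        assert flagged.rse is None


class TestFoldAssignment:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("scheme", ["spatial", "random"])
    def test_folds_partition_the_subplots(self, scheme, seed):
        table, _ = generate_dataset(small_config(), seed=seed)
        if scheme == "spatial":
            fa = spatial_block_kfold(table.data, k=4, block=(2.0, 2.0),
                                     seed=seed)
        else:
            fa = random_kfold(table.data, k=4, seed=seed)
        sub = table.data[["plot", "subplot"]].drop_duplicates()
        keys = set(zip(sub["plot"], sub["subplot"]))
        assert set(fa.mapping) == keys                  # complete
        assert set(fa.mapping.values()) == set(range(4))

    def test_default_survey_blocks_enumerate_as_expected(self, default_table):
        # 9 plots x four 3x3 blocks of 9 subplots -> 36 blocks, k=4 folds
        # of 9 blocks = 81 subplots each
        table, _ = default_table
        fa = spatial_block_kfold(table.data, k=4, seed=0)
        counts = pd.Series(list(fa.mapping.values())).value_counts()
        assert sorted(counts) == [81, 81, 81, 81]

    def test_years_of_a_subplot_share_the_fold(self, default_table):
        table, _ = default_table
        fa = spatial_block_kfold(table.data, k=4, seed=3)
        folds = fa.fold_of(table.data)
        df = table.data.assign(fold=folds)
        assert (df.groupby(["plot", "subplot"])["fold"].nunique() == 1).all()

    def test_too_few_blocks_rejected(self):
        table, _ = generate_dataset(small_config(n_plots=1), seed=0)
        with pytest.raises(ValueError, match="blocks"):
            spatial_block_kfold(table.data, k=5, block=(4.0, 4.0))


def linear_factory(seed):
    return AbundancePipeline(kind="abiotic", spec=ModelSpec("linear")).reseed(seed)


class TestEvaluationLoops:
    def test_repeated_split_is_deterministic(self):
        table, _ = generate_dataset(small_config(), seed=2)
        d1 = repeated_random_split_eval(table, linear_factory, n_runs=2, seed=9)
        d2 = repeated_random_split_eval(table, linear_factory, n_runs=2, seed=9)
        assert [r.r2 for r in d1.records] == [r.r2 for r in d2.records]
        assert [r.rmse for r in d1.records] == [r.rmse for r in d2.records]

    def test_median_summaries_recompute_from_members(self):
        table, _ = generate_dataset(small_config(), seed=2)
        dist = repeated_random_split_eval(table, linear_factory, n_runs=5,
                                          seed=1)
        assert dist.median_r2 == np.median([r.r2 for r in dist.records])
        assert dist.median_rmse == np.median([r.rmse for r in dist.records])

    def test_degenerate_split_fractions_rejected(self):
        table, _ = generate_dataset(small_config(), seed=2)
        with pytest.raises(ValueError):
            repeated_random_split_eval(table, linear_factory, n_runs=0)
        with pytest.raises(ValueError):
            repeated_random_split_eval(table, linear_factory, n_runs=1,
                                       test_fraction=1e-9)

    def test_leave_one_year_out_produces_one_record_per_year(self):
        table, _ = generate_dataset(small_config(), seed=2)
        dist = leave_one_year_out_eval(table, linear_factory)
        assert sorted(r.year for r in dist.records) == [2015, 2016, 2017]

    def test_loyo_training_includes_later_years(self):
        table, _ = generate_dataset(small_config(), seed=2)
        seen = {}

        class Probe:
            def __init__(self, year):
                self.year = year

            def fit(self, t):
                seen[self.year] = set(t.years)
                self._t = t
                return self

            def predict_table(self, t):
                out = t.data.melt(id_vars=["plot", "subplot", "year"],
                                  value_vars=list(t.species),
                                  var_name="species", value_name="observed")
                out["predicted"] = out["observed"] * 0.9 + 0.1
                return out

        years = iter(sorted(table.years))
        leave_one_year_out_eval(table, lambda s: Probe(next(years)))
        assert seen[2015] == {2016, 2017}       # later years train for 2015
        assert seen[2016] == {2015, 2017}

    def test_single_year_table_rejected(self):
        cfg = small_config(years=(2015,), precipitation=(500.0,))
        table, _ = generate_dataset(cfg, seed=2)
        with pytest.raises(ValueError, match="years"):
            leave_one_year_out_eval(table, linear_factory)

    def test_spatial_cv_scores_every_fold(self):
        table, _ = generate_dataset(small_config(), seed=2)
        dist = spatial_cv_eval(table, linear_factory, k=4, block=(2.0, 2.0))
        assert len(dist.records) == 4


class TestPerSpeciesMetrics:
    def test_single_species_reduces_to_global(self):
        y = [0.0, 1.0, 4.0, 2.0]
        yhat = [0.5, 1.0, 3.0, 2.0]
        recs = per_species_metrics(y, yhat, ["HOMA"] * 4)
        assert len(recs) == 1
        assert recs[0].rmse == pytest.approx(rmse(y, yhat))
        assert recs[0].r2 == pytest.approx(r_squared(y, yhat))

    def test_zero_variance_species_flagged_not_scored(self):
        recs = per_species_metrics([0, 0, 1, 2], [0.1, 0.2, 1.0, 2.0],
                                   ["A_ZERO", "A_ZERO", "B", "B"])
        by = {r.species: r for r in recs}
        assert by["A_ZERO"].flagged and by["A_ZERO"].r2 is None
        assert not by["B"].flagged


class TestMoransI:
    def test_iid_values_have_expectation_near_minus_one_over_n(self):
        rng = np.random.default_rng(0)
        xy = np.array([(i, j) for i in range(6) for j in range(6)], float)
        vals = [morans_i(rng.normal(size=36), xy) for _ in range(200)]
        assert np.mean(vals) == pytest.approx(-1 / 35, abs=0.02)

    def test_checkerboard_is_negatively_autocorrelated_under_rook(self):
        xy = np.array([(i, j) for i in range(4) for j in range(4)], float)
        z = np.array([(i + j) % 2 for i, j in xy], float)
        assert morans_i(z, xy, scheme="rook") < -0.9

    def test_smooth_gradient_is_positively_autocorrelated(self):
        xy = np.array([(i, j) for i in range(6) for j in range(6)], float)
        z = xy[:, 0] + 0.01 * xy[:, 1]
        assert morans_i(z, xy, scheme="rook") > 0.5

    def test_error_conditions(self):
        xy = np.array([(0, 0), (1, 0), (0, 1)], float)
        with pytest.raises(ValueError, match="zero-variance"):
            morans_i([1.0, 1.0, 1.0], xy)
        with pytest.raises(ValueError, match="3 sites"):
            morans_i([1.0, 2.0], xy[:2])
        with pytest.raises(ValueError, match="scheme"):
            morans_i([1.0, 2.0, 3.0], xy, scheme="queen")


class TestMetricProperties:
    from hypothesis import given, settings, strategies as st

    vectors = st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=50)

    @given(y=vectors, shift=st.floats(-100, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rmse_of_a_constant_shift_is_its_magnitude(self, y, shift):
        y = np.asarray(y)
        assert rmse(y, y + shift) == pytest.approx(abs(shift), abs=1e-6)

    @given(y=vectors)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_r_squared_is_one_iff_perfect(self, y):
        y = np.asarray(y)
        if np.all(y == y[0]):
            return
        assert r_squared(y, y) == pytest.approx(1.0)

    @given(y=vectors, scale=st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_r_squared_is_invariant_to_affine_rescaling(self, y, scale):
        y = np.asarray(y)
        if np.std(y) < 1e-3:
            return                      # numerically near-constant target
        yhat = y[::-1].copy()
        a = r_squared(y, yhat)
        b = r_squared(scale * y + 3.0, scale * yhat + 3.0)
        assert b == pytest.approx(a, abs=1e-4, rel=1e-4)
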