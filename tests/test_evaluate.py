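import itertools

import numpy as np
import pandas as pd
import pytest

from thermovine.evaluate import (
    kfold_indices,
    make_global_dataset,
    r2_cod,
    r2_pearson,
    rmse,
    run_protocol,
    slope_equality_test,
    stratified_split,
)
from thermovine.forest import RotationForestParams


def synthetic_records(n_dates=7, treatments=("T0", "T1", "T2"), n_blocks=4,
                      sides=("east",), vines=3, seed=0, noise=0.15):
    """Feature-table-shaped records with a linear psi/cwsi link."""
    rng = np.random.default_rng(seed)
    rows = []
    for d, t, b, s, v in itertools.product(
        range(n_dates), treatments, range(n_blocks), sides, range(vines)
    ):
        c = rng.uniform(0, 1)
        rows.append(
            {
                "date_index": d, "treatment": t, "block": b, "side": s, "vine": v,
                "air_temp": rng.normal(28, 2),
                "t_canopy_mean": 20 + 10 * c,
                "t_canopy_median": 20 + 10 * c + rng.normal(0, 0.1),
                "t_canopy_sd": abs(rng.normal(1, 0.2)),
                "cwsi": c,
                "ig": (1 - c) / max(c, 1e-6),
                "psi_stem": -0.4 - 1.65 * c + rng.normal(0, noise),
            }
        )
    return pd.DataFrame(rows)


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert r2_pearson(y, y) == pytest.approx(1.0)
        assert r2_cod(y, y) == pytest.approx(1.0)
        assert rmse(y, y) == 0.0

    def test_rmse_brute_force(self):
        rng = np.random.default_rng(0)
        o, p = rng.normal(size=50), rng.normal(size=50)
        assert rmse(o, p) == pytest.approx(np.sqrt(np.mean((o - p) ** 2)))

    def test_r2_pearson_in_unit_interval(self):
        rng = np.random.default_rng(1)
        o, p = rng.normal(size=50), rng.normal(size=50)
        assert 0.0 <= r2_pearson(o, p) <= 1.0

    def test_r2_zero_variance(self):
        assert r2_pearson(np.ones(5), np.arange(5.0)) == 0.0


class TestGlobalDataset:
    def test_default_design_counts(self):
        east = synthetic_records(sides=("east",), seed=1)
        west = synthetic_records(sides=("west",), seed=2)
        out = make_global_dataset(east, west, seed=0)
        assert len(out) == 252
        assert (out["side"] == "east").sum() == 126
        assert (out["side"] == "west").sum() == 126

    def test_per_cell_balance(self):
        east = synthetic_records(sides=("east",), seed=1)
        west = synthetic_records(sides=("west",), seed=2)
        out = make_global_dataset(east, west, seed=0)
        counts = out.groupby(["side", "treatment", "date_index"]).size()
        assert set(counts) == {6}  # 126 / (3 treatments x 7 dates)

    def test_identical_sides_give_half_each(self):
        east = synthetic_records(sides=("east",), seed=3)
        west = east.assign(side="west")
        out = make_global_dataset(east, west, seed=0)
        assert len(out) == len(east)

    def test_unbalanceable_cell_rejected(self):
        east = synthetic_records(n_dates=2, n_blocks=2, sides=("east",))
        west = synthetic_records(n_dates=3, n_blocks=2, sides=("west",))
        with pytest.raises(ValueError):
            make_global_dataset(east, west.iloc[:35], seed=0)

    def test_seed_determinism(self):
        east = synthetic_records(sides=("east",), seed=1)
        west = synthetic_records(sides=("west",), seed=2)
        a = make_global_dataset(east, west, seed=7)
        b = make_global_dataset(east, west, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestStratifiedSplit:
    def test_printed_counts_at_252(self):
        records = synthetic_records()
        split = stratified_split(records, 0.80, seed=0)
        assert split.n_train == 200
        assert split.n_test == 50
        assert len(split.dropped_indices) == 2

    def test_disjoint(self):
        records = synthetic_records()
        split = stratified_split(records, 0.80, seed=1)
        assert not set(split.train_indices) & set(split.test_indices)
        assert not set(split.train_indices) & set(split.dropped_indices)

    @pytest.mark.parametrize("seed", range(20))
    def test_extremes_in_test_set(self, seed):
        records = synthetic_records(seed=seed)
        split = stratified_split(records, 0.80, seed=seed)
        psi = records["psi_stem"].to_numpy()
        kept = np.concatenate([split.train_indices, split.test_indices])
        test_psi = psi[split.test_indices]
        assert test_psi.min() == psi[kept].min()
        assert test_psi.max() == psi[kept].max()

    def test_per_date_balance(self):
        records = synthetic_records()
        split = stratified_split(records, 0.80, seed=2)
        counts = records.iloc[split.test_indices].groupby("date_index").size()
        assert counts.max() - counts.min() <= 1

    def test_degenerate_ratio_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(synthetic_records(), 1.0, seed=0)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(synthetic_records().head(5), 0.8, seed=0)

    def test_determinism(self):
        records = synthetic_records()
        a = stratified_split(records, 0.80, seed=5)
        b = stratified_split(records, 0.80, seed=5)
        np.testing.assert_array_equal(a.test_indices, b.test_indices)
        np.testing.assert_array_equal(a.train_indices, b.train_indices)


class TestKFold:
    def test_partition(self):
        rng = np.random.default_rng(0)
        folds = kfold_indices(53, 10, rng)
        assert len(folds) == 10
        merged = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(merged, np.arange(53))

    def test_bad_k(self):
        with pytest.raises(ValueError):
            kfold_indices(5, 10, np.random.default_rng(0))


class TestRunProtocol:
    def test_report_shape_and_quality(self):
        records = synthetic_records(noise=0.1)
        split = stratified_split(records, 0.80, seed=0)
        report, preds = run_protocol(
            records, split, RotationForestParams(), "with_refs", seed=0, side="east"
        )
        assert report.n_train == 200 and report.n_test == 50
        assert report.r2_calibration > report.r2_cv - 0.05
        assert 0 <= report.r2_cv <= 1
        assert report.rmse_cv >= 0
        assert set(preds["stage"]) == {"calibration", "cross_validation", "prediction"}

    def test_prediction_rmse_matches_brute_force(self):
        records = synthetic_records(noise=0.1)
        split = stratified_split(records, 0.80, seed=3)
        report, preds = run_protocol(
            records, split, RotationForestParams(), "with_refs", seed=3
        )
        stage = preds[preds["stage"] == "prediction"]
        brute = np.sqrt(np.mean((stage["observed"] - stage["predicted"]) ** 2))
        assert report.rmse_prediction == pytest.approx(brute)

    def test_without_refs_uses_four_features(self):
        records = synthetic_records(noise=0.1).drop(columns=["cwsi", "ig"])
        split = stratified_split(records, 0.80, seed=1)
        report, _ = run_protocol(
            records, split, RotationForestParams(), "without_refs", seed=1
        )
        assert 0 <= report.r2_cv <= 1

    def test_missing_features_rejected(self):
        records = synthetic_records().drop(columns=["cwsi"])
        split = stratified_split(records, 0.80, seed=0)
        with pytest.raises(ValueError, match="cwsi"):
            run_protocol(records, split, RotationForestParams(), "with_refs", seed=0)

    def test_tiny_folds_rejected(self):
        records = synthetic_records(n_dates=2, n_blocks=1, vines=3)
        split = stratified_split(records, 0.80, seed=0)
        with pytest.raises(ValueError, match="fold"):
            run_protocol(
                records, split, RotationForestParams(), "with_refs", cv_folds=10, seed=0
            )

    def test_ablation_direction(self):
        # all signal rides on cwsi: with_refs should not trail without_refs badly
        records = synthetic_records(noise=0.1, seed=4)
        flat = records.assign(
            t_canopy_mean=np.random.default_rng(0).normal(25, 0.1, len(records)),
            t_canopy_median=np.random.default_rng(1).normal(25, 0.1, len(records)),
        )
        split = stratified_split(flat, 0.80, seed=4)
        with_r, _ = run_protocol(flat, split, RotationForestParams(), "with_refs", seed=4)
        without_r, _ = run_protocol(
            flat, split, RotationForestParams(), "without_refs", seed=4
        )
        assert with_r.r2_cv >= without_r.r2_cv - 0.05


class TestSlopeEquality:
    def test_identical_groups(self):
        rng = np.random.default_rng(0)
        pred = rng.normal(size=30)
        obs = pred + rng.normal(0, 0.3, 30)
        t, p = slope_equality_test(pred, obs, pred, obs)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_type_i_error_quick(self):
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            xa, xb = rng.normal(size=30), rng.normal(size=30)
            ya = 0.5 + 1.0 * xa + rng.normal(0, 0.5, 30)
            yb = 0.5 + 1.0 * xb + rng.normal(0, 0.5, 30)
            _, p = slope_equality_test(xa, ya, xb, yb)
            rejections += p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02)

    def test_power_on_different_slopes(self):
        rng = np.random.default_rng(1)
        xa, xb = rng.uniform(0, 1, 50), rng.uniform(0, 1, 50)
        ya = 1.0 * xa + rng.normal(0, 0.02, 50)
        yb = 0.5 * xb + rng.normal(0, 0.02, 50)
        _, p = slope_equality_test(xa, ya, xb, yb)
        assert p < 0.001

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            slope_equality_test([1, 2], [1, 2], [1, 2, 3], [1, 2, 3])

    def test_zero_predictor_variance(self):
        with pytest.raises(ValueError):
            slope_equality_test([1, 1, 1], [1, 2, 3], [1, 2, 3], [1, 2, 3])
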