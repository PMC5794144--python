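"""Model-development protocol: balanced global dataset, range- and
date-stratified 80/20 split, calibration / k-fold cross-validation / external
prediction, R2 and RMSE, and a slope-equality t-test between two
observed-vs-predicted regressions.

Primary R2 is the squared Pearson correlation between observed and predicted
(matching regression-plot presentation); the coefficient-of-determination
variant is also reported for transparency (``r2cd_*`` fields).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from thermovine._rng import substream
from thermovine.geometry import round_half_away
from thermovine.thermal import FEATURES_WITH_REFS, FEATURES_WITHOUT_REFS, KEY_COLUMNS
from thermovine.forest import RotationForestParams, fit_rotation_forest

__all__ = [
    "SplitPlan",
    "EvaluationReport",
    "r2_pearson",
    "r2_cod",
    "rmse",
    "feature_columns",
    "make_global_dataset",
    "stratified_split",
    "kfold_indices",
    "run_protocol",
    "slope_equality_test",
]

logger = logging.getLogger(__name__)


def r2_pearson(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Squared Pearson correlation; 0 if either side has zero variance."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.std() == 0 or predicted.std() == 0:
        return 0.0
    return float(np.corrcoef(observed, predicted)[0, 1] ** 2)


def r2_cod(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination 1 - SSE/SST (can be negative)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    sst = float(((observed - observed.mean()) ** 2).sum())
    if sst == 0:
        return 0.0
    sse = float(((observed - predicted) ** 2).sum())
    return 1.0 - sse / sst


def rmse(observed: np.ndarray, predicted: np.ndarray) -> float:
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def feature_columns(feature_set: str) -> list[str]:
    if feature_set == "with_refs":
        return list(FEATURES_WITH_REFS)
    if feature_set == "without_refs":
        return list(FEATURES_WITHOUT_REFS)
    raise ValueError("feature_set must be 'with_refs' or 'without_refs'")


@dataclass
class SplitPlan:
    train_indices: np.ndarray
    test_indices: np.ndarray
    dropped_indices: np.ndarray
    ratio: float
    test_quota_by_date: dict[int, int] = field(default_factory=dict)

    @property
    def n_train(self) -> int:
        return len(self.train_indices)

    @property
    def n_test(self) -> int:
        return len(self.test_indices)


@dataclass
class EvaluationReport:
    side: str
    feature_set: str
    n_train: int
    n_test: int
    r2_calibration: float
    rmse_calibration: float
    r2_cv: float
    rmse_cv: float
    r2_prediction: float
    rmse_prediction: float
    r2cd_calibration: float
    r2cd_cv: float
    r2cd_prediction: float

    def to_dict(self) -> dict:
        return asdict(self)


def make_global_dataset(
    east: pd.DataFrame, west: pd.DataFrame, seed: int | None = None
) -> pd.DataFrame:
    """Balanced pooled dataset: half of each side, equal counts per
    (side, treatment, date) cell, pseudorandom within-cell selection."""
    rng = substream(0 if seed is None else seed, "global_dataset")
    parts = []
    for side_df in (east, west):
        n_take_total = len(side_df) // 2
        cells = side_df.groupby(["treatment", "date_index"], sort=True)
        n_cells = cells.ngroups
        per_cell, rem = divmod(n_take_total, n_cells)
        if rem:
            raise ValueError(
                f"cannot balance {n_take_total} samples over {n_cells} cells"
            )
        for key, cell in cells:
            if len(cell) < per_cell:
                raise ValueError(f"cell {key} has {len(cell)} < {per_cell} samples")
            take = rng.choice(len(cell), size=per_cell, replace=False)
            parts.append(cell.iloc[np.sort(take)])
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(KEY_COLUMNS, ignore_index=True)


def stratified_split(
    records: pd.DataFrame, ratio: float = 0.80, seed: int | None = None
) -> SplitPlan:
    """Range- and date-stratified split.

    Test size is round((1-ratio) * n); train size is matched to the target
    ratio against that test size and any leftover rows are excluded from both
    sets at random (252 rows -> 200 train / 50 test / 2 dropped). The global
    minimum and maximum psi_stem are forced into the test set and the
    remaining slots are filled with even per-date quotas, seeded.
    """
    n = len(records)
    if n < 10:
        raise ValueError("need at least 10 records to split")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    rng = substream(0 if seed is None else seed, "split")

    n_test = round_half_away((1.0 - ratio) * n)
    if n_test < 2:
        raise ValueError("split leaves fewer than 2 test records")
    n_train = min(n - n_test, round_half_away(n_test * ratio / (1.0 - ratio)))
    n_drop = n - n_test - n_train

    positions = np.arange(n)
    dropped = np.array([], dtype=int)
    if n_drop > 0:
        dropped = np.sort(rng.choice(positions, size=n_drop, replace=False))
        logger.info("excluding %d leftover records from both sets: %s", n_drop, dropped)
    kept = np.setdiff1d(positions, dropped)

    psi = records["psi_stem"].to_numpy(dtype=float)
    dates = records["date_index"].to_numpy()
    date_values = np.unique(dates[kept])
    if len(date_values) > n_test:
        raise ValueError("more dates than test slots")

    base, rem = divmod(n_test, len(date_values))
    order = rng.permutation(len(date_values))
    quotas = {int(date_values[j]): base for j in range(len(date_values))}
    for j in order[:rem]:
        quotas[int(date_values[j])] += 1

    # force global extremes (among kept rows) into the test set
    kept_psi = psi[kept]
    forced = {int(kept[np.argmin(kept_psi)]), int(kept[np.argmax(kept_psi)])}
    test: list[int] = []
    remaining = dict(quotas)
    for i in sorted(forced):
        d = int(dates[i])
        if remaining.get(d, 0) <= 0:
            raise ValueError(f"date {d} has no test quota left for a forced extreme")
        remaining[d] -= 1
        test.append(i)

    for d in sorted(remaining):
        pool = np.array([i for i in kept if int(dates[i]) == d and i not in forced])
        if len(pool) - remaining[d] < 0:
            raise ValueError(f"date {d} has fewer records than its test quota")
        pick = rng.choice(pool, size=remaining[d], replace=False)
        test.extend(int(i) for i in pick)

    test_arr = np.sort(np.array(test, dtype=int))
    train_arr = np.setdiff1d(kept, test_arr)
    return SplitPlan(
        train_indices=train_arr,
        test_indices=test_arr,
        dropped_indices=dropped,
        ratio=ratio,
        test_quota_by_date=quotas,
    )


def kfold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Seeded random partition of range(n) into k near-equal folds."""
    if k < 2 or k > n:
        raise ValueError("need 2 <= k <= n")
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def run_protocol(
    records: pd.DataFrame,
    split: SplitPlan,
    forest_params: RotationForestParams,
    feature_set: str = "with_refs",
    cv_folds: int = 10,
    seed: int | None = None,
    side: str = "all",
) -> tuple[EvaluationReport, pd.DataFrame]:
    """Calibration, k-fold cross-validation on the train set, and external
    prediction on the test set. Returns the report and a per-sample
    predictions table (columns: stage, row, observed, predicted)."""
    cols = feature_columns(feature_set)
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise ValueError(f"records lack feature columns {missing}")
    master = 0 if seed is None else seed

    X = records[cols]
    y = records["psi_stem"].to_numpy(dtype=float)
    tr, te = split.train_indices, split.test_indices
    X_train, y_train = X.iloc[tr], y[tr]
    X_test, y_test = X.iloc[te], y[te]

    if len(y_train) // cv_folds < 2:
        raise ValueError("cross-validation folds would have fewer than 2 samples")

    def with_seed(s: int) -> RotationForestParams:
        return RotationForestParams(
            n_trees=forest_params.n_trees,
            feature_subset_size=forest_params.feature_subset_size,
            bootstrap_fraction=forest_params.bootstrap_fraction,
            tree_params=forest_params.tree_params,
            rotation=forest_params.rotation,
            seed=s,
        )

    # calibration model is also the external-prediction model
    from thermovine._rng import substream_seed

    model = fit_rotation_forest(X_train, y_train, with_seed(substream_seed(master, "fit")))
    pred_cal = model.predict(X_train)
    pred_test = model.predict(X_test)

    folds = kfold_indices(len(y_train), cv_folds, substream(master, "cv_folds"))
    pred_cv = np.empty(len(y_train))
    for f, fold in enumerate(folds):
        rest = np.setdiff1d(np.arange(len(y_train)), fold)
        m = fit_rotation_forest(
            X_train.iloc[rest], y_train[rest], with_seed(substream_seed(master, "cv_fit", f))
        )
        pred_cv[fold] = m.predict(X_train.iloc[fold])

    report = EvaluationReport(
        side=side,
        feature_set=feature_set,
        n_train=len(y_train),
        n_test=len(y_test),
        r2_calibration=r2_pearson(y_train, pred_cal),
        rmse_calibration=rmse(y_train, pred_cal),
        r2_cv=r2_pearson(y_train, pred_cv),
        rmse_cv=rmse(y_train, pred_cv),
        r2_prediction=r2_pearson(y_test, pred_test),
        rmse_prediction=rmse(y_test, pred_test),
        r2cd_calibration=r2_cod(y_train, pred_cal),
        r2cd_cv=r2_cod(y_train, pred_cv),
        r2cd_prediction=r2_cod(y_test, pred_test),
    )
    predictions = pd.concat(
        [
            pd.DataFrame({"stage": "calibration", "row": tr, "observed": y_train, "predicted": pred_cal}),
            pd.DataFrame({"stage": "cross_validation", "row": tr, "observed": y_train, "predicted": pred_cv}),
            pd.DataFrame({"stage": "prediction", "row": te, "observed": y_test, "predicted": pred_test}),
        ],
        ignore_index=True,
    )
    return report, predictions


def slope_equality_test(
    predicted_a: np.ndarray,
    observed_a: np.ndarray,
    predicted_b: np.ndarray,
    observed_b: np.ndarray,
) -> tuple[float, float]:
    """Two-sided t-test for equality of observed-vs-predicted slopes.

    Fits per-group least-squares lines of observed on predicted;
    t = (b1 - b2) / SE with pooled residual variance and n1 + n2 - 4 df.
    """
    xa, ya = np.asarray(predicted_a, float), np.asarray(observed_a, float)
    xb, yb = np.asarray(predicted_b, float), np.asarray(observed_b, float)
    if len(xa) < 3 or len(xb) < 3:
        raise ValueError("need at least 3 pairs per group")

    def fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
        sxx = float(((x - x.mean()) ** 2).sum())
        if sxx == 0:
            raise ValueError("zero predictor variance")
        slope = float(((x - x.mean()) * (y - y.mean())).sum()) / sxx
        intercept = y.mean() - slope * x.mean()
        sse = float(((y - intercept - slope * x) ** 2).sum())
        return slope, sxx, sse

    b1, sxx1, sse1 = fit(xa, ya)
    b2, sxx2, sse2 = fit(xb, yb)
    df = len(xa) + len(xb) - 4
    s2 = (sse1 + sse2) / df
    se = np.sqrt(s2 * (1.0 / sxx1 + 1.0 / sxx2))
    if se == 0:
        t = 0.0
    else:
        t = (b1 - b2) / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), min(p, 1.0)
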