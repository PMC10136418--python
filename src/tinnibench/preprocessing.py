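"""Missing-value filtering, iterative forest imputation, and encoding.

The preprocessing contract runs in a fixed order: drop patients with more
than 40% missing features, then drop features missing in more than 25% of
the surviving patients, then fill the remaining holes with a
MissForest-style iterative random-forest imputation.  Both filters use
strict inequalities.  A separate :func:`encode` step turns the fully
imputed mixed table into a numeric matrix (z-scored quantitative columns,
full one-hot categorical indicators) for the distance-based reducers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .data import CATEGORICAL, QUANTITATIVE, PatientTable

__all__ = [
    "filter_patients",
    "filter_features",
    "impute_iterative_forest",
    "preprocess",
    "encode",
    "EncodedMatrix",
    "impute_mean_mode",
]


def filter_patients(table: PatientTable, max_missing: float = 0.40) -> PatientTable:
    """Remove patients with strictly more than ``max_missing`` missing features.

    The missing fraction is computed over the table's current feature set;
    survivor order is preserved.
    """
    if not 0.0 < max_missing < 1.0:
        raise ValueError("max_missing must lie strictly in (0, 1)")
    frac = table.missing_mask.mean(axis=1)
    keep = np.flatnonzero((frac <= max_missing).to_numpy())
    if keep.size == 0:
        raise ValueError("no patients survive the missingness filter")
    return table.subset(keep)


def filter_features(table: PatientTable, max_missing: float = 0.25) -> PatientTable:
    """Remove features missing in strictly more than ``max_missing`` of patients.

    Applied after :func:`filter_patients`, so fractions refer to the
    surviving patients.  The label column is not a feature and is always
    exempt.
    """
    if not 0.0 < max_missing < 1.0:
        raise ValueError("max_missing must lie strictly in (0, 1)")
    frac = table.missing_mask.mean(axis=0)
    keep = [c for c in table.data.columns if frac[c] <= max_missing]
    if not keep:
        raise ValueError("no features survive the missingness filter")
    schema = {c: table.schema[c] for c in keep}
    return PatientTable(
        data=table.data[keep].copy(), schema=schema, labels=table.labels
    )


def impute_mean_mode(table: PatientTable) -> PatientTable:
    """Baseline imputation: column mean (quantitative) or mode (categorical)."""
    out = table.copy()
    for col in out.data.columns:
        if out.schema[col].kind == QUANTITATIVE:
            fill = out.data[col].mean()
        else:
            modes = out.data[col].mode(dropna=True)
            fill = modes.iloc[0]
        out.data[col] = out.data[col].fillna(fill)
    return out


def _predictor_matrix(table: PatientTable) -> np.ndarray:
    """Numeric predictor view: quantitative as-is, categorical as level codes."""
    cols = []
    for col in table.data.columns:
        if table.schema[col].kind == QUANTITATIVE:
            cols.append(table.data[col].to_numpy(dtype=float))
        else:
            levels = list(table.schema[col].levels)
            codes = table.data[col].map({lv: i for i, lv in enumerate(levels)})
            cols.append(codes.to_numpy(dtype=float))
    return np.column_stack(cols)


def impute_iterative_forest(
    table: PatientTable,
    max_iter: int = 10,
    n_trees: int = 100,
    seed: int = 0,
) -> PatientTable:
    """Fill missing cells by iterative random-forest imputation.

    Procedure: initialise holes with the column mean/mode; then, visiting
    features in ascending-missingness order, repeatedly fit a random-forest
    regressor (quantitative) or classifier (categorical) of that feature on
    the rows where it was observed and overwrite its missing cells with the
    forest's predictions.  Iteration stops when the change in the imputed
    values stops decreasing (the squared change over quantitative holes,
    scaled by the column variance, plus the disagreement rate over
    categorical holes increases relative to the previous sweep), or after
    ``max_iter`` sweeps; the values from the last improving sweep are kept.
    Deterministic under a fixed seed.  Observed cells are never altered.
    """
    mask = table.missing_mask
    if not mask.to_numpy().any():
        return table.copy()
    if mask.all(axis=0).any():
        bad = list(mask.columns[mask.all(axis=0)])
        raise ValueError(
            f"fully missing columns {bad}; run filter_features first"
        )
    if mask.all(axis=1).any():
        raise ValueError("some patients have no observed value; filter first")

    current = impute_mean_mode(table)
    order = mask.mean(axis=0).sort_values(kind="stable").index
    hole_cols = [c for c in order if mask[c].any()]
    seeds = np.random.SeedSequence(seed).generate_state(max_iter * len(hole_cols))
    quant_var = {
        c: max(float(table.data[c].var(ddof=0)), 1e-12)
        for c in table.quantitative_columns
    }

    best = current.copy()
    prev_delta = np.inf
    s = 0
    for _ in range(max_iter):
        previous = current.copy()
        X = _predictor_matrix(current)
        col_pos = {c: i for i, c in enumerate(current.data.columns)}
        for col in hole_cols:
            miss = mask[col].to_numpy()
            obs = ~miss
            others = [i for c, i in col_pos.items() if c != col]
            rf_seed = int(seeds[s] % (2**31)); s += 1
            if table.schema[col].kind == QUANTITATIVE:
                model = RandomForestRegressor(
                    n_estimators=n_trees, random_state=rf_seed, n_jobs=1
                )
                y = current.data[col].to_numpy(dtype=float)
                model.fit(X[obs][:, others], y[obs])
                pred = model.predict(X[miss][:, others])
                y = y.copy()
                y[miss] = pred
                current.data[col] = y
            else:
                model = RandomForestClassifier(
                    n_estimators=n_trees, random_state=rf_seed, n_jobs=1
                )
                y = current.data[col].to_numpy(dtype=object)
                model.fit(X[obs][:, others], y[obs])
                y = y.copy()
                y[miss] = model.predict(X[miss][:, others])
                current.data[col] = y
            X = _predictor_matrix(current)  # refreshed for subsequent columns

        # MissForest-style stopping statistic over the imputed cells only.
        delta = 0.0
        for col in hole_cols:
            miss = mask[col].to_numpy()
            if table.schema[col].kind == QUANTITATIVE:
                diff = (
                    current.data[col].to_numpy(dtype=float)[miss]
                    - previous.data[col].to_numpy(dtype=float)[miss]
                )
                delta += float(np.sum(diff**2)) / quant_var[col] / miss.sum()
            else:
                diff = (
                    current.data[col].to_numpy(object)[miss]
                    != previous.data[col].to_numpy(object)[miss]
                )
                delta += float(np.mean(diff))
        if delta >= prev_delta:
            return best
        best = current.copy()
        prev_delta = delta
        if delta == 0.0:
            break
    return best


def preprocess(
    table: PatientTable,
    max_patient_missing: float = 0.40,
    max_feature_missing: float = 0.25,
    max_iter: int = 10,
    n_trees: int = 100,
    seed: int = 0,
) -> PatientTable:
    """The full ordered preprocessing pipeline: patients, features, impute.

    The order matters and is fixed: the patient filter runs on the full
    feature set, the feature filter on the surviving patients, and the
    imputation on what remains.
    """
    table = filter_patients(table, max_patient_missing)
    table = filter_features(table, max_feature_missing)
    return impute_iterative_forest(
        table, max_iter=max_iter, n_trees=n_trees, seed=seed
    )


@dataclass
class EncodedMatrix:
    """Numeric encoding of a fully imputed mixed table.

    ``column_map`` records each output column's provenance as
    ``(feature, level-or-None)``; ``centers``/``scales`` hold the z-score
    statistics of the quantitative columns on the fitting data (scales for
    indicator columns are 1).
    """

    values: np.ndarray
    column_map: list[tuple[str, str | None]]
    centers: np.ndarray
    scales: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def encode(table: PatientTable, fit_stats: EncodedMatrix | None = None) -> EncodedMatrix:
    """Encode the mixed table: z-scored quantitative + full one-hot categorical.

    With ``fit_stats`` supplied, its centers/scales and column layout are
    reused (transform mode); a categorical level absent from the fitted
    layout raises.  Without it, statistics are fit on ``table`` itself.
    """
    if table.missing_mask.to_numpy().any():
        raise ValueError("encode requires a fully imputed table")

    if fit_stats is None:
        column_map: list[tuple[str, str | None]] = []
        for col in table.data.columns:
            if table.schema[col].kind == QUANTITATIVE:
                column_map.append((col, None))
            else:
                column_map.extend((col, lv) for lv in table.schema[col].levels)
    else:
        column_map = list(fit_stats.column_map)
        fitted_features = {f for f, _ in column_map}
        for col in table.data.columns:
            if table.schema[col].kind == CATEGORICAL:
                if col not in fitted_features:
                    raise ValueError(f"feature {col!r} unknown to fit_stats")
                known = {lv for f, lv in column_map if f == col}
                seen = set(table.data[col].unique())
                if seen - known:
                    raise ValueError(
                        f"unseen level(s) {sorted(seen - known)} in {col!r}"
                    )

    blocks = []
    for feat, level in column_map:
        if level is None:
            blocks.append(table.data[feat].to_numpy(dtype=float))
        else:
            blocks.append((table.data[feat].to_numpy(object) == level).astype(float))
    values = np.column_stack(blocks)

    if fit_stats is None:
        centers = np.zeros(values.shape[1])
        scales = np.ones(values.shape[1])
        for j, (feat, level) in enumerate(column_map):
            if level is None:
                centers[j] = values[:, j].mean()
                sd = values[:, j].std(ddof=0)
                if sd == 0:
                    warnings.warn(f"constant quantitative column {feat!r}")
                    sd = 1.0
                scales[j] = sd
    else:
        centers, scales = fit_stats.centers, fit_stats.scales

    out = values.copy()
    for j, (feat, level) in enumerate(column_map):
        if level is None:
            out[:, j] = (out[:, j] - centers[j]) / scales[j]
    return EncodedMatrix(
        values=out, column_map=column_map, centers=centers, scales=scales
    )
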