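"""Classical comparators evaluated on the identical windowed CV splits.

Four kinds: per-stratum ARIMA(0,2,0), lag-window SVR and random forest
(pooled across strata in z-units), and the plain LSTM (the network without
attention, fixed mid-range hyperparameters, no swarm tuning). Every model
is scored on exactly the same validation cells, in original rate units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from swarmcast.errors import ConfigError
from swarmcast.network import HyperParams, forward, train
from swarmcast.panel import AsirPanel
from swarmcast.tscv import FoldSpec, MetricReport, _fold_datasets, evaluate

KINDS = ("arima", "svr", "rf", "lstm_plain")

_DEFAULTS = {
    "arima": {"order": (0, 2, 0)},
    "svr": {"kernel": "rbf", "gamma": 0.1, "C": 10.0},
    "rf": {"n_estimators": 100, "max_depth": 10, "min_samples_split": 2},
    "lstm_plain": {"max_epochs": 100, "patience": 5, "l2": 1e-4},
}


@dataclass(frozen=True)
class BaselineConfig:
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ConfigError(f"unknown baseline kind {self.kind!r}; one of {KINDS}")
        merged = dict(_DEFAULTS[self.kind], **self.params)
        object.__setattr__(self, "params", merged)


@dataclass
class BaselineResult:
    config: BaselineConfig
    report: MetricReport
    per_fold: list  # dicts with fold, forecasts, actuals (rate units)
    fold_reports: list[MetricReport] = field(default_factory=list)


def _i2_extrapolate(series: np.ndarray, steps: int) -> np.ndarray:
    """Closed-form ARIMA(0,2,0) forecast: continue the last linear trend."""
    slope = series[-1] - series[-2]
    return series[-1] + slope * np.arange(1, steps + 1)


def _arima_forecast(series: np.ndarray, order, steps: int) -> np.ndarray:
    from statsmodels.tsa.arima.model import ARIMA

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = ARIMA(series, order=order).fit()
            out = np.asarray(fit.forecast(steps), dtype=float)
        if not np.all(np.isfinite(out)):
            raise ValueError("non-finite forecast")
        return out
    except Exception:
        # drift-free second-difference extrapolation fallback
        return _i2_extrapolate(series, steps)


def _lag_matrix(ds):
    """Pool per-stratum univariate lag vectors: (N*S, w) -> (N*S, h)."""
    N, w, S = ds.inputs.shape
    h = ds.targets.shape[1]
    X = np.transpose(ds.inputs, (0, 2, 1)).reshape(N * S, w)
    Y = np.transpose(ds.targets, (0, 2, 1)).reshape(N * S, h)
    return X, Y


def fit_predict_baseline(
    config: BaselineConfig,
    panel: AsirPanel,
    folds: Sequence[FoldSpec],
    w: int = 10,
    h: int = 5,
    seed: int = 0,
) -> BaselineResult:
    """Fit the baseline per fold and score it on the fold's validation cells.

    ARIMA is fitted univariately per stratum on the raw training series (it
    needs no scaling and estimates no parameters at order (0,2,0)); SVR/RF
    regress pooled z-unit lag vectors onto h-step targets; the plain LSTM
    trains on the fold's multivariate windows without attention.
    """
    per_fold = []
    fold_reports = []
    all_fc, all_act = [], []
    for k, fold in enumerate(folds):
        tr, va, norm = _fold_datasets(panel, fold, w, h)
        n_val, _, S = va.targets.shape
        act_rate = va.targets * norm.std + norm.mean

        if config.kind == "arima":
            fc_rate = np.empty_like(act_rate)
            year_to_row = {y: i for i, y in enumerate(panel.years)}
            for i, anchor in enumerate(va.anchor_years):
                hist = panel.values[: year_to_row[anchor] + 1]
                for j in range(S):
                    fc_rate[i, :, j] = _arima_forecast(
                        hist[:, j], config.params["order"], h
                    )
        elif config.kind in ("svr", "rf"):
            Xtr, Ytr = _lag_matrix(tr)
            Xva, _ = _lag_matrix(va)
            if config.kind == "svr":
                from sklearn.multioutput import MultiOutputRegressor
                from sklearn.svm import SVR

                est = MultiOutputRegressor(
                    SVR(
                        kernel=config.params["kernel"],
                        gamma=config.params["gamma"],
                        C=config.params["C"],
                    )
                )
            else:
                from sklearn.ensemble import RandomForestRegressor

                est = RandomForestRegressor(
                    n_estimators=config.params["n_estimators"],
                    max_depth=config.params["max_depth"],
                    min_samples_split=config.params["min_samples_split"],
                    random_state=seed + k,
                )
            est.fit(Xtr, Ytr)
            Z = np.asarray(est.predict(Xva))  # (n_val*S, h)
            fc_z = np.transpose(Z.reshape(n_val, S, h), (0, 2, 1))
            fc_rate = fc_z * norm.std + norm.mean
        elif config.kind == "lstm_plain":
            model = train(
                tr, va, HyperParams(), seed=seed + k,
                max_epochs=config.params["max_epochs"],
                patience=config.params["patience"],
                l2=config.params["l2"], use_attention=False,
            )
            fc_z = forward(va.inputs, model.params)
            fc_rate = fc_z * norm.std + norm.mean
        else:  # pragma: no cover
            raise ConfigError(config.kind)

        per_fold.append(
            {"fold": fold, "forecasts": fc_rate, "actuals": act_rate,
             "anchor_years": va.anchor_years}
        )
        fold_reports.append(
            evaluate(fc_rate, act_rate, label=f"{config.kind}/fold{k + 1}")
        )
        all_fc.append(fc_rate.ravel())
        all_act.append(act_rate.ravel())

    report = evaluate(
        np.concatenate(all_fc), np.concatenate(all_act), label=config.kind
    )
    return BaselineResult(
        config=config, report=report, per_fold=per_fold, fold_reports=fold_reports
    )


def comparison_table(reports: Sequence[MetricReport]) -> pd.DataFrame:
    """Min-max normalized scores (0 = best) per metric, plus a ranking.

    R^2 is negated before normalization so every column is lower-is-better.
    Ties in the mean normalized score are broken by label order.
    """
    if len(reports) < 2:
        raise ConfigError("comparison_table needs at least 2 reports")
    df = pd.DataFrame([r.as_dict() for r in reports]).set_index("label")
    cols = {"mse": 1, "r2": -1, "mape_percent": 1, "nrmse": 1, "mae": 1}
    normed = pd.DataFrame(index=df.index)
    for col, sign in cols.items():
        vals = sign * df[col]
        span = vals.max() - vals.min()
        normed[f"norm_{col}"] = 0.0 if span == 0 else (vals - vals.min()) / span
    normed["mean_score"] = normed.mean(axis=1)
    order = sorted(normed.index, key=lambda lbl: (normed.loc[lbl, "mean_score"], lbl))
    normed["rank"] = [order.index(lbl) + 1 for lbl in normed.index]
    return normed.join(df)
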