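"""Calendar-anchored expanding-window cross-validation and accuracy metrics.

Folds keep strict chronology: every training year precedes every validation
year. The canonical three folds for a 1990-2020+ panel are
(1990-2005 -> 2006-2010), (1990-2010 -> 2011-2015), (1990-2015 -> 2016-2020);
other spans get the analogous expanding-window layout (three folds,
five-year validation blocks, the last ending at the panel's penultimate
year).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from swarmcast.errors import ConfigError, SwarmcastError
from swarmcast.network import HyperParams, _val_mse, train
from swarmcast.panel import AsirPanel, normalize
from swarmcast.windowing import make_windows

# ------------------------------------------------------------------ metrics


def _check_pair(y, yhat):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size == 0:
        raise ConfigError("metric requires at least one data point")
    if y.shape != yhat.shape:
        raise ConfigError(f"length mismatch: {y.shape} vs {yhat.shape}")
    return y, yhat


def mse(y, yhat) -> float:
    """Mean squared residual."""
    y, yhat = _check_pair(y, yhat)
    return float(np.mean((y - yhat) ** 2))


def r2(y, yhat) -> float:
    """1 - SS_res / SS_tot, with SS_tot about the mean of the actuals."""
    y, yhat = _check_pair(y, yhat)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ConfigError("r2 undefined for constant actuals")
    return float(1.0 - np.sum((y - yhat) ** 2) / ss_tot)


def mape(y, yhat) -> float:
    """Mean absolute percentage error, in percent. Zero actuals are an error."""
    y, yhat = _check_pair(y, yhat)
    if np.any(y == 0):
        raise ConfigError("mape undefined when an actual value is zero")
    return float(np.mean(np.abs((y - yhat) / y)) * 100.0)


def nrmse(y, yhat) -> float:
    """RMSE divided by the range of the actuals."""
    y, yhat = _check_pair(y, yhat)
    rng = float(y.max() - y.min())
    if rng == 0:
        raise ConfigError("nrmse undefined for constant actuals")
    return float(np.sqrt(np.mean((y - yhat) ** 2)) / rng)


def mae(y, yhat) -> float:
    """Mean absolute residual."""
    y, yhat = _check_pair(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


@dataclass(frozen=True)
class MetricReport:
    """The five-metric evaluation record used in comparison tables."""

    label: str
    mse: float
    r2: float
    mape_percent: float
    nrmse: float
    mae: float
    n: int

    def as_dict(self) -> dict:
        return {
            "label": self.label, "mse": self.mse, "r2": self.r2,
            "mape_percent": self.mape_percent, "nrmse": self.nrmse,
            "mae": self.mae, "n": self.n,
        }


def evaluate(forecasts, actuals, label: str = "model") -> MetricReport:
    """Pool all (year, stratum) cells and apply the five metrics."""
    f = np.asarray(forecasts, dtype=float)
    a = np.asarray(actuals, dtype=float)
    if f.shape != a.shape:
        raise ConfigError(f"forecast shape {f.shape} != actual shape {a.shape}")
    return MetricReport(
        label=label,
        mse=mse(a, f),
        r2=r2(a, f),
        mape_percent=mape(a, f),
        nrmse=nrmse(a, f),
        mae=mae(a, f),
        n=int(a.size),
    )


def write_reports(reports: Sequence[MetricReport], path: str | Path) -> None:
    pd.DataFrame([r.as_dict() for r in reports]).to_csv(path, index=False)


# -------------------------------------------------------------------- folds


@dataclass(frozen=True)
class FoldSpec:
    """Inclusive train/validation year ranges; training strictly precedes
    validation."""

    train_years: tuple[int, int]
    val_years: tuple[int, int]

    def __post_init__(self):
        if self.train_years[1] >= self.val_years[0]:
            raise ConfigError(
                f"training years {self.train_years} must end before "
                f"validation years {self.val_years}"
            )


_CANONICAL_FOLDS = (
    FoldSpec((1990, 2005), (2006, 2010)),
    FoldSpec((1990, 2010), (2011, 2015)),
    FoldSpec((1990, 2015), (2016, 2020)),
)

#: layout constants for the expanding-window analogue
_N_FOLDS = 3
_VAL_LEN = 5
_MIN_FIRST_TRAIN = 10


def make_folds(panel: AsirPanel) -> list[FoldSpec]:
    """Three expanding-window folds for the panel's span.

    A panel starting in 1990 and reaching 2020 gets the canonical folds
    verbatim (any years past 2020 are unused by CV). Otherwise, with panel
    years [start, end]: the last validation block ends at end-1 and the three
    five-year validation blocks are laid back-to-back before it, each fold
    training on every year before its block. The first fold must keep at
    least 10 training years, so the minimum span is 26 years.
    """
    start, end = panel.years[0], panel.years[-1]
    if start == 1990 and end >= 2020:
        return list(_CANONICAL_FOLDS)
    min_span = _N_FOLDS * _VAL_LEN + 1 + _MIN_FIRST_TRAIN
    if end - start + 1 < min_span:
        raise ConfigError(
            f"panel span {start}-{end} too short for {_N_FOLDS} folds; "
            f"needs at least {min_span} years"
        )
    folds = []
    last_val_end = end - 1
    for j in range(_N_FOLDS):
        val_end = last_val_end - (_N_FOLDS - 1 - j) * _VAL_LEN
        val_start = val_end - _VAL_LEN + 1
        folds.append(FoldSpec((start, val_start - 1), (val_start, val_end)))
    return folds


# ------------------------------------------------------------------ fitness


def _fold_datasets(panel: AsirPanel, fold: FoldSpec, w: int, h: int):
    """Windowed train/val sets for one fold; z-scored with stats fitted on
    the fold's training years only; no year past the validation block is
    ever touched."""
    start = panel.years[0]
    t_lo, t_hi = fold.train_years
    v_lo, v_hi = fold.val_years
    if t_lo < start or v_hi > panel.years[-1]:
        raise ConfigError(f"fold {fold} outside panel span")
    if v_hi - v_lo + 1 < h:
        raise SwarmcastError(
            f"validation block {fold.val_years} shorter than horizon {h}"
        )
    # truncate the panel at the validation end: later years must not leak
    rows = [i for i, y in enumerate(panel.years) if y <= v_hi]
    sub = AsirPanel(
        years=panel.years[: len(rows)], strata=panel.strata,
        values=panel.values[rows], zscored=panel.zscored,
    )
    zsub, params = normalize(sub, fit_years=range(t_lo, t_hi + 1))
    ds = make_windows(zsub, w, h)
    anchors = np.asarray(ds.anchor_years)
    train_idx = np.flatnonzero(anchors + h <= t_hi)  # targets fully in train years
    val_idx = np.flatnonzero((anchors + 1 >= v_lo) & (anchors + h <= v_hi))
    if train_idx.size == 0 or val_idx.size == 0:
        raise SwarmcastError(
            f"fold {fold} yields no usable windows for w={w}, h={h}"
        )
    return ds.subset(train_idx), ds.subset(val_idx), params


def cv_fitness(
    hp: HyperParams,
    panel: AsirPanel,
    folds: Sequence[FoldSpec],
    seed: int = 0,
    w: int = 10,
    h: int = 5,
    inner_epochs: int = 30,
    patience: int = 5,
    l2: float = 1e-4,
    use_attention: bool = True,
) -> float:
    """Mean z-unit validation MSE over the folds (the swarm's objective).

    Per fold: fit normalization on training years only, window the fold
    (validation windows may take input context from the training tail, but
    every target year lies in the validation block), train under the inner
    epoch budget, and score the best-epoch weights on the validation windows.
    """
    scores = []
    for k, fold in enumerate(folds):
        tr, va, _ = _fold_datasets(panel, fold, w, h)
        model = train(
            tr, va, hp, seed=seed + k, max_epochs=inner_epochs,
            patience=patience, l2=l2, use_attention=use_attention,
        )
        scores.append(_val_mse(model.params, va))
    return float(np.mean(scores))
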