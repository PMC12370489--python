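"""End-to-end orchestration: load/simulate -> normalize -> window ->
swarm-tune -> final train -> forecast -> evaluate, plus the ablation harness.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from swarmcast import __version__
from swarmcast.errors import ConfigError
from swarmcast.network import (
    HyperParams,
    TrainedModel,
    forecast_next,
    forward,
    save_model,
    train,
)
from swarmcast.panel import AsirPanel, normalize, read_panel, write_panel
from swarmcast.pso import decode_position, default_search_space, optimize
from swarmcast.synthetic import SyntheticConfig, generate_panel
from swarmcast.tscv import (
    FoldSpec,
    MetricReport,
    _fold_datasets,
    cv_fitness,
    evaluate,
    make_folds,
    write_reports,
)
from swarmcast.windowing import make_windows

VARIANTS = ("lstm_only", "lstm_attention", "lstm_pso", "full")

#: fixed mid-range hyperparameters for the variants that skip swarm tuning
FIXED_HP = HyperParams(hidden_units=40, dropout_rate=0.2, learning_rate=1e-3, batch_size=32)


def _variant_flags(variant: str) -> tuple[bool, bool]:
    """(use_attention, use_pso) for an ablation variant name."""
    if variant not in VARIANTS:
        raise ConfigError(f"unknown variant {variant!r}; one of {VARIANTS}")
    return (
        variant in ("lstm_attention", "full"),
        variant in ("lstm_pso", "full"),
    )


@dataclass(frozen=True)
class RunConfig:
    input_csv: str | None = None
    synthetic: SyntheticConfig | None = None
    w: int = 10
    h: int = 5
    variant: str = "full"
    seed: int = 0
    n_particles: int = 10
    max_iter: int = 50
    swarm_patience: int = 5
    max_epochs: int = 100
    train_patience: int = 5
    l2: float = 1e-4
    inner_epochs: int = 30
    final_val_windows: int = 3
    out_dir: str = "runs/latest"

    def __post_init__(self):
        if self.input_csv is None and self.synthetic is None:
            raise ConfigError("provide input_csv or a synthetic config")
        _variant_flags(self.variant)

    def load_panel(self) -> AsirPanel:
        if self.input_csv is not None:
            return read_panel(self.input_csv)
        return generate_panel(self.synthetic)


def tune_hyperparams(
    panel: AsirPanel,
    folds: Sequence[FoldSpec],
    config: RunConfig,
    use_attention: bool = True,
) -> tuple[HyperParams, list[dict]]:
    """Swarm search over the four-knob space, fitness = mean CV validation MSE."""
    space = default_search_space()

    def fitness(position: np.ndarray) -> float:
        hp = decode_position(position, space)
        return cv_fitness(
            hp, panel, folds, seed=config.seed, w=config.w, h=config.h,
            inner_epochs=config.inner_epochs, patience=config.train_patience,
            l2=config.l2, use_attention=use_attention,
        )

    best_pos, _, trace = optimize(
        fitness, space, n_particles=config.n_particles, max_iter=config.max_iter,
        patience=config.swarm_patience, seed=config.seed,
    )
    return decode_position(best_pos, space), trace


def final_train(
    panel: AsirPanel, hp: HyperParams, config: RunConfig, use_attention: bool = True
) -> TrainedModel:
    """Train on the full panel (normalization fitted on all years), holding
    out the last few windows for early stopping."""
    zpanel, norm = normalize(panel)
    ds = make_windows(zpanel, config.w, config.h)
    n_val = min(config.final_val_windows, max(len(ds) - 1, 0))
    if n_val > 0:
        tr = ds.subset(np.arange(len(ds) - n_val))
        va = ds.subset(np.arange(len(ds) - n_val, len(ds)))
    else:
        tr, va = ds, None
    return train(
        tr, va, hp, seed=config.seed, max_epochs=config.max_epochs,
        patience=config.train_patience, l2=config.l2,
        use_attention=use_attention, normalization=norm,
    )


def evaluate_network_on_folds(
    panel: AsirPanel,
    folds: Sequence[FoldSpec],
    hp: HyperParams,
    config: RunConfig,
    use_attention: bool = True,
    label: str = "model",
) -> tuple[MetricReport, list[MetricReport]]:
    """CV evaluation in original rate units on the shared validation cells."""
    all_fc, all_act = [], []
    fold_reports = []
    for k, fold in enumerate(folds):
        tr, va, norm = _fold_datasets(panel, fold, config.w, config.h)
        model = train(
            tr, va, hp, seed=config.seed + k, max_epochs=config.max_epochs,
            patience=config.train_patience, l2=config.l2, use_attention=use_attention,
        )
        fc_rate = forward(va.inputs, model.params) * norm.std + norm.mean
        act_rate = va.targets * norm.std + norm.mean
        fold_reports.append(evaluate(fc_rate, act_rate, label=f"{label}/fold{k + 1}"))
        all_fc.append(fc_rate.ravel())
        all_act.append(act_rate.ravel())
    pooled = evaluate(np.concatenate(all_fc), np.concatenate(all_act), label=label)
    return pooled, fold_reports


@dataclass
class PipelineResult:
    config: RunConfig
    hyperparams: HyperParams
    model: TrainedModel
    forecast: AsirPanel
    report: MetricReport
    fold_reports: list[MetricReport]
    trace: list[dict] = field(default_factory=list)


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineResult:
    """The full flow for one variant; writes all artifacts under out_dir."""
    panel = config.load_panel()
    folds = make_folds(panel)
    use_attention, use_pso = _variant_flags(config.variant)

    if use_pso:
        hp, trace = tune_hyperparams(panel, folds, config, use_attention=use_attention)
    else:
        hp, trace = FIXED_HP, []

    model = final_train(panel, hp, config, use_attention=use_attention)
    fc = forecast_next(panel, model, config.h)
    report, fold_reports = evaluate_network_on_folds(
        panel, folds, hp, config, use_attention=use_attention, label=config.variant
    )

    result = PipelineResult(
        config=config, hyperparams=hp, model=model, forecast=fc,
        report=report, fold_reports=fold_reports, trace=trace,
    )
    if write:
        _write_artifacts(result, panel)
    return result


def _write_artifacts(result: PipelineResult, panel: AsirPanel) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_panel(result.forecast, out / "forecast.csv")
    write_reports([result.report, *result.fold_reports], out / "metrics.csv")
    save_model(result.model, out / "model")
    if result.trace:
        pd.DataFrame(
            [
                {
                    "iteration": row["iteration"],
                    "omega": row["omega"],
                    "best_score": row["best_score"],
                    **{
                        f"best_{k}": v
                        for k, v in dataclasses.asdict(row["best_decoded"]).items()
                    },
                }
                for row in result.trace
            ]
        ).to_csv(out / "pso_trace.csv", index=False)
    manifest = {
        "package_version": __version__,
        "config": _config_dict(result.config),
        "variant": result.config.variant,
        "pso_skipped": not _variant_flags(result.config.variant)[1],
        "attention_enabled": _variant_flags(result.config.variant)[0],
        "hyperparams": dataclasses.asdict(result.hyperparams),
        "panel_span": [panel.years[0], panel.years[-1]],
        "n_strata": panel.n_strata,
        "seed": result.config.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def run_ablation(config: RunConfig, write: bool = True) -> pd.DataFrame:
    """All four variants on identical panel/folds/seed; Table-shaped output.

    Returns a DataFrame with one row per variant and the five pooled metrics.
    """
    panel = config.load_panel()
    folds = make_folds(panel)
    rows = []
    reports = []
    split_hashes = set()
    for variant in VARIANTS:
        use_attention, use_pso = _variant_flags(variant)
        vc = dataclasses.replace(config, variant=variant)
        if use_pso:
            hp, _ = tune_hyperparams(panel, folds, vc, use_attention=use_attention)
        else:
            hp = FIXED_HP
        report, _ = evaluate_network_on_folds(
            panel, folds, hp, vc, use_attention=use_attention, label=variant
        )
        # all variants must see byte-identical splits
        tr0, va0, _ = _fold_datasets(panel, folds[0], config.w, config.h)
        split_hashes.add((tuple(tr0.anchor_years), tuple(va0.anchor_years)))
        reports.append(report)
        rows.append({"variant": variant, **{k: v for k, v in report.as_dict().items() if k != "label"}})
    assert len(split_hashes) == 1, "ablation variants saw different splits"
    table = pd.DataFrame(rows)
    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "ablation.csv", index=False)
    return table
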