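# swarmcast

Swarm-tuned attention-LSTM forecasting for age/sex-stratified incidence
panels.

The package ingests long-format CSV tables of annual incidence rates (one
row per year × sex × age-group, the shape of a GBD results-tool export),
z-scores each stratum, cuts sliding multivariate windows (default 10-year
history, 5-year horizon), and fits a single-layer LSTM encoder with an
additive attention layer and a single-shot multi-horizon dense head. The
four training hyperparameters (hidden units, dropout, learning rate, batch
size) are selected by a from-scratch particle swarm optimizer whose fitness
is the mean validation MSE under strict expanding-window time-series
cross-validation. Classical baselines (ARIMA(0,2,0), SVR, random forest,
plain LSTM) are evaluated on identical validation cells, and a synthetic
panel generator with a monotone age gradient, sex-ratio offset, logistic
trends, and multiplicative lognormal noise makes the whole pipeline
testable without any external data.

The network (forward pass, hand-written backprop, Adam, L2, dropout, early
stopping) is implemented directly in NumPy — no deep-learning framework is
required. At these problem sizes (≤24 strata, ≤64 hidden units) a full
100-epoch fit takes well under a second on one CPU core.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the end-to-end checks (structural counts,
metric/PSO/network oracles, noiseless-panel parameter recovery, leakage
guards); the rest are per-module unit and property tests.

## CLI

```bash
# generate a synthetic 32-year, 24-stratum panel
swarmcast simulate --seed 1 --out panel.csv

# full pipeline: swarm tuning + final training + 5-year forecast + metrics
swarmcast train --input panel.csv --variant full --out-dir runs/demo

# individual stages
swarmcast tune --input panel.csv --out-dir runs/tune
swarmcast forecast --model runs/demo/model --input panel.csv --out fc.csv
swarmcast evaluate --forecast fc.csv --actual actual.csv

# ablation (lstm_only / lstm_attention / lstm_pso / full) and baselines
swarmcast ablate --input panel.csv --out-dir runs/ablation
swarmcast compare --input panel.csv --out-dir runs/compare
```

Every run directory receives a `manifest.json` echoing the resolved
configuration and seeds; reruns with the same config and seed reproduce the
swarm trace and metric reports exactly.

## Layout

| module | contents |
| --- | --- |
| `swarmcast.panel` | long-CSV read/write, panel validation, per-stratum z-normalization |
| `swarmcast.synthetic` | stratified panel generator + expectation-surface oracle |
| `swarmcast.windowing` | sliding-window extraction and sample counting |
| `swarmcast.network` | LSTM + attention + dense head, Adam training, save/load |
| `swarmcast.pso` | particle swarm optimizer, search space, position decoding |
| `swarmcast.tscv` | expanding-window folds, CV fitness, the five metrics |
| `swarmcast.baselines` | ARIMA/SVR/RF/plain-LSTM comparators, comparison table |
| `swarmcast.pipeline` | end-to-end orchestration and the ablation harness |
| `swarmcast.cli` | click command-line interface |
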