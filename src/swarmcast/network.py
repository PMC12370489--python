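"""Attention-augmented LSTM forecaster.

A single-layer LSTM encoder runs over a w-year multivariate window, an
additive (tanh) attention layer pools the per-step hidden states into a
context vector, and a dense head emits all h future years for all S strata
in one shot. Training minimizes MSE + L2 with Adam, mini-batches, and
early stopping on validation MSE.

Implemented directly in NumPy (forward and backward passes are hand-written)
so the package has no deep-learning framework dependency; the problem sizes
here (S<=24, hidden<=64, w=10) make this fast on one CPU core.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from swarmcast.errors import ConfigError, StratumMismatchError, TrainingDivergedError
from swarmcast.panel import AsirPanel, NormalizationParams, normalize
from swarmcast.windowing import WindowedDataset

HP_BOUNDS = {
    "hidden_units": (16, 64),
    "dropout_rate": (0.0, 0.4),
    "learning_rate": (1e-4, 1e-2),
    "batch_size": (16, 64),
}


@dataclass(frozen=True)
class HyperParams:
    """The four swarm-tuned knobs; each validated against its search bound."""

    hidden_units: int = 40
    dropout_rate: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 32

    def __post_init__(self):
        for name, (lo, hi) in HP_BOUNDS.items():
            val = getattr(self, name)
            if not (lo <= val <= hi):
                raise ConfigError(f"{name}={val} outside [{lo}, {hi}]")
        if self.hidden_units != int(self.hidden_units):
            raise ConfigError("hidden_units must be an integer")
        if self.batch_size != int(self.batch_size):
            raise ConfigError("batch_size must be an integer")


_WEIGHT_FIELDS = ("W_f", "W_i", "W_o", "W_c", "W_a", "v", "W_y")
_BIAS_FIELDS = ("b_f", "b_i", "b_o", "b_c", "b_a", "b_y")
_PARAM_FIELDS = _WEIGHT_FIELDS + _BIAS_FIELDS


@dataclass
class ModelParams:
    """All trainable arrays plus the architecture they imply.

    Gate weights act on the concatenation [h_prev, x_t] (shape hidden+S ->
    hidden). Attention score dim equals hidden_units. The head maps the
    context vector to horizon*S outputs.
    """

    n_features: int
    hidden: int
    horizon: int
    use_attention: bool = True
    W_f: np.ndarray = None
    b_f: np.ndarray = None
    W_i: np.ndarray = None
    b_i: np.ndarray = None
    W_o: np.ndarray = None
    b_o: np.ndarray = None
    W_c: np.ndarray = None
    b_c: np.ndarray = None
    W_a: np.ndarray = None
    b_a: np.ndarray = None
    v: np.ndarray = None
    W_y: np.ndarray = None
    b_y: np.ndarray = None

    def __post_init__(self):
        S, H, hor = self.n_features, self.hidden, self.horizon
        shapes = {
            "W_f": (H, H + S), "b_f": (H,),
            "W_i": (H, H + S), "b_i": (H,),
            "W_o": (H, H + S), "b_o": (H,),
            "W_c": (H, H + S), "b_c": (H,),
            "W_a": (H, H), "b_a": (H,),
            "v": (H,),
            "W_y": (hor * S, H), "b_y": (hor * S,),
        }
        for name, shape in shapes.items():
            arr = getattr(self, name)
            if arr is None:
                arr = np.zeros(shape)
                setattr(self, name, arr)
            arr = np.asarray(arr, dtype=float)
            if arr.shape != shape:
                raise ConfigError(f"{name} has shape {arr.shape}, expected {shape}")
            setattr(self, name, arr)

    def copy(self) -> "ModelParams":
        kw = {f: getattr(self, f).copy() for f in _PARAM_FIELDS}
        return ModelParams(
            n_features=self.n_features, hidden=self.hidden, horizon=self.horizon,
            use_attention=self.use_attention, **kw,
        )


def init_params(
    n_features: int, hidden: int, horizon: int, seed: int,
    use_attention: bool = True, scale: float = 0.08,
) -> ModelParams:
    """Small seeded uniform init; biases zero."""
    rng = np.random.default_rng(seed)
    p = ModelParams(n_features=n_features, hidden=hidden, horizon=horizon,
                    use_attention=use_attention)
    for name in _WEIGHT_FIELDS:
        arr = getattr(p, name)
        setattr(p, name, rng.uniform(-scale, scale, size=arr.shape))
    return p


# ---------------------------------------------------------------- primitives

def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def lstm_step(x_t, h_prev, C_prev, params: ModelParams):
    """One recurrence step: gated update of (hidden, cell) state.

    f, i, o are sigmoids of affine maps of [h_prev, x_t]; the cell blends
    the previous cell (forget gate) with a tanh candidate (input gate); the
    hidden state is the output gate times tanh(cell).
    """
    x_t = np.asarray(x_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    C_prev = np.asarray(C_prev, dtype=float)
    if x_t.shape[-1] != params.n_features or h_prev.shape[-1] != params.hidden:
        raise ConfigError(
            f"lstm_step shape mismatch: x {x_t.shape}, h {h_prev.shape} for "
            f"S={params.n_features}, hidden={params.hidden}"
        )
    z = np.concatenate([h_prev, x_t], axis=-1)
    f = _sigmoid(z @ params.W_f.T + params.b_f)
    i = _sigmoid(z @ params.W_i.T + params.b_i)
    o = _sigmoid(z @ params.W_o.T + params.b_o)
    g = np.tanh(z @ params.W_c.T + params.b_c)
    C_t = f * C_prev + i * g
    h_t = o * np.tanh(C_t)
    return h_t, C_t


def attention_weights(H: np.ndarray, params: ModelParams) -> np.ndarray:
    """Softmax over additive scores e_t = v . tanh(W_a h_t + b_a)."""
    H = np.asarray(H, dtype=float)
    u = np.tanh(H @ params.W_a.T + params.b_a)
    e = u @ params.v
    e = e - e.max(axis=-1, keepdims=True)
    ex = np.exp(e)
    return ex / ex.sum(axis=-1, keepdims=True)


def attention_context(H: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Convex combination of hidden states: a = sum_t alpha_t h_t."""
    return np.einsum("...t,...th->...h", np.asarray(alpha, float), np.asarray(H, float))


def output_head(a: np.ndarray, params: ModelParams) -> np.ndarray:
    """Affine map of the context vector, reshaped to (horizon, S)."""
    a = np.asarray(a, dtype=float)
    y = a @ params.W_y.T + params.b_y
    return y.reshape(a.shape[:-1] + (params.horizon, params.n_features))


def forward(window: np.ndarray, params: ModelParams, training: bool = False,
            dropout_rate: float = 0.0, rng: np.random.Generator | None = None) -> np.ndarray:
    """Full pass: recurrence over w steps from zero state, attention pooling
    (or last hidden state when attention is disabled), dense head.

    Inference (``training=False``) is a pure function of (window, params).
    """
    window = np.asarray(window, dtype=float)
    single = window.ndim == 2
    X = window[None] if single else window
    y, _ = _forward_batch(X, params, training=training,
                          dropout_rate=dropout_rate, rng=rng)
    out = y.reshape(X.shape[0], params.horizon, params.n_features)
    return out[0] if single else out


# ------------------------------------------------------- batched fwd/bwd

def _forward_batch(X, params: ModelParams, training=False, dropout_rate=0.0,
                   rng=None, want_cache=False):
    B, w, S = X.shape
    Hn = params.hidden
    h = np.zeros((B, Hn))
    C = np.zeros((B, Hn))
    cache = {"z": [], "f": [], "i": [], "o": [], "g": [], "C": [np.zeros((B, Hn))],
             "tanhC": [], "H": []}
    for t in range(w):
        z = np.concatenate([h, X[:, t, :]], axis=1)
        f = _sigmoid(z @ params.W_f.T + params.b_f)
        i = _sigmoid(z @ params.W_i.T + params.b_i)
        o = _sigmoid(z @ params.W_o.T + params.b_o)
        g = np.tanh(z @ params.W_c.T + params.b_c)
        C = f * cache["C"][-1] + i * g
        tC = np.tanh(C)
        h = o * tC
        for k, val in (("z", z), ("f", f), ("i", i), ("o", o), ("g", g),
                       ("C", C), ("tanhC", tC), ("H", h)):
            cache[k].append(val)
    Hs = np.stack(cache["H"], axis=1)  # (B, w, hidden)

    if training and dropout_rate > 0:
        if rng is None:
            raise ValueError("rng required for dropout in training mode")
        mask = (rng.random(Hs.shape) >= dropout_rate) / (1.0 - dropout_rate)
    else:
        mask = np.ones_like(Hs)
    Hd = Hs * mask

    if params.use_attention:
        U = np.tanh(Hd @ params.W_a.T + params.b_a)  # (B, w, hidden)
        e = U @ params.v  # (B, w)
        e = e - e.max(axis=1, keepdims=True)
        ex = np.exp(e)
        alpha = ex / ex.sum(axis=1, keepdims=True)
        a = np.einsum("bt,bth->bh", alpha, Hd)
    else:
        U, alpha = None, None
        a = Hd[:, -1, :]
    y = a @ params.W_y.T + params.b_y  # (B, horizon*S)

    if not want_cache:
        return y, None
    cache.update(Hs=Hs, Hd=Hd, mask=mask, U=U, alpha=alpha, a=a, X=X)
    return y, cache


def _loss_and_grads(params: ModelParams, X, Yflat, dropout_rate, l2, rng):
    """MSE + L2 loss and gradients for one mini-batch (hand-written backprop)."""
    B, w, S = X.shape
    Hn = params.hidden
    y, cc = _forward_batch(X, params, training=True, dropout_rate=dropout_rate,
                           rng=rng, want_cache=True)
    resid = y - Yflat
    data_loss = np.mean(resid**2)
    reg = sum(np.sum(getattr(params, n) ** 2) for n in _WEIGHT_FIELDS)
    loss = data_loss + l2 * reg

    g = {n: np.zeros_like(getattr(params, n)) for n in _PARAM_FIELDS}
    dy = 2.0 * resid / resid.size  # (B, horizon*S)
    g["W_y"] = dy.T @ cc["a"]
    g["b_y"] = dy.sum(axis=0)
    da = dy @ params.W_y  # (B, hidden)

    dHd = np.zeros_like(cc["Hd"])
    if params.use_attention:
        alpha, U, Hd = cc["alpha"], cc["U"], cc["Hd"]
        dalpha = np.einsum("bh,bth->bt", da, Hd)
        dHd += alpha[:, :, None] * da[:, None, :]
        # softmax backward
        de = alpha * (dalpha - np.sum(alpha * dalpha, axis=1, keepdims=True))
        g["v"] = np.einsum("bt,bth->h", de, U)
        dU = de[:, :, None] * params.v[None, None, :]
        dpre = dU * (1.0 - U**2)  # (B, w, hidden)
        g["W_a"] = np.einsum("bti,btj->ij", dpre, Hd)
        g["b_a"] = dpre.sum(axis=(0, 1))
        dHd += dpre @ params.W_a
    else:
        dHd[:, -1, :] += da
    dH = dHd * cc["mask"]  # dropout backward -> (B, w, hidden)

    dh_next = np.zeros((B, Hn))
    dC_next = np.zeros((B, Hn))
    for t in range(w - 1, -1, -1):
        f, i, o, gg = cc["f"][t], cc["i"][t], cc["o"][t], cc["g"][t]
        tC = cc["tanhC"][t]
        C_prev = cc["C"][t]  # cache["C"][0] is the zero initial cell
        z = cc["z"][t]
        dh = dH[:, t, :] + dh_next
        do = dh * tC
        dC = dh * o * (1.0 - tC**2) + dC_next
        df = dC * C_prev
        di = dC * gg
        dg = dC * i
        dC_next = dC * f
        dzf = df * f * (1.0 - f)
        dzi = di * i * (1.0 - i)
        dzo = do * o * (1.0 - o)
        dzg = dg * (1.0 - gg**2)
        g["W_f"] += dzf.T @ z
        g["W_i"] += dzi.T @ z
        g["W_o"] += dzo.T @ z
        g["W_c"] += dzg.T @ z
        g["b_f"] += dzf.sum(axis=0)
        g["b_i"] += dzi.sum(axis=0)
        g["b_o"] += dzo.sum(axis=0)
        g["b_c"] += dzg.sum(axis=0)
        dz = dzf @ params.W_f + dzi @ params.W_i + dzo @ params.W_o + dzg @ params.W_c
        dh_next = dz[:, :Hn]

    for n in _WEIGHT_FIELDS:
        g[n] += 2.0 * l2 * getattr(params, n)
    return loss, g


# --------------------------------------------------------------- training

@dataclass
class TrainedModel:
    """A fitted forecaster plus everything needed to reproduce and apply it."""

    params: ModelParams
    hyperparams: HyperParams
    normalization: NormalizationParams | None
    history: dict = field(default_factory=dict)  # train_loss / val_mse per epoch
    stop_epoch: int = 0
    best_epoch: int = 0
    seed: int = 0
    window_length: int = 10


def _val_mse(params, val_set: WindowedDataset) -> float:
    y, _ = _forward_batch(val_set.inputs, params)
    return float(np.mean((y - val_set.targets.reshape(len(val_set), -1)) ** 2))


def train(
    train_set: WindowedDataset,
    val_set: WindowedDataset | None,
    hp: HyperParams,
    seed: int = 0,
    max_epochs: int = 100,
    patience: int = 5,
    l2: float = 1e-4,
    use_attention: bool = True,
    normalization: NormalizationParams | None = None,
) -> TrainedModel:
    """Fit with Adam on MSE + L2; seeded shuffling; early stopping on
    validation MSE with best-epoch weight restoration.

    Stops after ``patience`` consecutive epochs without validation
    improvement, or at ``max_epochs``. With ``val_set=None`` early stopping
    is disabled and training runs the full budget.
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    S = train_set.n_strata
    params = init_params(S, hp.hidden_units, train_set.h, seed=seed,
                         use_attention=use_attention)
    X = train_set.inputs
    Yflat = train_set.targets.reshape(len(train_set), -1)

    # Adam state
    m = {n: np.zeros_like(getattr(params, n)) for n in _PARAM_FIELDS}
    vv = {n: np.zeros_like(getattr(params, n)) for n in _PARAM_FIELDS}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    history = {"train_loss": [], "val_mse": []}
    best_val = np.inf
    best_params = params.copy()
    best_epoch = 0
    stall = 0
    stop_epoch = max_epochs

    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(len(train_set))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), hp.batch_size):
            idx = order[start : start + hp.batch_size]
            loss, grads = _loss_and_grads(
                params, X[idx], Yflat[idx], hp.dropout_rate, l2, rng
            )
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            step += 1
            for n in _PARAM_FIELDS:
                m[n] = beta1 * m[n] + (1 - beta1) * grads[n]
                vv[n] = beta2 * vv[n] + (1 - beta2) * grads[n] ** 2
                mhat = m[n] / (1 - beta1**step)
                vhat = vv[n] / (1 - beta2**step)
                getattr(params, n)[...] -= hp.learning_rate * mhat / (np.sqrt(vhat) + eps)
            epoch_loss += loss
            n_batches += 1
        history["train_loss"].append(epoch_loss / n_batches)

        if val_set is not None and len(val_set) > 0:
            vm = _val_mse(params, val_set)
            if not np.isfinite(vm):
                raise TrainingDivergedError(epoch)
            history["val_mse"].append(vm)
            if vm < best_val - 1e-12:
                best_val = vm
                best_params = params.copy()
                best_epoch = epoch
                stall = 0
            else:
                stall += 1
                if stall >= patience:
                    stop_epoch = epoch
                    break
        else:
            best_params = params
            best_epoch = epoch
        stop_epoch = epoch

    final = best_params if (val_set is not None and len(val_set) > 0) else params
    return TrainedModel(
        params=final, hyperparams=hp, normalization=normalization,
        history=history, stop_epoch=stop_epoch, best_epoch=best_epoch, seed=seed,
        window_length=train_set.w,
    )


def forecast_next(panel: AsirPanel, model: TrainedModel, h: int | None = None) -> AsirPanel:
    """Forecast the h years after the panel's last year, in rate units.

    Normalizes the last w panel years with the model's stored params, runs
    one forward pass, denormalizes, and labels the horizon years.
    """
    norm = model.normalization
    if norm is None:
        raise ConfigError("model carries no normalization params; cannot forecast rates")
    if tuple(norm.strata) != tuple(panel.strata):
        raise StratumMismatchError("model normalization strata do not match panel")
    if h is None:
        h = model.params.horizon
    if h != model.params.horizon:
        raise ConfigError(
            f"model emits horizon {model.params.horizon}, requested {h}"
        )
    w = model.window_length
    if panel.n_years < w:
        raise ConfigError(f"panel has {panel.n_years} years; window needs {w}")
    window = (panel.values[-w:] - norm.mean) / norm.std
    z_fc = forward(window, model.params)  # (h, S)
    rates = z_fc * norm.std + norm.mean
    rates = np.clip(rates, 0.0, None)
    years = tuple(panel.years[-1] + k for k in range(1, h + 1))
    return AsirPanel(years=years, strata=panel.strata, values=rates)


# ---------------------------------------------------------------- save/load

def save_model(model: TrainedModel, directory: str | Path) -> None:
    """On-disk bundle: ``weights.npz`` + ``model.json`` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz",
             **{n: getattr(model.params, n) for n in _PARAM_FIELDS})
    side = {
        "n_features": model.params.n_features,
        "hidden": model.params.hidden,
        "horizon": model.params.horizon,
        "use_attention": model.params.use_attention,
        "hyperparams": dataclasses.asdict(model.hyperparams),
        "seed": model.seed,
        "window_length": model.window_length,
        "stop_epoch": model.stop_epoch,
        "best_epoch": model.best_epoch,
        "history": model.history,
        "normalization": None,
    }
    if model.normalization is not None:
        side["normalization"] = {
            "strata": [list(st) for st in model.normalization.strata],
            "mean": model.normalization.mean.tolist(),
            "std": model.normalization.std.tolist(),
            "fit_years": list(model.normalization.fit_years),
        }
    (directory / "model.json").write_text(json.dumps(side, indent=2))


def load_model(directory: str | Path) -> TrainedModel:
    directory = Path(directory)
    side = json.loads((directory / "model.json").read_text())
    with np.load(directory / "weights.npz") as zf:
        arrays = {n: zf[n] for n in _PARAM_FIELDS}
    params = ModelParams(
        n_features=side["n_features"], hidden=side["hidden"],
        horizon=side["horizon"], use_attention=side["use_attention"], **arrays,
    )
    norm = None
    if side["normalization"] is not None:
        ns = side["normalization"]
        norm = NormalizationParams(
            strata=tuple(tuple(st) for st in ns["strata"]),
            mean=np.array(ns["mean"]), std=np.array(ns["std"]),
            fit_years=tuple(ns["fit_years"]),
        )
    return TrainedModel(
        params=params, hyperparams=HyperParams(**side["hyperparams"]),
        normalization=norm, history=side["history"],
        stop_epoch=side["stop_epoch"], best_epoch=side["best_epoch"],
        seed=side["seed"], window_length=side.get("window_length", 10),
    )
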