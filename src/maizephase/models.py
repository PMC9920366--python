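"""Yield regressors: bagged decision-tree ensemble and gated recurrent network.

Two model families map per-phase yield factors to final yield (kg/ha):

* a random-forest regressor (scikit-learn) with its three main
  hyperparameters tuned by cross-validated grid search on the training set;
* a stacked gated-recurrent-unit network, implemented here in NumPy
  (update/reset-gate cells, backpropagation through time, Adam, inverted
  dropout, early stopping on a validation slice), consuming one timestep
  per growth phase so the recurrence follows the crop season.

Inputs are min-max normalized column-wise; the recurrent net also normalizes
the yield target and inverts the transform at prediction, so both families
predict on the kg/ha scale. Feature importance is computed model-agnostically
as mean decrease of held-out R² under column permutation.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold

from .errors import ConfigurationError, InputError
from .features import PhaseFeatureMatrix, minmax_normalize

__all__ = [
    "SplitSpec",
    "TreeEnsembleConfig",
    "RecurrentNetConfig",
    "TrainedModel",
    "split_data",
    "train_tree_ensemble",
    "train_recurrent",
    "predict",
    "importance",
]


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition: 9:1 random by default; optional grouping keeps
    all scenarios of a weather site-year on one side (leakage probe)."""

    train_fraction: float = 0.9
    seed: int = 0
    grouping: str = "random"  # or "by_site_year"

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must lie in (0, 1)")
        if self.grouping not in ("random", "by_site_year"):
            raise ConfigurationError("grouping must be 'random' or 'by_site_year'")


def split_data(matrix, spec: SplitSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive, seeded train/test partition of the feature rows."""
    frame = matrix.frame if isinstance(matrix, PhaseFeatureMatrix) else matrix
    n = len(frame)
    if n < 10:
        raise InputError("splitting needs at least 10 rows")
    rng = np.random.default_rng(spec.seed)
    if spec.grouping == "random":
        perm = rng.permutation(n)
        n_train = int(round(spec.train_fraction * n))
        train_idx, test_idx = perm[:n_train], perm[n_train:]
    else:
        keys = list(zip(frame["site"], frame["year"]))
        groups = sorted(set(keys))
        if len(groups) < 2:
            raise ConfigurationError(
                "by_site_year grouping impossible: only one site-year group"
            )
        order = rng.permutation(len(groups))
        sizes = pd.Series(keys).value_counts()
        train_groups, filled = [], 0
        target = spec.train_fraction * n
        for gi in order:
            g = groups[gi]
            if filled < target:
                train_groups.append(g)
                filled += sizes[g]
        in_train = np.array([k in set(train_groups) for k in keys])
        train_idx = np.nonzero(in_train)[0]
        test_idx = np.nonzero(~in_train)[0]
        if len(test_idx) == 0:  # keep the partition exhaustive and disjoint
            g = train_groups.pop()
            in_train = np.array([k in set(train_groups) for k in keys])
            train_idx = np.nonzero(in_train)[0]
            test_idx = np.nonzero(~in_train)[0]
    return frame.iloc[np.sort(train_idx)].copy(), frame.iloc[np.sort(test_idx)].copy()


@dataclass(frozen=True)
class TreeEnsembleConfig:
    n_estimators_grid: tuple = (100, 300)
    max_depth_grid: tuple = (8, 16, None)
    max_features_grid: tuple = ("sqrt", 1 / 3, 1.0)
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if not self.n_estimators_grid or not self.max_depth_grid or not self.max_features_grid:
            raise ConfigurationError("hyperparameter grids must be nonempty")
        if any(n <= 0 for n in self.n_estimators_grid):
            raise ConfigurationError("n_estimators_grid entries must be positive")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")


@dataclass(frozen=True)
class RecurrentNetConfig:
    n_layers: int = 2
    units: int = 64
    dense_units: int = 32
    epochs: int = 500
    batch_size: int = 128
    dropout: float = 0.1
    learning_rate: float = 2.5e-3
    seed: int = 0
    val_fraction: float = 0.1
    patience: int = 60
    #: halve the learning rate after this many epochs without validation
    #: improvement (0 disables the decay)
    lr_plateau: int = 15
    min_learning_rate: float = 1e-4

    def __post_init__(self):
        if self.units <= 0 or self.n_layers <= 0:
            raise ConfigurationError("units and n_layers must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must lie in [0, 1)")


@dataclass
class TrainedModel:
    """Fitted regressor plus everything needed to reproduce its predictions:
    normalization bounds per column, feature layout, seeds and data hash."""

    kind: str  # "tree_ensemble" | "recurrent"
    inner: object
    feature_columns: list[str]
    x_bounds: dict[str, tuple[float, float]]
    y_bounds: tuple[float, float] | None
    layout: list[tuple[str, list[str]]] | None = None  # recurrent sequence spec
    metadata: dict = field(default_factory=dict)

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        return predict(self, rows)


def _normalize_columns(frame: pd.DataFrame, columns: list[str],
                       bounds: dict[str, tuple[float, float]] | None = None):
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise InputError(f"feature layout mismatch, missing columns: {missing}")
    out = np.empty((len(frame), len(columns)))
    fitted = {}
    for j, c in enumerate(columns):
        lo, hi = bounds[c] if bounds else (None, None)
        out[:, j], lo, hi = minmax_normalize(frame[c].to_numpy(float), lo, hi)
        if bounds:
            out[:, j] = np.clip(out[:, j], 0.0, 1.0)
        fitted[c] = (lo, hi)
    return out, fitted


def _data_hash(frame: pd.DataFrame) -> str:
    return f"{int(pd.util.hash_pandas_object(frame, index=False).sum()):x}"


def _r2(actual: np.ndarray, predicted: np.ndarray) -> float:
    ss_res = float(np.sum((actual - predicted) ** 2))
    ss_tot = float(np.sum((actual - actual.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# Tree ensemble
# ---------------------------------------------------------------------------

def train_tree_ensemble(train: pd.DataFrame, feature_columns: list[str],
                        config: TreeEnsembleConfig = TreeEnsembleConfig(),
                        target: str = "yield") -> TrainedModel:
    """Grid-searched random forest; the best grid point is refitted on the
    full training set. The forest fits the raw kg/ha target (trees are
    scale-invariant); inputs are min-max normalized."""
    if len(train) == 0:
        raise InputError("training set is empty")
    y = train[target].to_numpy(float)
    if np.std(y) == 0:
        raise InputError("degenerate target: zero variance")
    x, bounds = _normalize_columns(train, feature_columns)
    grid = {
        "n_estimators": list(config.n_estimators_grid),
        "max_depth": list(config.max_depth_grid),
        "max_features": list(config.max_features_grid),
    }
    cv = KFold(n_splits=min(config.cv_folds, len(train)), shuffle=True,
               random_state=config.seed)
    search = GridSearchCV(
        RandomForestRegressor(random_state=config.seed, n_jobs=1),
        grid, cv=cv, scoring="neg_mean_squared_error", n_jobs=1, refit=True,
    )
    search.fit(x, y)
    return TrainedModel(
        kind="tree_ensemble",
        inner=search.best_estimator_,
        feature_columns=list(feature_columns),
        x_bounds=bounds,
        y_bounds=None,
        metadata={
            "config": config,
            "best_params": search.best_params_,
            "data_hash": _data_hash(train[feature_columns + [target]]),
        },
    )


# ---------------------------------------------------------------------------
# Gated recurrent network (NumPy implementation)
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _init_gru_params(rng, n_layers: int, units: int, n_features: int,
                     dense_units: int = 0,
                     dtype=np.float32) -> dict[str, np.ndarray]:
    def glorot(fan_in, fan_out):
        s = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-s, s, (fan_in, fan_out)).astype(dtype)

    params: dict[str, np.ndarray] = {}
    f_in = n_features
    for layer in range(n_layers):
        for gate in ("z", "r", "c"):
            params[f"l{layer}_Wx{gate}"] = glorot(f_in, units)
            params[f"l{layer}_Wh{gate}"] = glorot(units, units)
            params[f"l{layer}_b{gate}"] = np.zeros(units, dtype=dtype)
        f_in = units
    if dense_units:
        params["dense_w"] = glorot(units, dense_units)
        params["dense_b"] = np.zeros(dense_units, dtype=dtype)
        params["head_w"] = glorot(dense_units, 1)[:, 0]
    else:
        params["head_w"] = glorot(units, 1)[:, 0]
    params["head_b"] = np.zeros(1, dtype=dtype)
    return params


def _gru_forward(params, x, n_layers, units, dropout=0.0, rng=None):
    """Forward pass; returns predictions and caches for backprop.

    x has shape (batch, timesteps, features); dropout (inverted) is applied
    to each recurrent layer's output sequence during training only.
    """
    batch, steps, _ = x.shape
    inp = x
    caches = []
    for layer in range(n_layers):
        wxz = params[f"l{layer}_Wxz"]; whz = params[f"l{layer}_Whz"]; bz = params[f"l{layer}_bz"]
        wxr = params[f"l{layer}_Wxr"]; whr = params[f"l{layer}_Whr"]; br = params[f"l{layer}_br"]
        wxc = params[f"l{layer}_Wxc"]; whc = params[f"l{layer}_Whc"]; bc = params[f"l{layer}_bc"]
        h = np.zeros((batch, units))
        steps_cache = []
        hs = np.empty((batch, steps, units))
        for t in range(steps):
            xt = inp[:, t, :]
            z = _sigmoid(xt @ wxz + h @ whz + bz)
            r = _sigmoid(xt @ wxr + h @ whr + br)
            c = np.tanh(xt @ wxc + (r * h) @ whc + bc)
            h_new = (1.0 - z) * h + z * c
            steps_cache.append((xt, h, z, r, c))
            h = h_new
            hs[:, t, :] = h
        mask = None
        if dropout > 0.0 and rng is not None:
            mask = (rng.random(hs.shape) >= dropout) / (1.0 - dropout)
            hs = hs * mask
        caches.append((steps_cache, mask))
        inp = hs
    h_last = inp[:, -1, :]
    if "dense_w" in params:
        pre = h_last @ params["dense_w"] + params["dense_b"]
        hidden = np.maximum(pre, 0.0)  # ReLU dense head
        yhat = hidden @ params["head_w"] + params["head_b"][0]
        head_cache = (h_last, pre, hidden)
    else:
        yhat = h_last @ params["head_w"] + params["head_b"][0]
        head_cache = (h_last, None, None)
    return yhat, (inp, head_cache), caches


def _gru_backward(params, x, y, n_layers, units, dropout=0.0, rng=None):
    """MSE loss and full-parameter gradients by backprop through time."""
    batch, steps, _ = x.shape
    yhat, (top, head_cache), caches = _gru_forward(params, x, n_layers, units,
                                                   dropout, rng)
    err = yhat - y
    loss = float(np.mean(err ** 2))
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    dy = 2.0 * err / batch
    h_last, pre, hidden = head_cache
    if "dense_w" in params:
        grads["head_w"] = hidden.T @ dy
        grads["head_b"] = np.array([dy.sum()])
        d_hidden = dy[:, None] * params["head_w"][None, :]
        d_pre = d_hidden * (pre > 0)
        grads["dense_w"] = h_last.T @ d_pre
        grads["dense_b"] = d_pre.sum(axis=0)
        d_h_last = d_pre @ params["dense_w"].T
    else:
        grads["head_w"] = h_last.T @ dy
        grads["head_b"] = np.array([dy.sum()])
        d_h_last = dy[:, None] * params["head_w"][None, :]
    d_out = np.zeros((batch, steps, units))
    d_out[:, -1, :] = d_h_last
    for layer in range(n_layers - 1, -1, -1):
        steps_cache, mask = caches[layer]
        if mask is not None:
            d_out = d_out * mask
        wxz = params[f"l{layer}_Wxz"]; whz = params[f"l{layer}_Whz"]
        wxr = params[f"l{layer}_Wxr"]; whr = params[f"l{layer}_Whr"]
        wxc = params[f"l{layer}_Wxc"]; whc = params[f"l{layer}_Whc"]
        f_in = wxz.shape[0]
        dx_seq = np.zeros((batch, steps, f_in))
        dh_carry = np.zeros((batch, units))
        for t in range(steps - 1, -1, -1):
            xt, h_prev, z, r, c = steps_cache[t]
            dh = d_out[:, t, :] + dh_carry
            dz = dh * (c - h_prev)
            daz = dz * z * (1.0 - z)
            dc = dh * z
            dac = dc * (1.0 - c * c)
            g = dac @ whc.T
            dr = g * h_prev
            dar = dr * r * (1.0 - r)
            dh_carry = dh * (1.0 - z) + daz @ whz.T + dar @ whr.T + g * r
            dx_seq[:, t, :] = daz @ wxz.T + dar @ wxr.T + dac @ wxc.T
            grads[f"l{layer}_Wxz"] += xt.T @ daz
            grads[f"l{layer}_Whz"] += h_prev.T @ daz
            grads[f"l{layer}_bz"] += daz.sum(axis=0)
            grads[f"l{layer}_Wxr"] += xt.T @ dar
            grads[f"l{layer}_Whr"] += h_prev.T @ dar
            grads[f"l{layer}_br"] += dar.sum(axis=0)
            grads[f"l{layer}_Wxc"] += xt.T @ dac
            grads[f"l{layer}_Whc"] += (r * h_prev).T @ dac
            grads[f"l{layer}_bc"] += dac.sum(axis=0)
        d_out = dx_seq
    return loss, grads


class _GRUNet:
    """Stacked GRU regressor trained with Adam and early stopping."""

    def __init__(self, n_features: int, config: RecurrentNetConfig):
        self.config = config
        self.n_features = n_features
        rng = np.random.default_rng(config.seed)
        self.params = _init_gru_params(rng, config.n_layers, config.units,
                                       n_features, config.dense_units)
        self._train_rng = rng

    def fit(self, x: np.ndarray, y: np.ndarray) -> dict:
        cfg = self.config
        rng = self._train_rng
        x = x.astype(np.float32)
        y = y.astype(np.float32)
        n = len(x)
        n_val = max(1, int(round(cfg.val_fraction * n))) if n >= 10 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        x_tr, y_tr = x[tr_idx], y[tr_idx]
        x_val, y_val = x[val_idx], y[val_idx]

        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(v) for k, v in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_val = np.inf
        best_params = copy.deepcopy(self.params)
        stale = 0
        lr_stale = 0
        lr = cfg.learning_rate
        history = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(x_tr))
            for start in range(0, len(x_tr), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                _, grads = _gru_backward(
                    self.params, x_tr[idx], y_tr[idx], cfg.n_layers, cfg.units,
                    dropout=cfg.dropout, rng=rng,
                )
                step += 1
                for k in self.params:
                    m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                    v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                    m_hat = m[k] / (1 - beta1 ** step)
                    v_hat = v[k] / (1 - beta2 ** step)
                    self.params[k] -= lr * m_hat / (np.sqrt(v_hat) + eps)
            if n_val:
                val_pred, _, _ = _gru_forward(
                    self.params, x_val, cfg.n_layers, cfg.units)
                val_loss = float(np.mean((val_pred - y_val) ** 2))
                history.append(val_loss)
                if val_loss < best_val - 1e-7:
                    best_val = val_loss
                    best_params = copy.deepcopy(self.params)
                    stale = 0
                    lr_stale = 0
                else:
                    stale += 1
                    lr_stale += 1
                    if stale >= cfg.patience:
                        break
                    if (cfg.lr_plateau and lr_stale >= cfg.lr_plateau
                            and lr > cfg.min_learning_rate):
                        lr = max(cfg.min_learning_rate, 0.5 * lr)
                        lr_stale = 0
        if n_val:
            self.params = best_params
        return {"val_history": history, "best_val_mse": best_val}

    def predict(self, x: np.ndarray) -> np.ndarray:
        yhat, _, _ = _gru_forward(self.params, x.astype(np.float32),
                                  self.config.n_layers, self.config.units)
        return yhat.astype(np.float64)


def _sequence_tensor(frame: pd.DataFrame, layout, bounds=None):
    """Build the (n, timesteps, features) tensor from flat feature columns."""
    all_cols = [c for _, cols in layout for c in cols]
    flat, fitted = _normalize_columns(frame, all_cols, bounds)
    steps = len(layout)
    width = len(layout[0][1])
    x = flat.reshape(len(frame), steps, width)
    return x, fitted


def train_recurrent(train: pd.DataFrame, layout: list[tuple[str, list[str]]],
                    config: RecurrentNetConfig = RecurrentNetConfig(),
                    target: str = "yield") -> TrainedModel:
    """Train the gated recurrent regressor over a per-phase sequence layout.

    ``layout`` lists (phase, feature columns) per timestep, each step with
    the same number of features. A single-step layout degenerates to a
    feedforward fit (warned, still runs). Inputs and target are min-max
    normalized; predictions are inverted back to kg/ha.
    """
    if len(train) == 0:
        raise InputError("training set is empty")
    widths = {len(cols) for _, cols in layout}
    if len(widths) != 1:
        raise ConfigurationError("every sequence step must carry the same feature count")
    if len(layout) < 2:
        warnings.warn("sequence length < 2: recurrent model degenerates to a "
                      "feedforward fit")
    y_raw = train[target].to_numpy(float)
    if np.std(y_raw) == 0:
        raise InputError("degenerate target: zero variance")
    x, x_bounds = _sequence_tensor(train, layout)
    y, y_lo, y_hi = minmax_normalize(y_raw)
    net = _GRUNet(n_features=len(layout[0][1]), config=config)
    fit_info = net.fit(x, y)
    return TrainedModel(
        kind="recurrent",
        inner=net,
        feature_columns=[c for _, cols in layout for c in cols],
        x_bounds=x_bounds,
        y_bounds=(y_lo, y_hi),
        layout=[(p, list(cols)) for p, cols in layout],
        metadata={
            "config": config,
            "fit": fit_info,
            "data_hash": _data_hash(train[[c for _, cols in layout for c in cols] + [target]]),
        },
    )


# ---------------------------------------------------------------------------
# Prediction and importance
# ---------------------------------------------------------------------------

def predict(model: TrainedModel, rows: pd.DataFrame) -> np.ndarray:
    """De-normalized yield predictions in kg/ha; deterministic given model."""
    if model.kind == "tree_ensemble":
        x, _ = _normalize_columns(rows, model.feature_columns, model.x_bounds)
        return model.inner.predict(x)
    x, _ = _sequence_tensor(rows, model.layout, model.x_bounds)
    y_norm = model.inner.predict(x)
    lo, hi = model.y_bounds
    return y_norm * (hi - lo) + lo if hi > lo else np.full(len(rows), lo)


def importance(model: TrainedModel, held_out: pd.DataFrame, seed: int = 0,
               n_repeats: int = 10, target: str = "yield") -> dict[str, float]:
    """Permutation importance: mean held-out R² drop per feature column,
    negative drops floored at zero, normalized to sum to one."""
    if len(held_out) == 0:
        raise InputError("held-out set is empty")
    rng = np.random.default_rng(seed)
    y = held_out[target].to_numpy(float)
    base = _r2(y, predict(model, held_out))
    drops = {}
    for col in model.feature_columns:
        vals = []
        for _ in range(n_repeats):
            shuffled = held_out.copy()
            shuffled[col] = rng.permutation(shuffled[col].to_numpy())
            vals.append(base - _r2(y, predict(model, shuffled)))
        drops[col] = max(0.0, float(np.mean(vals)))
    total = sum(drops.values())
    if total <= 0:
        warnings.warn("no feature permutation reduced accuracy; returning "
                      "uniform importances")
        return {c: 1.0 / len(drops) for c in drops}
    return {c: v / total for c, v in drops.items()}
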