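"""From-scratch multilayer-perceptron ensemble for mSCL regression.

The predictive model is a fixed 3–7–9–1 fully connected network: three
normalized trait predictors in, tanh activations on the two hidden layers,
and a linear output neuron carrying the predicted mean percent SCL change
(the outcome spans roughly −9 to 6, so a bounded output activation would be
unable to represent it).  Each of k cross-validation folds trains its own
copy with full-batch Adam and early stopping on validation RMSE, restoring
the best-validation weights; the final predictor is the convex combination
of the fold networks with weights proportional to the inverse of each fold's
validation loss.

Everything here — forward pass, backpropagation, Adam, the fold logic — is
implemented directly on numpy arrays so that training is deterministic given
(data, config, seed) and gradients can be verified against finite
differences.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

#: fixed architecture: input, two hidden layers, output
LAYER_SIZES = (3, 7, 9, 1)


@dataclass
class MLPWeights:
    """Weight matrices (7×3, 9×7, 1×9) and bias vectors (7, 9, 1)."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    W3: np.ndarray
    b3: np.ndarray

    def __post_init__(self) -> None:
        shapes = {"W1": (7, 3), "b1": (7,), "W2": (9, 7), "b2": (9,),
                  "W3": (1, 9), "b3": (1,)}
        for name, want in shapes.items():
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != want:
                raise ValueError(f"{name} must have shape {want}, got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")
            setattr(self, name, arr)

    def params(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3]

    def copy(self) -> "MLPWeights":
        return MLPWeights(*(p.copy() for p in self.params()))


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters for one ensemble fit.

    Defaults: full-batch Adam at step size 1e-3 with standard decay rates,
    up to 5,000 epochs, early stopping after 100 epochs without validation
    improvement, k = 10 folds.
    """

    max_epochs: int = 5000
    patience: int = 100
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    k: int = 10
    seed: int = 0
    weight_loss: str = "validation"  # or "full": losses used for ensemble weights

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.weight_loss not in ("validation", "full"):
            raise ValueError("weight_loss must be 'validation' or 'full'")


@dataclass
class FoldModel:
    """Best-validation weight snapshot of one fold."""

    weights: MLPWeights
    val_loss: float
    epochs_run: int


@dataclass
class EnsembleModel:
    """k fold networks with normalized inverse-loss weights."""

    folds: list[FoldModel]
    ensemble_weights: np.ndarray
    config: TrainConfig


@dataclass(frozen=True)
class FitMetrics:
    """RMSE and coefficient of determination on a named split."""

    rmse: float
    r2: float
    split: str = "all"


def init_weights(seed: int, scheme: str = "glorot") -> MLPWeights:
    """Deterministic initial weights; Glorot-uniform by default."""
    rng = np.random.default_rng(seed)
    mats = []
    for fan_out, fan_in in ((7, 3), (9, 7), (1, 9)):
        if scheme == "glorot":
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            W = rng.uniform(-bound, bound, size=(fan_out, fan_in))
        elif scheme == "zeros":
            W = np.zeros((fan_out, fan_in))
        else:
            raise ValueError(f"unknown init scheme {scheme!r}")
        mats.append(W)
        mats.append(np.zeros(fan_out))
    return MLPWeights(*mats)


def _forward_full(w: MLPWeights, X: np.ndarray):
    """Forward pass keeping hidden activations (needed for backprop)."""
    h1 = np.tanh(X @ w.W1.T + w.b1)
    h2 = np.tanh(h1 @ w.W2.T + w.b2)
    y = h2 @ w.W3.T + w.b3
    return h1, h2, y[:, 0]


def forward(w: MLPWeights, x) -> float | np.ndarray:
    """Network output for a single 3-vector (scalar) or an (n, 3) batch."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != 3:
        raise ValueError(f"expected 3 predictors, got shape {x.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite predictor values")
    _, _, y = _forward_full(w, X)
    return float(y[0]) if single else y


def gradient(w: MLPWeights, X: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Analytic gradient of the mean-squared error over the batch.

    MSE is the training surrogate for RMSE (same minimizer, smooth at zero
    error).  Returned in the order of ``MLPWeights.params()``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty batch")
    h1, h2, yhat = _forward_full(w, X)
    # dL/dyhat for L = mean((yhat - y)^2)
    delta3 = (2.0 / n) * (yhat - y)                      # (n,)
    gW3 = delta3[None, :] @ h2                           # (1, 9)
    gb3 = np.array([delta3.sum()])
    delta2 = (delta3[:, None] * w.W3) * (1.0 - h2 ** 2)  # (n, 9)
    gW2 = delta2.T @ h1
    gb2 = delta2.sum(axis=0)
    delta1 = (delta2 @ w.W2) * (1.0 - h1 ** 2)           # (n, 7)
    gW1 = delta1.T @ X
    gb1 = delta1.sum(axis=0)
    return [gW1, gb1, gW2, gb2, gW3, gb3]


def mse(w: MLPWeights, X: np.ndarray, y: np.ndarray) -> float:
    yhat = forward(w, np.atleast_2d(X))
    return float(np.mean((yhat - np.asarray(y, dtype=float).ravel()) ** 2))


def rmse_of(w: MLPWeights, X: np.ndarray, y: np.ndarray) -> float:
    return float(np.sqrt(mse(w, X, y)))


@dataclass
class AdamState:
    """First/second moment accumulators and the step counter."""

    m: list[np.ndarray]
    v: list[np.ndarray]
    t: int = 0

    @classmethod
    def for_weights(cls, w: MLPWeights) -> "AdamState":
        return cls(m=[np.zeros_like(p) for p in w.params()],
                   v=[np.zeros_like(p) for p in w.params()])


def adam_step(w: MLPWeights, state: AdamState, grads: list[np.ndarray],
              config: TrainConfig) -> None:
    """One in-place Adam update with bias correction."""
    state.t += 1
    b1, b2 = config.beta1, config.beta2
    lr, eps = config.learning_rate, config.eps
    for p, m, v, g in zip(w.params(), state.m, state.v, grads):
        m *= b1
        m += (1 - b1) * g
        v *= b2
        v += (1 - b2) * g ** 2
        mhat = m / (1 - b1 ** state.t)
        vhat = v / (1 - b2 ** state.t)
        p -= lr * mhat / (np.sqrt(vhat) + eps)


def kfold_split(n: int, k: int, seed: int = 0) -> list[np.ndarray]:
    """k disjoint validation index sets whose union is range(n).

    Indices are shuffled deterministically; set sizes differ by at most one
    (n = 30, k = 10 gives ten sets of 3, i.e. 27 training / 3 validation).
    """
    if n < k:
        raise ValueError(f"need n >= k, got n={n}, k={k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def train_fold(X_train: np.ndarray, y_train: np.ndarray, X_val: np.ndarray,
               y_val: np.ndarray, config: TrainConfig, seed: int) -> FoldModel:
    """Full-batch Adam with early stopping on validation RMSE.

    Stops after ``config.patience`` epochs without strict improvement and
    returns the weights from the best-validation epoch.
    """
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("training and validation splits must be non-empty")
    w = init_weights(seed)
    state = AdamState.for_weights(w)
    best = w.copy()
    best_loss = rmse_of(w, X_val, y_val)
    since_improvement = 0
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        grads = gradient(w, X_train, y_train)
        adam_step(w, state, grads, config)
        val = rmse_of(w, X_val, y_val)
        if not np.isfinite(val):
            raise FloatingPointError(
                f"non-finite validation loss at epoch {epoch}; "
                "lower the learning rate or rescale the data")
        if val < best_loss:
            best_loss = val
            best = w.copy()
            since_improvement = 0
        else:
            since_improvement += 1
            if since_improvement >= config.patience:
                break
    return FoldModel(weights=best, val_loss=best_loss, epochs_run=epoch)


def ensemble_weights_from_losses(losses, eps: float = 1e-12) -> np.ndarray:
    """Normalized inverse-loss weights; an epsilon floor guards zero losses."""
    inv = 1.0 / np.maximum(np.asarray(losses, dtype=float), eps)
    return inv / inv.sum()


def train_ensemble(X: np.ndarray, y: np.ndarray, config: TrainConfig | None = None,
                   ) -> EnsembleModel:
    """k-fold training of the fixed architecture plus inverse-loss averaging.

    Each fold sees its own train/validation split of the rows and a fold
    seed derived from ``config.seed``; ensemble weights come from validation
    RMSE by default (``config.weight_loss='full'`` uses whole-dataset RMSE
    instead).
    """
    config = config if config is not None else TrainConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < config.k:
        raise ValueError(f"need at least k={config.k} rows, got {n}")
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(config.seed).spawn(config.k + 1)]
    val_sets = kfold_split(n, config.k, seed=seeds[0])
    folds = []
    for fold_idx, val_idx in enumerate(val_sets):
        train_idx = np.setdiff1d(np.arange(n), val_idx)
        folds.append(train_fold(X[train_idx], y[train_idx], X[val_idx], y[val_idx],
                                config, seed=seeds[fold_idx + 1]))
    if config.weight_loss == "validation":
        losses = [f.val_loss for f in folds]
    else:
        losses = [rmse_of(f.weights, X, y) for f in folds]
    return EnsembleModel(folds=folds,
                         ensemble_weights=ensemble_weights_from_losses(losses),
                         config=config)


def predict(ensemble: EnsembleModel, x) -> float | np.ndarray:
    """Inverse-loss-weighted average of the fold predictions."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    preds = np.stack([forward(f.weights, X) for f in ensemble.folds])
    out = ensemble.ensemble_weights @ preds
    return float(out[0]) if single else out


def evaluate(ensemble: EnsembleModel, X, y, split: str = "all") -> FitMetrics:
    """RMSE and standard coefficient of determination (1 − SSres/SStot)."""
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("no rows to evaluate")
    yhat = predict(ensemble, np.atleast_2d(X))
    res = y - yhat
    ss_res = float(np.sum(res ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return FitMetrics(rmse=float(np.sqrt(np.mean(res ** 2))), r2=r2, split=split)


# --- serialization ----------------------------------------------------------

def ensemble_to_dict(ensemble: EnsembleModel) -> dict:
    return {
        "layer_sizes": list(LAYER_SIZES),
        "config": asdict(ensemble.config),
        "ensemble_weights": ensemble.ensemble_weights.tolist(),
        "folds": [
            {"val_loss": f.val_loss, "epochs_run": f.epochs_run,
             "weights": {name: getattr(f.weights, name).tolist()
                         for name in ("W1", "b1", "W2", "b2", "W3", "b3")}}
            for f in ensemble.folds
        ],
    }


def ensemble_from_dict(payload: dict) -> EnsembleModel:
    if tuple(payload["layer_sizes"]) != LAYER_SIZES:
        raise ValueError(f"unsupported layer sizes {payload['layer_sizes']}")
    folds = [FoldModel(weights=MLPWeights(**{k: np.asarray(v)
                                             for k, v in f["weights"].items()}),
                       val_loss=f["val_loss"], epochs_run=f["epochs_run"])
             for f in payload["folds"]]
    return EnsembleModel(folds=folds,
                         ensemble_weights=np.asarray(payload["ensemble_weights"]),
                         config=TrainConfig(**payload["config"]))


def save_ensemble(ensemble: EnsembleModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(ensemble_to_dict(ensemble), fh)


def load_ensemble(path) -> EnsembleModel:
    with open(path) as fh:
        return ensemble_from_dict(json.load(fh))
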