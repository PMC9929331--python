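"""Interpretation of a trained ensemble: surfaces, terciles, importances.

A trained ensemble is read out three ways:

* **Prediction surfaces** — the predicted mSCL over a grid of two predictors
  with the third pinned at each of its tercile midpoints (the slicing scheme
  behind the study's response-surface figures).
* **Impact matrices** — the normalized predictor cube is partitioned into
  3³ = 27 tercile boxes; dense-grid predictions inside each box are
  classified low / moderate / high against the mSCL tercile thresholds and
  the box is labelled with the majority class.  This is an explicit
  operationalization of a qualitative figure reading, and is reported as
  such.
* **Variable importance** — either permutation importance (increase in RMSE
  when one predictor's column is shuffled) or a connection-weights method
  (Garson's algorithm chained through both hidden layers); both are
  normalized to percentages summing to 100 per model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mlp import EnsembleModel, forward, predict

#: mSCL class thresholds reported for the study cohort (33.3rd/66.7th percentiles)
DEFAULT_THRESHOLDS = (-4.0, 1.0)

CLASSES = ("low", "moderate", "high")


def classify_mscl(value: float, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
                  ) -> str:
    """Classify an mSCL value as low / moderate / high.

    Strictly above the upper threshold is high, strictly below the lower is
    low; boundary values are moderate.
    """
    if not np.isfinite(value):
        raise ValueError(f"cannot classify non-finite value {value}")
    lower, upper = thresholds
    if value > upper:
        return "high"
    if value < lower:
        return "low"
    return "moderate"


def tercile_midpoints(values, *, convention: str = "median") -> np.ndarray:
    """Three representative values, one per tercile of the data.

    ``convention="median"`` (default) returns the within-tercile medians,
    i.e. the 16.67th, 50th and 83.33rd percentiles; ``"boundary-mid"``
    returns the arithmetic midpoints between consecutive tercile boundaries
    (data min/max at the ends).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"tercile midpoints need >= 3 values, got {x.size}")
    if convention == "median":
        return np.percentile(x, [100.0 / 6.0, 50.0, 500.0 / 6.0])
    if convention == "boundary-mid":
        lo, b1, b2, hi = np.percentile(x, [0.0, 100.0 / 3.0, 200.0 / 3.0, 100.0])
        return np.array([(lo + b1) / 2.0, (b1 + b2) / 2.0, (b2 + hi) / 2.0])
    raise ValueError(f"unknown midpoint convention {convention!r}")


@dataclass
class PredictionSurface:
    """Gridded ensemble predictions over two predictors with one pinned."""

    x_name: str
    y_name: str
    fixed_name: str
    fixed_value: float
    x_axis: np.ndarray
    y_axis: np.ndarray
    values: np.ndarray  # shape (len(y_axis), len(x_axis))

    def to_dataframe(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x_axis, self.y_axis)
        return pd.DataFrame({
            self.x_name: xx.ravel(),
            self.y_name: yy.ravel(),
            self.fixed_name: self.fixed_value,
            "mscl_pred": self.values.ravel(),
        })


def prediction_surface(ensemble: EnsembleModel, predictors: tuple[str, str, str],
                       varying: tuple[str, str], fixed_value: float,
                       resolution: int = 25,
                       value_range: tuple[float, float] = (-1.0, 1.0),
                       ) -> PredictionSurface:
    """Evaluate the ensemble on a regular grid with the third predictor pinned.

    ``predictors`` gives the model's input order; ``varying`` names the two
    grid axes (x, y).  All axes are in normalized [−1, 1] units.
    """
    if resolution < 2:
        raise ValueError("grid resolution must be >= 2")
    x_name, y_name = varying
    fixed_name, = (p for p in predictors if p not in varying)
    axis = np.linspace(value_range[0], value_range[1], resolution)
    xx, yy = np.meshgrid(axis, axis)
    cols = {x_name: xx.ravel(), y_name: yy.ravel(),
            fixed_name: np.full(xx.size, fixed_value)}
    X = np.column_stack([cols[p] for p in predictors])
    vals = predict(ensemble, X).reshape(resolution, resolution)
    return PredictionSurface(x_name, y_name, fixed_name, fixed_value,
                             axis, axis, vals)


def sliced_surfaces(ensemble: EnsembleModel, predictors: tuple[str, str, str],
                    predictor_values: pd.DataFrame, resolution: int = 25,
                    convention: str = "median") -> list[PredictionSurface]:
    """All three slicing layouts × three tercile midpoints of the pinned axis."""
    surfaces = []
    for fixed in predictors:
        varying = tuple(p for p in predictors if p != fixed)
        mids = tercile_midpoints(predictor_values[fixed].to_numpy(),
                                 convention=convention)
        for mid in mids:
            surfaces.append(prediction_surface(
                ensemble, predictors, varying, float(mid), resolution))
    return surfaces


def _tercile_edges(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    b1, b2 = np.percentile(x, [100.0 / 3.0, 200.0 / 3.0])
    return np.array([-1.0, b1, b2, 1.0])


def impact_matrix(ensemble: EnsembleModel, predictor_values: pd.DataFrame,
                  predictors: tuple[str, str, str],
                  thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
                  resolution: int = 7) -> pd.DataFrame:
    """Tercile-box classification of the predictor cube (27 rows).

    Per predictor, tercile boundaries are taken from the observed normalized
    values; each of the 27 boxes is probed with a ``resolution³`` grid of
    ensemble predictions, every prediction is classified against the mSCL
    ``thresholds``, and the box's class is the majority (ties broken toward
    the class of the box-mean prediction).  Rows are grouped by SCL class.
    """
    if not ensemble.folds:
        raise ValueError("ensemble has no trained folds")
    edges = {p: _tercile_edges(predictor_values[p].to_numpy()) for p in predictors}
    rows = []
    for i, lvl_a in enumerate(CLASSES):
        for j, lvl_b in enumerate(CLASSES):
            for k, lvl_c in enumerate(CLASSES):
                levels = dict(zip(predictors, (lvl_a, lvl_b, lvl_c)))
                axes = []
                for p, t in zip(predictors, (i, j, k)):
                    lo, hi = edges[p][t], edges[p][t + 1]
                    axes.append(np.linspace(lo, hi, resolution + 2)[1:-1])
                grid = np.stack(np.meshgrid(*axes), axis=-1).reshape(-1, 3)
                preds = predict(ensemble, grid)
                classes = np.array([classify_mscl(v, thresholds) for v in preds])
                fracs = {f"frac_{c}": float(np.mean(classes == c)) for c in CLASSES}
                counts = {c: int(np.sum(classes == c)) for c in CLASSES}
                top = max(counts.values())
                winners = [c for c, ct in counts.items() if ct == top]
                if len(winners) == 1:
                    label = winners[0]
                else:
                    label = classify_mscl(float(np.mean(preds)), thresholds)
                    if label not in winners:
                        label = winners[0]
                rows.append({"scl_class": label, **levels,
                             "mean_prediction": float(np.mean(preds)), **fracs})
    out = pd.DataFrame(rows)
    order = {c: i for i, c in enumerate(("high", "moderate", "low"))}
    return (out.sort_values("scl_class", key=lambda s: s.map(order), kind="stable")
            .reset_index(drop=True))


def permutation_importance(ensemble: EnsembleModel, X, y, reps: int = 20,
                           seed: int = 0) -> pd.DataFrame:
    """Permutation importance as percentages summing to 100.

    For each predictor column, the increase in RMSE when that column is
    shuffled (averaged over ``reps`` seeded permutations); negative raw
    increases are floored at zero before normalization.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    names = list(X.columns) if hasattr(X, "columns") else None
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("no rows given")
    rng = np.random.default_rng(seed)
    base = float(np.sqrt(np.mean((predict(ensemble, X) - y) ** 2)))
    raw = np.zeros(X.shape[1])
    for col in range(X.shape[1]):
        for _ in range(reps):
            Xp = X.copy()
            Xp[:, col] = rng.permutation(Xp[:, col])
            rmse_p = float(np.sqrt(np.mean((predict(ensemble, Xp) - y) ** 2)))
            raw[col] += max(rmse_p - base, 0.0)
    raw /= reps
    total = raw.sum()
    pct = raw / total * 100.0 if total > 0 else np.full(X.shape[1], 100.0 / X.shape[1])
    return pd.DataFrame({"predictor": list(names) if names is not None
                         else [f"x{c}" for c in range(X.shape[1])],
                         "importance_pct": pct,
                         "method": "permutation"})


def _garson_shares(weights) -> np.ndarray:
    """Input shares from chained absolute connection weights (sums to 1)."""
    def rownorm(M):
        A = np.abs(M)
        s = A.sum(axis=1, keepdims=True)
        s[s == 0] = 1.0
        return A / s

    R1 = rownorm(weights.W1)              # (7, 3): share of each input per h1
    R2 = rownorm(weights.W2)              # (9, 7)
    R3 = rownorm(weights.W3)              # (1, 9)
    shares = (R3 @ R2 @ R1)[0]
    total = shares.sum()
    return shares / total if total > 0 else np.full(3, 1.0 / 3.0)


def garson_importance(ensemble: EnsembleModel,
                      predictor_names=("x0", "x1", "x2")) -> pd.DataFrame:
    """Connection-weights importance, ensemble-weighted across folds.

    Garson's algorithm extended through two hidden layers: each layer's
    absolute weight matrix is row-normalized and the products chained from
    output back to the inputs; fold shares are combined with the ensemble
    weights and expressed as percentages.
    """
    if not ensemble.folds:
        raise ValueError("ensemble has no trained folds")
    shares = np.zeros(3)
    for f, ew in zip(ensemble.folds, ensemble.ensemble_weights):
        shares += ew * _garson_shares(f.weights)
    return pd.DataFrame({"predictor": list(predictor_names),
                         "importance_pct": shares / shares.sum() * 100.0,
                         "method": "garson"})


def partial_dependence(ensemble: EnsembleModel, X, col: int,
                       grid: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """1-D partial dependence: average prediction as one predictor sweeps.

    Returns ``(grid, pd_values)``; used to check that fitted effect
    directions match planted coefficient signs.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if grid is None:
        grid = np.linspace(-1.0, 1.0, 11)
    out = np.empty(grid.size)
    for i, g in enumerate(grid):
        Xg = X.copy()
        Xg[:, col] = g
        out[i] = float(np.mean(predict(ensemble, Xg)))
    return grid, out


def plot_surface(surface: PredictionSurface, path,
                 thresholds: tuple[float, float] = DEFAULT_THRESHOLDS) -> None:
    """Render a surface heat-map (red/orange high, yellow/green moderate, blue low)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3.8))
    span = max(abs(float(surface.values.min())), abs(float(surface.values.max())),
               abs(thresholds[0]), abs(thresholds[1]))
    im = ax.pcolormesh(surface.x_axis, surface.y_axis, surface.values,
                       cmap="RdYlBu_r", vmin=-span, vmax=span, shading="auto")
    cs = ax.contour(surface.x_axis, surface.y_axis, surface.values,
                    levels=list(thresholds), colors="k", linewidths=0.7)
    ax.clabel(cs, fmt="%g")
    ax.set_xlabel(surface.x_name)
    ax.set_ylabel(surface.y_name)
    ax.set_title(f"{surface.fixed_name} = {surface.fixed_value:.2f}", fontsize=9)
    fig.colorbar(im, ax=ax, label="predicted mSCL (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
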