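"""Predicting human recognition accuracy at untested PIQ levels.

Human psychophysics covers only 9 of the 25 PIQ levels; the recognition
models cover all 25.  Given the strong model-human correlation on the
9 shared levels, two mappings extrapolate human accuracy to the 16
untested levels:

* a **linear map** — least-squares regression of human mean accuracy (y)
  on model mean accuracy (x) over the 9 tested levels, applied to the
  model's accuracy at untested levels (clipped to [0, 100]);
* a **shallow nonlinear predictor** — a single-hidden-layer network whose
  input is a model instance's per-condition accuracy 5-vector at one PIQ
  level concatenated with that instance's Pearson correlation with one
  subject (6 inputs), and whose output is the subject's per-condition
  accuracy 5-vector (hidden width 3 for square-bitmap phosphenes, 4 for
  Gaussian ones; mean squared error; Adam; batch 16; 3000 epochs; 9:1
  train-validation split).

A dip detector flags nonlinear estimates that fall below both grid
neighbors — the symptom that justified preferring the linear map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import nn
from .evaluation import pearson_correlation
from .phosphenes import PIQLevel, piq_grid

N_CONDITIONS = 5  # human-protocol facial conditions
PIQ_KEYS = ["pixels", "grayscales"]


@dataclass(frozen=True)
class LinearMap:
    """Fitted model-to-human accuracy regression over the tested levels."""

    slope: float
    intercept: float
    r: float
    k: int
    mode: str
    tested_levels: tuple

    def __call__(self, x):
        return np.clip(self.slope * np.asarray(x, dtype=float) + self.intercept, 0.0, 100.0)


def _level_index(table: pd.DataFrame) -> pd.Series:
    return pd.Series(
        table["mean"].to_numpy(),
        index=pd.MultiIndex.from_frame(table[PIQ_KEYS]),
    )


def fit_linear_map(
    model_table: pd.DataFrame,
    human_table: pd.DataFrame,
    k: int = 1,
    mode: str = "ngb",
) -> LinearMap:
    """Least-squares line through the (model mean, human mean) pairs.

    Both tables are tidy accuracy tables (pixels, grayscales, mean, ...)
    over the same tested PIQ levels, in percent.
    """
    mx = _level_index(model_table)
    hy = _level_index(human_table)
    missing = sorted(set(mx.index) ^ set(hy.index))
    if missing:
        raise ValueError(f"tables disagree on PIQ levels: {missing}")
    keys = sorted(mx.index)
    x = mx.loc[keys].to_numpy()
    y = hy.loc[keys].to_numpy()
    fit = stats.linregress(x, y)
    return LinearMap(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=pearson_correlation(x, y),
        k=k,
        mode=mode,
        tested_levels=tuple(keys),
    )


def predict_linear(lmap: LinearMap, model_table: pd.DataFrame) -> pd.DataFrame:
    """Apply a fitted linear map to model accuracies at untested levels.

    Returns a table of estimated human accuracies (percent, clipped to
    [0, 100]) with provenance column "linear_estimate".  Raises if any
    level overlaps the levels the map was fitted on.
    """
    mx = _level_index(model_table)
    overlap = sorted(set(mx.index) & set(lmap.tested_levels))
    if overlap:
        raise ValueError(f"untested levels overlap the fitted levels: {overlap}")
    out = model_table[PIQ_KEYS].copy()
    out["mean"] = lmap(mx.to_numpy())
    out["k"] = lmap.k
    out["provenance"] = "linear_estimate"
    return out


def untested_levels(grid: str = "full", tested: str = "human") -> list[PIQLevel]:
    """PIQ levels in ``grid`` that the ``tested`` subset does not cover
    (the 16 levels extrapolation must fill for the full grid)."""
    tested_set = set(piq_grid(tested))
    return [piq for piq in piq_grid(grid) if piq not in tested_set]


@dataclass
class ShallowPredictorConfig:
    """Training configuration of the shallow nonlinear predictor."""

    hidden_units: int = 3  # 3 for NGB, 4 for GB
    batch_size: int = 16
    epochs: int = 3000
    train_val_split: float = 0.9
    lr: float = 1e-3
    seed: int = 0


def build_feature_table(
    model_cond_acc: pd.DataFrame,
    human_cond_acc: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble (subject x instance x PIQ) feature/target rows.

    Inputs are per-condition accuracy tables in percent with columns
    ``instance`` / ``subject``, pixels, grayscales, viewpoint_deg,
    expression, mean.  Output rows carry the instance's 5 condition
    accuracies (x0..x4), the instance-subject Pearson correlation over all
    shared (PIQ, condition) cells (x5), and the subject's 5 condition
    accuracies (y0..y4).  At the study scale — 18 subjects, 10 instances,
    9 levels — this yields 1620 rows.
    """
    cond_keys = ["viewpoint_deg", "expression"]
    m = model_cond_acc.pivot_table(
        index=["instance", *PIQ_KEYS], columns=cond_keys, values="mean", sort=True
    )
    h = human_cond_acc.pivot_table(
        index=["subject", *PIQ_KEYS], columns=cond_keys, values="mean", sort=True
    )
    if m.shape[1] != N_CONDITIONS or h.shape[1] != N_CONDITIONS:
        raise ValueError(
            f"expected {N_CONDITIONS} conditions, got {m.shape[1]} (model) / {h.shape[1]} (human)"
        )
    if list(m.columns) != list(h.columns):
        raise ValueError("model and human tables disagree on conditions")

    instances = m.index.get_level_values("instance").unique()
    subjects = h.index.get_level_values("subject").unique()
    levels = sorted(
        set(map(tuple, m.reset_index()[PIQ_KEYS].drop_duplicates().to_numpy()))
    )

    rows = []
    for inst in instances:
        mi = m.xs(inst, level="instance")
        for subj in subjects:
            hs = h.xs(subj, level="subject")
            shared = sorted(set(mi.index) & set(hs.index))
            r = pearson_correlation(
                mi.loc[shared].to_numpy().ravel(), hs.loc[shared].to_numpy().ravel()
            )
            for lv in levels:
                row = {
                    "instance": inst,
                    "subject": subj,
                    "pixels": lv[0],
                    "grayscales": lv[1],
                    "corr": r,
                }
                for j in range(N_CONDITIONS):
                    row[f"x{j}"] = mi.loc[lv].iloc[j]
                    row[f"y{j}"] = hs.loc[lv].iloc[j]
                rows.append(row)
    return pd.DataFrame(rows)


class ShallowPredictor:
    """Single-hidden-layer network: 6 inputs -> hidden -> 5 outputs."""

    def __init__(self, cfg: ShallowPredictorConfig):
        self.cfg = cfg
        self.net = nn.Sequential(
            [nn.Dense(cfg.hidden_units), nn.ReLU(), nn.Dense(N_CONDITIONS)]
        )
        self.net.init_shapes(np.random.default_rng(cfg.seed), (N_CONDITIONS + 1,))
        self.val_mse: float | None = None
        # feature/target standardization fitted from training data; the
        # public interface stays in percent
        self._x_stats: tuple[np.ndarray, np.ndarray] | None = None
        self._y_stats: tuple[np.ndarray, np.ndarray] | None = None

    @staticmethod
    def _xy(features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        x = features[[f"x{j}" for j in range(N_CONDITIONS)] + ["corr"]].to_numpy(float)
        y = features[[f"y{j}" for j in range(N_CONDITIONS)]].to_numpy(float)
        return x, y

    def fit(self, features: pd.DataFrame) -> "ShallowPredictor":
        cfg = self.cfg
        x, y = self._xy(features)
        if x.shape[1] != N_CONDITIONS + 1:
            raise ValueError("feature rows must have 6 inputs")
        self._x_stats = (x.mean(0), np.maximum(x.std(0), 1e-6))
        self._y_stats = (y.mean(0), np.maximum(y.std(0), 1e-6))
        xz = (x - self._x_stats[0]) / self._x_stats[1]
        yz = (y - self._y_stats[0]) / self._y_stats[1]
        rng = np.random.default_rng([cfg.seed, 1])
        order = rng.permutation(len(x))
        n_train = int(round(len(x) * cfg.train_val_split))
        tr, va = order[:n_train], order[n_train:]
        opt = nn.Adam(self.net.params(), lr=cfg.lr)
        for _epoch in range(cfg.epochs):
            ep_order = rng.permutation(tr)
            for s in range(0, len(ep_order), cfg.batch_size):
                idx = ep_order[s : s + cfg.batch_size]
                pred = self.net.forward(xz[idx], train=True)
                _, grad = nn.mse(pred, yz[idx])
                self.net.backward(grad)
                opt.step()
        if len(va):
            self.val_mse, _ = nn.mse(self._predict_raw(x[va]), y[va])
        return self

    def _predict_raw(self, x: np.ndarray) -> np.ndarray:
        if self._x_stats is None or self._y_stats is None:
            raise RuntimeError("predictor not fitted")
        xz = (x - self._x_stats[0]) / self._x_stats[1]
        return self.net.forward(xz) * self._y_stats[1] + self._y_stats[0]

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        x, _ = self._xy(features)
        return np.clip(self._predict_raw(x), 0.0, 100.0)


def fit_shallow_predictor(
    features: pd.DataFrame,
    cfg: ShallowPredictorConfig | None = None,
) -> ShallowPredictor:
    """Train the shallow nonlinear model-to-human predictor."""
    return ShallowPredictor(cfg or ShallowPredictorConfig()).fit(features)


def predict_shallow(
    predictor: ShallowPredictor,
    features: pd.DataFrame,
) -> pd.DataFrame:
    """Estimate per-condition human accuracies at untested levels.

    ``features`` rows are built exactly as in training (the y columns may
    be filled with NaN).  Predictions for each (subject, instance) pair
    are clipped to [0, 100] and averaged per PIQ level into a tidy table
    with provenance "shallow_estimate".
    """
    preds = predictor.predict(features)
    out = features[[*PIQ_KEYS]].copy()
    out["mean_conditions"] = preds.mean(axis=1)
    table = (
        out.groupby(PIQ_KEYS, observed=True)["mean_conditions"]
        .mean()
        .reset_index()
        .rename(columns={"mean_conditions": "mean"})
    )
    table["provenance"] = "shallow_estimate"
    return table


def flag_dips(estimates: pd.DataFrame, margin: float = 0.0) -> pd.DataFrame:
    """Flag estimates lower than both PIQ-grid neighbors.

    ``estimates`` is a tidy table (pixels, grayscales, mean) over any
    subset of the 5 x 5 grid.  A cell dips if its value is more than
    ``margin`` below both of its neighbors along the resolution axis at
    fixed gray depth, or along the gray-depth axis at fixed resolution.
    Returns the offending rows (empty if the surface is clean).
    """
    grid = estimates.set_index(PIQ_KEYS)["mean"]
    flags = []
    for (p, g), v in grid.items():
        for axis, seq in (("pixels", sorted({i for i, _ in grid.index})),
                          ("grayscales", sorted({j for _, j in grid.index}))):
            vals = seq
            pos = vals.index(p if axis == "pixels" else g)
            if pos == 0 or pos == len(vals) - 1:
                continue
            if axis == "pixels":
                lo, hi = (vals[pos - 1], g), (vals[pos + 1], g)
            else:
                lo, hi = (p, vals[pos - 1]), (p, vals[pos + 1])
            if lo in grid.index and hi in grid.index:
                if v < grid[lo] - margin and v < grid[hi] - margin:
                    flags.append({"pixels": p, "grayscales": g, "mean": v, "axis": axis})
    return pd.DataFrame(flags, columns=["pixels", "grayscales", "mean", "axis"])
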