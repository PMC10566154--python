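"""Satellite FVC retrieval with a small backpropagation neural network.

The network maps 2 m downscaled satellite surface reflectance (green, red,
NIR by default) to the FVC_UAS label at the same cell. Architecture: 3
inputs, one hidden layer of 6 logistic-sigmoid nodes, linear output — at
most 31 weights, which makes full-batch Levenberg-Marquardt (damped
Gauss-Newton on the residual vector) the natural optimizer. Training splits
the pairs 8:1:1 into train/validation/test, z-scores the inputs from the
training split, and stops when the validation RMSE reaches the goal (0.06),
when it stalls for a patience window, or at the iteration cap.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .raster import Raster

SAT_INPUT_BANDS = ("green", "red", "nir")


@dataclass
class BPNNConfig:
    """Training configuration; defaults mirror the study's published setup."""

    n_hidden: int = 6
    goal_rmse: float = 0.06
    max_iter: int = 5000
    patience: int = 15
    patience_tol: float = 1e-5
    split: tuple = (0.8, 0.1, 0.1)
    lambda0: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.goal_rmse <= 0:
            raise ValueError("goal_rmse must be positive")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


@dataclass
class BPNN:
    """Fitted 3-6-1 feedforward network with per-band input z-scoring."""

    W1: np.ndarray  # (n_in, n_hidden)
    b1: np.ndarray  # (n_hidden,)
    W2: np.ndarray  # (n_hidden,)
    b2: float
    x_mean: np.ndarray
    x_sd: np.ndarray
    bands: tuple = SAT_INPUT_BANDS
    config: BPNNConfig = field(default_factory=BPNNConfig)

    def forward(self, X):
        """Raw network output sigmoid(Xs W1 + b1) . W2 + b2 (no clipping)."""
        Xs = (np.asarray(X, float) - self.x_mean) / self.x_sd
        h = _sigmoid(Xs @ self.W1 + self.b1)
        return h @ self.W2 + self.b2

    def predict(self, X):
        """FVC prediction, clipped into [0, 1]."""
        return np.clip(self.forward(X), 0.0, 1.0)

    def to_dict(self):
        return {
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": float(self.b2),
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "bands": list(self.bands),
            "config": asdict(self.config),
        }

    @classmethod
    def from_dict(cls, d):
        cfg = dict(d["config"])
        cfg["split"] = tuple(cfg["split"])
        return cls(
            W1=np.array(d["W1"]),
            b1=np.array(d["b1"]),
            W2=np.array(d["W2"]),
            b2=float(d["b2"]),
            x_mean=np.array(d["x_mean"]),
            x_sd=np.array(d["x_sd"]),
            bands=tuple(d["bands"]),
            config=BPNNConfig(**cfg),
        )

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_pairs(sat_2m: Raster, labels_2m: Raster, stage=None) -> pd.DataFrame:
    """Training-pair table from co-gridded satellite reflectance and labels.

    One row per cell where every satellite band and the label are valid;
    columns are the band names, ``label``, ``row``, ``col`` and ``stage``.
    """
    if sat_2m.grid != labels_2m.grid:
        raise ValueError("satellite and label rasters must share the same grid")
    valid = sat_2m.valid_mask() & labels_2m.valid_mask()
    rows, cols = np.nonzero(valid)
    rec = {b: sat_2m.band(b)[valid] for b in sat_2m.bands}
    rec["label"] = labels_2m.band(labels_2m.bands[0])[valid]
    rec["row"] = rows
    rec["col"] = cols
    df = pd.DataFrame(rec)
    df["stage"] = stage
    return df


def _jacobian(Xs, W1, b1, W2):
    """Analytic Jacobian of the residual wrt the flattened parameters."""
    n, n_in = Xs.shape
    nh = W1.shape[1]
    h = _sigmoid(Xs @ W1 + b1)
    dh = h * (1 - h)  # (n, nh)
    J = np.empty((n, n_in * nh + nh + nh + 1))
    # d/dW1[i,j] = W2[j] * dh[:, j] * Xs[:, i]
    block = (dh * W2) [:, None, :] * Xs[:, :, None]  # (n, n_in, nh)
    J[:, : n_in * nh] = block.reshape(n, n_in * nh)
    J[:, n_in * nh : n_in * nh + nh] = dh * W2  # d/db1
    J[:, n_in * nh + nh : n_in * nh + 2 * nh] = h  # d/dW2
    J[:, -1] = 1.0  # d/db2
    return J, h


def _unpack(p, n_in, nh):
    W1 = p[: n_in * nh].reshape(n_in, nh)
    b1 = p[n_in * nh : n_in * nh + nh]
    W2 = p[n_in * nh + nh : n_in * nh + 2 * nh]
    b2 = p[-1]
    return W1, b1, W2, b2


def train_bpnn(X, y, config: BPNNConfig = None, bands=SAT_INPUT_BANDS):
    """Levenberg-Marquardt training of the BPNN on (reflectance, FVC) pairs.

    Returns ``(model, trace)`` where the trace is a DataFrame of
    per-iteration train/validation RMSE, the damping factor, and the stop
    reason in ``trace.attrs["stop_reason"]``; the held-out test indices are
    in ``trace.attrs["test_idx"]``. Deterministic given ``config.seed``.
    """
    config = config or BPNNConfig()
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, n_in = X.shape
    if n < 100:
        raise ValueError(f"need >= 100 pairs to train, got {n}")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)
    n_tr = int(round(config.split[0] * n))
    n_va = int(round(config.split[1] * n))
    tr, va, te = order[:n_tr], order[n_tr : n_tr + n_va], order[n_tr + n_va :]
    x_mean = X[tr].mean(axis=0)
    x_sd = X[tr].std(axis=0)
    x_sd[x_sd == 0] = 1.0
    Xs_tr = (X[tr] - x_mean) / x_sd
    Xs_va = (X[va] - x_mean) / x_sd
    y_tr, y_va = y[tr], y[va]

    nh = config.n_hidden
    n_par = n_in * nh + 2 * nh + 1
    p = rng.uniform(-0.5, 0.5, n_par)
    lam = config.lambda0
    trace_rows = []
    stop = "max_iter"
    stalled = 0
    prev_val = None

    def rmse_of(p_, Xs, y_):
        W1, b1, W2, b2 = _unpack(p_, n_in, nh)
        r = _sigmoid(Xs @ W1 + b1) @ W2 + b2 - y_
        return float(np.sqrt(np.mean(r**2)))

    for it in range(1, config.max_iter + 1):
        W1, b1, W2, b2 = _unpack(p, n_in, nh)
        J, h = _jacobian(Xs_tr, W1, b1, W2)
        r = h @ W2 + b2 - y_tr
        sse = float(r @ r)
        JtJ = J.T @ J
        Jtr = J.T @ r
        accepted = False
        for _ in range(50):  # inner damping search
            A = JtJ + lam * np.diag(np.maximum(np.diag(JtJ), 1e-12))
            try:
                step = np.linalg.solve(A, -Jtr)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            p_new = p + step
            if not np.all(np.isfinite(p_new)):
                lam /= 2  # retry once with halved damping, then abort
                p_new = p + np.linalg.solve(
                    JtJ + lam * np.diag(np.maximum(np.diag(JtJ), 1e-12)), -Jtr
                )
                if not np.all(np.isfinite(p_new)):
                    raise RuntimeError(
                        f"non-finite update at iteration {it} (lambda={lam:g})"
                    )
            new_sse = None
            W1n, b1n, W2n, b2n = _unpack(p_new, n_in, nh)
            rn = _sigmoid(Xs_tr @ W1n + b1n) @ W2n + b2n - y_tr
            new_sse = float(rn @ rn)
            if np.isfinite(new_sse) and new_sse < sse:
                p = p_new
                lam = max(lam / 10, 1e-12)
                accepted = True
                break
            lam *= 10
            if lam > 1e12:
                break
        val_rmse = rmse_of(p, Xs_va, y_va) if len(va) else rmse_of(p, Xs_tr, y_tr)
        train_rmse = rmse_of(p, Xs_tr, y_tr)
        trace_rows.append(
            {"iter": it, "train_rmse": train_rmse, "val_rmse": val_rmse, "lambda": lam,
             "accepted": accepted}
        )
        if val_rmse <= config.goal_rmse:
            stop = "goal"
            break
        if prev_val is not None and abs(prev_val - val_rmse) <= config.patience_tol * max(
            prev_val, 1e-12
        ):
            stalled += 1
            if stalled >= config.patience:
                stop = "patience"
                break
        else:
            stalled = 0
        prev_val = val_rmse
        if not accepted:
            stop = "stalled_damping"
            break

    W1, b1, W2, b2 = _unpack(p, n_in, nh)
    model = BPNN(W1, b1, W2, float(b2), x_mean, x_sd, tuple(bands), config)
    trace = pd.DataFrame(trace_rows)
    trace.attrs["stop_reason"] = stop
    trace.attrs["train_idx"] = tr
    trace.attrs["val_idx"] = va
    trace.attrs["test_idx"] = te
    return model, trace


def predict_raster(model: BPNN, sat: Raster) -> Raster:
    """Wall-to-wall FVC map from a satellite reflectance raster.

    Works at any scale (2 m or 10 m) as long as the model's input bands are
    present; nodata propagates; the clip count is stored in
    ``result_raster_attrs`` via the returned raster's ``clip_count``.
    """
    missing = [b for b in model.bands if b not in sat.bands]
    if missing:
        raise KeyError(f"satellite raster lacks bands {missing}")
    valid = sat.valid_mask()
    X = np.stack([sat.band(b)[valid] for b in model.bands], axis=1)
    out = np.full((sat.n_rows, sat.n_cols), sat.nodata)
    raw = model.forward(X)
    out[valid] = np.clip(raw, 0.0, 1.0)
    result = sat.with_data(out[None], bands=("fvc",))
    result.clip_count = int(np.sum((raw < 0) | (raw > 1)))
    return result


def data_volume_experiment(
    pairs: pd.DataFrame,
    sizes,
    repeats=5,
    config: BPNNConfig = None,
    seed=0,
    holdout_frac=0.2,
    bands=SAT_INPUT_BANDS,
) -> pd.DataFrame:
    """Training-set-size sensitivity: RMSE on a fixed held-out set.

    For each admissible size, ``repeats`` random subsamples (without
    replacement) of the training pool are drawn, a BPNN is trained on each,
    and RMSE is evaluated on a held-out fraction fixed across all sizes and
    repeats. Sizes exceeding the pool are skipped with a warning.
    """
    import warnings

    config = config or BPNNConfig()
    rng = np.random.default_rng(seed)
    X = pairs[list(bands)].to_numpy(float)
    y = pairs["label"].to_numpy(float)
    n = len(y)
    order = rng.permutation(n)
    n_hold = max(int(round(holdout_frac * n)), 1)
    hold, pool = order[:n_hold], order[n_hold:]
    rows = []
    for size in sizes:
        if size > len(pool):
            warnings.warn(f"size {size} exceeds available pool ({len(pool)}); skipped")
            continue
        rmses = []
        for rep in range(repeats):
            sub = rng.choice(pool, size=size, replace=False)
            cfg = BPNNConfig(**{**asdict(config), "seed": int(rng.integers(2**31))})
            model, _ = train_bpnn(X[sub], y[sub], cfg, bands=bands)
            err = model.predict(X[hold]) - y[hold]
            rmses.append(float(np.sqrt(np.mean(err**2))))
        rows.append(
            {
                "size": int(size),
                "mean_rmse": float(np.mean(rmses)),
                "sd_rmse": float(np.std(rmses, ddof=1)) if len(rmses) > 1 else 0.0,
                "repeats": len(rmses),
            }
        )
    return pd.DataFrame(rows)
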