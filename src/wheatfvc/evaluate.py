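"""Accuracy metrics and the two analysis experiments.

Metrics are the coefficient of determination R^2 = 1 - SS_res/SS_tot and
RMSE = sqrt(mean((pred - obs)^2)), computed after dropping nodata pairs.

``boundary_interior_eval`` stratifies the error of an FVC map into cells
near plot boundaries (within a configurable radius of any plot perimeter)
versus plot-interior cells, sampling a fixed number of points per stratum.
``strategy_comparison`` tabulates RMSE by scale-bridging strategy, growth
stage and evaluation scale, and reports the relative RMSE change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import Raster
from .synth import SceneConfig


@dataclass
class EvalReport:
    r2: float
    rmse: float
    n: int
    stratum: str = "all"
    r2_definition: str = "1 - SS_res/SS_tot"


def _clean(pred, obs, nodata=None):
    pred = np.asarray(pred, float).ravel()
    obs = np.asarray(obs, float).ravel()
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must have equal length")
    keep = np.isfinite(pred) & np.isfinite(obs)
    if nodata is not None:
        keep &= (pred != nodata) & (obs != nodata)
    dropped = int(pred.size - keep.sum())
    return pred[keep], obs[keep], dropped


def rmse(pred, obs, nodata=None) -> float:
    """Root mean square error, nodata/NaN pairs excluded."""
    p, o, _ = _clean(pred, obs, nodata)
    if p.size == 0:
        raise ValueError("no valid prediction/observation pairs")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def r2(pred, obs, nodata=None) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot of predictions."""
    p, o, _ = _clean(pred, obs, nodata)
    if p.size == 0:
        raise ValueError("no valid prediction/observation pairs")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observations have zero variance; R^2 undefined")
    ss_res = float(np.sum((p - o) ** 2))
    return 1.0 - ss_res / ss_tot


def report(pred, obs, stratum="all", nodata=None) -> EvalReport:
    p, o, _ = _clean(pred, obs, nodata)
    return EvalReport(r2=r2(p, o), rmse=rmse(p, o), n=int(p.size), stratum=stratum)


def boundary_interior_eval(
    fvc_map: Raster,
    truth: Raster,
    scene: SceneConfig,
    radius_m=5.0,
    n_points=150,
    seed=0,
) -> dict:
    """Stratified accuracy at plot-boundary versus plot-interior cells.

    Boundary cells have centres within ``radius_m`` of any plot perimeter;
    interior cells are the remaining cells inside plots. ``n_points`` cells
    are sampled without replacement per stratum (all cells, with a warning,
    when a stratum is smaller). Returns ``{"boundary": EvalReport,
    "interior": EvalReport}``.
    """
    if fvc_map.grid != truth.grid:
        raise ValueError("map and truth must share a grid")
    g = fvc_map.grid
    rows, cols = np.meshgrid(np.arange(g.n_rows), np.arange(g.n_cols), indexing="ij")
    x, y = g.cell_center(rows, cols)
    dist = scene.boundary_distance(x, y)
    inside = np.zeros(x.shape, bool)
    for p in scene.plots:
        inside |= p.contains(x, y)
    valid = fvc_map.valid_mask() & truth.valid_mask()
    strata = {
        "boundary": (dist <= radius_m) & valid,
        "interior": inside & (dist > radius_m) & valid,
    }
    rng = np.random.default_rng(seed)
    out = {}
    pred_vals = fvc_map.band("fvc")
    true_vals = truth.band(truth.bands[0])
    for name, mask in strata.items():
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"stratum {name!r} has no candidate cells")
        if idx.size < n_points:
            warnings.warn(
                f"stratum {name!r} has only {idx.size} cells (< {n_points}); using all"
            )
            chosen = idx
        else:
            chosen = rng.choice(idx, size=n_points, replace=False)
        p = pred_vals.ravel()[chosen]
        o = true_vals.ravel()[chosen]
        out[name] = EvalReport(r2=r2(p, o), rmse=rmse(p, o), n=len(chosen), stratum=name)
    return out


def percent_change(old, new) -> float:
    """Relative change (old - new)/old * 100: positive when new improves."""
    if old == 0:
        raise ValueError("undefined percent change from zero")
    return (old - new) / old * 100.0


def strategy_comparison(records) -> pd.DataFrame:
    """RMSE table for strategy x stage x scale comparisons.

    ``records`` is an iterable of dicts with keys ``strategy`` (e.g.
    "up-down", "up-only"), ``stage``, ``scale``, ``pred`` and ``truth``
    (rasters or arrays). Records with a missing prediction are skipped with
    a warning. When both strategies appear at a (stage, scale), the row for
    "up-down" carries ``rmse_change_pct`` relative to "up-only".
    """
    rows = []
    for rec in records:
        if rec.get("pred") is None:
            warnings.warn(
                f"missing model for {rec.get('strategy')}/{rec.get('stage')}; skipped"
            )
            continue
        pred = rec["pred"]
        truth = rec["truth"]
        nodata = None
        if isinstance(pred, Raster):
            nodata = pred.nodata
            pred = pred.data.ravel()
        if isinstance(truth, Raster):
            truth = truth.data.ravel()
        rows.append(
            {
                "strategy": rec["strategy"],
                "stage": rec["stage"],
                "scale": rec["scale"],
                "rmse": rmse(pred, truth, nodata=nodata),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["rmse_change_pct"] = np.nan
    for (stage, scale), sub in df.groupby(["stage", "scale"]):
        strategies = dict(zip(sub.strategy, sub.rmse))
        if "up-down" in strategies and "up-only" in strategies:
            change = percent_change(strategies["up-only"], strategies["up-down"])
            df.loc[
                (df.stage == stage) & (df.scale == scale) & (df.strategy == "up-down"),
                "rmse_change_pct",
            ] = change
    return df
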