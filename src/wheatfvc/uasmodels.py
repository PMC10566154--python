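"""FVC estimation from upscaled UAS multispectral reflectance.

Four estimators produce the 2 m FVC_UAS label rasters used to train the
satellite model:

* **RFR** — random-forest regression of FVC on the four UAS bands, with
  (Mtry, Ntree) selected by k-fold cross-validated RMSE;
* **SVR** — RBF-kernel support vector regression on standardized bands,
  (gamma, cost) by the same grid search;
* **NDVI dichotomy** — linear unmixing of pixel NDVI between a bare-soil
  endmember NDVI_s and a full-vegetation endmember NDVI_v:
  FVC = (NDVI - NDVI_s) / (NDVI_v - NDVI_s), clipped to [0, 1];
* **HAGFVC** — half-Gaussian fitting on the a* histogram of RGB tiles: the
  outer flanks of the vegetation and background peaks are each fitted with
  a (scaled) half-Gaussian, the two full Gaussians are reconstructed and
  the segmentation threshold is their equal-density point.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .groundfvc import _normal_pdf, rgb_to_a_channel
from .raster import Raster, fvc_raster


@dataclass
class DichotomyParams:
    """NDVI endmembers of the pixel-dichotomy model."""

    ndvi_s: float
    ndvi_v: float

    def __post_init__(self):
        for v in (self.ndvi_s, self.ndvi_v):
            if not -1 <= v <= 1:
                raise ValueError("endmember NDVI must be in [-1, 1]")
        if self.ndvi_v <= self.ndvi_s:
            raise ValueError("ndvi_v must exceed ndvi_s")


def compute_ndvi(raster: Raster) -> Raster:
    """(NIR - Red) / (NIR + Red) from the raster's red/nir bands."""
    red = raster.band("red")
    nir = raster.band("nir")
    valid = raster.valid_mask()
    denom = nir + red
    ok = valid & (denom != 0)
    ndvi = np.full(red.shape, raster.nodata)
    ndvi[ok] = (nir[ok] - red[ok]) / denom[ok]
    return raster.with_data(ndvi[None], bands=("ndvi",))


def dichotomy_fvc(ndvi: Raster, params: DichotomyParams) -> Raster:
    """Pixel-dichotomy FVC from an NDVI raster, clipped to [0, 1]."""
    v = ndvi.band("ndvi")
    valid = ndvi.valid_mask()
    fvc = np.full(v.shape, ndvi.nodata)
    fvc[valid] = np.clip(
        (v[valid] - params.ndvi_s) / (params.ndvi_v - params.ndvi_s), 0.0, 1.0
    )
    return ndvi.with_data(fvc[None], bands=("fvc",))


def select_endmembers(
    ndvi: Raster, lo_pct=5.0, hi_pct=95.0, ndvi_s=None, ndvi_v=None
) -> DichotomyParams:
    """Endmember NDVIs as percentiles of the valid NDVI values.

    Literal overrides ``ndvi_s``/``ndvi_v`` pass through unchanged.
    """
    if not 0 <= lo_pct < hi_pct <= 100:
        raise ValueError("need 0 <= lo_pct < hi_pct <= 100")
    vals = ndvi.band("ndvi")[ndvi.valid_mask()]
    if vals.size == 0:
        raise ValueError("no valid NDVI values")
    s = float(np.percentile(vals, lo_pct)) if ndvi_s is None else float(ndvi_s)
    v = float(np.percentile(vals, hi_pct)) if ndvi_v is None else float(ndvi_v)
    if v <= s:
        raise ValueError(
            "degenerate endmembers (ndvi_v <= ndvi_s); supply literal overrides"
        )
    return DichotomyParams(ndvi_s=s, ndvi_v=v)


@dataclass
class CVResult:
    """Fitted estimator plus its grid-search cross-validation report."""

    model: object
    best_params: dict
    cv_rmse: float
    cv_table: pd.DataFrame


def _cv_rmse(make_model, X, y, k_folds, seed):
    n = len(y)
    k = min(k_folds, n)
    if k < k_folds:
        warnings.warn(f"only {n} samples; reducing folds to {k}")
    rmses = []
    for train, test in KFold(n_splits=k, shuffle=True, random_state=seed).split(X):
        m = make_model()
        m.fit(X[train], y[train])
        err = m.predict(X[test]) - y[test]
        rmses.append(np.sqrt(np.mean(err**2)))
    return float(np.mean(rmses))


def train_rfr(
    X,
    y,
    mtry_grid=(1, 2, 3, 4),
    ntree_grid=(100, 350),
    k_folds=10,
    seed=0,
    bootstrap=True,
) -> CVResult:
    """Grid-search random-forest regression by k-fold CV RMSE.

    Trees split on variance reduction (the child sets minimizing the summed
    squared deviation from the child means) and the forest predicts the mean
    over trees. Ties break toward the simpler model (fewer trees, then
    smaller Mtry). The winning configuration is refit on all samples.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if len(y) < 20:
        warnings.warn(f"only {len(y)} training samples (>= 20 recommended)")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("FVC responses must lie in [0, 1]")
    n_features = X.shape[1]
    rows = []
    for ntree, mtry in itertools.product(sorted(ntree_grid), sorted(mtry_grid)):
        if mtry > n_features:
            continue
        make = lambda nt=ntree, mt=mtry: RandomForestRegressor(
            n_estimators=nt,
            max_features=mt,
            random_state=seed,
            criterion="squared_error",
            bootstrap=bootstrap,
        )
        rows.append(
            {"ntree": ntree, "mtry": mtry, "cv_rmse": _cv_rmse(make, X, y, k_folds, seed)}
        )
    table = pd.DataFrame(rows)
    best = table.sort_values(["cv_rmse", "ntree", "mtry"]).iloc[0]
    model = RandomForestRegressor(
        n_estimators=int(best.ntree),
        max_features=int(best.mtry),
        random_state=seed,
        criterion="squared_error",
        bootstrap=bootstrap,
    ).fit(X, y)
    return CVResult(
        model=model,
        best_params={"ntree": int(best.ntree), "mtry": int(best.mtry)},
        cv_rmse=float(best.cv_rmse),
        cv_table=table,
    )


def train_svr(
    X,
    y,
    gamma_grid=(0.1, 0.4, 0.8, 1.6),
    cost_grid=(1.0, 3.0, 10.0),
    k_folds=10,
    seed=0,
) -> CVResult:
    """Grid-search RBF support vector regression by k-fold CV RMSE.

    Features are z-scored inside the fitted pipeline; the prediction is the
    kernel expansion sum_i alpha_i K(x_i, x) + w0. Ties break toward the
    smaller cost, then smaller gamma.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    rows = []
    for cost, gamma in itertools.product(sorted(cost_grid), sorted(gamma_grid)):
        make = lambda c=cost, g=gamma: make_pipeline(
            StandardScaler(), SVR(kernel="rbf", C=c, gamma=g)
        )
        rows.append(
            {"cost": cost, "gamma": gamma, "cv_rmse": _cv_rmse(make, X, y, k_folds, seed)}
        )
    table = pd.DataFrame(rows)
    best = table.sort_values(["cv_rmse", "cost", "gamma"]).iloc[0]
    model = make_pipeline(
        StandardScaler(), SVR(kernel="rbf", C=float(best.cost), gamma=float(best.gamma))
    ).fit(X, y)
    return CVResult(
        model=model,
        best_params={"cost": float(best.cost), "gamma": float(best.gamma)},
        cv_rmse=float(best.cv_rmse),
        cv_table=table,
    )


@dataclass
class HalfGaussianPair:
    """Half-Gaussian parameters of the vegetation and background a* peaks."""

    mu_v: float
    sigma_v: float
    mu_b: float
    sigma_b: float
    w_v: float = 0.5
    w_b: float = 0.5

    def __post_init__(self):
        if self.mu_v >= self.mu_b:
            raise ValueError("vegetation mean must be below background mean")
        if self.sigma_v <= 0 or self.sigma_b <= 0:
            raise ValueError("standard deviations must be positive")


@dataclass
class HagResult:
    fvc: float
    threshold: float
    mask: np.ndarray
    params: HalfGaussianPair
    degenerate: bool = False


def _fit_half_gaussian(centers, density, side):
    """Least-squares fit of A*exp(-(x-mu)^2/(2 sigma^2)) to one flank.

    The flank runs outward from the class peak, so the component mean is
    pinned near the flank's inner edge (its maximum for the left/vegetation
    flank, its minimum for the right/background flank); amplitude and width
    are free.
    """
    inner = centers.max() if side == "left" else centers.min()
    bw = np.median(np.diff(centers)) if centers.size > 1 else 1.0
    a0 = density.max()
    s0 = max(np.ptp(centers) / 4.0, 0.5)

    def resid(p):
        a, mu, s = p
        return a * np.exp(-0.5 * ((centers - mu) / s) ** 2) - density

    lo = [0.0, inner - 3 * bw, 1e-3]
    hi = [np.inf, inner + 3 * bw, np.ptp(centers) + 10]
    sol = optimize.least_squares(resid, [a0, inner, s0], bounds=(lo, hi))
    a, mu, s = sol.x
    return a, mu, s


def hagfvc(rgb_tile, bins=128, min_flank_bins=30) -> HagResult:
    """Half-Gaussian-fitting FVC from an RGB orthophoto tile.

    The outer flank of each a* histogram peak (left of the vegetation peak,
    right of the background peak) is fitted with a scaled half-Gaussian,
    avoiding the overlap region between peaks. The two full Gaussians are
    reconstructed, weights recovered from the fitted amplitudes, and the
    threshold is their equal-weighted-density point; FVC is the fraction of
    pixels below the threshold.
    """
    a = rgb_to_a_channel(rgb_tile)
    vals = a.ravel()
    density, edges = np.histogram(vals, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    from scipy.ndimage import gaussian_filter1d
    from scipy.signal import find_peaks

    # strong smoothing and a prominence floor suppress the quantization comb
    # of 8-bit photos before locating the outermost class peaks
    smooth = gaussian_filter1d(density, 3.0)
    peaks, _ = find_peaks(
        smooth, height=smooth.max() * 0.2, prominence=smooth.max() * 0.1
    )
    if len(peaks) < 2:
        return HagResult(
            fvc=float("nan"),
            threshold=float("nan"),
            mask=np.zeros(a.shape, bool),
            params=HalfGaussianPair(-1.0, 1.0, 1.0, 1.0),
            degenerate=True,
        )
    pv, pb = peaks.min(), peaks.max()  # outermost peaks: vegetation left, bg right
    left = slice(0, pv + 1)
    right = slice(pb, None)
    if (density[left] > 0).sum() < min_flank_bins or (density[right] > 0).sum() < min_flank_bins:
        degenerate = True
    else:
        degenerate = False
    av, mu_v, s_v = _fit_half_gaussian(centers[left], density[left], "left")
    ab, mu_b, s_b = _fit_half_gaussian(centers[right], density[right], "right")
    # amplitude of a weighted Gaussian is w / (sqrt(2 pi) sigma)
    w_v = av * np.sqrt(2 * np.pi) * s_v
    w_b = ab * np.sqrt(2 * np.pi) * s_b
    tot = w_v + w_b
    if tot > 0:
        w_v, w_b = w_v / tot, w_b / tot
    if mu_v >= mu_b:
        return HagResult(float("nan"), float("nan"), np.zeros(a.shape, bool),
                         HalfGaussianPair(-1.0, 1.0, 1.0, 1.0), degenerate=True)
    params = HalfGaussianPair(mu_v, s_v, mu_b, s_b, w_v, w_b)

    def g(x):
        return w_v * _normal_pdf(x, mu_v, s_v) - w_b * _normal_pdf(x, mu_b, s_b)

    eps = 1e-9 * max(1.0, mu_b - mu_v)
    if g(mu_v + eps) * g(mu_b - eps) < 0:
        thr = float(optimize.brentq(g, mu_v + eps, mu_b - eps))
    else:
        thr = float(0.5 * (mu_v + mu_b))
    mask = a < thr
    return HagResult(
        fvc=float(np.clip(mask.mean(), 0.0, 1.0)),
        threshold=thr,
        mask=mask,
        params=params,
        degenerate=degenerate,
    )


def predict_fvc_map(model, raster: Raster, bands=None) -> Raster:
    """Per-cell FVC prediction from a fitted regressor, clipped to [0, 1].

    ``bands`` defaults to all raster bands and must match the training
    feature order; nodata cells propagate.
    """
    bands = raster.bands if bands is None else tuple(bands)
    missing = [b for b in bands if b not in raster.bands]
    if missing:
        raise KeyError(f"raster lacks bands {missing}")
    n_expected = getattr(model, "n_features_in_", None)
    if n_expected is not None and n_expected != len(bands):
        raise ValueError(
            f"model expects {n_expected} features, got {len(bands)} bands"
        )
    valid = raster.valid_mask()
    X = np.stack([raster.band(b)[valid] for b in bands], axis=1)
    out = np.full((raster.n_rows, raster.n_cols), raster.nodata)
    if X.shape[0]:
        out[valid] = np.clip(model.predict(X), 0.0, 1.0)
    return raster.with_data(out[None], bands=("fvc",))
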