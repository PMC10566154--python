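"""Seeded synthetic scenes for the ground–UAS–satellite workflow.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without field data:

* a spatially correlated fractional-vegetation-cover (FVC) field over
  rectangular wheat plots separated by bare path corridors;
* per-pixel surface reflectance as a linear vegetation/soil endmember
  mixture plus Gaussian sensor noise;
* satellite pixels as block means of the fine grid (idealized sensor PSF);
* ground photos whose a*-channel histogram is a two-Gaussian mixture
  (vegetation mode below the background mode on the green–red axis);
* a five-point ground-sampling layout: 10 m sites holding five 2 m
  sub-squares on the diagonals (centre + four corners).

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage import color

from .raster import Raster, fvc_raster

UAS_BANDS = ("green", "red", "rededge", "nir")
SAT_BANDS = ("green", "red", "nir")

#: band centre wavelengths (nm) of the UAS multispectral sensor
BAND_WAVELENGTHS = {"green": 550, "red": 660, "rededge": 735, "nir": 790}

#: default FVC ranges per phenological stage (canopy closure regimes)
STAGE_FVC_RANGE = {"jointing": (0.2, 0.8), "booting": (0.7, 0.98)}


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class PlotRect:
    """Axis-aligned rectangular wheat plot in scene coordinates (metres)."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self):
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ConfigurationError(f"degenerate (zero-area) plot: {self}")

    @property
    def width(self):
        return self.x1 - self.x0

    @property
    def height(self):
        return self.y1 - self.y0

    def contains(self, x, y):
        x, y = np.asarray(x), np.asarray(y)
        return (x >= self.x0) & (x < self.x1) & (y >= self.y0) & (y < self.y1)

    def boundary_distance(self, x, y):
        """Euclidean distance from points to the plot's perimeter (inside or out)."""
        x, y = np.asarray(x, float), np.asarray(y, float)
        dx = np.maximum.reduce([self.x0 - x, np.zeros_like(x), x - self.x1])
        dy = np.maximum.reduce([self.y0 - y, np.zeros_like(y), y - self.y1])
        outside = np.hypot(dx, dy)
        inside = np.minimum.reduce([x - self.x0, self.x1 - x, y - self.y0, self.y1 - y])
        return np.where(outside > 0, outside, np.maximum(inside, 0.0))


@dataclass
class SceneConfig:
    """Layout and statistical parameters of a synthetic wheat scene."""

    width_m: float
    height_m: float
    plots: list
    fvc_range: tuple = None
    correlation_length_m: float = 8.0
    stage: str = "jointing"
    uas_gsd: float = 0.05
    sat_gsd: float = 10.0
    cell_m: float = 2.0
    edge_taper_m: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.stage not in STAGE_FVC_RANGE:
            raise ConfigurationError(f"unknown stage {self.stage!r}")
        if self.fvc_range is None:
            self.fvc_range = STAGE_FVC_RANGE[self.stage]
        lo, hi = self.fvc_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigurationError(f"fvc_range must satisfy 0 <= lo <= hi <= 1")
        if self.correlation_length_m <= 0:
            raise ConfigurationError("correlation_length_m must be positive")
        if not self.plots:
            raise ConfigurationError("scene needs at least one plot")
        for i, a in enumerate(self.plots):
            for b in self.plots[i + 1 :]:
                if a.x0 < b.x1 and b.x0 < a.x1 and a.y0 < b.y1 and b.y0 < a.y1:
                    raise ConfigurationError(f"plots overlap: {a} / {b}")

    @classmethod
    def grid_layout(
        cls,
        n_plot_rows=2,
        n_plot_cols=3,
        plot_w=76.0,
        plot_h=76.0,
        path_w=4.0,
        margin=None,
        pad_to=None,
        **kw,
    ) -> "SceneConfig":
        """Regular grid of plots separated by bare paths.

        ``margin`` is the bare border around the outermost plots (defaults
        to ``path_w``; 0 lets fields reach the scene edge). ``pad_to``
        rounds the scene width/height up to the next multiple (extra bare
        margin at the right/bottom) so the scene tiles exactly into
        satellite pixels.
        """
        if margin is None:
            margin = path_w
        plots = []
        for r in range(n_plot_rows):
            for c in range(n_plot_cols):
                x0 = margin + c * (plot_w + path_w)
                y0 = margin + r * (plot_h + path_w)
                plots.append(PlotRect(x0, y0, x0 + plot_w, y0 + plot_h))
        width = 2 * margin + n_plot_cols * plot_w + (n_plot_cols - 1) * path_w
        height = 2 * margin + n_plot_rows * plot_h + (n_plot_rows - 1) * path_w
        if pad_to:
            width = float(np.ceil(width / pad_to) * pad_to)
            height = float(np.ceil(height / pad_to) * pad_to)
        return cls(width_m=width, height_m=height, plots=plots, **kw)

    def plot_mask(self, grid) -> np.ndarray:
        """Boolean wheat mask on a GridSpec, by pixel-centre containment."""
        rows = np.arange(grid.n_rows)
        cols = np.arange(grid.n_cols)
        x, _ = grid.cell_center(np.zeros_like(cols), cols)
        _, y = grid.cell_center(rows, np.zeros_like(rows))
        xg, yg = np.meshgrid(x, y)
        mask = np.zeros(xg.shape, bool)
        for p in self.plots:
            mask |= p.contains(xg, yg)
        return mask

    def boundary_distance(self, x, y):
        """Distance to the nearest plot perimeter over all plots."""
        return np.minimum.reduce([p.boundary_distance(x, y) for p in self.plots])


@dataclass
class EndmemberSpectra:
    """Pure vegetation and bare-soil reflectance per band, with sensor noise.

    Per-pixel reflectance is the linear mixture
    ``r_b = f * veg_b + (1 - f) * soil_b + eps_b`` with
    ``eps_b ~ N(0, noise_sd_b)``, clipped into [0, 1].
    """

    vegetation: dict
    soil: dict
    noise_sd: dict = None

    def __post_init__(self):
        if self.noise_sd is None:
            self.noise_sd = {b: 0.01 for b in self.vegetation}
        elif np.isscalar(self.noise_sd):
            self.noise_sd = {b: float(self.noise_sd) for b in self.vegetation}
        for d in (self.vegetation, self.soil):
            for b, v in d.items():
                if not 0 <= v <= 1:
                    raise ConfigurationError(f"reflectance out of [0,1]: {b}={v}")
        if self.vegetation["nir"] <= self.vegetation["red"]:
            raise ConfigurationError("vegetation NIR must exceed vegetation red")
        if self.ndvi("soil") >= self.ndvi("vegetation"):
            raise ConfigurationError("soil NDVI must be below vegetation NDVI")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ConfigurationError("noise_sd must be >= 0")

    def ndvi(self, which) -> float:
        s = self.vegetation if which == "vegetation" else self.soil
        return (s["nir"] - s["red"]) / (s["nir"] + s["red"])

    @classmethod
    def default(cls, noise_sd=0.01) -> "EndmemberSpectra":
        """Typical green-canopy / bare-soil spectra (NDVI ~0.9 vs ~0.1)."""
        veg = {"green": 0.08, "red": 0.03, "rededge": 0.30, "nir": 0.55}
        soil = {"green": 0.15, "red": 0.20, "rededge": 0.22, "nir": 0.25}
        return cls(veg, soil, noise_sd)

    @classmethod
    def ndvi_linear(cls, noise_sd=0.0) -> "EndmemberSpectra":
        """Variant with veg(red+nir) == soil(red+nir), making pixel NDVI
        exactly linear in FVC (useful for dichotomy-exactness checks)."""
        veg = {"green": 0.08, "red": 0.03, "rededge": 0.30, "nir": 0.55}
        soil = {"green": 0.15, "red": 0.26, "rededge": 0.22, "nir": 0.32}
        return cls(veg, soil, noise_sd)


@dataclass
class PhotoColorModel:
    """Class-conditional CIE L*a*b* statistics of ground photos.

    Only a* is stochastic: vegetation pixels draw a* from N(veg_a_mean,
    veg_a_sd), background from N(bg_a_mean, bg_a_sd); L* and b* are held
    constant per class so that the a* histogram is the sole information
    channel. Vegetation is greener, hence the lower a* mean.
    """

    veg_a_mean: float = -20.0
    veg_a_sd: float = 4.0
    bg_a_mean: float = 10.0
    bg_a_sd: float = 5.0
    veg_L: float = 45.0
    bg_L: float = 55.0
    veg_b: float = 30.0
    bg_b: float = 18.0

    def __post_init__(self):
        if self.veg_a_mean >= self.bg_a_mean:
            raise ConfigurationError("vegetation a* mean must be below background")
        if self.veg_a_sd <= 0 or self.bg_a_sd <= 0:
            raise ConfigurationError("a* standard deviations must be positive")


def generate_fvc_field(config: SceneConfig) -> Raster:
    """Spatially correlated FVC truth field on the fine (UAS) grid.

    Seeded white noise is smoothed with a Gaussian kernel whose scale is set
    by ``correlation_length_m`` (e-folding of the autocorrelation), then
    min-max rescaled to ``fvc_range`` over the wheat plots; path corridors
    are bare (FVC 0).

    Within ``edge_taper_m`` of a plot perimeter the cover ramps linearly
    from 0 up to its interior level, emulating the stand thinning seen at
    real field margins (a canopy does not stop in a knife edge at the
    boundary line). ``edge_taper_m=0`` disables the ramp.
    """
    gsd = config.uas_gsd
    n_rows = int(round(config.height_m / gsd))
    n_cols = int(round(config.width_m / gsd))
    rng = np.random.default_rng(config.seed)
    noise = rng.standard_normal((n_rows, n_cols))
    sigma_px = config.correlation_length_m / (2.0 * gsd)
    smooth = gaussian_filter(noise, sigma_px, mode="reflect")
    out = fvc_raster(np.zeros((n_rows, n_cols)), gsd=gsd)
    mask = config.plot_mask(out.grid)
    lo, hi = config.fvc_range
    vals = smooth[mask]
    span = vals.max() - vals.min()
    if span == 0 or lo == hi:
        field_vals = np.full(vals.shape, 0.5 * (lo + hi))
    else:
        field_vals = lo + (hi - lo) * (vals - vals.min()) / span
    out.data[0][mask] = field_vals
    if config.edge_taper_m > 0:
        rows = np.arange(n_rows)
        cols = np.arange(n_cols)
        x = out.grid.x0 + (cols + 0.5) * gsd
        y = out.grid.y0 + (rows + 0.5) * gsd
        xg, yg = np.meshgrid(x, y)
        ramp = np.clip(
            config.boundary_distance(xg[mask], yg[mask]) / config.edge_taper_m, 0.0, 1.0
        )
        out.data[0][mask] *= ramp
    return out


def render_reflectance(
    fvc: Raster,
    spectra: EndmemberSpectra,
    bands=UAS_BANDS,
    seed=0,
    nir_saturation=None,
) -> Raster:
    """Linear vegetation/soil mixture reflectance on the FVC grid.

    ``nir_saturation=(knee, sd)`` optionally adds extra NIR noise whose
    standard deviation ramps from 0 at FVC=knee to ``sd`` at FVC=1,
    emulating the loss of NIR information in dense canopies that causes
    NDVI saturation.
    """
    for b in bands:
        if b not in spectra.vegetation or b not in spectra.soil:
            raise KeyError(f"band {b!r} missing from endmember spectra")
    f = fvc.band("fvc")
    rng = np.random.default_rng(seed)
    data = np.empty((len(bands),) + f.shape)
    for i, b in enumerate(bands):
        r = f * spectra.vegetation[b] + (1.0 - f) * spectra.soil[b]
        sd = spectra.noise_sd.get(b, 0.0)
        if sd > 0:
            r = r + rng.normal(0.0, sd, f.shape)
        if b == "nir" and nir_saturation is not None:
            knee, sat_sd = nir_saturation
            ramp = np.clip((f - knee) / max(1.0 - knee, 1e-9), 0.0, 1.0)
            r = r + rng.standard_normal(f.shape) * (sat_sd * ramp)
        data[i] = np.clip(r, 0.0, 1.0)
    return Raster(data, bands, fvc.x0, fvc.y0, fvc.gsd, fvc.nodata)


def render_satellite_from_fine(fine: Raster, factor: int) -> Raster:
    """Coarse raster whose pixels are block means of factor x factor fine blocks."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if fine.n_rows % factor or fine.n_cols % factor:
        raise ValueError(
            f"fine shape {fine.n_rows}x{fine.n_cols} not divisible by {factor}"
        )
    nb = fine.data.shape[0]
    coarse = fine.data.reshape(
        nb, fine.n_rows // factor, factor, fine.n_cols // factor, factor
    ).mean(axis=(2, 4))
    return Raster(coarse, fine.bands, fine.x0, fine.y0, fine.gsd * factor, fine.nodata)


def add_sensor_noise(raster: Raster, sd, seed=0) -> Raster:
    """Add seeded Gaussian noise (clipped to [0,1]) at the raster's own scale."""
    rng = np.random.default_rng(seed)
    if np.isscalar(sd):
        sd = {b: float(sd) for b in raster.bands}
    data = raster.data.copy()
    valid = raster.valid_mask()
    for i, b in enumerate(raster.bands):
        noisy = np.clip(data[i] + rng.normal(0.0, sd[b], data[i].shape), 0.0, 1.0)
        data[i] = np.where(valid, noisy, data[i])
    return raster.with_data(data)


def render_ground_photo(fvc_target, model: PhotoColorModel, size=(128, 128), seed=0):
    """Render an sRGB ground photo with a known vegetation mask.

    Exactly ``round(fvc_target * H * W)`` pixels are vegetation (so the
    realized fraction is within one pixel quantum of the target), placed at
    seeded random positions. Returns ``(photo_uint8, truth_mask,
    clip_fraction)`` where clip_fraction is the share of pixels whose Lab
    color fell outside the sRGB gamut and was clipped.
    """
    if not 0 <= fvc_target <= 1:
        raise ValueError("fvc_target must be in [0, 1]")
    h, w = size
    n = h * w
    n_veg = int(round(fvc_target * n))
    rng = np.random.default_rng(seed)
    mask = np.zeros(n, bool)
    mask[rng.permutation(n)[:n_veg]] = True
    a = np.where(
        mask,
        rng.normal(model.veg_a_mean, model.veg_a_sd, n),
        rng.normal(model.bg_a_mean, model.bg_a_sd, n),
    )
    L = np.where(mask, model.veg_L, model.bg_L)
    b = np.where(mask, model.veg_b, model.bg_b)
    lab = np.stack([L, a, b], axis=-1).reshape(h, w, 3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lab2rgb warns on out-of-gamut clipping
        rgb = color.lab2rgb(lab)
    back = color.rgb2lab(rgb)
    clip_fraction = float(np.mean(np.abs(back[..., 1] - lab[..., 1]) > 0.5))
    photo = (np.clip(rgb, 0, 1) * 255).round().astype(np.uint8)
    return photo, mask.reshape(h, w), clip_fraction


#: sub-square offsets (m) from the site centre along the 10 m square diagonals
FIVE_POINT_OFFSETS = {
    "c": (0.0, 0.0),
    "nw": (-3.0, -3.0),
    "ne": (3.0, -3.0),
    "sw": (-3.0, 3.0),
    "se": (3.0, 3.0),
}


def place_ground_samples(
    config: SceneConfig, n_sites, seed=0, site_m=10.0, sub_m=2.0, max_tries=1000
) -> pd.DataFrame:
    """Five-point ground-sampling layout: one row per 2 m sub-square.

    Each site is a ``site_m`` square fully inside one plot; its five
    ``sub_m`` sub-squares sit on the diagonals (centre + four). Columns:
    site_id, subsample_id, x, y (sub-square centres), scale_m, is_center.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    half = site_m / 2.0
    candidates = [p for p in config.plots if p.width > site_m and p.height > site_m]
    if not candidates:
        raise ConfigurationError(f"no plot can hold a {site_m} m site")
    areas = np.array([p.width * p.height for p in candidates])
    rows = []
    for site in range(n_sites):
        for attempt in range(max_tries):
            plot = candidates[rng.choice(len(candidates), p=areas / areas.sum())]
            cx = rng.uniform(plot.x0 + half, plot.x1 - half)
            cy = rng.uniform(plot.y0 + half, plot.y1 - half)
            if 0 <= cx - half and cx + half <= config.width_m and 0 <= cy - half:
                if cy + half <= config.height_m:
                    break
        else:
            raise ConfigurationError("could not place site inside the scene")
        for sub_id, (dx, dy) in FIVE_POINT_OFFSETS.items():
            rows.append(
                {
                    "site_id": site,
                    "subsample_id": sub_id,
                    "x": cx + dx,
                    "y": cy + dy,
                    "scale_m": sub_m,
                    "is_center": sub_id == "c",
                }
            )
    return pd.DataFrame(rows)


def place_bare_samples(config: SceneConfig, n_sites, seed=0, min_clearance_m=1.0,
                       max_tries=1000) -> pd.DataFrame:
    """Single 2 m reference squares on the bare path corridors.

    Low-cover reference samples anchor the FVC_UAS regression at the bare
    end of the range; each record carries one photo like the five-point
    sub-squares but stands alone (scale 2 m only).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for site in range(n_sites):
        for _ in range(max_tries):
            x = rng.uniform(1.0, config.width_m - 1.0)
            y = rng.uniform(1.0, config.height_m - 1.0)
            on_plot = any(p.contains(x, y) for p in config.plots)
            if not on_plot and config.boundary_distance(x, y) >= min_clearance_m:
                break
        else:
            raise ConfigurationError("could not place a bare site on the corridors")
        rows.append(
            {
                "site_id": f"bare-{site}",
                "subsample_id": "c",
                "x": x,
                "y": y,
                "scale_m": 2.0,
                "is_center": True,
            }
        )
    return pd.DataFrame(rows)


def sample_truth(fvc: Raster, table: pd.DataFrame, box_m=2.0) -> pd.DataFrame:
    """Append ``truth_fvc``: mean of the truth field over each sub-square."""
    f = fvc.band("fvc")
    g = fvc.grid
    out = table.copy()
    truths = []
    for _, rec in table.iterrows():
        r0, c0 = g.cell_of(rec.x - box_m / 2, rec.y - box_m / 2)
        r1, c1 = g.cell_of(rec.x + box_m / 2, rec.y + box_m / 2)
        block = f[max(r0, 0) : r1, max(c0, 0) : c1]
        truths.append(float(block.mean()))
    out["truth_fvc"] = truths
    return out
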