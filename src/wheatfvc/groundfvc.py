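"""Ground-photo FVC extraction via a two-Gaussian fit to the a* histogram.

A nadir RGB photo of a wheat canopy is converted to CIE L*a*b*; on the a*
(green-to-red) axis the histogram is bimodal — a vegetation mode at negative
a* and a soil/background mode at higher a*. The density

    f(x) = w1 N(x; beta1, delta1) + w2 N(x; beta2, delta2),   w1 + w2 = 1

is fitted to the normalized histogram by nonlinear least squares, a threshold
is solved where the two weighted component densities are equal, and FVC is
reported both as the fitted vegetation weight w1 (headline, unbiased under
component overlap) and as the fraction of pixels below the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from skimage import color
from sklearn.cluster import KMeans

_SQRT2PI = np.sqrt(2.0 * np.pi)


def _normal_pdf(x, mean, sd):
    return np.exp(-0.5 * ((x - mean) / sd) ** 2) / (_SQRT2PI * sd)


@dataclass
class GaussianMixture1D:
    """Two-component 1-D Gaussian mixture (vegetation first: beta1 <= beta2)."""

    w1: float
    w2: float
    beta1: float
    beta2: float
    delta1: float
    delta2: float
    converged: bool = True
    degenerate: bool = False
    fit_residual: float = 0.0

    def __post_init__(self):
        # normalize weights, enforce vegetation-first ordering
        tot = self.w1 + self.w2
        if tot > 0:
            self.w1, self.w2 = self.w1 / tot, self.w2 / tot
        if self.beta1 > self.beta2:
            self.w1, self.w2 = self.w2, self.w1
            self.beta1, self.beta2 = self.beta2, self.beta1
            self.delta1, self.delta2 = self.delta2, self.delta1
        if self.delta1 <= 0 or self.delta2 <= 0:
            raise ValueError("component standard deviations must be positive")

    def pdf(self, x):
        return self.w1 * _normal_pdf(x, self.beta1, self.delta1) + self.w2 * _normal_pdf(
            x, self.beta2, self.delta2
        )


@dataclass
class SegmentationResult:
    """Output of the photo FVC chain (convert -> fit -> threshold -> mask)."""

    threshold: float
    fvc_threshold: float
    fvc_weight: float
    mask: np.ndarray
    mixture: GaussianMixture1D
    estimator: str = "weight"
    fit_residual: float = 0.0
    n_bins: int = 256
    threshold_is_midpoint: bool = False

    @property
    def fvc(self) -> float:
        """Headline FVC estimate, per the configured estimator."""
        return self.fvc_weight if self.estimator == "weight" else self.fvc_threshold


def rgb_to_a_channel(photo) -> np.ndarray:
    """a* channel of an sRGB photo (8-bit ints or floats in [0,1])."""
    photo = np.asarray(photo)
    if photo.ndim != 3 or photo.shape[-1] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got shape {photo.shape}")
    if photo.dtype == np.uint8:
        photo = photo.astype(float) / 255.0
    return color.rgb2lab(photo)[..., 1]


def _initial_guess(a, centers, density):
    """Init from the two largest local maxima of the smoothed histogram,
    falling back to 1-D k-means on the raw values when < 2 peaks show."""
    from scipy.ndimage import gaussian_filter1d
    from scipy.signal import find_peaks

    smooth = gaussian_filter1d(density, 2.0)
    peaks, props = find_peaks(smooth, height=smooth.max() * 0.02)
    if len(peaks) >= 2:
        top = peaks[np.argsort(props["peak_heights"])[-2:]]
        m1, m2 = sorted(centers[top])
        return m1, m2, False
    # unimodal histogram: components not distinguishable from peaks alone
    sub = a if a.size <= 20000 else a[:: a.size // 20000]
    km = KMeans(n_clusters=2, n_init=3, random_state=0).fit(sub[:, None])
    m1, m2 = sorted(km.cluster_centers_.ravel())
    return m1, m2, True


def fit_mixture(a_values, bins=256) -> GaussianMixture1D:
    """Least-squares fit of the two-Gaussian density to the a* histogram.

    The histogram uses ``bins`` equal-width bins over [min, max] and is
    density-normalized; the six parameters are found by bounded nonlinear
    least squares with w2 = 1 - w1 enforced. A ``degenerate`` flag marks
    fits where the two components are not distinguishable.
    """
    a = np.asarray(a_values, float).ravel()
    a = a[np.isfinite(a)]
    if a.size < 10:
        raise ValueError("too few finite a* values to fit")
    if a.max() == a.min():
        return GaussianMixture1D(1.0, 0.0, a[0], a[0] + 1.0, 1e-3, 1e-3, degenerate=True)
    density, edges = np.histogram(a, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    m1, m2, unimodal = _initial_guess(a, centers, density)
    spread = max((m2 - m1) / 4.0, a.std() / 4.0, 0.5)
    frac_lo = float(np.mean(a < 0.5 * (m1 + m2)))
    p0 = [np.clip(frac_lo, 0.05, 0.95), m1, spread, m2, spread]
    lo_b, hi_b = a.min() - 1, a.max() + 1

    def resid(p):
        w1, b1, d1, b2, d2 = p
        model = w1 * _normal_pdf(centers, b1, d1) + (1 - w1) * _normal_pdf(
            centers, b2, d2
        )
        return model - density

    sol = optimize.least_squares(
        resid,
        p0,
        bounds=([0.0, lo_b, 1e-3, lo_b, 1e-3], [1.0, hi_b, hi_b - lo_b, hi_b, hi_b - lo_b]),
    )
    w1, b1, d1, b2, d2 = sol.x
    mix = GaussianMixture1D(
        w1, 1 - w1, b1, b2, d1, d2, converged=sol.success,
        fit_residual=float(np.linalg.norm(sol.fun)),
    )
    # components are indistinguishable when the modes merge (separation small
    # against the widths) or one weight has collapsed
    sep = abs(mix.beta2 - mix.beta1)
    mix.degenerate = bool(
        sep < 0.75 * (mix.delta1 + mix.delta2) or min(mix.w1, mix.w2) < 1e-3
    )
    return mix


def solve_threshold(mixture: GaussianMixture1D):
    """a* threshold where the weighted component densities are equal.

    Returns ``(threshold, used_midpoint)``. The root of
    w1 N(x; beta1, delta1) = w2 N(x; beta2, delta2) is bracketed in
    (beta1, beta2); if no sign change exists there the midpoint is returned
    with a warning flag. Degenerate mixtures raise (a manual threshold,
    e.g. judged visually for waterlogged plots, must then be supplied).
    """
    if mixture.degenerate:
        raise ValueError(
            "degenerate mixture: components indistinguishable; supply manual_threshold"
        )

    def g(x):
        return mixture.w1 * _normal_pdf(x, mixture.beta1, mixture.delta1) - (
            mixture.w2 * _normal_pdf(x, mixture.beta2, mixture.delta2)
        )

    lo, hi = mixture.beta1, mixture.beta2
    eps = 1e-9 * max(1.0, hi - lo)
    if g(lo + eps) * g(hi - eps) < 0:
        root = optimize.brentq(g, lo + eps, hi - eps)
        return float(root), False
    warnings.warn("no equal-density root between component means; using midpoint")
    return float(0.5 * (lo + hi)), True


def photo_fvc(
    photo, bins=256, estimator="weight", manual_threshold=None
) -> SegmentationResult:
    """Full photo chain: convert to a*, fit the mixture, threshold, mask.

    ``estimator`` selects the headline FVC: "weight" (fitted w1) or
    "threshold" (pixel fraction below the threshold). A ``manual_threshold``
    bypasses the solver (the mixture is still fitted when possible).
    """
    if estimator not in ("weight", "threshold"):
        raise ValueError("estimator must be 'weight' or 'threshold'")
    a = rgb_to_a_channel(photo)
    mix = fit_mixture(a, bins=bins)
    midpoint = False
    if manual_threshold is not None:
        thr = float(manual_threshold)
    else:
        thr, midpoint = solve_threshold(mix)
    mask = a < thr
    frac = float(mask.mean())
    return SegmentationResult(
        threshold=thr,
        fvc_threshold=frac,
        fvc_weight=float(np.clip(mix.w1, 0.0, 1.0)),
        mask=mask,
        mixture=mix,
        estimator=estimator,
        fit_residual=mix.fit_residual,
        n_bins=bins,
        threshold_is_midpoint=midpoint,
    )


def aggregate_site(results: dict, center_id="c"):
    """Combine the five 2 m sub-square FVCs of one site.

    Returns ``(fvc_2m, fvc_10m)``: the 2 m value is the centre sub-square
    alone; the 10 m value is the arithmetic mean of all five.
    """
    if len(results) != 5:
        raise ValueError(f"expected exactly 5 sub-square results, got {len(results)}")
    if center_id not in results:
        raise ValueError(f"centre sub-square {center_id!r} missing")
    values = {
        k: (v.fvc if isinstance(v, SegmentationResult) else float(v))
        for k, v in results.items()
    }
    fvc_10m = float(np.mean(list(values.values())))
    return values[center_id], fvc_10m
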