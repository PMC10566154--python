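"""Scale bridging between satellite, target (2 m) and UAS grids.

Downscaling (10 m -> 2 m) uses cubic-convolution interpolation: each target
value is a weighted sum over the 4x4 source neighborhood with the piecewise
cubic kernel

    W(x) = |x|^3 - 2|x|^2 + 1            for |x| < 1
         = -|x|^3 + 5|x|^2 - 8|x| + 4    for 1 <= |x| <= 2
         = 0                             otherwise

applied separably in rows and columns. The pixel-centre mapping
``src = (dst + 0.5)/factor - 0.5`` makes the centre fine pixel of every
block coincide with a source node for odd factors, so 10 m values are
preserved in the middle of the resampled 2 m pixels.

Upscaling aggregates fine pixels onto a coarser grid by the zonal mean:
each target cell averages the fine pixels whose centres fall inside it
(half-open cell extents).
"""

from __future__ import annotations

import numpy as np

from .raster import GridSpec, Raster


def cubic_kernel(x):
    """Cubic-convolution interpolation kernel (vectorized, zero outside |x|<=2)."""
    ax = np.abs(np.asarray(x, float))
    out = np.zeros_like(ax)
    near = ax < 1
    mid = (ax >= 1) & (ax <= 2)
    out[near] = ax[near] ** 3 - 2 * ax[near] ** 2 + 1
    out[mid] = -(ax[mid] ** 3) + 5 * ax[mid] ** 2 - 8 * ax[mid] + 4
    if np.isscalar(x):
        return float(out)
    return out


def _axis_weights(n_src, factor):
    """Per-target-index 4-neighbor source indices (clamped) and kernel weights."""
    dst = np.arange(n_src * factor)
    src = (dst + 0.5) / factor - 0.5
    i = np.floor(src).astype(int)
    u = src - i
    offsets = np.array([-1, 0, 1, 2])
    idx = i[:, None] + offsets[None, :]
    # kernel argument: distance from target point to each source node
    w = cubic_kernel(u[:, None] - offsets[None, :])
    idx_clamped = np.clip(idx, 0, n_src - 1)  # replicate padding at borders
    return idx_clamped, w


def downscale_bicubic(coarse: Raster, factor=5, renormalize_nodata=False) -> Raster:
    """Cubic-convolution interpolation of a coarse raster onto a grid
    ``factor`` times finer.

    Nodata handling: a target pixel whose 4x4 source neighborhood touches
    nodata becomes nodata, unless ``renormalize_nodata`` is set, in which
    case the remaining weights are renormalized (separably) to ignore the
    invalid sources.
    """
    if int(factor) != factor or factor < 2:
        raise ValueError("factor must be an integer >= 2")
    factor = int(factor)
    if coarse.n_rows < 4 or coarse.n_cols < 4:
        raise ValueError("raster must be at least 4x4 for cubic convolution")
    ridx, rw = _axis_weights(coarse.n_rows, factor)
    cidx, cw = _axis_weights(coarse.n_cols, factor)
    valid = coarse.valid_mask()
    all_valid = bool(valid.all())
    out = np.empty((coarse.data.shape[0], coarse.n_rows * factor, coarse.n_cols * factor))
    for b in range(coarse.data.shape[0]):
        src = coarse.data[b]
        if all_valid:
            rows = np.einsum("tkc,tk->tc", src[ridx, :], rw)  # rows: (Ht, n_cols)
            fine = np.einsum("twk,wk->tw", rows[:, cidx], cw)
        else:
            v = valid.astype(float)
            srcz = np.where(valid, src, 0.0)
            num_r = np.einsum("tkc,tk->tc", srcz[ridx, :], rw)
            den_r = np.einsum("tkc,tk->tc", v[ridx, :], rw)
            num = np.einsum("twk,wk->tw", num_r[:, cidx], cw)
            den = np.einsum("twk,wk->tw", den_r[:, cidx], cw)
            # touched-by-nodata detection: any invalid source in the 4x4 window
            inv = (~valid).astype(float)
            touched_r = inv[ridx, :].max(axis=1)
            touched = touched_r[:, cidx].max(axis=2) > 0
            if renormalize_nodata:
                with np.errstate(divide="ignore", invalid="ignore"):
                    fine = np.where(np.abs(den) > 1e-9, num / den, coarse.nodata)
                fine = np.where(touched & (np.abs(den) <= 1e-9), coarse.nodata, fine)
            else:
                fine = np.where(touched, coarse.nodata, num)
        out[b] = fine
    return Raster(
        out, coarse.bands, coarse.x0, coarse.y0, coarse.gsd / factor, coarse.nodata
    )


def upscale_zonal(fine: Raster, target) -> Raster:
    """Zonal-mean aggregation of a fine raster onto a coarser target grid.

    ``target`` is a GridSpec or a Raster providing one. Each target cell is
    the mean of the fine pixels whose centres fall inside it; cells with no
    contributing valid pixel become nodata.
    """
    grid = target.grid if isinstance(target, Raster) else target
    if not isinstance(grid, GridSpec):
        raise TypeError("target must be a Raster or GridSpec")
    if fine.gsd >= grid.gsd:
        raise ValueError("fine GSD must be strictly smaller than the target cell")
    rows = np.arange(fine.n_rows)
    cols = np.arange(fine.n_cols)
    xc = fine.x0 + (cols + 0.5) * fine.gsd
    yc = fine.y0 + (rows + 0.5) * fine.gsd
    ti = np.floor((yc - grid.y0) / grid.gsd).astype(int)
    tj = np.floor((xc - grid.x0) / grid.gsd).astype(int)
    in_i = (ti >= 0) & (ti < grid.n_rows)
    in_j = (tj >= 0) & (tj < grid.n_cols)
    if not in_i.any() or not in_j.any():
        raise ValueError("fine raster extent is disjoint from the target grid")
    cell = ti[:, None] * grid.n_cols + tj[None, :]
    inside = in_i[:, None] & in_j[None, :]
    valid = fine.valid_mask() & inside
    flat_cell = cell[valid]
    n_cells = grid.n_rows * grid.n_cols
    counts = np.bincount(flat_cell, minlength=n_cells)
    out = np.full((fine.data.shape[0], n_cells), fine.nodata)
    nonzero = counts > 0
    for b in range(fine.data.shape[0]):
        sums = np.bincount(flat_cell, weights=fine.data[b][valid], minlength=n_cells)
        out[b, nonzero] = sums[nonzero] / counts[nonzero]
    return Raster(
        out.reshape(fine.data.shape[0], grid.n_rows, grid.n_cols),
        fine.bands,
        grid.x0,
        grid.y0,
        grid.gsd,
        fine.nodata,
    )


def block_expand(coarse: Raster, factor: int) -> Raster:
    """Nearest-neighbor expansion: every coarse pixel replicated factor x factor.

    Used to judge a coarse product against fine reference samples — each
    fine cell inherits the value of its containing coarse pixel.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be a positive integer")
    data = np.repeat(np.repeat(coarse.data, factor, axis=1), factor, axis=2)
    return Raster(
        data, coarse.bands, coarse.x0, coarse.y0, coarse.gsd / factor, coarse.nodata
    )


def upscale_fvc_10m(fvc_2m: Raster, factor=5) -> Raster:
    """Block-mean aggregation of a 2 m FVC raster to the 10 m grid.

    The 2 m grid must be block-aligned (shape divisible by ``factor``);
    blocks containing any nodata cell become nodata.
    """
    if fvc_2m.n_rows % factor or fvc_2m.n_cols % factor:
        raise ValueError(
            f"grid {fvc_2m.n_rows}x{fvc_2m.n_cols} not block-aligned to factor {factor}"
        )
    nb = fvc_2m.data.shape[0]
    blocks = fvc_2m.data.reshape(
        nb, fvc_2m.n_rows // factor, factor, fvc_2m.n_cols // factor, factor
    )
    vmask = (
        np.isfinite(fvc_2m.data) & (fvc_2m.data != fvc_2m.nodata)
    ).reshape(blocks.shape)
    complete = vmask.all(axis=(2, 4))
    means = blocks.mean(axis=(2, 4))
    out = np.where(complete, means, fvc_2m.nodata)
    return Raster(
        out, fvc_2m.bands, fvc_2m.x0, fvc_2m.y0, fvc_2m.gsd * factor, fvc_2m.nodata
    )
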