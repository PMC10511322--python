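"""Inverse-distance-weighted downscaling of coarse fields to a fine grid.

The value at each fine cell center is a distance-decay weighted average of
the k nearest non-missing coarse cell centers, with great-circle distances
so that zonal spacing is treated correctly at high latitudes.  A fine
center essentially coincident with a coarse center copies that coarse
value exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import DailyField
from .grids import GridSpec, great_circle_km


@dataclass(frozen=True)
class IdwParams:
    """Interpolation parameters: weight w_i = d_i^(-power) over k neighbors."""

    power: float = 2.0
    k: int = 4
    coincidence_tol_deg: float = 1e-6

    def __post_init__(self):
        if self.power <= 0:
            raise ValueError("power must be > 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")


def _pairwise_distances(target: GridSpec, source: GridSpec) -> np.ndarray:
    """(n_fine, n_coarse) great-circle distance matrix between cell centers."""
    flat, flon = target.cell_centers()
    clat, clon = source.cell_centers()
    return great_circle_km(
        flon.ravel()[:, None], flat.ravel()[:, None],
        clon.ravel()[None, :], clat.ravel()[None, :],
    )


def idw_downscale(coarse: DailyField, target: GridSpec,
                  params: IdwParams | None = None) -> DailyField:
    """Interpolate a coarse daily field onto a fine grid by IDW.

    For each date the k nearest *non-missing* coarse centers contribute with
    weight d^(-power); cell-dates whose every neighbor is missing become
    NaN.  The result is bounded by the extremes of the contributing
    neighbors and reproduces spatially constant fields exactly.
    """
    params = params or IdwParams()
    src = coarse.grid
    n_fine = target.ncells
    n_coarse = src.ncells

    dist = _pairwise_distances(target, src)  # (n_fine, n_coarse)
    if dist.min() > great_circle_km(0, 0, src.dlon * src.nlon, src.dlat * src.nlat):
        raise ValueError("target grid does not overlap the coarse domain")

    tol_km = great_circle_km(0.0, 0.0, params.coincidence_tol_deg, 0.0)
    coincident = dist <= max(tol_km, 1e-9)

    flat_src = coarse.values.reshape(coarse.ndates, n_coarse)
    out = np.full((coarse.ndates, n_fine), np.nan)

    finite_patterns = np.isfinite(flat_src)
    # interpolation weights only depend on the missingness pattern; group
    # dates sharing a pattern so the common all-finite case is solved once
    uniq, inverse = np.unique(finite_patterns, axis=0, return_inverse=True)
    k = min(params.k, n_coarse)

    for p, pattern in enumerate(uniq):
        dates = np.where(inverse == p)[0]
        avail = np.where(pattern)[0]
        if avail.size == 0:
            continue
        d = dist[:, avail]
        kk = min(k, avail.size)
        nearest = np.argpartition(d, kk - 1, axis=1)[:, :kk]
        nd = np.take_along_axis(d, nearest, axis=1)
        w = np.power(np.maximum(nd, 1e-12), -params.power)
        w /= w.sum(axis=1, keepdims=True)
        src_idx = avail[nearest]                       # (n_fine, kk)
        vals = flat_src[np.ix_(dates, avail)]          # (n_dates_p, n_avail)
        neigh = vals[:, nearest]                       # (n_dates_p, n_fine, kk)
        est = np.einsum("dfk,fk->df", neigh, w)

        # exact copy at coincident centers that are non-missing
        coin = coincident[:, avail]
        rows, cols = np.where(coin)
        if rows.size:
            est[:, rows] = vals[:, cols]
        out[dates] = est

    return DailyField(target, coarse.dates,
                      out.reshape(coarse.ndates, target.nlat, target.nlon),
                      name=coarse.name, units=coarse.units)
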