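"""Variogram estimation, ordinary kriging, refuge centers, and gradient tests.

The spatial workflow interpolates per-individual statistics (heterozygosity,
ROH counts, load metrics) onto a lon/lat grid by ordinary kriging with a
fitted isotropic variogram, extracts the refuge center as the centroid of
presence-predicted raster cells, and tests each statistic against
great-circle distance to that center with Pearson correlation (two-tailed)
plus Benjamini-Hochberg FDR across the statistics tested in a run.

Distances are great-circle km (lon/lat inputs over a sub-continental
extent); the variogram ``range_km`` is the distance-scale parameter of the
chosen family (for the exponential family the effective range, where the
semivariance reaches ~95% of the sill, is about 3x the parameter).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .geo import haversine_km, pairwise_km
from .raster import NODATA, Raster

logger = logging.getLogger(__name__)

FAMILIES = ("spherical", "exponential", "gaussian")
_JITTER_DEG = 1e-6  # jitter applied to duplicate coordinates, degrees


@dataclass
class VariogramModel:
    family: str
    nugget: float
    partial_sill: float
    range_km: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.nugget < 0 or self.partial_sill < 0 or self.range_km <= 0:
            raise ValueError("require nugget >= 0, partial_sill >= 0, range_km > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def __call__(self, h):
        """Semivariance at lag h (km); gamma(0) = 0, jumping to the nugget."""
        h = np.asarray(h, dtype=float)
        x = h / self.range_km
        if self.family == "exponential":
            struct = 1.0 - np.exp(-x)
        elif self.family == "gaussian":
            struct = 1.0 - np.exp(-(x**2))
        else:  # spherical
            struct = np.where(x < 1.0, 1.5 * x - 0.5 * x**3, 1.0)
        gamma = self.nugget + self.partial_sill * struct
        return np.where(h == 0, 0.0, gamma)

    def covariance(self, h):
        """C(h) = sill - gamma(h), with C(0) = sill."""
        h = np.asarray(h, dtype=float)
        return np.where(h == 0, self.sill, self.sill - self.__call__(h))


def empirical_variogram(lons, lats, values, n_lags: int = 12,
                        max_dist: float | None = None) -> pd.DataFrame:
    """Binned empirical semivariogram over great-circle distances.

    gamma_hat(h) = (1/2N(h)) * sum (z_i - z_j)^2 over point pairs whose
    distance falls in the bin; empty bins are dropped. Default ``max_dist``
    is half the maximum pairwise distance. A constant field yields a valid
    all-zero variogram (flagged in the log).
    """
    lons = np.asarray(lons, float)
    lats = np.asarray(lats, float)
    values = np.asarray(values, float)
    finite = np.isfinite(values)
    if finite.sum() < 2:
        raise ValueError("need >= 2 points with finite values")
    if finite.sum() < 5:
        logger.warning("empirical_variogram: < 5 points, estimate will be unstable")
    lons, lats, values = lons[finite], lats[finite], values[finite]
    d = pairwise_km(lons, lats)
    iu = np.triu_indices(len(values), k=1)
    h = d[iu]
    sq = 0.5 * (values[iu[0]] - values[iu[1]]) ** 2
    if max_dist is None:
        max_dist = float(h.max()) / 2.0
    sel = (h > 0) & (h <= max_dist)
    if not sel.any():
        sel = h > 0
    edges = np.linspace(0.0, max_dist if max_dist > 0 else float(h.max()), n_lags + 1)
    which = np.digitize(h[sel], edges[1:-1])
    rows = []
    for b in range(n_lags):
        m = which == b
        if not m.any():
            continue
        rows.append((float(h[sel][m].mean()), float(sq[sel][m].mean()), int(m.sum())))
    out = pd.DataFrame(rows, columns=["h", "gamma", "n_pairs"])
    if (out["gamma"] == 0).all():
        logger.warning("empirical_variogram: constant field, all-zero variogram")
    return out


def fit_variogram(lag_table: pd.DataFrame, family: str = "exponential") -> VariogramModel:
    """Weighted least squares fit (weights N(h)/h^2) with a deterministic
    multi-start over range values; best start wins."""
    if len(lag_table) < 3:
        raise ValueError("need >= 3 non-empty lags to fit a variogram")
    h = lag_table["h"].to_numpy(float)
    g = lag_table["gamma"].to_numpy(float)
    npairs = lag_table["n_pairs"].to_numpy(float)
    w = np.sqrt(npairs) / np.maximum(h, 1e-12)
    gmax = g.max()
    hmax = h.max()
    if gmax == 0:
        return VariogramModel(family, 0.0, 0.0, max(hmax, 1.0))

    def resid(theta):
        nug, psill, rng_ = theta
        model = VariogramModel(family, max(nug, 0.0), max(psill, 0.0), max(rng_, 1e-9))
        return w * (model(h) - g)

    best = None
    for r0 in (0.1, 0.25, 0.5, 1.0, 2.0):
        x0 = np.array([0.0, gmax, max(r0 * hmax, 1e-6)])
        try:
            sol = scipy.optimize.least_squares(
                resid, x0, bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    if best is None:
        raise ValueError("variogram fit failed on a degenerate lag table")
    nug, psill, rng_ = best.x
    return VariogramModel(family, float(nug), float(psill), float(rng_))


# ---------------------------------------------------------------------------
# ordinary kriging
# ---------------------------------------------------------------------------

def _jitter_duplicates(lons, lats):
    pts = np.column_stack([lons, lats])
    out = pts.copy()
    seen = {}
    n_dup = 0
    for i, key in enumerate(map(tuple, pts)):
        count = seen.get(key, 0)
        if count:
            out[i, 0] += _JITTER_DEG * count
            out[i, 1] += _JITTER_DEG * count
            n_dup += 1
        seen[key] = count + 1
    if n_dup:
        logger.info("ordinary_krige: jittered %d duplicate coordinates by %g deg",
                    n_dup, _JITTER_DEG)
    return out[:, 0], out[:, 1]


def default_grid(lons, lats, n_cells: int = 100, pad_frac: float = 0.05) -> Raster:
    """Bounding box of the points padded 5%, n_cells x n_cells, filled with nodata."""
    lon_lo, lon_hi = float(np.min(lons)), float(np.max(lons))
    lat_lo, lat_hi = float(np.min(lats)), float(np.max(lats))
    pad_lon = max((lon_hi - lon_lo) * pad_frac, 1e-3)
    pad_lat = max((lat_hi - lat_lo) * pad_frac, 1e-3)
    lon_lo -= pad_lon
    lon_hi += pad_lon
    lat_lo -= pad_lat
    lat_hi += pad_lat
    cell = max((lon_hi - lon_lo), (lat_hi - lat_lo)) / n_cells
    ncols = max(int(np.ceil((lon_hi - lon_lo) / cell)), 1)
    nrows = max(int(np.ceil((lat_hi - lat_lo) / cell)), 1)
    vals = np.full((nrows, ncols), NODATA)
    return Raster(lon0=lon_lo + cell / 2, lat0=lat_hi - cell / 2, cell_deg=cell, values=vals)


def ordinary_krige(lons, lats, values, model: VariogramModel,
                   grid: Raster | None = None, mask: np.ndarray | None = None):
    """Ordinary kriging of point values onto a raster grid.

    Solves the semivariogram form of the OK system per grid node (weights
    sum to 1 via a Lagrange multiplier); an exact interpolator at data
    coordinates when the nugget is zero. Returns (prediction Raster,
    kriging-variance Raster). Duplicate coordinates are jittered by 1e-6
    degrees.
    """
    lons = np.asarray(lons, float)
    lats = np.asarray(lats, float)
    values = np.asarray(values, float)
    finite = np.isfinite(values)
    lons, lats, values = lons[finite], lats[finite], values[finite]
    n = len(values)
    if n < 2 or len(np.unique(np.column_stack([lons, lats]), axis=0)) < 2:
        raise ValueError("kriging needs >= 2 distinct data points")
    lons, lats = _jitter_duplicates(lons, lats)
    if grid is None:
        grid = default_grid(lons, lats)

    d = pairwise_km(lons, lats)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = model(d)
    np.fill_diagonal(A[:n, :n], 0.0)
    A[n, :] = 1.0
    A[:, n] = 1.0
    A[n, n] = 0.0
    try:
        lu, piv = scipy.linalg.lu_factor(A)
    except scipy.linalg.LinAlgError as err:  # pragma: no cover
        raise ValueError("singular kriging system after jitter") from err

    glon, glat = grid.cell_centers()
    nodes = np.ones(glon.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    node_lon = glon[nodes]
    node_lat = glat[nodes]
    d0 = haversine_km(node_lon[:, None], node_lat[:, None], lons[None, :], lats[None, :])
    B = np.empty((n + 1, len(node_lon)))
    B[:n, :] = model(d0).T
    B[n, :] = 1.0
    W = scipy.linalg.lu_solve((lu, piv), B)
    pred_flat = W[:n, :].T @ values
    var_flat = np.einsum("ij,ij->j", W, B)
    var_flat = np.maximum(var_flat, 0.0)

    pred = np.full(glon.shape, grid.nodata)
    var = np.full(glon.shape, grid.nodata)
    pred[nodes] = pred_flat
    var[nodes] = var_flat
    mk = lambda v: Raster(grid.lon0, grid.lat0, grid.cell_deg, v, nodata=grid.nodata)
    return mk(pred), mk(var)


def kriging_weights(lons, lats, model: VariogramModel, at_lon, at_lat) -> np.ndarray:
    """OK weights for a single prediction point (diagnostic; sums to 1)."""
    lons = np.asarray(lons, float)
    lats = np.asarray(lats, float)
    n = len(lons)
    d = pairwise_km(lons, lats)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = model(d)
    np.fill_diagonal(A[:n, :n], 0.0)
    A[n, :] = 1.0
    A[:, n] = 1.0
    A[n, n] = 0.0
    b = np.empty(n + 1)
    b[:n] = model(haversine_km(at_lon, at_lat, lons, lats))
    b[n] = 1.0
    w = np.linalg.solve(A, b)
    return w[:n]


# ---------------------------------------------------------------------------
# refuge center and gradient tests
# ---------------------------------------------------------------------------

def refuge_center(presence: Raster, spherical: bool = False) -> tuple:
    """Centroid (mean lon, mean lat) of presence-predicted (value 1) cells.

    ``spherical=True`` averages 3-D unit vectors instead of raw lon/lat;
    the two agree closely at sub-continental extents.
    """
    glon, glat = presence.cell_centers()
    present = presence.values == 1
    if not present.any():
        raise ValueError("presence raster has no presence cells")
    if not spherical:
        return float(glon[present].mean()), float(glat[present].mean())
    lam = np.radians(glon[present])
    phi = np.radians(glat[present])
    x = (np.cos(phi) * np.cos(lam)).mean()
    y = (np.cos(phi) * np.sin(lam)).mean()
    z = np.sin(phi).mean()
    return (float(np.degrees(np.arctan2(y, x))),
            float(np.degrees(np.arctan2(z, np.hypot(x, y)))))


@dataclass
class GradientResult:
    statistic: str
    r: float
    p: float
    q: float  # FDR-adjusted; NaN until fdr applied across a family of tests
    n: int

    def __post_init__(self) -> None:
        if np.isfinite(self.r) and not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("r out of [-1, 1]")


def gradient_test(values, samples: pd.DataFrame, center: tuple,
                  statistic: str = "statistic") -> GradientResult:
    """Pearson correlation (two-tailed) between a per-individual statistic
    and great-circle distance to the refuge center."""
    values = np.asarray(values, float)
    if len(values) != len(samples):
        raise ValueError("values and samples must align")
    dist = haversine_km(samples["lon"].to_numpy(), samples["lat"].to_numpy(),
                        center[0], center[1])
    finite = np.isfinite(values)
    if (~finite).any():
        logger.info("gradient_test[%s]: dropped %d undefined values",
                    statistic, int((~finite).sum()))
    v = values[finite]
    d = np.atleast_1d(dist)[finite]
    if len(v) < 3:
        raise ValueError("need >= 3 individuals with a finite statistic")
    if np.std(v) == 0 or np.std(d) == 0:
        raise ValueError("zero variance in statistic or distance")
    res = scipy.stats.pearsonr(d, v)
    return GradientResult(statistic=statistic, r=float(res.statistic),
                          p=float(res.pvalue), q=np.nan, n=len(v))


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def gradient_table(results: list[GradientResult]) -> pd.DataFrame:
    """Combine gradient tests, applying FDR across the family."""
    q = fdr_adjust([g.p for g in results])
    for g, qi in zip(results, q):
        g.q = float(qi)
    return pd.DataFrame([{"statistic": g.statistic, "r": g.r, "p": g.p,
                          "q": g.q, "n": g.n} for g in results])
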