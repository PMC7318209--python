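"""Pre-model steps: log-transform decision, bagplot outlier removal, and
estimation of the yield observation-error SD from the variogram nugget.

The bagplot is the bivariate box-plot of Rousseeuw, Ruts & Tukey: Tukey
halfspace depth defines a central "bag" holding half the points; inflating
the bag about the Tukey median by a fence factor gives the outlier fence.
Halfspace depth is computed exactly by the sorted-angle construction.

The observation-error variance sigma_e^2 of zone yields is approximated by
the nugget of a variogram model fitted to the pooled empirical semivariogram
of yield, by weighted least squares over spherical and exponential families.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.optimize import least_squares
from scipy.spatial import ConvexHull, cKDTree
from scipy.spatial.distance import pdist
from scipy.stats import skew
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)


class CollinearInputError(ValueError):
    """All points collinear: bivariate depth regions are degenerate; use
    univariate (box-plot) methods instead."""


@dataclass(frozen=True)
class TransformDecision:
    variable: str
    raw_skewness: float
    log_skewness: float
    threshold: float
    applied: bool


@dataclass
class OutlierResult:
    flags: np.ndarray            # True = outlier
    depths: np.ndarray           # integer halfspace depth per point
    tukey_median: np.ndarray
    bag_vertices: np.ndarray
    fence_vertices: np.ndarray
    fence_factor: float

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


@dataclass
class VariogramEstimate:
    lags: np.ndarray             # bin centres (m)
    semivariances: np.ndarray    # (t/ha)^2
    pair_counts: np.ndarray
    model: str                   # "spherical" | "exponential"
    nugget: float
    partial_sill: float
    range_: float
    wls_objective: float

    @property
    def sigma_e(self) -> float:
        return math.sqrt(max(self.nugget, 0.0))


def decide_transform(values, threshold: float = 1.0, variable: str = "x") -> TransformDecision:
    """Decide whether to model a variable on the natural-log scale.

    Computes the moment-coefficient skewness (m3/m2^1.5) of the raw and of
    the log values; the log transform is applied when the raw skewness
    exceeds ``threshold`` and logging actually reduces it.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 values")
    if np.any(values <= 0) or np.any(~np.isfinite(values)):
        raise ValueError("values must be positive and finite to consider a log transform")
    raw = float(skew(values))
    logged = float(skew(np.log(values)))
    applied = raw > threshold and logged < raw
    return TransformDecision(variable, raw, logged, threshold, applied)


def _depth_from_angles(angles: np.ndarray, n_zero: int) -> int:
    """Exact Tukey depth given angles of (cloud − point) and the count of
    coincident points.

    depth = n_zero + min over ψ of #{a_j in the closed half-circle (ψ, ψ+π]},
    minimized just after each angle a_i (where a point exits the arc).
    """
    n = angles.size
    if n == 0:
        return n_zero
    a = np.sort(angles)
    b = np.concatenate([a, a + 2.0 * math.pi])
    hi = np.searchsorted(b, a + math.pi, side="right")
    lo = np.searchsorted(b, a, side="right")
    return n_zero + int(np.min(hi - lo))


def halfspace_depth(point, cloud) -> int:
    """Exact Tukey halfspace depth of ``point`` with respect to ``cloud``.

    The depth is the minimum, over closed halfplanes whose boundary passes
    through the point, of the number of cloud points in the halfplane.
    """
    point = np.asarray(point, dtype=float)
    cloud = np.asarray(cloud, dtype=float)
    if cloud.ndim != 2 or cloud.shape[1] != 2:
        raise ValueError("cloud must be an (n, 2) array")
    d = cloud - point
    nonzero = np.any(d != 0.0, axis=1)
    angles = np.arctan2(d[nonzero, 1], d[nonzero, 0])
    angles = np.mod(angles, 2.0 * math.pi)
    return _depth_from_angles(angles, int((~nonzero).sum()))


def _all_depths(points: np.ndarray) -> np.ndarray:
    return np.array([halfspace_depth(p, points) for p in points])


def _covers(poly: Polygon, points: np.ndarray) -> np.ndarray:
    return shapely.covers(poly, shapely.points(points))


def _scaled(hull_pts: np.ndarray, centre: np.ndarray, t: float) -> Polygon:
    return Polygon(centre + t * (hull_pts - centre))


def bagplot_outliers(
    points,
    fence_factor: float = 3.0,
    max_exact: int = 20_000,
    rng: np.random.Generator | int | None = 0,
) -> OutlierResult:
    """Flag bivariate outliers with a halfspace-depth bagplot.

    The Tukey median is the average of the deepest points.  The bag is the
    convex hull of the deepest points that still number at least n/2, shrunk
    about the Tukey median (bisection on the scale factor) until it holds
    exactly half the data — an interpolation between consecutive depth
    contours.  The fence is the bag inflated by ``fence_factor`` about the
    median; points strictly outside the fence are flagged.

    For n > ``max_exact`` a random subsample defines the bag and fence and
    every point is then tested against the fence.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < 10:
        raise ValueError("need at least 10 points")
    if fence_factor <= 1.0:
        raise ValueError("fence_factor must exceed 1")
    centred = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-10 * max(1.0, np.abs(centred).max())) < 2:
        raise CollinearInputError(
            "points are collinear; bagplot undefined, use univariate methods"
        )

    if n > max_exact:
        rng = np.random.default_rng(rng)
        idx = rng.choice(n, size=max_exact, replace=False)
        ref = points[idx]
    else:
        ref = points
    m = ref.shape[0]

    depths_ref = _all_depths(ref)
    dmax = depths_ref.max()
    tukey_median = ref[depths_ref == dmax].mean(axis=0)

    # outermost depth contour still holding at least half of the points
    half = int(math.ceil(m / 2))
    k_out = dmax
    for k in range(dmax, 0, -1):
        if int((depths_ref >= k).sum()) >= half:
            k_out = k
            break
    outer_pts = ref[depths_ref >= k_out]
    hull = ConvexHull(outer_pts)
    hull_pts = outer_pts[hull.vertices]

    # shrink the outer contour about the Tukey median until it covers half
    lo_t, hi_t = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo_t + hi_t)
        if _covers(_scaled(hull_pts, tukey_median, mid), ref).sum() >= half:
            hi_t = mid
        else:
            lo_t = mid
    bag_pts = tukey_median + hi_t * (hull_pts - tukey_median)
    fence_pts = tukey_median + fence_factor * hi_t * (hull_pts - tukey_median)
    fence_poly = Polygon(fence_pts)

    flags = ~_covers(fence_poly, points)
    depths = depths_ref if n <= max_exact else np.array(
        [halfspace_depth(p, ref) for p in points]
    )
    if flags.any():
        logger.info("bagplot flagged %d of %d points as outliers", flags.sum(), n)
    return OutlierResult(
        flags=flags,
        depths=depths,
        tukey_median=tukey_median,
        bag_vertices=bag_pts,
        fence_vertices=fence_pts,
        fence_factor=fence_factor,
    )


# ---------------------------------------------------------------------------
# variogram nugget -> sigma_e


def _spherical(h, c0, c1, a):
    hr = np.minimum(h / a, 1.0)
    return c0 + c1 * (1.5 * hr - 0.5 * hr**3)


def _exponential(h, c0, c1, a):
    return c0 + c1 * (1.0 - np.exp(-h / a))


_FAMILIES = {"spherical": _spherical, "exponential": _exponential}


def empirical_variogram(
    coords, values, n_bins: int = 15, min_pairs: int = 30,
    max_lag: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Matheron semivariogram with equal-width lag bins.

    The maximum lag defaults to the smaller of half the maximum inter-point
    distance and ``20 x`` the median nearest-neighbour distance: nugget
    estimation needs the short-range structure resolved at the sampling
    scale, and lags beyond it carry no information about it.  Bins with
    fewer than ``min_pairs`` pairs are dropped."""
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    d = pdist(coords)
    if d.max() == 0:
        raise ValueError("all coordinates identical; variogram undefined")
    g = 0.5 * pdist(values[:, None], metric="sqeuclidean")
    if max_lag is None:
        nn = cKDTree(coords).query(coords, k=2)[0][:, 1]
        max_lag = min(d.max() / 2.0, 20.0 * float(np.median(nn)))
    hmax = float(max_lag)
    edges = np.linspace(0.0, hmax, n_bins + 1)
    which = np.digitize(d, edges[1:-1])
    inside = d <= hmax
    lags, semis, counts = [], [], []
    for j in range(n_bins):
        sel = inside & (which == j)
        npairs = int(sel.sum())
        if npairs < min_pairs:
            continue
        lags.append(d[sel].mean())
        semis.append(g[sel].mean())
        counts.append(npairs)
    if len(lags) < 4:
        raise ValueError("too few usable lag bins for a variogram fit")
    return np.array(lags), np.array(semis), np.array(counts, dtype=int)


def fit_variogram_model(
    lags: np.ndarray, semis: np.ndarray, counts: np.ndarray
) -> tuple[str, float, float, float, float]:
    """WLS fit (weights N_j / h_j^2) of spherical and exponential models;
    the family with the smaller objective wins.  Returns
    (family, nugget, partial sill, range, objective)."""
    best = None
    sill0 = semis[-3:].mean()
    c0_0 = max(min(semis[0], sill0), 0.0)
    c1_0 = max(sill0 - c0_0, 1e-6 * max(sill0, 1.0))
    w = np.sqrt(counts) / lags
    for name, fam in _FAMILIES.items():
        def resid(p, fam=fam):
            return w * (fam(lags, *p) - semis)
        for a0 in (lags.max() / 3.0, lags.max()):
            sol = least_squares(
                resid,
                x0=[c0_0, c1_0, a0],
                bounds=([0.0, 0.0, lags.min() / 10.0], [np.inf, np.inf, 10.0 * lags.max()]),
                method="trf",
            )
            obj = float(np.sum(sol.fun**2))
            if best is None or obj < best[4]:
                c0, c1, a = sol.x
                best = (name, float(c0), float(c1), float(a), obj)
    return best


def estimate_sigma_e(
    records=None,
    coords=None,
    values=None,
    n_bins: int = 15,
    min_pairs: int = 30,
    max_lag: float | None = None,
    demean_by_farm: bool = False,
) -> VariogramEstimate:
    """Estimate the yield observation-error SD from the variogram nugget.

    Accepts either a list of ZoneRecord (coordinates east/north, yield) or
    explicit ``coords`` (n, 2) and ``values`` arrays.  The empirical
    semivariogram is pooled over the dataset; ``demean_by_farm`` subtracts
    farm means first (off by default).
    """
    if records is not None:
        coords = np.array([[r.east, r.north] for r in records], dtype=float)
        values = np.array([r.yield_t_ha for r in records], dtype=float)
        if demean_by_farm:
            import pandas as pd

            farms = pd.Series([r.farm_id for r in records])
            values = values - farms.map(
                pd.Series(values).groupby(farms).mean()
            ).to_numpy()
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if coords.shape[0] < 100:
        raise ValueError("need at least 100 located records")

    if np.allclose(values, values[0]):
        # constant field: all semivariances zero, nugget zero
        lags = np.linspace(1.0, 10.0, n_bins)
        return VariogramEstimate(lags, np.zeros(n_bins), np.zeros(n_bins, dtype=int),
                                 "spherical", 0.0, 0.0, float(lags[-1]), 0.0)

    lags, semis, counts = empirical_variogram(coords, values, n_bins, min_pairs, max_lag)
    family, nugget, psill, rng_, obj = fit_variogram_model(lags, semis, counts)
    if nugget < 0:
        warnings.warn("negative fitted nugget clamped to 0")
        nugget = 0.0
    return VariogramEstimate(lags, semis, counts, family, nugget, psill, rng_, obj)
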