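"""Synthetic zone-level datasets with the structure the analysis assumes.

Emulates national-scale farm data: farms of ~27 management zones laid out on
jittered grids, a latent bivariate-normal (yield, log-concentration) pair per
zone, optional upper censoring of yield by a bounded-linear boundary or a
constant, spatially structured yield error plus iid observation noise, and
optional gross bivariate outliers.  Nutrient concentrations are stored in
mg/L (exponentiated), so raw concentrations are positively skewed while log
concentrations are near-symmetric.

When spatial structure is requested, the latent pair is generated from
farm-block Gaussian processes (Cholesky factorization per farm) so that zone
yields are spatially correlated and the variogram nugget of observed yield
identifies the observation-noise variance sigma_e^2.  With ``spatial=None``
zones are iid draws from the model exactly as the likelihood assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import quad
from scipy.stats import norm

from .data_io import DEPTH_CLASSES, NUTRIENT_COLUMNS, ZoneRecord
from .model_core import BoundaryParams, LatentBivariate, eval_boundary


@dataclass(frozen=True)
class SpatialStructure:
    """Covariance of the spatially structured part of the yield field."""

    model: str = "spherical"           # or "exponential"
    range_m: float = 4000.0
    partial_sill: float = 0.5          # (t/ha)^2 of structured yield error
    nugget: float | None = None        # defaults to sigma_e^2 of the spec

    def correlation(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        a = self.range_m
        if self.model == "spherical":
            hr = np.minimum(h / a, 1.0)
            return 1.0 - (1.5 * hr - 0.5 * hr**3)
        if self.model == "exponential":
            return np.exp(-h / a)
        raise ValueError(f"unknown spatial model {self.model!r}")


@dataclass(frozen=True)
class GeneratorSpec:
    """Full description of one synthetic dataset."""

    n_farms: int = 200
    zones_per_farm: int = 27
    latent: LatentBivariate = LatentBivariate(
        mu_y=12.0, mu_x=4.0, sigma_y=2.5, sigma_x=0.5, rho=0.3
    )
    boundary: BoundaryParams | None = BoundaryParams(-21.05, 10.15, 13.64)
    constant_censor: float | None = None
    sigma_e: float = 0.5
    spatial: SpatialStructure | None = SpatialStructure()
    outlier_fraction: float = 0.0
    rng_seed: int = 0
    nutrient: str = "Mg"
    crop: str = "milling"
    season: int = 2016
    zone_spacing_m: float = 150.0
    farm_spacing_m: float = 5000.0

    def __post_init__(self) -> None:
        if self.boundary is not None and self.constant_censor is not None:
            raise ValueError("at most one of boundary / constant_censor may be active")
        if not 0.0 <= self.outlier_fraction < 0.2:
            raise ValueError("outlier_fraction must lie in [0, 0.2)")
        if self.sigma_e < 0:
            raise ValueError("sigma_e must be non-negative")
        if self.nutrient not in NUTRIENT_COLUMNS:
            raise ValueError(f"unknown nutrient {self.nutrient!r}")

    @property
    def n_zones(self) -> int:
        return self.n_farms * self.zones_per_farm

    @property
    def nugget(self) -> float:
        if self.spatial is not None and self.spatial.nugget is not None:
            return self.spatial.nugget
        return self.sigma_e**2


def _farm_coordinates(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    """Zone centroids: farms on a coarse grid, zones on jittered fine grids."""
    n_side = math.ceil(math.sqrt(spec.zones_per_farm))
    fcols = math.ceil(math.sqrt(spec.n_farms))
    coords = np.empty((spec.n_zones, 2))
    k = 0
    for f in range(spec.n_farms):
        fx = (f % fcols) * spec.farm_spacing_m
        fy = (f // fcols) * spec.farm_spacing_m
        for z in range(spec.zones_per_farm):
            gx = (z % n_side) * spec.zone_spacing_m
            gy = (z // n_side) * spec.zone_spacing_m
            jitter = rng.uniform(-0.2, 0.2, size=2) * spec.zone_spacing_m
            coords[k] = (fx + gx + jitter[0], fy + gy + jitter[1])
            k += 1
    return coords


def _farm_gps(
    spec: GeneratorSpec, coords: np.ndarray, rng: np.random.Generator, n_fields: int
) -> np.ndarray:
    """``n_fields`` independent unit-variance GPs on the zone centroids,
    farms independent (block Cholesky)."""
    out = np.empty((n_fields, spec.n_zones))
    zpf = spec.zones_per_farm
    for f in range(spec.n_farms):
        sl = slice(f * zpf, (f + 1) * zpf)
        c = coords[sl]
        d = np.hypot(c[:, 0:1] - c[None, :, 0], c[:, 1:2] - c[None, :, 1])
        corr = spec.spatial.correlation(d)
        L = np.linalg.cholesky(corr + 1e-9 * np.eye(zpf))
        z = rng.standard_normal((n_fields, zpf))
        out[:, sl] = z @ L.T
    return out


def generate_zones(
    spec: GeneratorSpec, return_trace: bool = False
) -> list[ZoneRecord] | tuple[list[ZoneRecord], dict]:
    """Generate one dataset of zone records from the spec.

    Per zone: draw the latent pair (Y, X), censor the yield from above if a
    boundary or constant censor is active, add structured + iid observation
    error, exponentiate X for the stored mg/L concentration.  The optional
    trace exposes the latent draws (for invariant checks)."""
    rng = np.random.default_rng(spec.rng_seed)
    lat = spec.latent
    n = spec.n_zones
    coords = _farm_coordinates(spec, rng)

    if spec.spatial is None:
        g1 = rng.standard_normal(n)
        g2 = rng.standard_normal(n)
        e_struct = np.zeros(n)
    else:
        g1, g2 = _farm_gps(spec, coords, rng, 2)
        if spec.spatial.partial_sill > 0:
            e_struct = math.sqrt(spec.spatial.partial_sill) * _farm_gps(spec, coords, rng, 1)[0]
        else:
            e_struct = np.zeros(n)

    x_log = lat.mu_x + lat.sigma_x * g1
    y_latent = lat.mu_y + lat.sigma_y * (lat.rho * g1 + math.sqrt(1 - lat.rho**2) * g2)

    if spec.boundary is not None:
        lam = eval_boundary(spec.boundary, x_log)
    elif spec.constant_censor is not None:
        lam = np.full(n, spec.constant_censor)
    else:
        lam = np.full(n, np.inf)
    y_censored = np.minimum(y_latent, lam)

    noise_sd = math.sqrt(spec.nugget)
    y_obs = y_censored + e_struct + noise_sd * rng.standard_normal(n)

    outlier_idx = np.array([], dtype=int)
    if spec.outlier_fraction > 0:
        k = int(round(spec.outlier_fraction * n))
        outlier_idx = rng.choice(n, size=k, replace=False)
        theta = rng.uniform(0.0, 2.0 * math.pi, size=k)
        x_log = x_log.copy()
        x_log[outlier_idx] += 6.0 * lat.sigma_x * np.cos(theta)
        y_obs[outlier_idx] += 6.0 * lat.sigma_y * np.sin(theta)

    ph = np.clip(rng.normal(7.2, 0.6, size=n), 3.0, 10.0)
    depth = rng.choice(DEPTH_CLASSES, size=n, p=(0.25, 0.35, 0.40))
    conc = np.exp(x_log)
    nut_col = NUTRIENT_COLUMNS[spec.nutrient]

    records = []
    zpf = spec.zones_per_farm
    for i in range(n):
        farm = f"F{i // zpf:04d}"
        kwargs = {
            "zone_id": f"{farm}Z{i % zpf:03d}",
            "farm_id": farm,
            "east": float(coords[i, 0]),
            "north": float(coords[i, 1]),
            "season": spec.season,
            "crop": spec.crop,
            "yield_t_ha": float(max(y_obs[i], 0.0)),
            "ph": float(ph[i]),
            "depth_class": str(depth[i]),
            nut_col: float(conc[i]),
        }
        records.append(ZoneRecord(**kwargs))

    if not return_trace:
        return records
    trace = {
        "coords": coords,
        "x_log": x_log,
        "y_latent": y_latent,
        "y_censored": y_censored,
        "censored": y_latent > lam,
        "y_obs": y_obs,
        "outlier_idx": outlier_idx,
    }
    return records, trace


def censoring_fraction(spec: GeneratorSpec) -> float:
    """P(Y > Λ(X)) under the latent bivariate normal, by 1-D quadrature over
    x of the conditional exceedance probability (relative tolerance 1e-6)."""
    lat = spec.latent
    for v in (lat.mu_y, lat.mu_x, lat.sigma_y, lat.sigma_x, lat.rho):
        if not np.isfinite(v):
            raise ValueError("non-finite latent parameters")
    if spec.boundary is None and spec.constant_censor is None:
        raise ValueError("no censoring mechanism active")
    sig_c = lat.sigma_y * math.sqrt(1.0 - lat.rho**2)

    def integrand(x):
        if spec.boundary is not None:
            lam = min(spec.boundary.beta0 + spec.boundary.beta1 * x, spec.boundary.beta2)
        else:
            lam = spec.constant_censor
        mu_c = lat.mu_y + lat.rho * (lat.sigma_y / lat.sigma_x) * (x - lat.mu_x)
        return norm.pdf(x, lat.mu_x, lat.sigma_x) * norm.sf((lam - mu_c) / sig_c)

    lo, hi = lat.mu_x - 12 * lat.sigma_x, lat.mu_x + 12 * lat.sigma_x
    pts = []
    if spec.boundary is not None and spec.boundary.beta1 != 0:
        knot = (spec.boundary.beta2 - spec.boundary.beta0) / spec.boundary.beta1
        if lo < knot < hi:
            pts = [knot]
    val, _ = quad(integrand, lo, hi, points=pts or None, epsrel=1e-9, limit=200)
    return float(val)


def uncensored_spec(**overrides) -> GeneratorSpec:
    """A plain bivariate-normal dataset (no boundary, no constant censor)."""
    base = GeneratorSpec(boundary=None, constant_censor=None)
    return replace(base, **overrides)
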