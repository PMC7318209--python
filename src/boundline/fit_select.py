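"""Maximum-likelihood fitting of the three competing models and AIC-weight
model competition.

Fitting is multi-start: a moment-based initial guess, a derivative-free
simplex pass followed by a quasi-Newton polish (the likelihood has
kink-induced curvature where the boundary knot crosses data), a second pass
re-optimized with per-parameter scaling derived from numerical curvature at
the first solution, and a configurable number of jittered restarts.  SDs are
optimized as logs and the correlation as arctanh, so the search is
unconstrained; sigma_e stays fixed throughout and is not counted as a free
parameter.

Standard errors come from the finite-difference Hessian of the negative
log-likelihood in the original parameterization, inverted to a covariance
matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .model_core import (
    PARAM_COUNT,
    BoundaryParams,
    LatentBivariate,
    ModelSpec,
    negative_log_likelihood,
)

logger = logging.getLogger(__name__)

PARAM_NAMES = {
    "BL": ("beta0", "beta1", "beta2", "mu_y", "mu_x", "sigma_y", "sigma_x", "rho"),
    "MVN": ("mu_y", "mu_x", "sigma_y", "sigma_x", "rho"),
    "MVN_c": ("mu_y", "mu_x", "sigma_y", "sigma_x", "rho", "censor"),
}

_VAR_FLOOR = 1e-6


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for one model fit."""

    n_extra_starts: int = 8
    jitter_scale: float = 0.25
    rescale: bool = True
    nm_maxiter: int = 1000
    gtol: float = 1e-6
    rng_seed: int = 0
    hessian_step: float = 5e-3
    compute_cov: bool = True


@dataclass
class FittedModel:
    """One model at its maximum-likelihood optimum."""

    kind: str
    spec: ModelSpec
    params: dict[str, float]
    ell: float
    P: int
    A: float
    cov: np.ndarray
    se: dict[str, float]
    n_starts: int
    converged: bool
    hessian_ok: bool = True

    @property
    def param_names(self) -> tuple[str, ...]:
        return PARAM_NAMES[self.kind]

    def beta_cov(self) -> np.ndarray:
        """3x3 marginal covariance of (beta0, beta1, beta2) (BL only)."""
        if self.kind != "BL":
            raise ValueError("boundary covariance only defined for BL fits")
        return self.cov[:3, :3]


@dataclass
class ModelComparison:
    fits: dict[str, FittedModel]
    delta: dict[str, float]
    weights: dict[str, float]
    preferred: str
    selected: str | None          # "BL" or None (BL rejected)


# ---------------------------------------------------------------------------
# parameterization


def _spec_from_original(kind: str, p: np.ndarray, sigma_e: float) -> ModelSpec:
    if kind == "BL":
        b = BoundaryParams(*p[:3])
        lat = LatentBivariate(p[3], p[4], p[5], p[6], p[7], sigma_e)
        return ModelSpec("BL", lat, boundary=b)
    lat = LatentBivariate(p[0], p[1], p[2], p[3], p[4], sigma_e)
    if kind == "MVN":
        return ModelSpec("MVN", lat)
    return ModelSpec("MVN_c", lat, censor=float(p[5]))


def _orig_to_transformed(kind: str, p: np.ndarray) -> np.ndarray:
    t = np.array(p, dtype=float)
    off = 3 if kind == "BL" else 0
    t[off + 2] = math.log(p[off + 2])
    t[off + 3] = math.log(p[off + 3])
    t[off + 4] = math.atanh(p[off + 4])
    return t


def _transformed_to_orig(kind: str, t: np.ndarray) -> np.ndarray:
    p = np.array(t, dtype=float)
    off = 3 if kind == "BL" else 0
    p[off + 2] = math.exp(t[off + 2])
    p[off + 3] = math.exp(t[off + 3])
    p[off + 4] = math.tanh(t[off + 4])
    return p


def _make_nll_t(kind: str, y: np.ndarray, x: np.ndarray, sigma_e: float):
    def nll_t(t: np.ndarray) -> float:
        try:
            spec = _spec_from_original(kind, _transformed_to_orig(kind, t), sigma_e)
        except (ValueError, OverflowError):
            return float("inf")
        return negative_log_likelihood(y, x, spec)

    return nll_t


def _make_nll_orig(kind: str, y: np.ndarray, x: np.ndarray, sigma_e: float):
    def nll_o(p: np.ndarray) -> float:
        try:
            spec = _spec_from_original(kind, np.asarray(p, dtype=float), sigma_e)
        except (ValueError, OverflowError):
            return float("inf")
        return negative_log_likelihood(y, x, spec)

    return nll_o


# ---------------------------------------------------------------------------
# starts


def closed_form_mvn(y, x, sigma_e: float) -> LatentBivariate:
    """Exact ML latent parameters for the uncensored model: sample means and
    1/n (co)variances, with sigma_e^2 subtracted from the yield variance
    (floored to keep it positive)."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    mu_y, mu_x = y.mean(), x.mean()
    vy = max(y.var() - sigma_e**2, _VAR_FLOOR)
    vx = max(x.var(), _VAR_FLOOR)
    cxy = np.mean((y - mu_y) * (x - mu_x))
    rho = cxy / math.sqrt(vy * vx)
    rho = float(np.clip(rho, -0.99, 0.99))
    return LatentBivariate(float(mu_y), float(mu_x), math.sqrt(vy), math.sqrt(vx),
                           rho, sigma_e)


def _bl_boundary_starts(y: np.ndarray, x: np.ndarray) -> list[BoundaryParams]:
    """Candidate boundary starts.

    The boundary likelihood has a flat-censor local optimum (slope → 0), so
    the candidate set deliberately includes strongly sloped boundaries that
    bind on the lower-x data: (a) slope through the maximal-yield points of
    the lower and upper x-halves, (b) a line fitted to upper yield quantiles
    of x-bins on the rising limb, (c) steep boundaries hinged at interior
    knots."""
    beta2 = float(np.quantile(y, 0.99))
    starts: list[BoundaryParams] = []

    med = np.median(x)
    lo, hi = x <= med, x > med
    i = int(np.argmax(np.where(lo, y, -np.inf)))
    j = int(np.argmax(np.where(hi, y, -np.inf)))
    dx = x[j] - x[i]
    slope = (y[j] - y[i]) / dx if dx != 0 else 0.0
    if slope > 0:
        starts.append(BoundaryParams(float(y[i] - slope * x[i]), float(slope), beta2))

    # upper-quantile line through the lower-x bins
    edges = np.quantile(x, np.linspace(0.0, 1.0, 11))
    centres, tops = [], []
    for k in range(10):
        sel = (x >= edges[k]) & (x <= edges[k + 1])
        if sel.sum() >= 5:
            centres.append(x[sel].mean())
            tops.append(np.quantile(y[sel], 0.95))
    centres, tops = np.array(centres), np.array(tops)
    if centres.size >= 4:
        half = centres <= np.median(centres)
        if half.sum() >= 2:
            b1, b0 = np.polyfit(centres[half], tops[half], 1)
            if b1 > 0:
                starts.append(BoundaryParams(float(b0), float(b1), beta2))

    # steep boundaries hinged at interior x-quantiles, reaching down to the
    # bulk of the yields at the low-x edge
    y_low = float(np.quantile(y, 0.3))
    x_edge = float(np.quantile(x, 0.02))
    for q in (0.2, 0.5):
        knot = float(np.quantile(x, q))
        if knot > x_edge:
            s = (beta2 - y_low) / (knot - x_edge)
            starts.append(BoundaryParams(beta2 - s * knot, s, beta2))
    if not starts:
        s = y.std() / max(x.std(), 1e-6)
        starts.append(BoundaryParams(beta2 - s * float(np.median(x)), float(s), beta2))
    return starts


def _initial_originals(kind: str, y: np.ndarray, x: np.ndarray, sigma_e: float) -> list[np.ndarray]:
    lat = closed_form_mvn(y, x, sigma_e)
    lat_vec = [lat.mu_y, lat.mu_x, lat.sigma_y, lat.sigma_x, lat.rho]
    if kind == "MVN":
        return [np.array(lat_vec)]
    if kind == "MVN_c":
        return [np.array(lat_vec + [float(np.quantile(y, 0.99))])]
    return [
        np.array([b.beta0, b.beta1, b.beta2] + lat_vec)
        for b in _bl_boundary_starts(y, x)
    ]


# ---------------------------------------------------------------------------
# optimization


def _optimize(nll_t, t0: np.ndarray, cfg: FitConfig) -> tuple[np.ndarray, float, bool]:
    """Simplex pass then quasi-Newton polish; returns (t, f, converged)."""
    r1 = minimize(nll_t, t0, method="Nelder-Mead",
                  options={"maxiter": cfg.nm_maxiter, "xatol": 1e-6, "fatol": 1e-8})
    try:
        r2 = minimize(nll_t, r1.x, method="L-BFGS-B",
                      options={"gtol": cfg.gtol, "maxiter": 500})
        if np.isfinite(r2.fun) and r2.fun <= r1.fun:
            return r2.x, float(r2.fun), bool(r2.success or r1.success)
    except (ValueError, np.linalg.LinAlgError):  # inf/nan in FD gradients
        pass
    return r1.x, float(r1.fun), bool(r1.success)


def _rescaled_pass(nll_t, t: np.ndarray, f: float, cfg: FitConfig):
    """Re-optimize with per-parameter scaling from numerical curvature at the
    first solution, so a unit step changes the likelihood comparably."""
    d = np.empty_like(t)
    for i in range(t.size):
        h = 1e-3 * max(abs(t[i]), 1.0)
        e = np.zeros_like(t)
        e[i] = h
        d[i] = (nll_t(t + e) - 2.0 * f + nll_t(t - e)) / h**2
    scale = 1.0 / np.sqrt(np.clip(d, 1e-8, None))
    scale = np.clip(scale / np.exp(np.mean(np.log(scale))), 1e-3, 1e3)

    def nll_u(u):
        return nll_t(u * scale)

    u, fu, ok = _optimize(nll_u, t / scale, cfg)
    return (u * scale, fu, ok) if fu < f else (t, f, True)


def fit_model(y, x, kind: str, sigma_e: float, config: FitConfig | None = None) -> FittedModel:
    """Fit one model kind to (yield, log-concentration) data by ML.

    ``sigma_e`` is the fixed observation-noise SD from preprocessing.
    Returns the best solution over all starts with Hessian-based SEs; if no
    optimizer run converged the best-effort estimates are flagged.
    """
    cfg = config or FitConfig()
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size < 30:
        raise ValueError("need at least 30 observations")
    if kind not in PARAM_COUNT:
        raise ValueError(f"unknown model kind {kind!r}")

    nll_t = _make_nll_t(kind, y, x, sigma_e)
    # screen the candidate starts with a short simplex run, then fully
    # optimize from the two most promising
    screened = []
    n_starts = 0
    for p0 in _initial_originals(kind, y, x, sigma_e):
        t0 = _orig_to_transformed(kind, p0)
        r = minimize(nll_t, t0, method="Nelder-Mead",
                     options={"maxiter": 200, "xatol": 1e-4, "fatol": 1e-4})
        screened.append((float(r.fun), r.x))
        n_starts += 1
    screened.sort(key=lambda s: s[0])
    best_t = best_f = best_ok = None
    for _, t0 in screened[:2]:
        t, f, ok = _optimize(nll_t, t0, cfg)
        if best_f is None or f < best_f:
            best_t, best_f, best_ok = t, f, ok
    if cfg.rescale:
        best_t, best_f, ok = _rescaled_pass(nll_t, best_t, best_f, cfg)
        best_ok = best_ok or ok

    rng = np.random.default_rng(cfg.rng_seed)
    spread = np.maximum(np.abs(best_t), 0.5)
    cfg_jit = replace(cfg, nm_maxiter=min(cfg.nm_maxiter, 300))
    for _ in range(cfg.n_extra_starts):
        tj = best_t + cfg.jitter_scale * spread * rng.standard_normal(best_t.size)
        t, f, ok = _optimize(nll_t, tj, cfg_jit)
        n_starts += 1
        if f < best_f:
            best_t, best_f, best_ok = t, f, ok

    p_opt = _transformed_to_orig(kind, best_t)
    spec = _spec_from_original(kind, p_opt, sigma_e)
    P = PARAM_COUNT[kind]
    names = PARAM_NAMES[kind]
    if cfg.compute_cov:
        nll_o = _make_nll_orig(kind, y, x, sigma_e)
        cov, hessian_ok = hessian_covariance(
            nll_o, p_opt, step=cfg.hessian_step, rng_seed=cfg.rng_seed
        )
        se = {nm: float(math.sqrt(max(cov[i, i], 0.0))) for i, nm in enumerate(names)}
    else:
        cov = np.full((P, P), np.nan)
        hessian_ok = False
        se = {nm: float("nan") for nm in names}
    if not best_ok:
        logger.warning("%s fit: no optimizer start reported convergence", kind)
    return FittedModel(
        kind=kind,
        spec=spec,
        params={nm: float(v) for nm, v in zip(names, p_opt)},
        ell=best_f,
        P=P,
        A=aic(best_f, P),
        cov=cov,
        se=se,
        n_starts=n_starts,
        converged=best_ok,
        hessian_ok=hessian_ok,
    )


def finite_difference_hessian(fun, theta: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function."""
    theta = np.asarray(theta, dtype=float)
    k = theta.size
    h = step * np.maximum(np.abs(theta), 1.0)
    H = np.empty((k, k))
    f0 = fun(theta)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        H[i, i] = (fun(theta + ei) - 2.0 * f0 + fun(theta - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(theta + ei + ej) - fun(theta + ei - ej)
                - fun(theta - ei + ej) + fun(theta - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _quadratic_fit_hessian(fun, theta: np.ndarray, cov: np.ndarray,
                           rng: np.random.Generator, n_pts: int = 300,
                           spread: float = 1.5) -> np.ndarray:
    """Least-squares quadratic fit of ``fun`` over a cloud of points drawn
    from N(theta, spread^2 * cov); returns the fitted Hessian."""
    k = theta.size
    L = np.linalg.cholesky(cov + 1e-12 * np.trace(cov) / k * np.eye(k))
    D = (rng.standard_normal((n_pts, k)) @ L.T) * spread
    f = np.array([fun(theta + d) for d in D])
    ok = np.isfinite(f)
    D, f = D[ok], f[ok]
    iu = np.triu_indices(k)
    X = np.concatenate(
        [
            np.ones((D.shape[0], 1)),
            D,
            np.stack([D[:, i] * D[:, j] * (0.5 if i == j else 1.0)
                      for i, j in zip(*iu)], axis=1),
        ],
        axis=1,
    )
    coef, *_ = np.linalg.lstsq(X, f, rcond=None)
    H = np.zeros((k, k))
    for m, (i, j) in enumerate(zip(*iu)):
        H[i, j] = H[j, i] = coef[1 + k + m]
    return H


def hessian_covariance(fun, theta: np.ndarray, step: float = 5e-3,
                       rng_seed: int = 0) -> tuple[np.ndarray, bool]:
    """Covariance of ML estimates from the numerical Hessian of the negative
    log-likelihood at the optimum, in the original parameterization.

    A pointwise central-difference Hessian is computed first.  Because the
    boundary likelihood is only piecewise smooth (a data point crossing the
    boundary knot introduces a micro-kink) and the information matrix has a
    near-flat direction along the β0–β1 trade-off, the raw difference
    quotient is unstable there: it is refined by iterating a least-squares
    quadratic fit of ℓ over a cloud of points matched to the current
    covariance estimate, which averages the kink noise and resolves the flat
    direction.  Returns (covariance, ok); ok is False when eigenvalue
    clipping was needed to keep the final Hessian positive definite."""
    theta = np.asarray(theta, dtype=float)
    k = theta.size
    H = finite_difference_hessian(fun, theta, step)
    try:
        c, low = cho_factor(H)
        cov = cho_solve((c, low), np.eye(k))
    except np.linalg.LinAlgError:
        # fall back to conditional (diagonal) curvatures for the initial scale
        d = np.clip(np.diag(H), 1e-6, None)
        cov = np.diag(1.0 / d)
    rng = np.random.default_rng(rng_seed)
    ok = True
    for _ in range(3):
        H = _quadratic_fit_hessian(fun, theta, cov, rng)
        w, V = np.linalg.eigh(H)
        ok = bool(w.min() > 0)
        w = np.clip(w, 1e-8, None)
        cov = V @ np.diag(1.0 / w) @ V.T
    if not ok:
        logger.warning("curvature not positive definite at the optimum; "
                       "smallest eigenvalue clipped")
    return cov, ok


# ---------------------------------------------------------------------------
# AIC competition


def aic(ell: float, P: int) -> float:
    """Akaike's information criterion A = 2ℓ + 2P."""
    if P < 0:
        raise ValueError("P must be non-negative")
    return 2.0 * ell + 2.0 * P


def akaike_weights(A) -> np.ndarray:
    """w_i = exp(−Δ_i/2) / Σ_j exp(−Δ_j/2) with Δ_i = A_i − min(A)."""
    A = np.asarray(A, dtype=float)
    if A.size < 2 or not np.all(np.isfinite(A)):
        raise ValueError("need at least two finite AIC values")
    delta = A - A.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def select_model(cmp: ModelComparison, threshold: float = 0.5) -> str | None:
    """Boundary-line selection rule: BL is adopted iff its A is strictly the
    smallest of the three AND its Akaike weight is at least ``threshold``.
    Otherwise no boundary interpretation is made (the minimum-A model is
    still reported as preferred)."""
    a_bl = cmp.fits["BL"].A
    others = [f.A for k, f in cmp.fits.items() if k != "BL"]
    if a_bl < min(others) and cmp.weights["BL"] >= threshold:
        return "BL"
    if a_bl == min(others):
        logger.info("exact AIC tie involving BL: boundary model not selected")
    return None


def compare_models(fits: dict[str, FittedModel], threshold: float = 0.5) -> ModelComparison:
    """Akaike-weight competition of the fitted models (expects keys BL, MVN,
    MVN_c)."""
    kinds = list(fits)
    A = np.array([fits[k].A for k in kinds])
    w = akaike_weights(A)
    cmp = ModelComparison(
        fits=fits,
        delta={k: float(a - A.min()) for k, a in zip(kinds, A)},
        weights={k: float(wi) for k, wi in zip(kinds, w)},
        preferred=kinds[int(np.argmin(A))],
        selected=None,
    )
    cmp.selected = select_model(cmp, threshold)
    return cmp
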