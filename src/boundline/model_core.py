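"""Censored bivariate-normal models for boundary line analysis.

The central object is a latent Gaussian pair ``Z = (Y, X)`` — yield and
log nutrient concentration — censored from above in the yield direction by
a boundary function ``Λ(x)``.  The observable yield is

    y = min(Y, Λ(X)) + e,      e ~ N(0, sigma_e^2),

with ``X`` observed without error.  Three model kinds share this machinery:

* ``BL``    — bounded-linear boundary Λ(x) = min(β0 + β1·x, β2); 8 free
  parameters (β0, β1, β2, μ_y, μ_x, σ_y, σ_x, ρ).
* ``MVN``   — no censoring (Λ ≡ +∞); 5 free parameters.
* ``MVN_c`` — constant censor Λ ≡ c; 6 free parameters.

``sigma_e`` is fixed externally (from the variogram nugget of yield) and is
never counted as a free parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

PARAM_COUNT = {"BL": 8, "MVN": 5, "MVN_c": 6}


class UndefinedCriticalValueError(ValueError):
    """Raised when the boundary slope is non-positive so x_crit is meaningless."""


@dataclass(frozen=True)
class BoundaryParams:
    """Bounded-linear boundary Λ(x) = min(beta0 + beta1·x, beta2).

    ``beta2`` is the plateau (maximum yield, t/ha); ``beta1`` the slope of the
    limiting response (t/ha per log unit of concentration).
    """

    beta0: float
    beta1: float
    beta2: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.beta2):
            raise ValueError("beta2 must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2], dtype=float)


@dataclass(frozen=True)
class LatentBivariate:
    """Parameters of the uncensored Gaussian pair (Y, X) plus fixed noise SD."""

    mu_y: float
    mu_x: float
    sigma_y: float
    sigma_x: float
    rho: float
    sigma_e: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_y <= 0 or self.sigma_x <= 0:
            raise ValueError("sigma_y and sigma_x must be positive")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie strictly in (-1, 1)")
        if self.sigma_e < 0:
            raise ValueError("sigma_e must be non-negative")


@dataclass(frozen=True)
class ModelSpec:
    """One of the three competing models, fully parameterized.

    ``boundary`` is required for kind BL, ``censor`` for kind MVN_c.
    """

    kind: str
    latent: LatentBivariate
    boundary: BoundaryParams | None = None
    censor: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in PARAM_COUNT:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "BL" and self.boundary is None:
            raise ValueError("BL spec requires boundary parameters")
        if self.kind == "MVN_c" and self.censor is None:
            raise ValueError("MVN_c spec requires a censor level")

    @property
    def n_params(self) -> int:
        return PARAM_COUNT[self.kind]

    def boundary_at(self, x: np.ndarray) -> np.ndarray:
        """Censor level Λ(x) for this spec (vectorized; +inf for MVN)."""
        x = np.asarray(x, dtype=float)
        if self.kind == "BL":
            return eval_boundary(self.boundary, x)
        if self.kind == "MVN_c":
            return np.full_like(x, float(self.censor))
        return np.full_like(x, np.inf)


def eval_boundary(b: BoundaryParams, x) -> np.ndarray | float:
    """Boundary yield Λ(x) = min(b.beta0 + b.beta1·x, b.beta2)."""
    out = np.minimum(b.beta0 + b.beta1 * np.asarray(x, dtype=float), b.beta2)
    return float(out) if np.ndim(x) == 0 else out


def crit_value(b: BoundaryParams) -> tuple[float, float]:
    """Critical log-concentration x_crit = (β2 − β0)/β1 and exp(x_crit) in mg/L.

    Beyond x_crit the boundary is flat and the nutrient is no longer limiting
    under the model.  Requires a positive slope.
    """
    if b.beta1 <= 0:
        raise UndefinedCriticalValueError(
            f"x_crit undefined for non-positive slope beta1={b.beta1}"
        )
    x_crit = (b.beta2 - b.beta0) / b.beta1
    return x_crit, math.exp(x_crit)


def _norm_logpdf(z: np.ndarray, mu, sd) -> np.ndarray:
    return -0.5 * ((z - mu) / sd) ** 2 - np.log(sd) - _LOG_SQRT_2PI


def log_density_y_given_x(y, x, spec: ModelSpec) -> np.ndarray:
    """Log of the censored-and-convolved conditional density f_b(y | x).

    The censored conditional ``min(Y|x, Λ)`` has a continuous part below Λ
    and an atom of mass 1 − Φ((Λ − μ_c)/σ_c) at Λ.  Convolving with
    N(0, sigma_e²) gives

        f_b(y|x) = N(y; μ_c, σ_c² + σe²)·Φ((Λ − m)/s)
                 + [1 − Φ((Λ − μ_c)/σ_c)]·N(y; Λ, σe²),

    with ``m = μ_c + σ_c²(y − μ_c)/(σ_c² + σe²)`` and
    ``s² = σ_c²σe²/(σ_c² + σe²)``.  For sigma_e = 0 the atom is not smeared:
    only the continuous part is returned and y > Λ has density 0.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    lat = spec.latent
    mu_c = lat.mu_y + lat.rho * (lat.sigma_y / lat.sigma_x) * (x - lat.mu_x)
    sig_c2 = lat.sigma_y**2 * (1.0 - lat.rho**2)
    sig_c = math.sqrt(sig_c2)
    lam = spec.boundary_at(x)
    se = lat.sigma_e

    if se == 0.0:
        with np.errstate(invalid="ignore"):
            logf = np.where(y <= lam, _norm_logpdf(y, mu_c, sig_c), -np.inf)
        return logf

    s_tot2 = sig_c2 + se**2
    m = mu_c + sig_c2 * (y - mu_c) / s_tot2
    s = math.sqrt(sig_c2 * se**2 / s_tot2)
    with np.errstate(invalid="ignore", over="ignore"):
        term1 = _norm_logpdf(y, mu_c, math.sqrt(s_tot2)) + log_ndtr((lam - m) / s)
        # atom mass log(1 - Phi((lam - mu_c)/sig_c)) = log_ndtr(-(lam - mu_c)/sig_c)
        term2 = log_ndtr(-(lam - mu_c) / sig_c) + _norm_logpdf(y, lam, se)
        term2 = np.where(np.isfinite(lam), term2, -np.inf)
        return np.logaddexp(term1, term2)


def log_observed_density(y, x, spec: ModelSpec) -> np.ndarray:
    """Log joint density log f(y, x) = log f_b(y|x) + log N(x; μ_x, σ_x²)."""
    lat = spec.latent
    return log_density_y_given_x(y, x, spec) + _norm_logpdf(
        np.asarray(x, dtype=float), lat.mu_x, lat.sigma_x
    )


def observed_density(y, x, spec: ModelSpec):
    """Joint density f(y, x) under the spec (vectorized)."""
    out = np.exp(log_observed_density(y, x, spec))
    return float(out) if np.ndim(y) == 0 and np.ndim(x) == 0 else out


def negative_log_likelihood(
    y, x, spec: ModelSpec, conditional: bool = False
) -> float:
    """ℓ = −Σ log f(y_k, x_k | spec), observations treated as independent.

    ``conditional=True`` drops the marginal N(x; μ_x, σ_x²) factor (sensitivity
    option only; the fitted models use the joint form).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size == 0:
        raise ValueError("need at least one observation")
    if conditional:
        logf = log_density_y_given_x(y, x, spec)
    else:
        logf = log_observed_density(y, x, spec)
    if not np.all(np.isfinite(logf)):
        return float("inf")
    return float(-np.sum(logf))
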