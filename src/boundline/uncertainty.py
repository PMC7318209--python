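"""Monte-Carlo propagation of boundary-parameter uncertainty to x_crit.

Draws (β0, β1, β2) from the asymptotic normal N(β̂, Σ̂), maps each draw to the
critical log-concentration x_crit = (β2 − β0)/β1, summarizes the draws by a
highest-density interval and by the probability of falling in each agronomic
index band (RB209-style concentration bands in mg/L).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model_core import BoundaryParams, crit_value


@dataclass(frozen=True)
class IndexScheme:
    """Ordered concentration bands for one nutrient.

    ``cutpoints`` (mg/L, strictly increasing) delimit ``len(cutpoints)+1``
    bands; band i is [cutpoints[i-1], cutpoints[i]) with open-ended extremes.
    """

    nutrient: str
    cutpoints: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        cp = tuple(float(c) for c in self.cutpoints)
        object.__setattr__(self, "cutpoints", cp)
        object.__setattr__(self, "labels", tuple(self.labels))
        if any(b <= a for a, b in zip(cp, cp[1:])):
            raise ValueError("cutpoints must be strictly increasing")
        if len(self.labels) != len(cp) + 1:
            raise ValueError("need exactly one label per band")


# Published RB209 advisory bands (not printed in the source analysis; defaults
# only, overridable in AnalysisConfig).
DEFAULT_INDEX_SCHEMES = {
    "P": IndexScheme("P", (10.0, 16.0, 26.0, 46.0, 71.0), ("0", "1", "2", "3", "4", "5")),
    "K": IndexScheme("K", (60.0, 120.0, 180.0, 240.0, 400.0), ("0", "1", "2-", "2+", "3", "4")),
    "Mg": IndexScheme("Mg", (25.0, 50.0, 100.0, 175.0, 250.0), ("0", "1", "2", "3", "4", "5")),
}


class UnstableSlopeError(RuntimeError):
    """Raised when most MC draws have β1 ≤ 0 so x_crit inference is refused."""


@dataclass
class CritDraws:
    """Retained Monte-Carlo draws of the critical value."""

    log_draws: np.ndarray
    n_requested: int
    discarded_fraction: float

    @property
    def mgL_draws(self) -> np.ndarray:
        return np.exp(self.log_draws)


@dataclass
class CritValueInference:
    """Point estimate, HDI and index-band probabilities for x_crit."""

    point_log: float
    point_mgL: float
    hdi_low: float
    hdi_high: float
    hdi_mass: float
    index_probs: dict[str, float]
    n_requested: int
    n_retained: int
    discarded_fraction: float
    hdi_scale: str = "log"


def sample_crit_values(
    b_hat: BoundaryParams,
    cov_b: np.ndarray,
    n: int,
    rng: np.random.Generator | int | None = None,
    max_discard: float = 0.5,
) -> CritDraws:
    """Draw β ~ N(b_hat, cov_b) and return x_crit = (β2 − β0)/β1 per draw.

    Draws with β1 ≤ 0 (no rising limb, x_crit meaningless) are discarded and
    their fraction reported; if it exceeds ``max_discard`` the slope sign is
    judged unstable and inference is refused.
    """
    if n < 1000:
        raise ValueError("need at least 1000 draws")
    cov_b = np.asarray(cov_b, dtype=float)
    if cov_b.shape != (3, 3):
        raise ValueError("cov_b must be 3x3 (beta0, beta1, beta2)")
    if not np.allclose(cov_b, cov_b.T, atol=1e-10):
        raise ValueError("cov_b must be symmetric")
    rng = np.random.default_rng(rng)
    mean = b_hat.as_array()
    draws = rng.multivariate_normal(mean, cov_b, size=n, method="eigh")
    b0, b1, b2 = draws[:, 0], draws[:, 1], draws[:, 2]
    keep = b1 > 0
    frac_discarded = 1.0 - keep.mean()
    if frac_discarded > max_discard:
        raise UnstableSlopeError(
            f"{frac_discarded:.1%} of draws have non-positive slope; "
            "critical-value inference refused"
        )
    log_draws = (b2[keep] - b0[keep]) / b1[keep]
    return CritDraws(log_draws=log_draws, n_requested=n,
                     discarded_fraction=float(frac_discarded))


def hdi(draws, mass: float) -> tuple[float, float]:
    """Shortest contiguous interval holding ⌈mass·n⌉ of the sorted draws."""
    draws = np.sort(np.asarray(draws, dtype=float))
    n = draws.size
    if n < 100:
        raise ValueError("need at least 100 draws for an HDI")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    m = int(math.ceil(mass * n))
    widths = draws[m - 1:] - draws[: n - m + 1]
    i = int(np.argmin(widths))
    return float(draws[i]), float(draws[i + m - 1])


def index_probabilities(draws_mgL, scheme: IndexScheme) -> dict[str, float]:
    """Fraction of draws in each band [c_i, c_{i+1}); extremes open-ended."""
    draws_mgL = np.asarray(draws_mgL, dtype=float)
    idx = np.searchsorted(np.asarray(scheme.cutpoints), draws_mgL, side="right")
    counts = np.bincount(idx, minlength=len(scheme.labels))
    probs = counts / draws_mgL.size
    return {lab: float(p) for lab, p in zip(scheme.labels, probs)}


def infer_crit_value(
    b_hat: BoundaryParams,
    cov_b: np.ndarray,
    scheme: IndexScheme,
    n_draws: int = 500_000,
    hdi_mass: float = 0.95,
    rng: np.random.Generator | int | None = None,
    hdi_scale: str = "log",
) -> CritValueInference:
    """Full x_crit inference: point estimate, HDI and index-band probabilities.

    The HDI is computed on the log-concentration draws and exponentiated
    endpoint-wise by default (``hdi_scale="log"``); ``"mgL"`` computes it on
    the exponentiated draws directly.
    """
    x_crit, point_mgL = crit_value(b_hat)
    draws = sample_crit_values(b_hat, cov_b, n_draws, rng=rng)
    if hdi_scale == "log":
        lo, hi = hdi(draws.log_draws, hdi_mass)
        lo, hi = math.exp(lo), math.exp(hi)
    elif hdi_scale == "mgL":
        lo, hi = hdi(draws.mgL_draws, hdi_mass)
    else:
        raise ValueError("hdi_scale must be 'log' or 'mgL'")
    probs = index_probabilities(draws.mgL_draws, scheme)
    return CritValueInference(
        point_log=x_crit,
        point_mgL=point_mgL,
        hdi_low=lo,
        hdi_high=hi,
        hdi_mass=hdi_mass,
        index_probs=probs,
        n_requested=n_draws,
        n_retained=int(draws.log_draws.size),
        discarded_fraction=draws.discarded_fraction,
        hdi_scale=hdi_scale,
    )
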