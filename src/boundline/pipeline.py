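"""End-to-end boundary line analysis of a zone table.

Stages: subset → log-transform decision → bagplot outlier removal →
variogram-nugget estimation of the yield observation-error SD → ML fits of
the three competing models → Akaike-weight competition → (if the boundary
model is selected) Monte-Carlo inference for the critical concentration.
Stage failures are recorded in the report and the pipeline continues,
emitting a partial report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fit_select, preprocessing, uncertainty
from .data_io import NUTRIENT_COLUMNS, ZoneRecord, subset_records
from .fit_select import FitConfig, ModelComparison
from .preprocessing import OutlierResult, TransformDecision, VariogramEstimate
from .uncertainty import DEFAULT_INDEX_SCHEMES, CritValueInference, IndexScheme

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything a single boundary-line analysis needs."""

    nutrient: str = "P"
    subset_rule: str | None = None
    transform_skew_threshold: float = 1.0
    bagplot_fence_factor: float = 3.0
    n_mc_draws: int = 500_000
    hdi_mass: float = 0.95
    selection_threshold: float = 0.5
    index_scheme: IndexScheme | None = None
    rng_seed: int = 0
    min_records: int = 50
    hdi_scale: str = "log"
    demean_by_farm: bool = False
    fit: FitConfig = field(default_factory=FitConfig)

    def __post_init__(self) -> None:
        if not 0.0 < self.hdi_mass < 1.0:
            raise ValueError("hdi_mass must lie in (0, 1)")
        if self.n_mc_draws < 1000:
            raise ValueError("n_mc_draws must be at least 1000")
        if self.bagplot_fence_factor <= 1.0:
            raise ValueError("bagplot_fence_factor must exceed 1")
        if self.nutrient not in NUTRIENT_COLUMNS:
            raise ValueError(f"unknown nutrient {self.nutrient!r}")

    def resolved_scheme(self) -> IndexScheme:
        return self.index_scheme or DEFAULT_INDEX_SCHEMES[self.nutrient]


@dataclass
class AnalysisReport:
    """Every intermediate artifact of one analysis run."""

    config: AnalysisConfig
    n_input: int = 0
    n_subset: int = 0
    n_with_nutrient: int = 0
    n_after_outliers: int = 0
    transform: TransformDecision | None = None
    outliers: OutlierResult | None = None
    variogram: VariogramEstimate | None = None
    sigma_e: float | None = None
    comparison: ModelComparison | None = None
    crit: CritValueInference | None = None
    stage_errors: dict[str, str] = field(default_factory=dict)
    index_scheme_provenance: str = (
        "RB209 advisory bands (package defaults; user-overridable)"
    )

    # -- table-shaped summaries -------------------------------------------

    def model_table(self) -> pd.DataFrame:
        """Per-model ℓ, A and Akaike weight (layout of a model-competition
        table)."""
        if self.comparison is None:
            return pd.DataFrame(columns=["model", "ell", "A", "w"])
        rows = [
            {"model": k, "ell": f.ell, "A": f.A, "w": self.comparison.weights[k]}
            for k, f in self.comparison.fits.items()
        ]
        return pd.DataFrame(rows)

    def params_table(self) -> pd.DataFrame:
        """Boundary parameter estimates and SEs (rows β2, β0, β1)."""
        if self.comparison is None or "BL" not in self.comparison.fits:
            return pd.DataFrame(columns=["parameter", "estimate", "se"])
        f = self.comparison.fits["BL"]
        return pd.DataFrame(
            [
                {"parameter": p, "estimate": f.params[p], "se": f.se[p]}
                for p in ("beta2", "beta0", "beta1")
            ]
        )

    def crit_table(self) -> pd.DataFrame:
        """Critical concentration, HDI bounds and index-band probabilities."""
        if self.crit is None:
            return pd.DataFrame()
        row = {
            "estimate_mgL": self.crit.point_mgL,
            "hdi_low_mgL": self.crit.hdi_low,
            "hdi_high_mgL": self.crit.hdi_high,
        }
        row.update({f"P(index {k})": v for k, v in self.crit.index_probs.items()})
        return pd.DataFrame([row])

    def to_dict(self) -> dict:
        d = {
            "config": _jsonable(dataclasses.asdict(self.config)),
            "n_input": self.n_input,
            "n_subset": self.n_subset,
            "n_with_nutrient": self.n_with_nutrient,
            "n_after_outliers": self.n_after_outliers,
            "sigma_e": self.sigma_e,
            "stage_errors": self.stage_errors,
            "index_scheme_provenance": self.index_scheme_provenance,
        }
        if self.transform is not None:
            d["transform"] = _jsonable(dataclasses.asdict(self.transform))
        if self.outliers is not None:
            d["outliers"] = {
                "n_flagged": self.outliers.n_flagged,
                "fence_factor": self.outliers.fence_factor,
                "tukey_median": _jsonable(self.outliers.tukey_median),
                "bag_vertices": _jsonable(self.outliers.bag_vertices),
                "fence_vertices": _jsonable(self.outliers.fence_vertices),
            }
        if self.variogram is not None:
            v = self.variogram
            d["variogram"] = _jsonable(
                {
                    "model": v.model, "nugget": v.nugget,
                    "partial_sill": v.partial_sill, "range": v.range_,
                    "lags": v.lags, "semivariances": v.semivariances,
                    "pair_counts": v.pair_counts, "wls_objective": v.wls_objective,
                }
            )
        if self.comparison is not None:
            d["models"] = {
                k: {
                    "params": f.params, "se": f.se, "ell": f.ell, "P": f.P,
                    "A": f.A, "converged": f.converged, "hessian_ok": f.hessian_ok,
                }
                for k, f in self.comparison.fits.items()
            }
            d["selection"] = {
                "weights": self.comparison.weights,
                "delta": self.comparison.delta,
                "preferred": self.comparison.preferred,
                "selected": self.comparison.selected,
            }
        if self.crit is not None:
            d["crit"] = _jsonable(dataclasses.asdict(self.crit))
        return d

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def run_analysis(records: list[ZoneRecord], config: AnalysisConfig) -> AnalysisReport:
    """Run the full boundary-line analysis on a set of zone records.

    Requires at least ``config.min_records`` records after subsetting (those
    with the analysed nutrient present).  Every later stage failure is
    caught, recorded under its stage name and the partial report returned.
    """
    report = AnalysisReport(config=config)
    report.n_input = len(records)

    subset = subset_records(records, config.subset_rule)
    report.n_subset = len(subset)
    subset = [r for r in subset if r.nutrient(config.nutrient) is not None]
    report.n_with_nutrient = len(subset)
    if len(subset) < config.min_records:
        raise ValueError(
            f"only {len(subset)} usable records after subsetting "
            f"(minimum {config.min_records})"
        )

    conc = np.array([r.nutrient(config.nutrient) for r in subset])
    yields = np.array([r.yield_t_ha for r in subset])

    # 1. transform decision
    x = conc
    try:
        report.transform = preprocessing.decide_transform(
            conc, config.transform_skew_threshold, variable=config.nutrient
        )
        if report.transform.applied:
            x = np.log(conc)
    except Exception as exc:  # noqa: BLE001 - stage errors are reported, not raised
        report.stage_errors["transform"] = str(exc)

    # 2. bagplot outlier removal in the (x, yield) plane
    keep = np.ones(len(subset), dtype=bool)
    try:
        res = preprocessing.bagplot_outliers(
            np.column_stack([x, yields]),
            fence_factor=config.bagplot_fence_factor,
            rng=config.rng_seed,
        )
        report.outliers = res
        keep = ~res.flags
    except Exception as exc:  # noqa: BLE001
        report.stage_errors["outliers"] = str(exc)
    retained = [r for r, k in zip(subset, keep) if k]
    x_kept, y_kept = x[keep], yields[keep]
    report.n_after_outliers = len(retained)

    # 3. sigma_e from the variogram nugget of yield
    sigma_e = 0.0
    try:
        vg = preprocessing.estimate_sigma_e(
            records=retained, demean_by_farm=config.demean_by_farm
        )
        report.variogram = vg
        sigma_e = vg.sigma_e
    except Exception as exc:  # noqa: BLE001
        report.stage_errors["variogram"] = str(exc)
    cap = 0.8 * float(np.std(y_kept))
    if sigma_e > cap:
        # an observation-error SD rivalling the total yield SD is not
        # credible; keep the latent yield variance identifiable
        logger.warning("variogram nugget SD %.3f exceeds 0.8*SD(yield); capped", sigma_e)
        report.stage_errors["sigma_e_cap"] = (
            f"nugget SD {sigma_e:.3f} capped to {cap:.3f}"
        )
        sigma_e = cap
    report.sigma_e = sigma_e

    # 4. three model fits + AIC competition
    try:
        fits = {
            kind: fit_select.fit_model(y_kept, x_kept, kind, sigma_e, config.fit)
            for kind in ("BL", "MVN", "MVN_c")
        }
        report.comparison = fit_select.compare_models(
            fits, threshold=config.selection_threshold
        )
    except Exception as exc:  # noqa: BLE001
        report.stage_errors["fits"] = str(exc)
        return report

    # 5. critical-concentration inference (only when BL is selected)
    if report.comparison.selected == "BL":
        try:
            bl = report.comparison.fits["BL"]
            report.crit = uncertainty.infer_crit_value(
                bl.spec.boundary,
                bl.beta_cov(),
                config.resolved_scheme(),
                n_draws=config.n_mc_draws,
                hdi_mass=config.hdi_mass,
                rng=config.rng_seed,
                hdi_scale=config.hdi_scale,
            )
        except Exception as exc:  # noqa: BLE001
            report.stage_errors["crit"] = str(exc)
    return report


def write_report_tables(report: AnalysisReport, out_dir) -> list[Path]:
    """Write the flat summary tables (model competition, boundary parameters,
    critical value) as delimited text next to the JSON report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in (
        ("models", report.model_table()),
        ("boundary_params", report.params_table()),
        ("critical_value", report.crit_table()),
    ):
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    return written
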