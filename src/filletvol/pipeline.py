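"""End-to-end orchestration: simulate, scan, build traits, fit, report.

``run_pipeline`` is a pure function of its :class:`RunConfig` (including
the seed): it generates a virtual population, scans it, builds the full
volume-trait table and writes four CSV analogs of the study-style output
tables — descriptive statistics, simple regressions of actual fillet
volume on every trait, stepwise models for the standard candidate sets,
and correlations of both fillet-yield definitions with every trait.
Rounding is applied only at serialization; returned frames keep full
precision.

``validate_reference`` recomputes every internally derivable quantity of
the published summary tables (trait sums, regression predictions at the
means, CVs, yield arithmetic, critical correlation values) through the
package's own operations and reports pass/fail per check.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .cavalieri import (
    DEFAULT_SPAN_CONVENTIONS,
    build_trait_table,
    combo_volume,
    section_volume,
    spanning_volume,
)
from .models import (
    DegeneratePredictorError,
    critical_r,
    fillet_yield,
    fillet_yield_v15,
    fit_simple,
    pearson_with_significance,
    predict,
    stepwise_forward_cv,
)
from .population import (
    PopulationConfig,
    generate_population,
    population_to_frame,
    scan_population,
)

__all__ = [
    "SummaryStats",
    "RunConfig",
    "ReportBundle",
    "CheckResult",
    "summarize",
    "coefficient_of_variation",
    "run_pipeline",
    "validate_reference",
    "STEPWISE_CANDIDATE_SETS",
]

logger = logging.getLogger("filletvol")

#: Candidate-predictor sets for the stepwise analog of the study's
#: model-comparison table.
STEPWISE_CANDIDATE_SETS: dict[str, tuple[str, ...]] = {
    "slice_areas": tuple(f"A{i}" for i in range(1, 11)),
    "single_volumes": tuple(f"V{i}" for i in range(1, 10)),
    "pair_combinations": ("V1+2", "V3+4", "V5+6", "V7+8"),
    "triple_combinations": ("V1+2+3", "V4+5+6", "V7+8+9"),
    "v15_plus_caudal_singles": ("V1-5", "V6", "V7", "V8", "V9"),
    "cranial_singles_plus_v69": ("V1", "V2", "V3", "V4", "V5", "V6-9"),
    "halves": ("V1-5", "V6-9"),
}


@dataclass(frozen=True)
class SummaryStats:
    """Sample descriptive statistics; sd uses n-1, cv = 100·sd/mean (%)."""

    mean: float
    sd: float
    minimum: float
    maximum: float
    cv: float
    n: int


def coefficient_of_variation(mean: float, sd: float) -> float:
    """CV in percent, 100·sd/mean; scale-free dispersion."""
    return 100.0 * sd / mean


def summarize(values: Sequence[float]) -> SummaryStats:
    """Mean, sample sd, min, max and CV of one trait vector."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a vector of at least two values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    return SummaryStats(
        mean=mean,
        sd=sd,
        minimum=float(v.min()),
        maximum=float(v.max()),
        cv=coefficient_of_variation(mean, sd) if mean != 0 else float("nan"),
        n=v.size,
    )


@dataclass(frozen=True)
class RunConfig:
    """Everything the pipeline needs; the pipeline is a pure function of it."""

    population: PopulationConfig = field(default_factory=PopulationConfig)
    n_slices: int = 10
    placement: str = "start"
    span_conventions: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SPAN_CONVENTIONS)
    )
    stepwise_k: int = 10
    entry_tol: float = 1e-3
    out_dir: str | Path | None = None
    round_values: int = 2
    round_cv: int = 1


@dataclass(frozen=True)
class ReportBundle:
    """All frames produced by one pipeline run (full precision)."""

    population: pd.DataFrame
    traits: pd.DataFrame        # areas + volume traits + ground truth per fish
    descriptives: pd.DataFrame  # table-1 analog
    simple_fits: pd.DataFrame   # table-2 analog
    stepwise_fits: pd.DataFrame # table-3 analog
    correlations: pd.DataFrame  # table-4 analog
    paths: tuple[Path, ...] = ()


def _trait_frame(config: RunConfig):
    """Simulate, scan and assemble the per-fish trait frame."""
    t0 = time.perf_counter()
    population = generate_population(config.population)
    logger.info(
        "generated %d fish (seed=%d)", len(population), config.population.seed
    )
    profiles = scan_population(
        population,
        config.population,
        n_slices=config.n_slices,
        placement=config.placement,
    )
    pop_frame = population_to_frame(population, profiles)
    traits = build_trait_table(
        profiles,
        span_conventions=config.span_conventions,
        ids=[f.id for f in population],
    )
    traits = pop_frame.merge(traits, on="id")
    logger.info(
        "built %d traits per fish in %.3f s",
        traits.shape[1] - 1,
        time.perf_counter() - t0,
    )
    return population, pop_frame, traits


def _predictor_columns(traits: pd.DataFrame) -> list[str]:
    return [
        c
        for c in traits.columns
        if c.startswith(("A", "V")) and c not in ("A", "V")
    ]


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the full analysis on a synthetic population.

    Writes the four CSV analogs into ``config.out_dir`` when given.
    Constant predictor columns (possible when the noiseless profile
    vanishes at a slice position) are recorded as NaN rows rather than
    fitted.
    """
    population, pop_frame, traits = _trait_frame(config)
    y = traits["fillet_volume_cm3"].to_numpy(float)
    predictor_cols = _predictor_columns(traits)

    # table-1 analog: descriptives of fish traits and every RTU trait
    desc_rows = []
    for col in ["body_weight_g", "total_length_mm", "fillet_weight_g",
                "fillet_volume_cm3", "fillet_yield_pct", *predictor_cols]:
        s = summarize(traits[col].to_numpy(float))
        desc_rows.append(
            {"trait": col, "mean": s.mean, "sd": s.sd, "min": s.minimum,
             "max": s.maximum, "cv_pct": s.cv}
        )
    descriptives = pd.DataFrame(desc_rows)

    # table-2 analog: simple regression of actual fillet volume on each trait
    fit_rows = []
    for col in predictor_cols:
        x = traits[col].to_numpy(float)
        try:
            f = fit_simple(x, y, name=col)
        except DegeneratePredictorError:
            logger.warning("skipping constant predictor %s", col)
            fit_rows.append(
                {"independent": col, "intercept": np.nan, "slope": np.nan,
                 "r_squared": np.nan, "rmse_cv": np.nan, "rmse_resub": np.nan}
            )
            continue
        rmse = _cv_rmse_simple(x, y, config)
        fit_rows.append(
            {"independent": col, "intercept": f.intercept,
             "slope": f.slopes[0], "r_squared": f.r_squared,
             "rmse_cv": rmse, "rmse_resub": f.rmse_resub}
        )
    simple_fits = pd.DataFrame(fit_rows)

    # table-3 analog: stepwise models per candidate set
    step_rows = []
    for set_name, cols in STEPWISE_CANDIDATE_SETS.items():
        model = stepwise_forward_cv(
            traits[list(cols)], y,
            k=config.stepwise_k,
            seed=config.population.seed,
            entry_tol=config.entry_tol,
        )
        step_rows.append(
            {"candidate_set": set_name,
             "selected": " + ".join(model.selected),
             "intercept": model.fit.intercept,
             "slopes": "; ".join(
                 f"{s:.4g} {p}" for s, p in zip(model.fit.slopes, model.fit.predictors)
             ),
             "r_squared": model.fit.r_squared,
             "rmse_cv": model.fit.rmse_cv}
        )
    stepwise_fits = pd.DataFrame(step_rows)

    # table-4 analog: correlations of both yield definitions with every trait
    fit_v15 = fit_simple(traits["V1-5"].to_numpy(float), y, name="V1-5")
    yield_true = traits["fillet_yield_pct"].to_numpy(float)
    yield_v15 = fillet_yield_v15(
        fit_v15,
        traits["V1-5"].to_numpy(float),
        traits["body_weight_g"].to_numpy(float),
    )
    corr_rows = []
    for col in predictor_cols:
        x = traits[col].to_numpy(float)
        row = {"trait": col}
        for label, yy in (("fillet_yield", yield_true),
                          ("fillet_yield_v15", yield_v15)):
            try:
                c = pearson_with_significance(x, yy)
                row[f"r_{label}"] = c.r
                row[f"sig_{label}"] = c.significance
            except DegeneratePredictorError:
                row[f"r_{label}"] = np.nan
                row[f"sig_{label}"] = "undefined"
        corr_rows.append(row)
    correlations = pd.DataFrame(corr_rows)

    paths: tuple[Path, ...] = ()
    if config.out_dir is not None:
        paths = _write_bundle(
            config,
            {"population.csv": traits,
             "descriptives.csv": descriptives,
             "simple_regressions.csv": simple_fits,
             "stepwise_models.csv": stepwise_fits,
             "yield_correlations.csv": correlations},
        )
    return ReportBundle(
        population=pop_frame,
        traits=traits,
        descriptives=descriptives,
        simple_fits=simple_fits,
        stepwise_fits=stepwise_fits,
        correlations=correlations,
        paths=paths,
    )


def _cv_rmse_simple(x: np.ndarray, y: np.ndarray, config: RunConfig) -> float:
    from .models import cv_rmse

    return cv_rmse(
        pd.DataFrame({"x": x}), y, k=config.stepwise_k,
        seed=config.population.seed,
    )


def _write_bundle(config: RunConfig, frames: dict[str, pd.DataFrame]):
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, frame in frames.items():
        rounded = frame.copy()
        for col in rounded.columns:
            if rounded[col].dtype.kind != "f":
                continue
            nd = config.round_cv if "cv" in col and "rmse" not in col else config.round_values
            rounded[col] = rounded[col].round(nd)
        path = out / name
        rounded.to_csv(path, index=False, lineterminator="\n")
        logger.info("wrote %s", path)
        paths.append(path)
    return tuple(paths)


# ---------------------------------------------------------------------------
# internal-arithmetic validation against the published summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CheckResult:
    name: str
    computed: float
    expected: float
    tol: float

    @property
    def passed(self) -> bool:
        return abs(self.computed - self.expected) <= self.tol


def validate_reference(
    overrides: Mapping[str, float] | None = None,
) -> list[CheckResult]:
    """Recompute the internally derivable published-summary arithmetic.

    Each check runs a real package operation (``combo_volume``,
    ``spanning_volume``, ``predict``, ``fillet_yield``,
    ``coefficient_of_variation``, ``critical_r``) on the printed constants
    and compares against the expected value, with tolerances set by the
    printing precision of the inputs. ``overrides`` perturbs single
    constants (negative controls); failures are reported, never raised.
    """
    means: dict[str, float] = dict(reference.SINGLE_VOLUME_MEANS)
    means.update(reference.SLICE_AREA_MEANS)
    fish = {k: v[0] for k, v in reference.FISH_SUMMARIES.items()}
    fits = {k: v[:2] for k, v in reference.SIMPLE_FITS.items()}
    if overrides:
        for key, val in overrides.items():
            if key in means:
                means[key] = val
            elif key in fish:
                fish[key] = val
            else:
                raise KeyError(f"unknown override {key!r}")

    d = reference.SECTION_LENGTH_CM
    checks: list[CheckResult] = []

    def add(name, computed, expected, tol):
        checks.append(CheckResult(name, float(computed), expected, tol))

    # sums of printed single-volume means against printed aggregates
    add("total_volume_from_singles",
        combo_volume(means, range(1, 10)), 47.91, 0.05)
    add("v1_5_from_singles", combo_volume(means, range(1, 6)), 33.39, 0.03)
    add("v6_9_from_singles", combo_volume(means, range(6, 10)), 14.52, 0.03)
    add("combo_v1_2_3", combo_volume(means, [1, 2, 3]), 22.35, 0.02)
    add("combo_v4_5_6", combo_volume(means, [4, 5, 6]), 16.53, 0.02)
    add("halves_sum_equals_total",
        combo_volume(means, range(1, 6)) + combo_volume(means, range(6, 10)),
        47.91, 0.05)

    # one slab volume from the printed mean areas (mean-of-products caveat:
    # this is arithmetic on means, intentionally not the printed mean V1)
    add("section_volume_a1_a2",
        section_volume(means["A1"], means["A2"], d), 7.19, 0.01)

    # the regression through the means: predicted volume at the mean A2
    a2_fit = _fit_from_coeffs(fits["A2"], "A2")
    add("predict_a2_at_mean",
        predict(a2_fit, means["A2"]), fish["fillet_volume_cm3"], 0.03)

    # CV of fillet volume from printed mean and sd
    add("cv_fillet_volume",
        coefficient_of_variation(
            fish["fillet_volume_cm3"], reference.FISH_SUMMARIES["fillet_volume_cm3"][1]
        ),
        35.6, 0.1)

    # yield arithmetic on means (differs from the printed mean of ratios)
    add("yield_from_mean_weights",
        fillet_yield(fish["fillet_weight_g"], fish["body_weight_g"]),
        16.52, 0.01)
    v15_fit = _fit_from_coeffs(fits["V1-5"], "V1-5")
    add("yield_v15_at_means",
        fillet_yield_v15(
            v15_fit, reference.VOLUME_TRAIT_MEANS["V1-5"], fish["body_weight_g"]
        ),
        16.485, 0.01)

    # critical correlation at n = 44 (printed ns bound: below 0.298)
    add("critical_r_alpha05", critical_r(reference.N_FISH, 0.05), 0.2973, 0.003)

    # the two span conventions on the printed mean areas
    from .cavalieri import AreaProfile, SlicePlan

    plan = SlicePlan.regular(10 * d, n_slices=10, placement="start")
    profile = AreaProfile(
        tuple(means[f"A{i}"] for i in range(1, 11)), plan
    )
    add("v1_5_endpoints_on_mean_areas",
        spanning_volume(profile, 1, 5, convention="endpoints"), 30.57, 0.01)

    return checks


def _fit_from_coeffs(coeffs: tuple[float, float], name: str):
    from .models import RegressionFit

    return RegressionFit(
        predictors=(name,),
        intercept=coeffs[0],
        slopes=(coeffs[1],),
        r_squared=float("nan"),
        rmse_resub=float("nan"),
        n=reference.N_FISH,
    )
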