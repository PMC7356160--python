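"""Pipeline orchestration: intake reports, simulation reports, comparisons.

Report CSVs mirror the analysis tables: a per-subject intake table, a
subgroup summary (median and quartiles per reporting subgroup), an
exceedance table at the tolerable weekly intake, an age-stratified summary,
a weekly-intake histogram table, and a Monte Carlo summary (median, 5–95th
percentiles, range, n_reps, seed). Values are written both at full precision
and rounded to one decimal; rounding happens only at serialization.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .concentrations import ConcentrationTable, load_concentration_table
from .intake import (
    DEFAULT_AGE_BINS,
    REPORTING_SUBGROUPS,
    TWI_UG_PER_KG_BW_WEEK,
    apply_exclusions,
    classify_exceedance,
    cohort_summary,
    read_subject_table,
    results_frame,
    subject_daily_intake,
)
from .mapping import default_mapping, load_mapping, validate_coverage
from .montecarlo import (
    DEFAULT_N_REPS,
    LognormalFit,
    SimulationSummary,
    fit_lognormal_mle,
    fit_lognormal_quantiles,
    simulate,
    summarize_simulation,
    tail_probability,
)
from .stats import grubbs_iterative

logger = logging.getLogger(__name__)


class ReportError(ValueError):
    pass


@dataclass
class RunConfig:
    subject_table: Path | None = None
    concentration_table: Path | None = None  # None -> packaged default
    mapping_config: Path | None = None  # None -> packaged default
    output_dir: Path = Path("cdintake_out")
    threshold: float = TWI_UG_PER_KG_BW_WEEK
    grubbs_alpha: float = 0.05
    n_reps: int = DEFAULT_N_REPS
    seed: int = 0
    mass_change: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ReportError("threshold must be > 0")
        if self.n_reps < 1:
            raise ReportError("n_reps must be >= 1")


def _load_table(config: RunConfig) -> ConcentrationTable:
    if config.concentration_table is None:
        return ConcentrationTable.default()
    return ConcentrationTable(load_concentration_table(config.concentration_table))


def _load_rules(config: RunConfig, table: ConcentrationTable):
    if config.mapping_config is None:
        return default_mapping(table, mass_change=config.mass_change)
    return load_mapping(config.mapping_config, table, mass_change=config.mass_change)


def _summary_frame(values_by_name: Mapping[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for name, values in values_by_name.items():
        s = cohort_summary(values)["overall"]
        rows.append(
            {
                "quantity": name,
                "n": s.n,
                "median": s.median,
                "q25": s.q25,
                "q75": s.q75,
                "min": s.minimum,
                "max": s.maximum,
                "median_1dp": round(s.median, 1),
                "q25_1dp": round(s.q25, 1),
                "q75_1dp": round(s.q75, 1),
            }
        )
    return pd.DataFrame(rows)


def histogram_table(values: Sequence[float], bin_width: float = 1.0) -> pd.DataFrame:
    """Counts of weekly intakes in fixed-width bins (histogram mirror)."""
    values = np.asarray(values, dtype=float)
    hi = float(np.ceil(values.max() / bin_width) * bin_width)
    edges = np.arange(0.0, hi + bin_width, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    return pd.DataFrame(
        {"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts}
    )


def run_intake(config: RunConfig) -> dict[str, Path]:
    """Full intake run: exclusions, per-subject intake, subgroup/exceedance/
    age-stratified summaries, histogram table, exclusion log.

    Returns a dict of written file paths. Raises on any validation failure.
    """
    if config.subject_table is None or not Path(config.subject_table).exists():
        raise ReportError(f"subject table not found: {config.subject_table}")
    table = _load_table(config)
    rules = _load_rules(config, table)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    subjects = read_subject_table(config.subject_table)
    kept, exclusion_log = apply_exclusions(subjects)
    coverage = validate_coverage(rules, table=table)

    gm_by_area = {
        area: table.rice_gm(area) for area in ("A", "B") if "Rice" in table
    }
    results = [
        subject_daily_intake(
            s,
            rules,
            table,
            cohort_rice_gm=gm_by_area.get(s.area),
            threshold=config.threshold,
        )
        for s in kept
    ]
    frame = results_frame(results)
    paths: dict[str, Path] = {}

    paths["per_subject"] = out / "per_subject_intake.csv"
    frame.to_csv(paths["per_subject"], index=False)

    quantities = {sg: frame[sg].to_numpy() for sg in ("total_ug_per_day",) + REPORTING_SUBGROUPS}
    paths["subgroup_summary"] = out / "subgroup_summary.csv"
    _summary_frame(quantities).to_csv(paths["subgroup_summary"], index=False)

    weekly = frame["weekly_ug_per_kg_bw"].to_numpy()
    exc = classify_exceedance(weekly, config.threshold)
    paths["exceedance"] = out / "exceedance.csv"
    pd.DataFrame(
        [
            {"bin": f"<{config.threshold:g}", "count": exc.n_below, "percent": exc.pct_below},
            {
                "bin": f">={config.threshold:g}",
                "count": exc.n_at_or_above,
                "percent": exc.pct_at_or_above,
            },
        ]
    ).to_csv(paths["exceedance"], index=False)

    strata = cohort_summary(weekly, ages=frame["age"].to_numpy(), age_bins=DEFAULT_AGE_BINS)
    rows = []
    for label, s in strata.items():
        rows.append(
            {
                "stratum": label,
                "n": s.n,
                "median": s.median,
                "q25": s.q25,
                "q75": s.q75,
                "median_1dp": None if s.median is None else round(s.median, 1),
            }
        )
    paths["age_stratified"] = out / "age_stratified.csv"
    pd.DataFrame(rows).to_csv(paths["age_stratified"], index=False)

    paths["histogram"] = out / "weekly_histogram.csv"
    histogram_table(weekly).to_csv(paths["histogram"], index=False)

    paths["log"] = out / "run_log.txt"
    with open(paths["log"], "w", encoding="utf-8") as fh:
        fh.write(f"subjects read: {len(subjects)}\n")
        fh.write(f"subjects kept: {len(kept)}\n")
        for sid, reason in exclusion_log:
            fh.write(f"excluded {sid}: {reason}\n")
        fh.write(f"unmapped DHQ items: {coverage.unmapped_dhq_items}\n")
        fh.write(f"excluded (zero-contribution) items: {coverage.excluded_items}\n")
        fh.write(f"unused concentration items: {coverage.unused_concentration_items}\n")
    return paths


def run_simulation(
    config: RunConfig,
    weekly: Sequence[float] | None = None,
    quantiles: tuple[float, float, float] | None = None,
) -> tuple[SimulationSummary, LognormalFit, dict[str, Path]]:
    """Monte Carlo run from either a cohort of weekly intakes (outliers
    screened on the log scale via the iterative Grubbs test, then ML fit) or
    a (q25, median, q75) triple (quantile-matching fit).

    Writes a simulation summary CSV (median, 5–95th percentiles, range,
    n_reps, seed) and a histogram-density table of the draws.
    """
    if (weekly is None) == (quantiles is None):
        raise ReportError("supply exactly one of weekly cohort or quantile triple")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_outliers = 0
    if weekly is not None:
        arr = np.asarray(weekly, dtype=float)
        if np.any(arr <= 0):
            raise ReportError("weekly intakes must be positive")
        screening = grubbs_iterative(np.log(arr), alpha=config.grubbs_alpha)
        n_outliers = len(screening.outlier_indices)
        if n_outliers:
            logger.info("Grubbs screening removed %d outliers", n_outliers)
            arr = np.delete(arr, screening.outlier_indices)
        fit = fit_lognormal_mle(arr)
    else:
        q25, med, q75 = quantiles
        fit = fit_lognormal_quantiles(q25, med, q75)
    draws = simulate(fit, n_reps=config.n_reps, seed=config.seed)
    summary = summarize_simulation(draws, seed=config.seed)

    paths: dict[str, Path] = {}
    paths["simulation"] = out / "simulation_summary.csv"
    pd.DataFrame(
        [
            {
                "n_reps": summary.n_reps,
                "seed": config.seed,
                "fit_method": fit.method,
                "mu": fit.mu,
                "sigma": fit.sigma,
                "n_outliers_removed": n_outliers,
                "median": summary.median,
                "p5": summary.p5,
                "p95": summary.p95,
                "min": summary.minimum,
                "max": summary.maximum,
                "median_1dp": round(summary.median, 1),
                "tail_prob_at_threshold": tail_probability(fit, config.threshold),
            }
        ]
    ).to_csv(paths["simulation"], index=False)
    paths["density"] = out / "simulation_density.csv"
    histogram_table(draws).to_csv(paths["density"], index=False)
    return summary, fit, paths


def run_compare(
    cohort_medians: Mapping[str, float], references: Mapping[str, float]
) -> pd.DataFrame:
    """Fold ratios of cohort medians to general-population reference intakes.

    Keys present in both mappings are compared; ratios are rounded to one
    decimal alongside the raw value.
    """
    rows = []
    for key in cohort_medians:
        if key not in references:
            continue
        ref = references[key]
        if ref == 0:
            raise ReportError(f"zero reference value for {key!r}")
        ratio = cohort_medians[key] / ref
        rows.append(
            {
                "quantity": key,
                "cohort_median": cohort_medians[key],
                "reference": ref,
                "fold_ratio": ratio,
                "fold_ratio_1dp": round(ratio, 1),
            }
        )
    if not rows:
        raise ReportError("no overlapping keys between cohort and reference values")
    return pd.DataFrame(rows)
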