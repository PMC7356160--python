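"""Per-subject cadmium intake, exclusion filters, TWI exceedance, cohort summaries.

Intake arithmetic: a food intake in g/day times a concentration in mg/kg
(≡ µg/g) times a mass-change factor yields µg Cd/day. Daily totals convert to
weekly intake per body weight as ``7 × total / weight`` (µg/kg BW/week) and
are compared against the tolerable weekly intake (TWI) of 7 µg/kg BW/week.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .concentrations import ConcentrationTable
from .mapping import MappingRule, component_concentration, component_subgroup

logger = logging.getLogger(__name__)

TWI_UG_PER_KG_BW_WEEK = 7.0

#: The seven reporting subgroups of the intake tables. Seaweed, fish and
#: shellfish merge into "seafood"; livestock and miscellaneous foods merge
#: into "others"; fruit (Cd never detected) is excluded entirely.
REPORTING_SUBGROUPS = (
    "rice_and_rice_products",
    "cereals_tubers_roots",
    "soybeans",
    "vegetables",
    "mushrooms",
    "seafood",
    "others",
)

_CONC_TO_REPORTING = {
    "rice_products": "rice_and_rice_products",
    "cereals_tubers_roots": "cereals_tubers_roots",
    "soybeans": "soybeans",
    "vegetables": "vegetables",
    "mushrooms": "mushrooms",
    "seaweed": "seafood",
    "fish_shellfish": "seafood",
    "livestock": "others",
    "others": "others",
    "fruit": None,  # excluded from the intake calculation
}

#: Default decade age strata of the age-classified intake table.
DEFAULT_AGE_BINS = ((20, 29), (30, 39), (40, 49), (50, 59), (60, 69), (70, None))


class IntakeError(ValueError):
    """Raised for invalid subject data or intake computation inputs."""


@dataclass
class Subject:
    """One participant: covariates, per-item food intake, individual rice Cd."""

    id: str
    area: str
    age: float
    height: float  # cm
    weight: float  # kg
    energy: float  # kcal/day
    rice_cd: float | None  # mg/kg; None = missing measurement
    brown_rice: bool = False
    intakes: dict[str, float] = field(default_factory=dict)  # item -> g/day

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise IntakeError(f"subject {self.id}: weight must be > 0")
        if self.age < 0:
            raise IntakeError(f"subject {self.id}: age must be >= 0")
        for item, grams in self.intakes.items():
            if grams < 0:
                raise IntakeError(f"subject {self.id}: negative intake for {item!r}")


@dataclass
class IntakeResult:
    subject_id: str
    area: str
    age: float
    weight: float
    by_subgroup: dict[str, float]  # µg/day per reporting subgroup
    total: float  # µg/day
    weekly_per_bw: float  # µg/kg BW/week
    exceeds_twi: bool


@dataclass
class StratumSummary:
    n: int
    median: float | None = None
    q25: float | None = None
    q75: float | None = None
    minimum: float | None = None
    maximum: float | None = None


@dataclass
class ExceedanceTable:
    threshold: float
    n_below: int
    n_at_or_above: int
    pct_below: float
    pct_at_or_above: float

    @property
    def n(self) -> int:
        return self.n_below + self.n_at_or_above


def apply_exclusions(
    subjects: Iterable[Subject],
    energy_lo: float = 1000.0,
    energy_hi: float = 3500.0,
    rice_item: str = "rice",
) -> tuple[list[Subject], list[tuple[str, str]]]:
    """Drop subjects with extreme energy intake (≤ lo or ≥ hi kcal/day) or
    zero rice consumption; return kept subjects and a (subject id, reason) log."""
    kept: list[Subject] = []
    log: list[tuple[str, str]] = []
    for s in subjects:
        if s.energy <= energy_lo:
            log.append((s.id, f"energy {s.energy:g} kcal/day <= {energy_lo:g}"))
        elif s.energy >= energy_hi:
            log.append((s.id, f"energy {s.energy:g} kcal/day >= {energy_hi:g}"))
        elif s.intakes.get(rice_item, 0.0) == 0.0:
            log.append((s.id, "rice intake is zero"))
        else:
            kept.append(s)
    return kept, log


def subject_daily_intake(
    subject: Subject,
    rules: Mapping[str, MappingRule],
    table: ConcentrationTable,
    cohort_rice_gm: float | None = None,
    threshold: float = TWI_UG_PER_KG_BW_WEEK,
) -> IntakeResult:
    """Daily Cd intake (µg/day) by reporting subgroup for one subject.

    Each consumed item's contribution is its resolved concentration times
    intake times the rule's mass-change factor; multi-component rules are
    attributed subgroup-wise per component. Items with no rule contribute
    nothing (logged once per call).
    """
    by_subgroup = {sg: 0.0 for sg in REPORTING_SUBGROUPS}
    for item, grams in subject.intakes.items():
        if grams == 0.0:
            continue
        rule = rules.get(item)
        if rule is None:
            logger.warning(
                "subject %s: item %r has no mapping rule; contribution set to 0",
                subject.id,
                item,
            )
            continue
        if rule.excluded:
            continue
        for comp in rule.components:
            conc = component_concentration(
                comp, table, subject=subject, cohort_rice_gm=cohort_rice_gm
            )
            reporting = _CONC_TO_REPORTING[component_subgroup(comp, table)]
            if reporting is None:
                continue
            by_subgroup[reporting] += comp.weight * conc * grams * rule.mass_change_factor
    total = float(sum(by_subgroup.values()))
    weekly = weekly_per_bw(total, subject.weight)
    return IntakeResult(
        subject_id=subject.id,
        area=subject.area,
        age=subject.age,
        weight=subject.weight,
        by_subgroup=by_subgroup,
        total=total,
        weekly_per_bw=weekly,
        exceeds_twi=weekly >= threshold,
    )


def weekly_per_bw(total_ug_per_day: float, weight_kg: float) -> float:
    """Weekly Cd intake per body weight: 7 × daily total / weight."""
    if weight_kg <= 0:
        raise IntakeError("weight must be > 0")
    return 7.0 * total_ug_per_day / weight_kg


def classify_exceedance(
    weekly_values: Sequence[float], threshold: float = TWI_UG_PER_KG_BW_WEEK
) -> ExceedanceTable:
    """Partition weekly intakes into < threshold and ≥ threshold bins.

    A value exactly at the threshold counts as exceeding. Percentages are
    rounded to one decimal, matching the reporting convention.
    """
    if threshold <= 0:
        raise IntakeError("threshold must be > 0")
    values = np.asarray(weekly_values, dtype=float)
    n = values.size
    n_above = int(np.count_nonzero(values >= threshold))
    n_below = n - n_above
    return ExceedanceTable(
        threshold=threshold,
        n_below=n_below,
        n_at_or_above=n_above,
        pct_below=round(100.0 * n_below / n, 1) if n else 0.0,
        pct_at_or_above=round(100.0 * n_above / n, 1) if n else 0.0,
    )


def _stratum(values: np.ndarray) -> StratumSummary:
    if values.size == 0:
        return StratumSummary(n=0)
    q25, med, q75 = np.percentile(values, [25, 50, 75])  # linear ("type 7") interpolation
    return StratumSummary(
        n=int(values.size),
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        minimum=float(values.min()),
        maximum=float(values.max()),
    )


def cohort_summary(
    values: Sequence[float],
    ages: Sequence[float] | None = None,
    age_bins: Sequence[tuple[float, float | None]] = DEFAULT_AGE_BINS,
) -> dict[str, StratumSummary]:
    """Median/quartile/range summary overall and (optionally) per age stratum.

    Returns a dict keyed ``"overall"`` plus, when ``ages`` is given, one entry
    per age bin (e.g. ``"60-69"``, ``"70+"``); an empty stratum is reported
    with n = 0 and absent statistics.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise IntakeError("cohort_summary needs at least one value")
    out = {"overall": _stratum(values)}
    if ages is not None:
        ages_arr = np.asarray(ages, dtype=float)
        if ages_arr.size != values.size:
            raise IntakeError("ages and values must align")
        for lo, hi in age_bins:
            if hi is None:
                mask = ages_arr >= lo
                label = f"{int(lo)}+"
            else:
                # decade bin "20-29" covers ages in [20, 30)
                mask = (ages_arr >= lo) & (ages_arr < hi + 1)
                label = f"{int(lo)}-{int(hi)}"
            out[label] = _stratum(values[mask])
    return out


def results_frame(results: Iterable[IntakeResult]) -> pd.DataFrame:
    """Flatten IntakeResults into a per-subject DataFrame (one subgroup per column)."""
    rows = []
    for r in results:
        row = {
            "subject_id": r.subject_id,
            "area": r.area,
            "age": r.age,
            "weight_kg": r.weight,
        }
        row.update({sg: r.by_subgroup[sg] for sg in REPORTING_SUBGROUPS})
        row["total_ug_per_day"] = r.total
        row["weekly_ug_per_kg_bw"] = r.weekly_per_bw
        row["exceeds_twi"] = r.exceeds_twi
        rows.append(row)
    return pd.DataFrame(rows)


# --- subject table I/O -----------------------------------------------------

_SUBJECT_FIXED_COLS = [
    "id",
    "area",
    "age",
    "height_cm",
    "weight_kg",
    "energy_kcal",
    "rice_cd_mg_per_kg",
    "brown_rice",
]


def read_subject_table(path: str | Path) -> list[Subject]:
    """Read the subject CSV dialect (fixed covariate columns, then one column
    of g/day intake per questionnaire item)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_SUBJECT_FIXED_COLS) - set(df.columns)
    if missing:
        raise IntakeError(f"{path}: missing columns {sorted(missing)}")
    item_cols = [c for c in df.columns if c not in _SUBJECT_FIXED_COLS]
    subjects = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            rice_cd = None if pd.isna(row.rice_cd_mg_per_kg) else float(row.rice_cd_mg_per_kg)
            subjects.append(
                Subject(
                    id=str(row.id),
                    area=str(row.area),
                    age=float(row.age),
                    height=float(row.height_cm),
                    weight=float(row.weight_kg),
                    energy=float(row.energy_kcal),
                    rice_cd=rice_cd,
                    brown_rice=bool(row.brown_rice),
                    intakes={c: float(getattr(row, c)) for c in item_cols},
                )
            )
        except (IntakeError, ValueError) as exc:
            raise IntakeError(f"{path}: row {i}: {exc}") from exc
    return subjects


def write_subject_table(subjects: Sequence[Subject], path: str | Path) -> None:
    item_cols = sorted({item for s in subjects for item in s.intakes})
    rows = []
    for s in subjects:
        row = {
            "id": s.id,
            "area": s.area,
            "age": s.age,
            "height_cm": s.height,
            "weight_kg": s.weight,
            "energy_kcal": s.energy,
            "rice_cd_mg_per_kg": s.rice_cd,
            "brown_rice": int(s.brown_rice),
        }
        row.update({c: s.intakes.get(c, 0.0) for c in item_cols})
        rows.append(row)
    # %.17g keeps float64 round-trips lossless
    pd.DataFrame(rows, columns=_SUBJECT_FIXED_COLS + item_cols).to_csv(
        path, index=False, float_format="%.17g"
    )
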