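"""Food cadmium concentration records, summaries, and the packaged market-survey table.

Concentrations are in mg Cd per kg fresh weight (equivalently µg/g), so a
food intake in g/day multiplied by a concentration gives µg Cd/day directly.
Values below the analytical detection limit are carried as censored records
together with their LOD and are only turned into numbers through an explicit
substitution rule (``zero``, ``half_lod`` or ``lod``).

The packaged fixture transcribes a published market survey of ~100 local food
items in two cadmium-polluted areas (A and B): for each item the printed
sample size, mean (arithmetic, or geometric for rice), and range. Raw
replicates were not published; :func:`expand_summary` reconstructs, per item,
``n`` synthetic replicate values with the printed range endpoints fixed and
the interior solved so the recomputed mean reproduces the printed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

SUBGROUPS = (
    "rice_products",
    "cereals_tubers_roots",
    "soybeans",
    "vegetables",
    "mushrooms",
    "seaweed",
    "fish_shellfish",
    "livestock",
    "fruit",
    "others",
)

AREAS = ("A", "B", "pooled")

#: Default detection limits (mg/kg): cereal-group foods 0.01, drinking water
#: 0.001 (mg/L), everything else 0.005.
DEFAULT_LOD_CEREALS = 0.01
DEFAULT_LOD_OTHER = 0.005
DEFAULT_LOD_WATER = 0.001

SubstitutionRule = Literal["zero", "half_lod", "lod"]
MeanKind = Literal["AM", "GM"]

CSV_COLUMNS = ["item", "subgroup", "area", "value_mg_per_kg", "censored", "lod_mg_per_kg"]


class ConcentrationError(ValueError):
    """Raised for malformed or inconsistent concentration data."""


@dataclass(frozen=True)
class FoodConcentrationRecord:
    """One measured (or censored) Cd value for one food item in one area."""

    item: str
    subgroup: str
    area: str
    value: float | None  # mg/kg; None when censored
    censored: bool = False
    lod: float | None = None  # mg/kg; required when censored
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.subgroup not in SUBGROUPS:
            raise ConcentrationError(f"unknown subgroup {self.subgroup!r} for {self.item!r}")
        if self.area not in AREAS:
            raise ConcentrationError(f"unknown area {self.area!r} for {self.item!r}")
        if self.censored:
            if self.value is not None:
                raise ConcentrationError(f"censored record for {self.item!r} must not carry a value")
            if self.lod is None or self.lod <= 0:
                raise ConcentrationError(f"censored record for {self.item!r} needs lod > 0")
        else:
            if self.value is None or self.value < 0:
                raise ConcentrationError(f"record for {self.item!r} needs a nonnegative value")


@dataclass(frozen=True)
class ConcentrationSummary:
    item: str
    n: int
    mean: float
    mean_kind: MeanKind
    range_lo: float
    range_hi: float


def default_lod(subgroup: str, item: str = "") -> float:
    if subgroup in ("rice_products", "cereals_tubers_roots"):
        return DEFAULT_LOD_CEREALS
    if "water" in item.lower():
        return DEFAULT_LOD_WATER
    return DEFAULT_LOD_OTHER


def substitute_censored(
    records: Iterable[FoodConcentrationRecord], rule: SubstitutionRule
) -> np.ndarray:
    """Replace censored records by 0, LOD/2 or LOD; uncensored pass through."""
    factor = {"zero": 0.0, "half_lod": 0.5, "lod": 1.0}
    try:
        f = factor[rule]
    except KeyError:
        raise ConcentrationError(f"unknown substitution rule {rule!r}") from None
    out = []
    for rec in records:
        out.append(f * rec.lod if rec.censored else rec.value)
    return np.asarray(out, dtype=float)


def summarize_item(
    records: Sequence[FoodConcentrationRecord],
    mean_kind: MeanKind = "AM",
    substitution: SubstitutionRule = "half_lod",
) -> ConcentrationSummary:
    """Arithmetic or geometric mean and range of one item's (substituted) values."""
    records = list(records)
    if not records:
        raise ConcentrationError("summarize_item needs at least one record")
    items = {r.item for r in records}
    if len(items) > 1:
        raise ConcentrationError(f"records span several items: {sorted(items)}")
    values = substitute_censored(records, substitution)
    if mean_kind == "AM":
        mean = float(np.mean(values))
    elif mean_kind == "GM":
        if np.any(values <= 0):
            raise ConcentrationError(
                "geometric mean undefined with zero values; "
                "use a nonzero substitution rule (half_lod or lod)"
            )
        mean = float(np.exp(np.mean(np.log(values))))
    else:
        raise ConcentrationError(f"unknown mean_kind {mean_kind!r}")
    return ConcentrationSummary(
        item=records[0].item,
        n=len(records),
        mean=mean,
        mean_kind=mean_kind,
        range_lo=float(np.min(values)),
        range_hi=float(np.max(values)),
    )


def load_concentration_table(path: str | Path) -> list[FoodConcentrationRecord]:
    """Read a replicate-level concentration CSV.

    Expected header: ``item,subgroup,area,value_mg_per_kg,censored,lod_mg_per_kg``.
    Rows are validated individually; the first malformed row aborts the load
    with its (1-based, header-exclusive) row number.
    """
    df = pd.read_csv(
        path, dtype={"item": str, "subgroup": str, "area": str}, float_precision="round_trip"
    )
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ConcentrationError(f"{path}: missing columns {sorted(missing)}")
    records: list[FoodConcentrationRecord] = []
    counters: dict[tuple[str, str], int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        censored = bool(row.censored)
        value = None if censored else float(row.value_mg_per_kg)
        lod = None if pd.isna(row.lod_mg_per_kg) else float(row.lod_mg_per_kg)
        key = (str(row.item), str(row.area))
        rep = counters.get(key, 0)
        counters[key] = rep + 1
        try:
            records.append(
                FoodConcentrationRecord(
                    item=str(row.item),
                    subgroup=str(row.subgroup),
                    area=str(row.area),
                    value=value,
                    censored=censored,
                    lod=lod,
                    replicate=rep,
                )
            )
        except ConcentrationError as exc:
            raise ConcentrationError(f"{path}: row {i}: {exc}") from exc
    seen: set[tuple[str, str, int]] = set()
    for rec in records:
        k = (rec.item, rec.area, rec.replicate)
        if k in seen:
            raise ConcentrationError(f"{path}: duplicate record {k}")
        seen.add(k)
    return records


def write_concentration_table(
    records: Iterable[FoodConcentrationRecord], path: str | Path
) -> None:
    rows = [
        {
            "item": r.item,
            "subgroup": r.subgroup,
            "area": r.area,
            "value_mg_per_kg": r.value,
            "censored": int(r.censored),
            "lod_mg_per_kg": r.lod,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def expand_summary(
    item: str,
    subgroup: str,
    area: str,
    n: int,
    mean: float,
    mean_kind: MeanKind,
    range_lo: float | None,
    range_hi: float | None,
) -> list[FoodConcentrationRecord]:
    """Reconstruct ``n`` replicate values from a printed summary.

    The two printed range endpoints are kept verbatim; the ``n - 2`` interior
    replicates share a single value solved so the mean (arithmetic, or
    geometric on the log scale) reproduces the printed mean. When the printed
    (rounded) mean is not attainable with both endpoints inside the range the
    interior value is clipped to the range, leaving the recomputed mean within
    the print precision of the published one.
    """
    if n < 1:
        raise ConcentrationError(f"{item}: n must be >= 1")
    if n == 1 or range_lo is None or range_hi is None:
        values = [mean] * n
    elif n == 2:
        values = [range_lo, range_hi]
    else:
        if mean_kind == "GM":
            log_interior = (n * math.log(mean) - math.log(range_lo) - math.log(range_hi)) / (n - 2)
            interior = math.exp(log_interior)
        else:
            interior = (n * mean - range_lo - range_hi) / (n - 2)
        interior = min(max(interior, range_lo), range_hi)
        values = [range_lo] + [interior] * (n - 2) + [range_hi]
    return [
        FoodConcentrationRecord(item=item, subgroup=subgroup, area=area, value=v, replicate=i)
        for i, v in enumerate(values)
    ]


def _fixture_frame() -> pd.DataFrame:
    with resources.as_file(resources.files("cdintake.data") / "table_fixtures.csv") as p:
        return pd.read_csv(p)


def load_fixture_summaries() -> pd.DataFrame:
    """The packaged printed-summary table (item, subgroup, area, n, mean, range)."""
    return _fixture_frame()


def default_records() -> list[FoodConcentrationRecord]:
    """Expand the packaged summary table into replicate-level records."""
    records: list[FoodConcentrationRecord] = []
    for row in _fixture_frame().itertuples(index=False):
        if bool(row.censored):
            lod = float(row.lod_mg_per_kg)
            records.extend(
                FoodConcentrationRecord(
                    item=row.item,
                    subgroup=row.subgroup,
                    area=row.area,
                    value=None,
                    censored=True,
                    lod=lod,
                    replicate=i,
                )
                for i in range(int(row.n))
            )
        else:
            lo = None if pd.isna(row.range_lo_mg_per_kg) else float(row.range_lo_mg_per_kg)
            hi = None if pd.isna(row.range_hi_mg_per_kg) else float(row.range_hi_mg_per_kg)
            records.extend(
                expand_summary(
                    item=row.item,
                    subgroup=row.subgroup,
                    area=row.area,
                    n=int(row.n),
                    mean=float(row.mean_mg_per_kg),
                    mean_kind=row.mean_kind,
                    range_lo=lo,
                    range_hi=hi,
                )
            )
    return records


class ConcentrationTable:
    """Indexed view over a set of concentration records.

    Provides per-item lookups, pooled (area-agnostic) arithmetic means for the
    intake calculation, and the area-specific rice geometric means used to
    backfill subjects whose individual rice measurement is missing.
    """

    def __init__(self, records: Iterable[FoodConcentrationRecord]):
        self.records = list(records)
        self._by_item: dict[str, list[FoodConcentrationRecord]] = {}
        for rec in self.records:
            self._by_item.setdefault(rec.item, []).append(rec)
        self._pooled_cache: dict[tuple[str, str], float] = {}

    @classmethod
    def default(cls) -> "ConcentrationTable":
        return cls(default_records())

    def items(self) -> list[str]:
        return sorted(self._by_item)

    def __contains__(self, item: str) -> bool:
        return item in self._by_item

    def records_for(self, item: str, area: str | None = None) -> list[FoodConcentrationRecord]:
        try:
            recs = self._by_item[item]
        except KeyError:
            raise ConcentrationError(f"item {item!r} not in concentration table") from None
        if area is not None:
            recs = [r for r in recs if r.area == area]
        return recs

    def subgroup_of(self, item: str) -> str:
        return self.records_for(item)[0].subgroup

    def pooled_mean(self, item: str, substitution: SubstitutionRule = "zero") -> float:
        """Arithmetic mean over all of an item's records irrespective of area."""
        key = (item, substitution)
        if key not in self._pooled_cache:
            values = substitute_censored(self.records_for(item), substitution)
            self._pooled_cache[key] = float(np.mean(values))
        return self._pooled_cache[key]

    def summarize(
        self,
        item: str,
        mean_kind: MeanKind = "AM",
        substitution: SubstitutionRule = "half_lod",
        area: str | None = None,
    ) -> ConcentrationSummary:
        return summarize_item(self.records_for(item, area), mean_kind, substitution)

    def rice_gm(self, area: str, substitution: SubstitutionRule = "lod") -> float:
        """Area-specific geometric mean of rice Cd (mg/kg)."""
        return self.summarize("Rice", mean_kind="GM", substitution=substitution, area=area).mean


def pooled_mean(
    item: str,
    records: Iterable[FoodConcentrationRecord],
    substitution: SubstitutionRule = "zero",
) -> float:
    """AM of one item's records across areas (convenience over ConcentrationTable)."""
    recs = [r for r in records if r.item == item]
    if not recs:
        raise ConcentrationError(f"item {item!r} has no records")
    return float(np.mean(substitute_censored(recs, substitution)))
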