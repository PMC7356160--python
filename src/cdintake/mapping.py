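"""Declarative reconciliation of questionnaire items with measured concentrations.

The diet-history questionnaire (DHQ) and the market survey of food Cd do not
line up one-to-one: some questionnaire items pool several foods (noodles,
tubers, leafy greens), some measured foods are split across questionnaire
items, rice uses each subject's own measured concentration, and a number of
items are excluded outright (Cd never detected, or not assessed by the DHQ).
A :class:`MappingRule` captures one questionnaire item's resolution as a
weighted combination of concentration sources.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import yaml

from .concentrations import ConcentrationTable, SubstitutionRule

if TYPE_CHECKING:  # pragma: no cover
    from .intake import Subject

logger = logging.getLogger(__name__)

RICE_INDIVIDUAL = "RICE_INDIVIDUAL"

#: Polished-rice equivalent factor applied to a brown-rice Cd concentration
#: (polishing removes ~10% of the Cd).
BROWN_RICE_FACTOR = 0.9

WEIGHT_TOL = 1e-9


class MappingError(ValueError):
    """Raised for invalid mapping configuration."""


@dataclass(frozen=True)
class MappingComponent:
    """One weighted concentration source of a questionnaire item.

    Either ``source`` names a single concentration item (or the sentinel
    ``RICE_INDIVIDUAL``), or ``average_of`` names several items whose pooled
    arithmetic means are averaged.
    """

    weight: float
    source: str | None = None
    average_of: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.source is None) == (not self.average_of):
            raise MappingError("component needs exactly one of source / average_of")
        if not 0.0 <= self.weight <= 1.0:
            raise MappingError(f"weight {self.weight} outside [0, 1]")


@dataclass(frozen=True)
class MappingRule:
    dhq_item: str
    components: tuple[MappingComponent, ...] = ()
    mass_change_factor: float = 1.0
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.mass_change_factor <= 0:
            raise MappingError(f"{self.dhq_item}: mass_change_factor must be > 0")
        if self.excluded:
            if self.components:
                raise MappingError(f"{self.dhq_item}: excluded rule must have no components")
        else:
            total = sum(c.weight for c in self.components)
            if abs(total - 1.0) > WEIGHT_TOL:
                raise MappingError(
                    f"{self.dhq_item}: component weights sum to {total}, expected 1"
                )


@dataclass
class MappingReport:
    unmapped_dhq_items: list[str] = field(default_factory=list)
    unused_concentration_items: list[str] = field(default_factory=list)
    excluded_items: list[str] = field(default_factory=list)


def _validate_against_table(rule: MappingRule, table: ConcentrationTable) -> None:
    for comp in rule.components:
        if comp.source is not None:
            if comp.source != RICE_INDIVIDUAL and comp.source not in table:
                raise MappingError(
                    f"{rule.dhq_item}: source {comp.source!r} not in concentration table"
                )
        for name in comp.average_of:
            if name not in table:
                raise MappingError(
                    f"{rule.dhq_item}: average_of member {name!r} not in concentration table"
                )


def load_mapping(
    path: str | Path, table: ConcentrationTable, mass_change: Mapping[str, float] | None = None
) -> dict[str, MappingRule]:
    """Load and validate a mapping config (YAML, one entry per DHQ item).

    ``mass_change`` optionally overrides per-item mass-change factors (raw
    equivalent per gram as consumed); the default is 1.0 for every item.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "rules" not in doc:
        raise MappingError(f"{path}: expected a top-level 'rules' mapping")
    mass_change = dict(mass_change or {})
    rules: dict[str, MappingRule] = {}
    for dhq_item, entry in doc["rules"].items():
        factor = mass_change.get(dhq_item, 1.0)
        if entry == "excluded":
            rules[dhq_item] = MappingRule(dhq_item=dhq_item, excluded=True)
            continue
        if not isinstance(entry, dict) or "components" not in entry:
            raise MappingError(f"{path}: entry {dhq_item!r} needs 'components' or 'excluded'")
        comps = []
        for c in entry["components"]:
            if "average_of" in c:
                comps.append(
                    MappingComponent(weight=float(c["weight"]), average_of=tuple(c["average_of"]))
                )
            else:
                comps.append(MappingComponent(weight=float(c["weight"]), source=str(c["source"])))
        factor = float(entry.get("mass_change_factor", factor))
        rule = MappingRule(
            dhq_item=dhq_item, components=tuple(comps), mass_change_factor=factor
        )
        _validate_against_table(rule, table)
        rules[dhq_item] = rule
    return rules


def default_mapping(
    table: ConcentrationTable | None = None, mass_change: Mapping[str, float] | None = None
) -> dict[str, MappingRule]:
    """The packaged default mapping config, validated against ``table``."""
    table = table if table is not None else ConcentrationTable.default()
    with resources.as_file(resources.files("cdintake.data") / "default_mapping.yaml") as p:
        return load_mapping(p, table, mass_change=mass_change)


def component_concentration(
    comp: MappingComponent,
    table: ConcentrationTable,
    subject: "Subject | None" = None,
    cohort_rice_gm: float | None = None,
    substitution: SubstitutionRule = "zero",
) -> float:
    """Effective concentration (µg/g) of a single component, weight excluded."""
    if comp.average_of:
        means = [table.pooled_mean(name, substitution) for name in comp.average_of]
        return float(sum(means) / len(means))
    if comp.source == RICE_INDIVIDUAL:
        rice_cd = None if subject is None else subject.rice_cd
        if rice_cd is not None:
            return rice_cd * (BROWN_RICE_FACTOR if subject.brown_rice else 1.0)
        if cohort_rice_gm is None:
            raise MappingError(
                "individual rice Cd missing and no cohort rice GM supplied"
            )
        return cohort_rice_gm
    return table.pooled_mean(comp.source, substitution)


def component_subgroup(comp: MappingComponent, table: ConcentrationTable) -> str:
    """Concentration subgroup a component's Cd contribution belongs to."""
    if comp.source == RICE_INDIVIDUAL:
        return "rice_products"
    name = comp.source if comp.source is not None else comp.average_of[0]
    return table.subgroup_of(name)


def resolve_concentration(
    rule: MappingRule,
    table: ConcentrationTable,
    subject: "Subject | None" = None,
    cohort_rice_gm: float | None = None,
    substitution: SubstitutionRule = "zero",
) -> float:
    """Weight-combined effective concentration (µg/g) for a questionnaire item."""
    if rule.excluded:
        return 0.0
    return float(
        sum(
            c.weight
            * component_concentration(c, table, subject, cohort_rice_gm, substitution)
            for c in rule.components
        )
    )


def validate_coverage(
    rules: Mapping[str, MappingRule],
    dhq_catalog: Iterable[str] | None = None,
    table: ConcentrationTable | None = None,
) -> MappingReport:
    """Report unmapped questionnaire items, unreferenced concentration items,
    and explicit exclusions."""
    table = table if table is not None else ConcentrationTable.default()
    catalog = list(dhq_catalog) if dhq_catalog is not None else list(rules)
    referenced: set[str] = set()
    for rule in rules.values():
        for comp in rule.components:
            if comp.source == RICE_INDIVIDUAL:
                referenced.add("Rice")
            elif comp.source is not None:
                referenced.add(comp.source)
            referenced.update(comp.average_of)
    unmapped = [item for item in catalog if item not in rules]
    unused = [item for item in table.items() if item not in referenced]
    excluded = sorted(name for name, rule in rules.items() if rule.excluded)
    for item in unmapped:
        logger.warning("DHQ item %r has no mapping rule; its intake contributes no Cd", item)
    return MappingReport(
        unmapped_dhq_items=unmapped,
        unused_concentration_items=unused,
        excluded_items=excluded,
    )
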