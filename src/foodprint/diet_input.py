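"""Diet inputs: food-group serving vectors, survey records, analytic
exclusion rules, and population means.

A record carries one day-1-recall intake vector per participant; no
usual-intake modelling is attempted.  Servings are taken at face value —
conversion from raw recall food codes to group servings is an upstream
contract of the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import constants as C
from .errors import SchemaError


@dataclass(frozen=True)
class FoodGroupVector:
    """Daily servings for each of the 22 food groups.

    Entries are nonnegative finite quantities in the group's serving unit
    (cup-eq, oz-eq, or teaspoons).  Groups not present default to zero.
    """

    servings: Mapping[str, float]
    groups: tuple[str, ...] = C.FOOD_GROUPS

    def __post_init__(self):
        unknown = set(self.servings) - set(self.groups)
        if unknown:
            raise ValueError(f"unknown food group(s): {sorted(unknown)}")
        for g, v in self.servings.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"group {g}: servings must be finite and >= 0")

    def get(self, group: str) -> float:
        return float(self.servings.get(group, 0.0))

    def scale(self, factor: float) -> "FoodGroupVector":
        return FoodGroupVector(
            {g: v * factor for g, v in self.servings.items()}, self.groups
        )

    def is_zero(self) -> bool:
        return all(v == 0 for v in self.servings.values())

    def to_series(self) -> pd.Series:
        return pd.Series({g: self.get(g) for g in self.groups}, dtype=float)

    @classmethod
    def zeros(cls, groups: Sequence[str] = C.FOOD_GROUPS) -> "FoodGroupVector":
        return cls({}, tuple(groups))


@dataclass(frozen=True)
class DietRecord:
    """One survey participant's day-1 intake with survey metadata."""

    participant_id: str
    age_years: float
    survey_weight: float
    intake: FoodGroupVector
    survey_cycle: str = ""
    recall_reliable: bool = True
    energy_kcal: float | None = None

    def __post_init__(self):
        if not self.survey_weight > 0:
            raise ValueError(
                f"record {self.participant_id}: survey_weight must be > 0"
            )
        if self.age_years < 0:
            raise ValueError(f"record {self.participant_id}: negative age")


@dataclass(frozen=True)
class ScenarioConfig:
    """Population size, trade mode, and model toggles for one scenario."""

    population_size: float = 1.0
    trade_mode: str = "closed"  # open | closed
    include_aquatic_food: bool = True
    loss_waste_variant: str | None = None
    aquaculture_mode: str = "corrected"  # corrected | strict_paper
    trade_sign_mode: str = "narrative"  # narrative | printed

    def __post_init__(self):
        if not self.population_size > 0:
            raise ValueError("population_size must be > 0")
        if self.trade_mode not in ("open", "closed"):
            raise ValueError("trade_mode must be 'open' or 'closed'")
        if self.aquaculture_mode not in ("corrected", "strict_paper"):
            raise ValueError("aquaculture_mode must be 'corrected' or 'strict_paper'")
        if self.trade_sign_mode not in ("narrative", "printed"):
            raise ValueError("trade_sign_mode must be 'narrative' or 'printed'")


REQUIRED_META_COLUMNS = ("participant_id", "age_years", "survey_weight")
OPTIONAL_META_COLUMNS = ("survey_cycle", "recall_reliable", "energy_kcal")


def load_schema(path: str | Path) -> dict[str, str]:
    """Load a YAML column mapping {canonical name -> file column}."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return {str(k): str(v) for k, v in data.items()}


def read_diet_survey(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    groups: Sequence[str] = C.FOOD_GROUPS,
    sep: str = "\t",
) -> list[DietRecord]:
    """Read a delimited diet-survey file into records.

    Parameters
    ----------
    path
        Delimited file with participant metadata and one column per group.
    schema
        Optional mapping from canonical column names (``participant_id``,
        ``age_years``, ``survey_weight``, group names, ...) to the file's
        actual column names.
    """
    schema = dict(schema or {})
    df = pd.read_csv(path, sep=sep)

    def col(name: str) -> str:
        return schema.get(name, name)

    missing = [
        name
        for name in (*REQUIRED_META_COLUMNS, *groups)
        if col(name) not in df.columns
    ]
    if missing:
        raise SchemaError(f"diet survey {path}: missing column(s) {missing}")

    records: list[DietRecord] = []
    for idx, row in df.iterrows():
        intake = {}
        for g in groups:
            v = float(row[col(g)])
            if v < 0:
                raise SchemaError(f"row {idx}: negative intake for group {g!r}")
            intake[g] = v
        kwargs = {}
        if col("survey_cycle") in df.columns:
            kwargs["survey_cycle"] = str(row[col("survey_cycle")])
        if col("recall_reliable") in df.columns:
            kwargs["recall_reliable"] = bool(row[col("recall_reliable")])
        if col("energy_kcal") in df.columns and not pd.isna(row[col("energy_kcal")]):
            kwargs["energy_kcal"] = float(row[col("energy_kcal")])
        records.append(
            DietRecord(
                participant_id=str(row[col("participant_id")]),
                age_years=float(row[col("age_years")]),
                survey_weight=float(row[col("survey_weight")]),
                intake=FoodGroupVector(intake, tuple(groups)),
                **kwargs,
            )
        )
    return records


def write_diet_survey(records: Iterable[DietRecord], path: str | Path) -> None:
    """Write records in the canonical survey layout read by read_diet_survey."""
    rows = []
    for r in records:
        row = {
            "participant_id": r.participant_id,
            "age_years": r.age_years,
            "survey_weight": r.survey_weight,
            "survey_cycle": r.survey_cycle,
            "recall_reliable": r.recall_reliable,
            "energy_kcal": "" if r.energy_kcal is None else r.energy_kcal,
        }
        row.update({g: r.intake.get(g) for g in r.intake.groups})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# exclusions

EXCLUSION_REASONS = (
    "age<1",
    "unreliable recall",
    "no model food groups",
    "resource outlier >3 SD",
)

#: resource metrics screened by the 3-SD rule (irrigation deliberately not)
SCREENED_RESOURCES = ("land", "fertilizer", "pesticides")


@dataclass
class ExclusionResult:
    kept: list[DietRecord]
    tally: dict[str, int] = field(default_factory=dict)
    excluded_ids: dict[str, list[str]] = field(default_factory=dict)


def apply_exclusions(
    records: Sequence[DietRecord],
    resource_totals: Mapping[str, Mapping[str, float]] | None = None,
    screen_outliers: bool = False,
) -> ExclusionResult:
    """Apply the analytic exclusion rules in order.

    Rules, applied sequentially: age < 1 year; unreliable recall; zero
    intake across all model food groups; and, when ``screen_outliers`` is
    set, any of land / fertilizer-nutrient / pesticide totals more than
    3 SD from the (unweighted) mean of the surviving sample.  The outlier
    screen is a single pass; mean and SD use the sample SD (ddof=1).

    Parameters
    ----------
    resource_totals
        Mapping participant_id -> {"land": ..., "fertilizer": ...,
        "pesticides": ...}; required when ``screen_outliers`` is set.
    """
    tally = {reason: 0 for reason in EXCLUSION_REASONS}
    excluded: dict[str, list[str]] = {reason: [] for reason in EXCLUSION_REASONS}

    survivors: list[DietRecord] = []
    for r in records:
        if r.age_years < 1:
            tally["age<1"] += 1
            excluded["age<1"].append(r.participant_id)
        elif not r.recall_reliable:
            tally["unreliable recall"] += 1
            excluded["unreliable recall"].append(r.participant_id)
        elif r.intake.is_zero():
            tally["no model food groups"] += 1
            excluded["no model food groups"].append(r.participant_id)
        else:
            survivors.append(r)

    if screen_outliers:
        if resource_totals is None:
            raise ValueError(
                "outlier screen requested without per-record resource totals"
            )
        kept = _screen_resource_outliers(survivors, resource_totals)
        n_out = len(survivors) - len(kept)
        tally["resource outlier >3 SD"] = n_out
        kept_ids = {r.participant_id for r in kept}
        excluded["resource outlier >3 SD"] = [
            r.participant_id for r in survivors if r.participant_id not in kept_ids
        ]
        survivors = kept

    return ExclusionResult(kept=survivors, tally=tally, excluded_ids=excluded)


def _screen_resource_outliers(records, resource_totals):
    if len(records) < 2:
        return list(records)
    values = {
        metric: np.array(
            [float(resource_totals[r.participant_id][metric]) for r in records]
        )
        for metric in SCREENED_RESOURCES
    }
    kept = []
    stats = {
        m: (v.mean(), v.std(ddof=1)) for m, v in values.items()
    }
    for i, r in enumerate(records):
        is_outlier = any(
            sd > 0 and abs(values[m][i] - mean) > 3 * sd
            for m, (mean, sd) in stats.items()
        )
        if not is_outlier:
            kept.append(r)
    return kept


def population_mean_diet(
    records: Sequence[DietRecord], weighted: bool = False
) -> FoodGroupVector:
    """Arithmetic (or survey-weight-weighted) mean intake per group."""
    if not records:
        raise ValueError("population_mean_diet: empty record list")
    groups = records[0].intake.groups
    weights = np.array(
        [r.survey_weight if weighted else 1.0 for r in records], dtype=float
    )
    weights = weights / weights.sum()
    mean = {
        g: float(sum(w * r.intake.get(g) for w, r in zip(weights, records)))
        for g in groups
    }
    return FoodGroupVector(mean, groups)
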