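"""Data model and I/O for daily psychotherapy process data.

Daily self-ratings (visual-analog items on a bounded scale, grouped into
factors by a questionnaire schema) are held as a channels x days matrix with
an explicit missing mask; diary codings are held as a day -> category-set
timeline over a fixed vocabulary of transformation indicators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import CategoryError, SchemaError, SeriesError

__all__ = [
    "QuestionnaireSchema",
    "ProcessSeries",
    "CategoryTimeline",
    "CATEGORY_VOCABULARY",
    "CATEGORY_GROUPS",
    "NO_ENTRY",
    "default_schema",
    "load_schema",
    "load_process",
    "load_process_csv",
    "locf_impute",
    "factor_scores",
    "load_categories",
    "series_to_frame",
]

#: Diary transformation-indicator subcategories (atomic coding unit) plus the
#: explicit marker for a day without any diary entry.
NO_ENTRY = "no_entry"
CATEGORY_VOCABULARY = frozenset(
    {
        "feeling_helpless",
        "noticing_attractor",
        "regaining_control",
        "moment_of_improvement",
        "lasting_improvement",
        "broadening_perspective",
        "critical_instability",
        "kairos",
        NO_ENTRY,
    }
)

#: Parent groupings of the subcategories; derivable, never stored.
CATEGORY_GROUPS: Mapping[str, frozenset[str]] = {
    "stability": frozenset(
        {"feeling_helpless", "noticing_attractor", "regaining_control"}
    ),
    "improvement": frozenset({"moment_of_improvement", "lasting_improvement"}),
    "broadening_perspective": frozenset({"broadening_perspective"}),
    "critical_instability": frozenset({"critical_instability"}),
    "kairos": frozenset({"kairos"}),
}


@dataclass(frozen=True)
class QuestionnaireSchema:
    """Items, their factor assignment, and the rating-scale bounds.

    The packaged default mirrors the structure of the Therapy Process
    Questionnaire: 43 items under the seven factors WPE, RFP, TAS, EPI,
    ICP, MOT and MSC, rated 0-100 (visual analog scale).
    """

    items: tuple[str, ...]
    factor_of: Mapping[str, str]
    factors: tuple[str, ...]
    scale_min: float = 0.0
    scale_max: float = 100.0

    def __post_init__(self) -> None:
        if self.scale_min >= self.scale_max:
            raise SchemaError("scale_min must be below scale_max")
        if len(set(self.items)) != len(self.items):
            raise SchemaError("duplicate item identifiers")
        if set(self.factor_of) != set(self.items):
            raise SchemaError("every item must map to exactly one factor")
        if set(self.factor_of.values()) != set(self.factors):
            raise SchemaError("factor list must equal the set of mapped factors")

    @property
    def scale_range(self) -> float:
        return self.scale_max - self.scale_min

    def items_of(self, factor: str) -> list[str]:
        if factor not in self.factors:
            raise SchemaError(f"unknown factor {factor!r}")
        return [i for i in self.items if self.factor_of[i] == factor]

    @classmethod
    def from_dict(cls, doc: Mapping) -> "QuestionnaireSchema":
        factors = doc["factors"]
        items: list[str] = []
        factor_of: dict[str, str] = {}
        for label, members in factors.items():
            if not members:
                raise SchemaError(f"factor {label!r} has zero items")
            for item in members:
                items.append(item)
                factor_of[item] = label
        return cls(
            items=tuple(items),
            factor_of=factor_of,
            factors=tuple(factors),
            scale_min=float(doc.get("scale_min", 0.0)),
            scale_max=float(doc.get("scale_max", 100.0)),
        )


def load_schema(path) -> QuestionnaireSchema:
    """Read a schema from a JSON document ``{scale_min, scale_max, factors}``."""
    with open(path, encoding="utf-8") as fh:
        return QuestionnaireSchema.from_dict(json.load(fh))


def default_schema() -> QuestionnaireSchema:
    """The packaged 43-item / 7-factor default schema (``tpq43.json``)."""
    text = resources.files("patternshift.data").joinpath("tpq43.json").read_text()
    return QuestionnaireSchema.from_dict(json.loads(text))


@dataclass
class ProcessSeries:
    """One case's multichannel daily ratings on a contiguous daily grid.

    ``values`` is channels x days with NaN at missing cells; ``missing_mask``
    is True exactly where a value is missing. ``level`` records whether the
    channels are raw items or aggregated factor scores.
    """

    case_id: str
    days: np.ndarray  # 1-based, consecutive integers
    channels: tuple[str, ...]
    values: np.ndarray  # float, channels x days, NaN where missing
    missing_mask: np.ndarray  # bool, channels x days
    schema: QuestionnaireSchema
    level: str = "item"  # "item" | "factor"

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.level not in ("item", "factor"):
            raise SeriesError(f"level must be 'item' or 'factor', got {self.level!r}")
        if self.days.size < 2:
            raise SeriesError("a process series needs at least 2 days")
        if np.any(np.diff(self.days) != 1):
            raise SeriesError("days must be strictly increasing with step 1")
        shape = (len(self.channels), self.days.size)
        if self.values.shape != shape or self.missing_mask.shape != shape:
            raise SeriesError(
                f"values/missing_mask must have shape {shape}, "
                f"got {self.values.shape} / {self.missing_mask.shape}"
            )
        if np.any(np.isnan(self.values) != self.missing_mask):
            raise SeriesError("missing_mask must match NaN positions in values")
        observed = self.values[~self.missing_mask]
        lo, hi = self.schema.scale_min, self.schema.scale_max
        if observed.size and (observed.min() < lo or observed.max() > hi):
            raise SeriesError(f"observed values outside scale bounds [{lo}, {hi}]")

    @property
    def n_days(self) -> int:
        return int(self.days.size)

    @property
    def is_imputed(self) -> bool:
        return not bool(self.missing_mask.any())

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channels.index(label)
        except ValueError:
            raise SeriesError(f"unknown channel {label!r}") from None
        return self.values[idx]


def load_process(table: pd.DataFrame, schema: QuestionnaireSchema) -> ProcessSeries:
    """Build an item-level :class:`ProcessSeries` from long-format records.

    ``table`` needs columns ``case_id, day, item_id, value``; a blank/NaN
    value or an absent (day, item) pair becomes a missing cell. Days are
    completed to a contiguous grid between the observed minimum and maximum.
    """
    required = {"case_id", "day", "item_id", "value"}
    if not required.issubset(table.columns):
        raise SeriesError(f"table must have columns {sorted(required)}")
    if table.empty:
        raise SeriesError("empty record table")
    cases = table["case_id"].unique()
    if len(cases) != 1:
        raise SeriesError(f"expected a single case, got {list(cases)}")
    case_id = str(cases[0])

    unknown = set(table["item_id"].astype(str)) - set(schema.items)
    if unknown:
        raise SchemaError(f"unknown item ids: {sorted(unknown)}")
    if table.duplicated(["day", "item_id"]).any():
        dup = table[table.duplicated(["day", "item_id"], keep=False)]
        raise SeriesError(
            f"duplicate (day, item) records, e.g. {dup.iloc[0][['day', 'item_id']].tolist()}"
        )

    day_lo, day_hi = int(table["day"].min()), int(table["day"].max())
    days = np.arange(day_lo, day_hi + 1)
    if days.size < 2:
        raise SeriesError("fewer than 2 days of records")

    wide = (
        table.assign(item_id=table["item_id"].astype(str))
        .pivot(index="item_id", columns="day", values="value")
        .reindex(index=list(schema.items), columns=days)
    )
    values = wide.to_numpy(dtype=float)
    missing = np.isnan(values)
    observed = values[~missing]
    if observed.size and (
        observed.min() < schema.scale_min or observed.max() > schema.scale_max
    ):
        bad = observed[(observed < schema.scale_min) | (observed > schema.scale_max)]
        raise SeriesError(
            f"value {bad[0]} outside scale bounds "
            f"[{schema.scale_min}, {schema.scale_max}]"
        )
    return ProcessSeries(
        case_id=case_id,
        days=days,
        channels=tuple(schema.items),
        values=values,
        missing_mask=missing,
        schema=schema,
        level="item",
    )


def load_process_csv(path, schema: QuestionnaireSchema) -> ProcessSeries:
    """Read the standard long CSV (``case_id,day,item_id,value``)."""
    table = pd.read_csv(path, dtype={"case_id": str, "item_id": str})
    return load_process(table, schema)


def series_to_frame(series: ProcessSeries) -> pd.DataFrame:
    """Serialize back to long format; missing cells get blank values."""
    ch, days = np.meshgrid(np.arange(len(series.channels)), series.days, indexing="ij")
    return pd.DataFrame(
        {
            "case_id": series.case_id,
            "day": days.ravel(),
            "item_id": np.asarray(series.channels)[ch.ravel()],
            "value": series.values.ravel(),
        }
    )


def locf_impute(series: ProcessSeries) -> ProcessSeries:
    """Impute missing days by carrying the last observation forward.

    Leading gaps (no prior observation) take the first observed value of the
    channel, so every channel is total afterwards. A channel with zero
    observations is an error.
    """
    values = series.values.copy()
    for i, row in enumerate(values):
        obs = np.flatnonzero(~np.isnan(row))
        if obs.size == 0:
            raise SeriesError(
                f"channel {series.channels[i]!r} has no observed values"
            )
        # forward fill: index of the most recent observed day at each position
        idx = np.maximum.accumulate(
            np.where(~np.isnan(row), np.arange(row.size), -1)
        )
        idx[idx < 0] = obs[0]  # leading gap -> first observation
        values[i] = row[idx]
    return replace(
        series,
        values=values,
        missing_mask=np.zeros_like(series.missing_mask),
    )


def factor_scores(series: ProcessSeries) -> ProcessSeries:
    """Aggregate an imputed item-level series to factor scores.

    Each factor score is the unweighted arithmetic mean of its items on that
    day, which keeps values inside the scale bounds.
    """
    if series.level != "item":
        raise SeriesError("factor_scores expects an item-level series")
    if not series.is_imputed:
        raise SeriesError("factor_scores expects a fully imputed series")
    schema = series.schema
    rows = []
    for factor in schema.factors:
        member_idx = [series.channels.index(it) for it in schema.items_of(factor)]
        if not member_idx:
            raise SchemaError(f"factor {factor!r} has zero items")
        rows.append(series.values[member_idx].mean(axis=0))
    values = np.vstack(rows)
    return ProcessSeries(
        case_id=series.case_id,
        days=series.days,
        channels=tuple(schema.factors),
        values=values,
        missing_mask=np.zeros_like(values, dtype=bool),
        schema=schema,
        level="factor",
    )


@dataclass
class CategoryTimeline:
    """Diary coding per day: a set of subcategory codes, or ``no_entry``."""

    case_id: str
    entries: dict[int, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for day, codes in self.entries.items():
            bad = set(codes) - CATEGORY_VOCABULARY
            if bad:
                raise CategoryError(f"unknown category codes {sorted(bad)} on day {day}")
            if NO_ENTRY in codes and len(codes) > 1:
                raise CategoryError(
                    f"day {day}: {NO_ENTRY!r} cannot co-occur with another code"
                )

    def days_with(self, codes: Iterable[str]) -> np.ndarray:
        """Sorted days on which at least one of ``codes`` was recorded."""
        wanted = frozenset(codes)
        bad = wanted - CATEGORY_VOCABULARY
        if bad:
            raise CategoryError(f"unknown category codes {sorted(bad)}")
        return np.array(
            sorted(d for d, c in self.entries.items() if c & wanted), dtype=int
        )


def load_categories(table: pd.DataFrame, series: ProcessSeries) -> CategoryTimeline:
    """Attach diary-category records (``day, category_code``) to a series.

    Days of the series without any record are coded ``no_entry``.
    """
    required = {"day", "category_code"}
    if not required.issubset(table.columns):
        raise CategoryError(f"table must have columns {sorted(required)}")
    entries: dict[int, set[str]] = {int(d): set() for d in series.days}
    day_set = set(entries)
    for _, rec in table.iterrows():
        day = int(rec["day"])
        code = str(rec["category_code"])
        if code not in CATEGORY_VOCABULARY:
            raise CategoryError(f"unknown category code {code!r}")
        if day not in day_set:
            raise CategoryError(f"day {day} outside the series' day range")
        entries[day].add(code)
    for day, codes in entries.items():
        if not codes:
            codes.add(NO_ENTRY)
        elif NO_ENTRY in codes and len(codes) > 1:
            raise CategoryError(
                f"day {day}: {NO_ENTRY!r} cannot co-occur with another code"
            )
    return CategoryTimeline(
        case_id=series.case_id,
        entries={d: frozenset(c) for d, c in entries.items()},
    )
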