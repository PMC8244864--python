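"""Data model, I/O and censoring bookkeeping for nest-monitoring studies.

A nest-monitoring study follows individually marked great-ape nests from the
night of construction until they are no longer recognizable (age class 5).
The response of interest is the nest *age*: the number of whole days between
construction and the day before the nest was found fully decomposed.  Nests
still recognizable when monitoring ends are right-censored; their observed
age is a lower bound on the true decay time.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "NestRecord",
    "NestAge",
    "SurveyWindow",
    "ValidationError",
    "read_nest_table",
    "write_nest_table",
    "read_survey_table",
    "compute_nest_age",
    "compute_ages",
    "censor_summary",
]

NEST_COLUMNS = [
    "nest_id",
    "group_id",
    "construction_date",
    "forest_type",
    "exposure",
    "position",
    "construction",
    "nest_height_m",
    "tree_height_m",
    "lowest_branch_m",
    "tree_species",
    "decay_found_date",
    "censor_date",
]

FOREST_TYPES = ("swamp", "terra_firma")
EXPOSURES = ("close", "open")
POSITIONS = ("side_branch", "top")
CONSTRUCTIONS = ("single_tree", "integrated")


class ValidationError(ValueError):
    """A record or table violated a schema invariant."""


@dataclass(frozen=True)
class NestRecord:
    """One monitored nest, from construction to decay or censoring.

    Exactly one of ``decay_found_date`` / ``censor_date`` is present,
    consistent with the ``censored`` flag.  ``lowest_branch_m`` is optional:
    it is recorded in the field but never enters the model.
    """

    nest_id: str
    group_id: str
    construction_date: dt.date
    forest_type: str
    exposure: str
    position: str
    construction: str
    nest_height_m: float
    tree_height_m: float
    tree_species: str
    lowest_branch_m: float | None = None
    decay_found_date: dt.date | None = None
    censor_date: dt.date | None = None
    censored: bool = False

    def validate(self, row: object = None) -> "NestRecord":
        where = "" if row is None else f" (row {row})"
        if self.forest_type not in FOREST_TYPES:
            raise ValidationError(f"unknown forest_type {self.forest_type!r}{where}")
        if self.exposure not in EXPOSURES:
            raise ValidationError(f"unknown exposure {self.exposure!r}{where}")
        if self.position not in POSITIONS:
            raise ValidationError(f"unknown position {self.position!r}{where}")
        if self.construction not in CONSTRUCTIONS:
            raise ValidationError(f"unknown construction {self.construction!r}{where}")
        if self.decay_found_date is not None and self.censor_date is not None:
            raise ValidationError(f"ambiguous outcome for nest {self.nest_id}{where}: "
                                  "both decay_found_date and censor_date set")
        if self.decay_found_date is None and self.censor_date is None:
            raise ValidationError(f"nest {self.nest_id}{where} has no outcome date")
        if self.censored != (self.censor_date is not None):
            raise ValidationError(f"censored flag inconsistent with dates for nest "
                                  f"{self.nest_id}{where}")
        if self.decay_found_date is not None and \
                self.decay_found_date <= self.construction_date:
            raise ValidationError(f"decay_found_date <= construction_date for nest "
                                  f"{self.nest_id}{where}")
        if self.censor_date is not None and self.censor_date <= self.construction_date:
            raise ValidationError(f"censor_date <= construction_date for nest "
                                  f"{self.nest_id}{where}")
        if not (self.nest_height_m > 0 and self.tree_height_m > 0):
            raise ValidationError(f"non-positive height for nest {self.nest_id}{where}")
        if self.nest_height_m > self.tree_height_m:
            raise ValidationError(f"nest_height > tree_height for nest "
                                  f"{self.nest_id}{where}")
        return self


@dataclass(frozen=True)
class NestAge:
    """Observed nest age in whole days (>= 1); censored means the true decay
    age exceeds the observed age."""

    nest_id: str
    age_days: int
    censored: bool

    def __post_init__(self) -> None:
        if self.age_days < 1:
            raise ValidationError(f"nest {self.nest_id}: age {self.age_days} < 1 day")


@dataclass(frozen=True)
class SurveyWindow:
    """A labelled monitoring window (e.g. S1..S5, P1, P2)."""

    label: str
    start_date: dt.date
    end_date: dt.date

    def __post_init__(self) -> None:
        if self.end_date <= self.start_date:
            raise ValidationError(f"window {self.label}: end_date <= start_date")

    def contains(self, d: dt.date) -> bool:
        return self.start_date <= d <= self.end_date


def _parse_date(value: object, column: str, row: int) -> dt.date | None:
    if value is None or value == "" or pd.isna(value):
        return None
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise ValidationError(f"row {row}: unparsable date {value!r} "
                              f"in column {column}") from exc


def _parse_float(value: object, column: str, row: int) -> float | None:
    if value is None or value == "" or pd.isna(value):
        return None
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"row {row}: unparsable number {value!r} "
                              f"in column {column}") from exc


def read_nest_table(path, schema: dict[str, str] | None = None) -> list[NestRecord]:
    """Read a delimited nest table into validated :class:`NestRecord` objects.

    Parameters
    ----------
    path : file path
        CSV file with a header row; dates ISO-8601.
    schema : optional mapping
        Maps canonical column names (``NEST_COLUMNS``) to the names actually
        used in the file.

    Row numbers (1-based, excluding the header) are preserved in error
    messages.
    """
    df = pd.read_csv(path, dtype=str)
    colmap = {c: c for c in NEST_COLUMNS}
    if schema:
        colmap.update(schema)
    required = [c for c in NEST_COLUMNS if c not in ("lowest_branch_m", "censor_date",
                                                     "decay_found_date")]
    for canon in required:
        if colmap[canon] not in df.columns:
            raise ValidationError(f"missing required column {colmap[canon]!r}")
    records: list[NestRecord] = []
    for i, raw in enumerate(df.to_dict("records"), start=1):
        def get(canon: str) -> object:
            return raw.get(colmap[canon])

        rec = NestRecord(
            nest_id=str(get("nest_id")),
            group_id=str(get("group_id")),
            construction_date=_parse_date(get("construction_date"),
                                          "construction_date", i),
            forest_type=str(get("forest_type")).strip(),
            exposure=str(get("exposure")).strip(),
            position=str(get("position")).strip(),
            construction=str(get("construction")).strip(),
            nest_height_m=_parse_float(get("nest_height_m"), "nest_height_m", i),
            tree_height_m=_parse_float(get("tree_height_m"), "tree_height_m", i),
            lowest_branch_m=_parse_float(get("lowest_branch_m"),
                                         "lowest_branch_m", i),
            tree_species=str(get("tree_species")).strip(),
            decay_found_date=_parse_date(get("decay_found_date"),
                                         "decay_found_date", i),
            censor_date=_parse_date(get("censor_date"), "censor_date", i),
            censored=_parse_date(get("censor_date"), "censor_date", i) is not None,
        )
        if rec.construction_date is None:
            raise ValidationError(f"row {i}: missing construction_date")
        rec.validate(row=i)
        records.append(rec)
    return records


def write_nest_table(records: Iterable[NestRecord], path) -> None:
    """Write records to CSV in the canonical schema (round-trips with
    :func:`read_nest_table`)."""
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d.pop("censored")
        for key in ("construction_date", "decay_found_date", "censor_date"):
            d[key] = "" if d[key] is None else d[key].isoformat()
        rows.append({c: d[c] for c in NEST_COLUMNS})
    pd.DataFrame(rows, columns=NEST_COLUMNS).to_csv(path, index=False)


def read_survey_table(path) -> list[SurveyWindow]:
    """Read ``label,start_date,end_date`` survey windows."""
    df = pd.read_csv(path, dtype=str)
    for col in ("label", "start_date", "end_date"):
        if col not in df.columns:
            raise ValidationError(f"missing required column {col!r}")
    return [
        SurveyWindow(label=str(r["label"]),
                     start_date=_parse_date(r["start_date"], "start_date", i),
                     end_date=_parse_date(r["end_date"], "end_date", i))
        for i, r in enumerate(df.to_dict("records"), start=1)
    ]


def compute_nest_age(record: NestRecord) -> NestAge:
    """Observed age of one nest.

    Decayed nests: days between construction and the day *before* the nest
    was found fully decomposed, i.e. ``(found - construction) - 1``.
    Censored nests: ``censor_date - construction_date``, flagged censored.
    """
    if record.censored:
        age = (record.censor_date - record.construction_date).days
    else:
        age = (record.decay_found_date - record.construction_date).days - 1
    if age < 1:
        raise ValidationError(f"nest {record.nest_id}: degenerate age {age} < 1 day")
    return NestAge(nest_id=record.nest_id, age_days=age, censored=record.censored)


def compute_ages(records: Iterable[NestRecord]) -> pd.DataFrame:
    """Vector form of :func:`compute_nest_age`: one row per nest with
    ``nest_id, group_id, age_days, censored`` plus ``mark_offset_days``,
    the days between this nest's marking (construction) and the study's
    first marking -- the revisit-scenario builders need the marking spread.
    """
    rows = []
    for r in records:
        a = compute_nest_age(r)
        rows.append({"nest_id": a.nest_id, "group_id": r.group_id,
                     "construction_date": r.construction_date,
                     "age_days": a.age_days, "censored": a.censored})
    df = pd.DataFrame(rows)
    if not df.empty:
        first = df["construction_date"].min()
        df["mark_offset_days"] = [(d - first).days
                                  for d in df["construction_date"]]
        df = df.drop(columns=["construction_date"])
    return df


def censor_summary(records: Sequence[NestRecord],
                   windows: Sequence[SurveyWindow] | None = None) -> pd.DataFrame:
    """Per-window censoring bookkeeping.

    Returns one row per window with ``label, n_groups, n_nests, n_censored,
    pct_censored`` (percentage rounded to one decimal), plus a ``Total`` row.
    Nests whose construction date falls outside every window are collected in
    an ``unassigned`` bucket and a warning is issued.
    """
    import warnings

    records = list(records)
    if windows is None:
        windows = []
    buckets: dict[str, list[NestRecord]] = {w.label: [] for w in windows}
    unassigned: list[NestRecord] = []
    for r in records:
        hits = [w.label for w in windows if w.contains(r.construction_date)]
        if windows and not hits:
            unassigned.append(r)
        for lab in hits:
            buckets[lab].append(r)
    if unassigned:
        warnings.warn(f"{len(unassigned)} nests fall outside all survey windows",
                      stacklevel=2)
        buckets["unassigned"] = unassigned

    def row(label: str, recs: list[NestRecord]) -> dict:
        n = len(recs)
        n_cens = sum(r.censored for r in recs)
        pct = round(100.0 * n_cens / n, 1) if n else 0.0
        return {"label": label, "n_groups": len({r.group_id for r in recs}),
                "n_nests": n, "n_censored": n_cens, "pct_censored": pct}

    rows = [row(lab, recs) for lab, recs in buckets.items()]
    rows.append(row("Total", records))
    return pd.DataFrame(rows)
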