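"""Photo-scored occurrence records: parsing, validation, filtering, summaries.

One record is one scored plant datapoint: where and when a plant was
photographed, whether any flower showed an exserted style/stigma
(``present`` / ``possible`` / ``absent`` / ``unscorable``), how many flowers
were clearly visible and how many of those were style-exserted, whether
fruit was visible, and — for the two gynodioecious species — the plant's sex.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

SPECIES_CODES = ("inflata", "cardinalis", "kalmii", "siphilitica", "spicata")
GYNODIOECIOUS_SPECIES = ("siphilitica", "spicata")
EXSERTION_SCORES = ("present", "possible", "absent", "unscorable")
FRUIT_STATES = ("yes", "no", "unscorable")
SEXES = ("hermaphrodite", "female", "unknown")

#: canonical column order for the CSV interchange format
CSV_COLUMNS = (
    "record_id", "source_observation_id", "species", "latitude", "longitude",
    "gps_accuracy", "observation_date", "exsertion_score",
    "n_visible_flowers", "n_exserted_flowers", "flowers_present",
    "fruit_present", "sex", "elevation",
)


class RecordError(ValueError):
    """A record or partition violates a structural invariant."""


@dataclass(slots=True)
class OccurrenceRecord:
    """One photo-scored plant observation.

    ``n_exserted_flowers`` may be ``None`` for a ``present`` record whose
    exact exserted count was not recorded; such records enter the binary
    (presence/absence) dataset but not the count dataset.
    """

    record_id: str
    source_observation_id: str
    species: str
    latitude: Optional[float]
    longitude: Optional[float]
    observation_date: _dt.date
    exsertion_score: str
    n_visible_flowers: int
    n_exserted_flowers: Optional[int]
    flowers_present: bool = True
    fruit_present: str = "no"
    sex: str = "hermaphrodite"
    gps_accuracy: Optional[float] = None
    elevation: Optional[float] = None

    def validation_errors(self) -> list[str]:
        """Return all invariant violations (empty list when valid)."""
        errors: list[str] = []
        if self.species not in SPECIES_CODES:
            errors.append(f"unknown species code {self.species!r}")
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            errors.append(f"latitude {self.latitude} out of range [-90, 90]")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            errors.append(f"longitude {self.longitude} out of range [-180, 180]")
        if (self.latitude is None) != (self.longitude is None):
            errors.append("latitude and longitude must both be present or both missing")
        if self.exsertion_score not in EXSERTION_SCORES:
            errors.append(f"unknown exsertion score {self.exsertion_score!r}")
        if self.fruit_present not in FRUIT_STATES:
            errors.append(f"unknown fruit state {self.fruit_present!r}")
        if self.sex not in SEXES:
            errors.append(f"unknown sex {self.sex!r}")
        if self.n_visible_flowers < 0:
            errors.append("negative n_visible_flowers")
        if self.n_exserted_flowers is not None:
            if self.n_exserted_flowers < 0:
                errors.append("negative n_exserted_flowers")
            elif self.n_exserted_flowers > self.n_visible_flowers:
                errors.append(
                    f"n_exserted_flowers {self.n_exserted_flowers} exceeds "
                    f"n_visible_flowers {self.n_visible_flowers}"
                )
            if self.exsertion_score in EXSERTION_SCORES:
                if self.exsertion_score == "present" and self.n_exserted_flowers == 0:
                    errors.append("score 'present' but n_exserted_flowers is 0")
                if self.exsertion_score != "present" and self.n_exserted_flowers >= 1:
                    errors.append(
                        f"score {self.exsertion_score!r} but n_exserted_flowers >= 1"
                    )
        if self.exsertion_score == "unscorable" and self.n_visible_flowers != 0:
            errors.append("score 'unscorable' requires n_visible_flowers = 0")
        return errors


@dataclass(slots=True)
class ParseDiagnostic:
    """A row-level parse or validation problem; the row was excluded."""

    row: int  # 1-based data-row number (header not counted)
    field: str
    message: str


# filter rules in cascade order; each record is charged to its FIRST failure
FILTER_RULES = (
    "missing_coordinates",
    "non_hermaphrodite",
    "score_possible",
    "score_unscorable",
    "fruit_unscorable",
    "no_visible_flowers",
    "missing_elevation",
    "score_not_present",  # count model only
)


@dataclass(slots=True)
class FilterReport:
    """Audit trail for one pass of the inclusion cascade."""

    n_input: int
    removals: dict[str, int] = field(default_factory=dict)
    n_retained: int = 0

    @property
    def n_removed(self) -> int:
        return sum(self.removals.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("n_input", self.n_input)]
        rows += [(rule, self.removals.get(rule, 0)) for rule in FILTER_RULES]
        rows.append(("n_retained", self.n_retained))
        return pd.DataFrame(rows, columns=["rule", "count"])


def _parse_float(value: str) -> Optional[float]:
    value = value.strip()
    return float(value) if value else None


def _parse_int(value: str) -> Optional[int]:
    value = value.strip()
    if not value:
        return None
    as_float = float(value)
    if as_float != int(as_float):
        raise ValueError(f"not an integer: {value!r}")
    return int(as_float)


def _parse_bool(value: str) -> bool:
    lowered = value.strip().lower()
    if lowered in ("true", "t", "1", "yes", "y"):
        return True
    if lowered in ("false", "f", "0", "no", "n"):
        return False
    raise ValueError(f"not a boolean: {value!r}")


def parse_records(
    path,
    schema_options: Optional[dict[str, str]] = None,
) -> tuple[list[OccurrenceRecord], list[ParseDiagnostic]]:
    """Read occurrence records from a CSV file.

    Parameters
    ----------
    path
        CSV file with a header row. Dates must be ISO-8601 (YYYY-MM-DD).
    schema_options
        Optional mapping from canonical column names (see ``CSV_COLUMNS``)
        to the names used in the file.

    Returns
    -------
    (records, diagnostics)
        Valid rows as :class:`OccurrenceRecord`; every rejected row yields a
        :class:`ParseDiagnostic` naming the offending field — no silent drops.
    """
    mapping = {c: c for c in CSV_COLUMNS}
    if schema_options:
        mapping.update(schema_options)
    try:
        table = pd.read_csv(path, dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise RecordError(f"cannot read records file {path}: {exc}") from exc

    required = ("record_id", "species", "observation_date", "exsertion_score",
                "n_visible_flowers")
    missing_cols = [c for c in required if mapping[c] not in table.columns]
    if missing_cols:
        raise RecordError(
            f"records file {path} lacks required columns: "
            + ", ".join(mapping[c] for c in missing_cols)
        )

    def cell(row, name, default=""):
        col = mapping[name]
        return str(row.get(col, default)) if col in table.columns else default

    records: list[OccurrenceRecord] = []
    diagnostics: list[ParseDiagnostic] = []
    for i, (_, row) in enumerate(table.iterrows(), start=1):
        try:
            date_text = cell(row, "observation_date").strip()
            try:
                obs_date = _dt.date.fromisoformat(date_text)
            except ValueError as exc:
                raise _FieldError("observation_date", f"bad date {date_text!r}") from exc
            rec = OccurrenceRecord(
                record_id=cell(row, "record_id").strip(),
                source_observation_id=cell(row, "source_observation_id").strip(),
                species=cell(row, "species").strip(),
                latitude=_field(row, cell, "latitude", _parse_float),
                longitude=_field(row, cell, "longitude", _parse_float),
                gps_accuracy=_field(row, cell, "gps_accuracy", _parse_float),
                observation_date=obs_date,
                exsertion_score=cell(row, "exsertion_score").strip(),
                n_visible_flowers=_field(row, cell, "n_visible_flowers", _parse_int) or 0,
                n_exserted_flowers=_field(row, cell, "n_exserted_flowers", _parse_int),
                flowers_present=(
                    _parse_bool(cell(row, "flowers_present"))
                    if cell(row, "flowers_present").strip() else True
                ),
                fruit_present=cell(row, "fruit_present").strip() or "no",
                sex=cell(row, "sex").strip() or "hermaphrodite",
                elevation=_field(row, cell, "elevation", _parse_float),
            )
        except _FieldError as exc:
            diagnostics.append(ParseDiagnostic(i, exc.field, exc.message))
            continue
        problems = rec.validation_errors()
        if problems:
            diagnostics.append(ParseDiagnostic(i, "record", "; ".join(problems)))
            continue
        records.append(rec)
    return records, diagnostics


class _FieldError(ValueError):
    def __init__(self, field_name: str, message: str):
        super().__init__(message)
        self.field = field_name
        self.message = message


def _field(row, cell, name, parser):
    try:
        return parser(cell(row, name))
    except ValueError as exc:
        raise _FieldError(name, str(exc)) from exc


def write_records(records: Iterable[OccurrenceRecord], path) -> None:
    """Write records in the canonical CSV dialect (round-trips losslessly)."""

    def fmt(value):
        if value is None:
            return ""
        if isinstance(value, bool):
            return "true" if value else "false"
        if isinstance(value, float):
            return repr(value)
        return str(value)

    rows = [
        {col: fmt(getattr(r, col)) for col in CSV_COLUMNS}
        for r in records
    ]
    pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(path, index=False)


def apply_filters(
    records: Sequence[OccurrenceRecord],
    which_model: str = "binary",
    require_elevation: bool = False,
) -> tuple[list[OccurrenceRecord], FilterReport]:
    """Run the inclusion cascade and report per-rule removals.

    Rules are applied in a fixed order (coordinates, sex, exsertion score,
    fruit scorability, visible flowers, elevation, and — for the count
    model — presence) and each removed record is charged to the first rule
    it fails, so the report's arithmetic closes exactly.

    The sex rule removes female and unknown-sex records of the gynodioecious
    species (*L. siphilitica*, *L. spicata*): female plants always show
    exserted styles, so they carry no information about hermaphrodite
    outcrossing capability.
    """
    if which_model not in ("binary", "count"):
        raise ValueError(f"which_model must be 'binary' or 'count', got {which_model!r}")
    report = FilterReport(n_input=len(records))
    retained: list[OccurrenceRecord] = []
    for rec in records:
        rule = _first_failing_rule(rec, which_model, require_elevation)
        if rule is None:
            retained.append(rec)
        else:
            report.removals[rule] = report.removals.get(rule, 0) + 1
    report.n_retained = len(retained)
    return retained, report


def _first_failing_rule(
    rec: OccurrenceRecord, which_model: str, require_elevation: bool
) -> Optional[str]:
    if rec.latitude is None or rec.longitude is None:
        return "missing_coordinates"
    if rec.species in GYNODIOECIOUS_SPECIES and rec.sex != "hermaphrodite":
        return "non_hermaphrodite"
    if rec.exsertion_score == "possible":
        return "score_possible"
    if rec.exsertion_score == "unscorable":
        return "score_unscorable"
    if rec.fruit_present == "unscorable":
        return "fruit_unscorable"
    if rec.n_visible_flowers == 0:
        return "no_visible_flowers"
    if require_elevation and rec.elevation is None:
        return "missing_elevation"
    if which_model == "count" and (
        rec.exsertion_score != "present" or rec.n_exserted_flowers is None
    ):
        return "score_not_present"
    return None


def split_multiplant(
    record: OccurrenceRecord,
    plant_partitions: Sequence[tuple[int, int]],
) -> list[OccurrenceRecord]:
    """Split one observation of several distinct plants into per-plant records.

    ``plant_partitions`` gives ``(n_visible, n_exserted)`` for each plant.
    All derived records share the parent's coordinates, date, and source
    observation id, and get distinct record ids.
    """
    if not plant_partitions:
        raise RecordError("plant_partitions must be non-empty")
    out: list[OccurrenceRecord] = []
    for i, (n_visible, n_exserted) in enumerate(plant_partitions, start=1):
        if n_visible < 0 or n_exserted < 0:
            raise RecordError(f"negative count in partition {i}")
        if n_exserted > n_visible:
            raise RecordError(
                f"partition {i}: n_exserted {n_exserted} exceeds n_visible {n_visible}"
            )
        if n_visible == 0:
            score = "unscorable"
        elif n_exserted >= 1:
            score = "present"
        else:
            score = "absent"
        out.append(OccurrenceRecord(
            record_id=f"{record.record_id}-p{i}",
            source_observation_id=record.source_observation_id,
            species=record.species,
            latitude=record.latitude,
            longitude=record.longitude,
            gps_accuracy=record.gps_accuracy,
            observation_date=record.observation_date,
            exsertion_score=score,
            n_visible_flowers=n_visible,
            n_exserted_flowers=n_exserted,
            flowers_present=record.flowers_present,
            fruit_present=record.fruit_present,
            sex=record.sex,
            elevation=record.elevation,
        ))
    return out


def summarize_by_species(records: Sequence[OccurrenceRecord]) -> pd.DataFrame:
    """Per-species raw score counts with presence fractions and mean counts.

    ``fraction_present`` is present / (present + absent): the ``possible``
    and ``unscorable`` categories are excluded from the denominator because
    they carry no confident presence/absence call. ``mean_exserted_count``
    averages ``n_exserted_flowers`` over ``present`` records with a recorded
    count. Species with no confident calls get a missing fraction.
    """
    rows = []
    present_by_species = [r for r in records]
    for sp in SPECIES_CODES:
        recs = [r for r in present_by_species if r.species == sp]
        if not recs:
            continue
        n = {score: sum(1 for r in recs if r.exsertion_score == score)
             for score in EXSERTION_SCORES}
        denom = n["present"] + n["absent"]
        fraction = n["present"] / denom if denom else float("nan")
        exserted = [r.n_exserted_flowers for r in recs
                    if r.exsertion_score == "present"
                    and r.n_exserted_flowers is not None]
        mean_count = sum(exserted) / len(exserted) if exserted else float("nan")
        rows.append({
            "species": sp,
            "count_present": n["present"],
            "count_possible": n["possible"],
            "count_absent": n["absent"],
            "count_unscorable": n["unscorable"],
            "fraction_present": fraction,
            "mean_exserted_count": mean_count,
        })
    return pd.DataFrame(rows).set_index("species")


def obstructed_fraction(records: Sequence[OccurrenceRecord]) -> pd.Series:
    """Per-species fraction of datapoints whose flowers were all obstructed.

    These are the ``unscorable`` records: flowers were present in the image
    but none was clearly visible, so exsertion could not be assessed.
    """
    out = {}
    for sp in SPECIES_CODES:
        recs = [r for r in records if r.species == sp]
        if not recs:
            continue
        out[sp] = sum(1 for r in recs if r.exsertion_score == "unscorable") / len(recs)
    return pd.Series(out, name="obstructed_fraction", dtype=float)
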