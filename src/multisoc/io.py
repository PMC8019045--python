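"""Data model and validated CSV readers/writers for focal-scan pipelines.

All tabular inputs are plain comma-separated UTF-8 files with a header row,
ISO-8601 dates (``YYYY-MM-DD``), 24 h times, and ``YYYY-MM`` year-months.
Associate lists live in one cell, semicolon-separated. Unit identifiers are
case-sensitive opaque strings.

Readers validate every row. In strict mode an invalid row raises
:class:`RecordError`; in lenient mode it is logged and skipped.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

log = logging.getLogger("multisoc")

PLANT_PARTS = frozenset(
    {
        "young_leaf",
        "mature_leaf",
        "ripe_fruit",
        "unripe_fruit",
        "ripe_pod",
        "unripe_pod",
        "bud",
        "flower",
    }
)

#: Observation day runs 07:00-16:00 (scans every 2 h on the focal unit).
DAY_START = dt.time(7, 0)
DAY_END = dt.time(16, 0)


class RecordError(ValueError):
    """A row violates a domain-type invariant."""


@dataclass(frozen=True, order=True)
class ScanRecord:
    """One instantaneous scan: the focal unit plus every unit within the
    association radius (50 m in the design this emulates)."""

    date: dt.date
    time: dt.time
    focal_unit: str
    associates: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "associates", frozenset(self.associates))

    def validate(self, strict: bool = True) -> None:
        if not self.focal_unit:
            raise RecordError("empty focal unit identifier")
        if any(not a for a in self.associates):
            raise RecordError("empty associate identifier")
        if self.focal_unit in self.associates:
            raise RecordError(
                f"focal unit {self.focal_unit!r} listed among its own associates"
            )
        if strict and not (DAY_START <= self.time <= DAY_END):
            raise RecordError(f"scan time {self.time} outside 07:00-16:00")


@dataclass(frozen=True)
class PhenologyRecord:
    tree_id: str
    species: str
    month: str  # YYYY-MM
    plant_part: str
    score: int

    def validate(self, strict: bool = True) -> None:
        if self.plant_part not in PLANT_PARTS:
            raise RecordError(f"unknown plant part {self.plant_part!r}")
        if self.score not in (0, 1, 2, 3, 4):
            raise RecordError(f"phenology score {self.score} outside 0-4")
        if not self.tree_id or not self.species:
            raise RecordError("empty tree or species identifier")


@dataclass(frozen=True)
class SpeciesBasalArea:
    species: str
    basal_area: float  # m^2, total over surveyed transects

    def validate(self, strict: bool = True) -> None:
        if not self.species:
            raise RecordError("empty species identifier")
        if not self.basal_area > 0:
            raise RecordError(f"basal area must be positive, got {self.basal_area}")


@dataclass(frozen=True)
class RainfallRecord:
    month: str  # YYYY-MM
    rainfall: float  # mm

    def validate(self, strict: bool = True) -> None:
        if self.rainfall < 0:
            raise RecordError(f"negative rainfall {self.rainfall}")


@dataclass(frozen=True)
class DispersalEvent:
    """An individual's transfer between units, dated by a last-seen /
    first-seen range; ``assigned_month`` is filled by the dispersal analysis."""

    individual_id: str
    sex: str  # "male" | "female"
    from_unit: str
    to_unit: str
    last_seen_origin: dt.date
    first_seen_destination: dt.date
    assigned_month: str | None = None

    def validate(self, strict: bool = True) -> None:
        if self.sex not in ("male", "female"):
            raise RecordError(f"sex must be male/female, got {self.sex!r}")
        if self.from_unit == self.to_unit:
            raise RecordError("dispersal origin equals destination")
        if self.last_seen_origin > self.first_seen_destination:
            raise RecordError("dispersal date range inverted")
        if not self.individual_id:
            raise RecordError("empty individual identifier")


@dataclass
class StudyConfig:
    """Analysis-wide knobs; defaults follow the study design this package
    reimplements (31-day windows, AI cut 0.05, 10,000 permutations, 100
    bootstraps)."""

    window_days: int = 31
    shift_days: int = 31
    clan_cutoff: float = 0.05
    n_permutations: int = 10_000
    n_bootstrap: int = 100
    alpha: float = 0.05
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("window_days", "shift_days", "n_permutations", "n_bootstrap"):
            if getattr(self, name) < 1:
                raise RecordError(f"{name} must be >= 1")
        if not 0 < self.clan_cutoff < 1:
            raise RecordError("clan_cutoff must lie in (0, 1)")


# ---------------------------------------------------------------------------
# parsing helpers


def _parse_date(text: str) -> dt.date:
    return dt.date.fromisoformat(text.strip())


def _parse_time(text: str) -> dt.time:
    return dt.time.fromisoformat(text.strip())


def _parse_month(text: str) -> str:
    from ._util import parse_month

    y, m = parse_month(text)
    return f"{y:04d}-{m:02d}"


def _read_rows(path, fieldnames: Sequence[str]):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != list(
            fieldnames
        ):
            raise RecordError(
                f"{path}: expected header {','.join(fieldnames)}, "
                f"got {reader.fieldnames}"
            )
        yield from reader


def _collect(path, fieldnames, build, strict):
    out = []
    for i, row in enumerate(_read_rows(path, fieldnames), start=2):
        try:
            rec = build(row)
            rec.validate(strict=strict)
        except (RecordError, ValueError) as exc:
            if strict:
                raise RecordError(f"{path} line {i}: {exc}") from exc
            log.warning("%s line %d skipped: %s", path, i, exc)
            continue
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# readers

SCAN_FIELDS = ("date", "time", "focal_unit", "associates")
PHENOLOGY_FIELDS = ("tree_id", "species", "month", "plant_part", "score")
BASAL_FIELDS = ("species", "basal_area_m2")
RAINFALL_FIELDS = ("month", "rainfall_mm")
DISPERSAL_FIELDS = (
    "individual_id",
    "sex",
    "from_unit",
    "to_unit",
    "last_seen_origin",
    "first_seen_destination",
)


def read_scans(path, strict: bool = True) -> list[ScanRecord]:
    """Read scan samples; associate cell is semicolon-separated (may be empty).

    Warns when two scans of the same focal unit are less than 2 h apart —
    scan independence is the collector's responsibility, not enforced here.
    """

    def build(row):
        associates = frozenset(
            a.strip() for a in row["associates"].split(";") if a.strip()
        )
        return ScanRecord(
            date=_parse_date(row["date"]),
            time=_parse_time(row["time"]),
            focal_unit=row["focal_unit"].strip(),
            associates=associates,
        )

    scans = _collect(path, SCAN_FIELDS, build, strict)
    by_focal_day: dict[tuple, list[dt.time]] = {}
    for s in scans:
        by_focal_day.setdefault((s.focal_unit, s.date), []).append(s.time)
    for (unit, day), times in by_focal_day.items():
        times.sort()
        for t0, t1 in zip(times, times[1:]):
            delta = dt.datetime.combine(day, t1) - dt.datetime.combine(day, t0)
            if delta < dt.timedelta(hours=2):
                log.warning(
                    "scans of %s on %s only %s apart (< 2 h design interval)",
                    unit,
                    day,
                    delta,
                )
    return scans


def read_phenology(path, strict: bool = True) -> list[PhenologyRecord]:
    def build(row):
        return PhenologyRecord(
            tree_id=row["tree_id"].strip(),
            species=row["species"].strip(),
            month=_parse_month(row["month"]),
            plant_part=row["plant_part"].strip(),
            score=int(row["score"]),
        )

    return _collect(path, PHENOLOGY_FIELDS, build, strict)


def read_basal_areas(path, strict: bool = True) -> list[SpeciesBasalArea]:
    def build(row):
        return SpeciesBasalArea(
            species=row["species"].strip(), basal_area=float(row["basal_area_m2"])
        )

    return _collect(path, BASAL_FIELDS, build, strict)


def read_rainfall(path, strict: bool = True) -> list[RainfallRecord]:
    def build(row):
        return RainfallRecord(
            month=_parse_month(row["month"]), rainfall=float(row["rainfall_mm"])
        )

    return _collect(path, RAINFALL_FIELDS, build, strict)


def read_dispersals(path, strict: bool = True) -> list[DispersalEvent]:
    def build(row):
        return DispersalEvent(
            individual_id=row["individual_id"].strip(),
            sex=row["sex"].strip(),
            from_unit=row["from_unit"].strip(),
            to_unit=row["to_unit"].strip(),
            last_seen_origin=_parse_date(row["last_seen_origin"]),
            first_seen_destination=_parse_date(row["first_seen_destination"]),
        )

    return _collect(path, DISPERSAL_FIELDS, build, strict)


# ---------------------------------------------------------------------------
# writers (round-trip inverses of the readers)


def _write(path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def write_scans(path, scans: Iterable[ScanRecord]) -> None:
    _write(
        path,
        SCAN_FIELDS,
        (
            (
                s.date.isoformat(),
                s.time.isoformat(timespec="minutes"),
                s.focal_unit,
                ";".join(sorted(s.associates)),
            )
            for s in scans
        ),
    )


def write_phenology(path, records: Iterable[PhenologyRecord]) -> None:
    _write(
        path,
        PHENOLOGY_FIELDS,
        ((r.tree_id, r.species, r.month, r.plant_part, r.score) for r in records),
    )


def write_basal_areas(path, records: Iterable[SpeciesBasalArea]) -> None:
    _write(path, BASAL_FIELDS, ((r.species, repr(r.basal_area)) for r in records))


def write_rainfall(path, records: Iterable[RainfallRecord]) -> None:
    _write(path, RAINFALL_FIELDS, ((r.month, repr(r.rainfall)) for r in records))


def write_dispersals(path, events: Iterable[DispersalEvent]) -> None:
    _write(
        path,
        DISPERSAL_FIELDS,
        (
            (
                e.individual_id,
                e.sex,
                e.from_unit,
                e.to_unit,
                e.last_seen_origin.isoformat(),
                e.first_seen_destination.isoformat(),
            )
            for e in events
        ),
    )


# ---------------------------------------------------------------------------
# configuration


def read_config(path) -> StudyConfig:
    """Load a flat key/value YAML file mirroring :class:`StudyConfig`."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(StudyConfig)}
    unknown = set(data) - known
    if unknown:
        raise RecordError(f"unknown config keys: {sorted(unknown)}")
    cfg = StudyConfig(**data)
    cfg.validate()
    return cfg


def write_config(path, cfg: StudyConfig) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)
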