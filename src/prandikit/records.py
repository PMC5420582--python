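"""Domain types, tabular I/O and evaporation-corrected intake for CAFE cohorts.

The capillary feeder (CAFE) assay reads daily food intake of an individually
caged fly as the descent of the meniscus in a calibrated capillary over a
5-hour exposure.  Part of that descent is evaporation, measured in a fly-free
control cage kept in the same humidity-preservation chamber (HPC); the
corrected intake is the raw descent minus the matching control's descent,
floored at zero.

Data live in two long-format CSVs:

* records: ``fly_id,sex,diet,hpc_id,age_day,raw_descent,eggs,alive`` — one row
  per fly per day of life; ``eggs`` is empty for males.
* controls: ``hpc_id,age_day,evaporation`` — one row per chamber per day.

Ages are 1-based (day 1 = first adult day).  A missing day (no row) is
distinct from a zero reading and propagates as absent.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

RECORDS_HEADER = ["fly_id", "sex", "diet", "hpc_id", "age_day", "raw_descent", "eggs", "alive"]
CONTROLS_HEADER = ["hpc_id", "age_day", "evaporation"]
SCHEMA_VERSION = "1"


class Sex(str, enum.Enum):
    F = "F"
    M = "M"


class Diet(str, enum.Enum):
    SUGAR_LIQUID = "sugar"
    PROTEIN_LIQUID = "protein"


class ValidationError(ValueError):
    """A cohort table violates a structural invariant; names offending flies."""


class ParseError(ValueError):
    """A CSV row could not be parsed; names the 1-based line number."""


class MissingControlError(KeyError):
    """No control-capillary reading for a required (hpc_id, age_day)."""


class NegativeIntakeWarning(UserWarning):
    """Raw descent below the control's evaporation: corrected intake clipped to 0."""


@dataclass(frozen=True)
class FeedingRecord:
    """One fly-day observation: capillary reading, eggs laid, vital status."""

    fly_id: str
    sex: Sex
    diet: Diet
    hpc_id: str
    age_day: int
    raw_descent: float
    eggs: int | None = None
    alive: bool = True


@dataclass(frozen=True)
class ControlReading:
    """Meniscus descent of the fly-free control cage's capillary for one day."""

    hpc_id: str
    age_day: int
    evaporation: float


@dataclass
class CohortTable:
    """All feeding records of one cohort plus per-fly death days and controls."""

    records: list[FeedingRecord]
    controls: list[ControlReading]
    death_day: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.death_day:
            self.death_day = {
                fid: max(r.age_day for r in self.records if r.fly_id == fid)
                for fid in {r.fly_id for r in self.records}
            }

    def fly_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.fly_id, None)
        return list(seen)

    def control_map(self) -> dict[tuple[str, int], float]:
        return {(c.hpc_id, c.age_day): c.evaporation for c in self.controls}

    def validate(self) -> None:
        """Raise :class:`ValidationError` listing every offending fly."""
        bad: dict[str, str] = {}
        by_fly: dict[str, list[FeedingRecord]] = {}
        for r in self.records:
            by_fly.setdefault(r.fly_id, []).append(r)
            if r.age_day < 1:
                bad.setdefault(r.fly_id, f"age_day {r.age_day} < 1")
            if r.raw_descent < 0:
                bad.setdefault(r.fly_id, f"raw_descent {r.raw_descent} < 0")
            if r.eggs is not None and r.sex is not Sex.F:
                bad.setdefault(r.fly_id, "eggs recorded for a male fly")
            if r.eggs is not None and r.eggs < 0:
                bad.setdefault(r.fly_id, f"eggs {r.eggs} < 0")
        for fid, recs in by_fly.items():
            if fid not in self.death_day:
                bad.setdefault(fid, "fly missing from death_day map")
                continue
            if len({(r.sex, r.diet, r.hpc_id) for r in recs}) > 1:
                bad.setdefault(fid, "inconsistent sex/diet/hpc across records")
            if any(r.age_day > self.death_day[fid] for r in recs):
                bad.setdefault(fid, "record after recorded death day")
            # once dead, a fly must not reappear alive
            ordered = sorted(recs, key=lambda r: r.age_day)
            died = False
            for r in ordered:
                if died and r.alive:
                    bad.setdefault(fid, "alive record after a dead record")
                died = died or not r.alive
        seen_ctrl: set[tuple[str, int]] = set()
        for c in self.controls:
            if c.evaporation < 0:
                raise ValidationError(f"control ({c.hpc_id}, {c.age_day}): evaporation < 0")
            key = (c.hpc_id, c.age_day)
            if key in seen_ctrl:
                raise ValidationError(f"duplicate control reading for {key}")
            seen_ctrl.add(key)
        if bad:
            detail = "; ".join(f"{fid}: {msg}" for fid, msg in sorted(bad.items()))
            raise ValidationError(f"invalid cohort table — {detail}")


def correct_evaporation(raw_descent: float, control_evaporation: float) -> float:
    """Evaporation-corrected intake: ``max(raw - control, 0)``.

    A :class:`NegativeIntakeWarning` is issued (not raised) when the control
    exceeds the raw reading — measurement noise, clipped to zero because
    intake cannot be negative.
    """
    if raw_descent < 0 or control_evaporation < 0:
        raise ValueError(
            f"readings must be non-negative, got raw={raw_descent}, control={control_evaporation}"
        )
    diff = raw_descent - control_evaporation
    if diff < 0:
        warnings.warn(
            f"raw descent {raw_descent} below control evaporation "
            f"{control_evaporation}; intake clipped to 0",
            NegativeIntakeWarning,
            stacklevel=2,
        )
        return 0.0
    return float(diff)


def intake_series(table: CohortTable, fly_id: str) -> list[tuple[int, float]]:
    """Per-day corrected intake of one fly, matched to its chamber's control.

    Returns ``[(age_day, corrected intake), ...]`` sorted by day, one entry per
    observed day up to the fly's death.  Raises :class:`MissingControlError` if
    a day lacks a control reading for the fly's HPC.
    """
    recs = sorted((r for r in table.records if r.fly_id == fly_id), key=lambda r: r.age_day)
    if not recs:
        raise KeyError(f"unknown fly_id {fly_id!r}")
    controls = table.control_map()
    death = table.death_day[fly_id]
    out: list[tuple[int, float]] = []
    for r in recs:
        if r.age_day > death:
            continue
        key = (r.hpc_id, r.age_day)
        if key not in controls:
            raise MissingControlError(f"no control reading for (hpc_id={key[0]!r}, age_day={key[1]})")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NegativeIntakeWarning)
            out.append((r.age_day, correct_evaporation(r.raw_descent, controls[key])))
    return out


def read_cohort(
    records_path: str | Path,
    controls_path: str | Path,
    schema_version: str = SCHEMA_VERSION,
) -> CohortTable:
    """Read and validate a cohort from its records and controls CSVs."""
    if schema_version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {schema_version!r}")
    rdf = pd.read_csv(records_path, dtype=str, keep_default_na=False)
    if list(rdf.columns) != RECORDS_HEADER:
        raise ParseError(f"{records_path}: header must be {','.join(RECORDS_HEADER)}")
    records: list[FeedingRecord] = []
    for i, row in enumerate(rdf.itertuples(index=False), start=2):
        try:
            eggs = None if row.eggs == "" else int(row.eggs)
            records.append(
                FeedingRecord(
                    fly_id=row.fly_id,
                    sex=Sex(row.sex),
                    diet=Diet(row.diet),
                    hpc_id=row.hpc_id,
                    age_day=int(row.age_day),
                    raw_descent=float(row.raw_descent),
                    eggs=eggs,
                    alive={"True": True, "False": False, "1": True, "0": False}[row.alive],
                )
            )
        except (ValueError, KeyError) as exc:
            raise ParseError(f"{records_path}: line {i}: {exc}") from exc
    cdf = pd.read_csv(controls_path, dtype=str, keep_default_na=False)
    if list(cdf.columns) != CONTROLS_HEADER:
        raise ParseError(f"{controls_path}: header must be {','.join(CONTROLS_HEADER)}")
    controls: list[ControlReading] = []
    for i, row in enumerate(cdf.itertuples(index=False), start=2):
        try:
            controls.append(
                ControlReading(
                    hpc_id=row.hpc_id,
                    age_day=int(row.age_day),
                    evaporation=float(row.evaporation),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{controls_path}: line {i}: {exc}") from exc
    table = CohortTable(records=records, controls=controls)
    table.validate()
    return table


def write_cohort(table: CohortTable, records_path: str | Path, controls_path: str | Path) -> None:
    """Write a cohort's records and controls CSVs (inverse of :func:`read_cohort`)."""
    rdf = pd.DataFrame(
        [
            {
                "fly_id": r.fly_id,
                "sex": r.sex.value,
                "diet": r.diet.value,
                "hpc_id": r.hpc_id,
                "age_day": r.age_day,
                "raw_descent": repr(r.raw_descent),
                "eggs": "" if r.eggs is None else r.eggs,
                "alive": r.alive,
            }
            for r in table.records
        ],
        columns=RECORDS_HEADER,
    )
    rdf.to_csv(records_path, index=False)
    cdf = pd.DataFrame(
        [
            {"hpc_id": c.hpc_id, "age_day": c.age_day, "evaporation": repr(c.evaporation)}
            for c in table.controls
        ],
        columns=CONTROLS_HEADER,
    )
    cdf.to_csv(controls_path, index=False)
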