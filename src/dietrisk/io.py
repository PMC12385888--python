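"""CSV and JSON readers/writers for surveys, FFQ tables and configs.

Formats are plain text throughout:

* residue CSV — ``commodity,analyte,status,value_mg_per_kg,
  lod_mg_per_kg,loq_mg_per_kg`` with status ``detected`` or
  ``non_detected``; the value field must be empty iff non-detected;
* consumption CSV — ``respondent_id,commodity,frequency_category,
  portion_g,gender,age,education,employment,income`` with an empty
  portion for non-consumers;
* frequency-mapping CSV — ``category,events_per_day``.

Validation errors carry 1-based line numbers of the offending rows.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .consumption import ConsumptionRecord
from .residues import ResidueSample

RESIDUE_COLUMNS = [
    "commodity", "analyte", "status",
    "value_mg_per_kg", "lod_mg_per_kg", "loq_mg_per_kg",
]
CONSUMPTION_COLUMNS = [
    "respondent_id", "commodity", "frequency_category", "portion_g",
    "gender", "age", "education", "employment", "income",
]
_DEMOGRAPHIC_COLUMNS = ["gender", "age", "education", "employment", "income"]


class SchemaError(ValueError):
    """A file does not match the expected column schema or row format."""


def _check_header(header: Sequence[str] | None, required: Sequence[str], path) -> None:
    if header is None:
        raise SchemaError(f"{path}: empty file")
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_residue_csv(path: str | Path) -> list[ResidueSample]:
    """Read a residue survey CSV, validating row by row."""
    path = Path(path)
    samples: list[ResidueSample] = []
    errors: list[str] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, RESIDUE_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            try:
                status = row["status"].strip()
                if status not in ("detected", "non_detected"):
                    raise ValueError(f"bad status {status!r}")
                raw = (row["value_mg_per_kg"] or "").strip()
                if status == "detected":
                    if not raw:
                        raise ValueError("detected row without a value")
                    value = float(raw)
                else:
                    if raw:
                        raise ValueError("non_detected row carries a value")
                    value = None
                samples.append(ResidueSample(
                    commodity=row["commodity"].strip(),
                    analyte=row["analyte"].strip(),
                    detected=status == "detected",
                    value=value,
                    lod=float(row["lod_mg_per_kg"]),
                    loq=float(row["loq_mg_per_kg"]),
                ))
            except (ValueError, KeyError) as exc:
                errors.append(f"line {lineno}: {exc}")
    if errors:
        raise SchemaError(f"{path}: " + "; ".join(errors))
    return samples


def write_residue_csv(samples: Iterable[ResidueSample], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(RESIDUE_COLUMNS)
        for s in samples:
            w.writerow([
                s.commodity, s.analyte,
                "detected" if s.detected else "non_detected",
                repr(s.value) if s.detected else "",
                repr(s.lod), repr(s.loq),
            ])


def read_consumption_csv(path: str | Path) -> list[ConsumptionRecord]:
    """Read an FFQ table CSV; intakes are not derived here."""
    path = Path(path)
    records: list[ConsumptionRecord] = []
    errors: list[str] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, CONSUMPTION_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            try:
                raw = (row["portion_g"] or "").strip()
                portion = float(raw) if raw else None
                if portion is not None and portion < 0:
                    raise ValueError("negative portion_g")
                records.append(ConsumptionRecord(
                    respondent_id=row["respondent_id"].strip(),
                    commodity=row["commodity"].strip(),
                    frequency_category=row["frequency_category"].strip(),
                    portion_g=portion,
                    demographics={c: (row.get(c) or "").strip() for c in _DEMOGRAPHIC_COLUMNS},
                ))
            except (ValueError, KeyError) as exc:
                errors.append(f"line {lineno}: {exc}")
    if errors:
        raise SchemaError(f"{path}: " + "; ".join(errors))
    return records


def write_consumption_csv(records: Iterable[ConsumptionRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CONSUMPTION_COLUMNS)
        for r in records:
            w.writerow([
                r.respondent_id, r.commodity, r.frequency_category,
                "" if r.portion_g is None else repr(r.portion_g),
                *[r.demographics.get(c, "") for c in _DEMOGRAPHIC_COLUMNS],
            ])


def read_frequency_map_csv(path: str | Path) -> dict[str, float]:
    """Read a ``category,events_per_day`` mapping table."""
    path = Path(path)
    mapping: dict[str, float] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, ["category", "events_per_day"], path)
        for lineno, row in enumerate(reader, start=2):
            try:
                mapping[row["category"].strip()] = float(row["events_per_day"])
            except (ValueError, KeyError) as exc:
                raise SchemaError(f"{path}: line {lineno}: {exc}") from None
    return mapping


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def config_hash(obj) -> str:
    """Stable short hash of a configuration object, for provenance."""
    payload = json.dumps(_jsonable(obj), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
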