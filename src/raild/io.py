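"""Tabular readers and writers for claims bundles.

Each event stream lives in one comma-separated UTF-8 file with a header
row; dates are ISO-8601 (``YYYY-MM-DD``).  Column names can be remapped
through a schema configuration (a ``{table: {canonical: actual}}``
mapping, loadable from YAML/JSON), so extracts with site-specific headers
can be ingested without rewriting them.

Malformed rows (unparseable dates, unknown enum labels) are collected with
their file and line number; by default any bad row aborts the read
(``max_bad_rows=0``), which can be relaxed for dirty extracts.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .model import (
    AdjudicationOutcome,
    AdjudicationRecord,
    ClaimsBundle,
    CodeSystem,
    DiagnosisEvent,
    DrugClass,
    DrugEvent,
    EnrollmentSpan,
    HospitalStay,
    IncidenceClass,
    ProcedureEvent,
    ProcedureKind,
    Setting,
    Specialty,
)

TABLE_FILES = {
    "diagnoses": "diagnoses.csv",
    "procedures": "procedures.csv",
    "drugs": "drugs.csv",
    "enrollment": "enrollment.csv",
    "stays": "stays.csv",
    "meta": "bundle_meta.json",
}

_COLUMNS = {
    "diagnoses": ["patient_id", "service_date", "code", "code_system", "setting", "position", "specialty"],
    "procedures": ["patient_id", "service_date", "kind", "setting"],
    "drugs": ["patient_id", "service_date", "drug_class", "drug_name"],
    "enrollment": ["patient_id", "start_date", "end_date", "part_a", "part_b", "part_c"],
    "stays": ["patient_id", "admit_date", "discharge_date"],
}


class SchemaError(ValueError):
    """A required column is missing or the schema config is malformed."""


class BadRowsError(ValueError):
    """More malformed rows than the configured tolerance."""

    def __init__(self, issues: list[str]):
        super().__init__("; ".join(issues))
        self.issues = issues


def _parse_date(value: Any) -> dt.date:
    return dt.date.fromisoformat(str(value).strip())


def _parse_bool(value: Any) -> bool:
    s = str(value).strip().lower()
    if s in ("true", "1", "t", "yes", "y"):
        return True
    if s in ("false", "0", "f", "no", "n"):
        return False
    raise ValueError(f"not a boolean: {value!r}")


_PARSERS = {
    "service_date": _parse_date,
    "start_date": _parse_date,
    "end_date": _parse_date,
    "admit_date": _parse_date,
    "discharge_date": _parse_date,
    "code_system": lambda v: CodeSystem(str(v).strip()),
    "setting": lambda v: Setting(str(v).strip()),
    "specialty": lambda v: Specialty(str(v).strip()),
    "kind": lambda v: ProcedureKind(str(v).strip()),
    "drug_class": lambda v: DrugClass(str(v).strip()),
    "position": lambda v: int(v),
    "part_a": _parse_bool,
    "part_b": _parse_bool,
    "part_c": _parse_bool,
    "patient_id": lambda v: str(v).strip(),
    "code": lambda v: str(v).strip(),
    "drug_name": lambda v: str(v).strip(),
}

_TYPES = {
    "diagnoses": DiagnosisEvent,
    "procedures": ProcedureEvent,
    "drugs": DrugEvent,
    "enrollment": EnrollmentSpan,
    "stays": HospitalStay,
}


def _read_table(path: Path, table: str, colmap: Mapping[str, str], issues: list[str]) -> list:
    wanted = _COLUMNS[table]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {colmap.get(c, c): c for c in wanted}
    df = df.rename(columns=rename)
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    cls = _TYPES[table]
    events = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        try:
            kwargs = {c: _PARSERS[c](rec[c]) for c in wanted}
            events.append(cls(**kwargs))
        except (ValueError, KeyError) as exc:
            # +2: header row plus 1-based numbering
            issues.append(f"{path.name}:{i + 2}: {exc}")
    return events


def read_claims_bundle(
    directory: str | Path,
    schema_config: Mapping[str, Mapping[str, str]] | str | Path | None = None,
    max_bad_rows: int = 0,
) -> ClaimsBundle:
    """Read a bundle directory written by :func:`write_claims_bundle`.

    ``schema_config`` maps canonical column names to the actual header names
    per table, e.g. ``{"diagnoses": {"patient_id": "BENE_ID"}}``; it may be a
    dict or a path to a YAML/JSON file.  Rows that fail to parse are reported
    with file and line number; more than ``max_bad_rows`` of them raises
    :class:`BadRowsError`.
    """
    directory = Path(directory)
    if isinstance(schema_config, (str, Path)):
        schema_config = yaml.safe_load(Path(schema_config).read_text())
    schema_config = schema_config or {}

    issues: list[str] = []
    streams: dict[str, list] = {}
    for table in _TYPES:
        path = directory / TABLE_FILES[table]
        if path.exists():
            streams[table] = _read_table(path, table, schema_config.get(table, {}), issues)
        else:
            streams[table] = []
    if len(issues) > max_bad_rows:
        raise BadRowsError(issues)

    meta_path = directory / TABLE_FILES["meta"]
    meta: dict[str, Any] = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    kwargs: dict[str, Any] = {k: tuple(v) for k, v in streams.items()}
    if "data_start" in meta:
        kwargs["data_start"] = _parse_date(meta["data_start"])
    if "data_end" in meta:
        kwargs["data_end"] = _parse_date(meta["data_end"])
    return ClaimsBundle(**kwargs)


def _serialize(value: Any) -> Any:
    if isinstance(value, dt.date):
        return value.isoformat()
    if hasattr(value, "value"):
        return value.value
    return value


def write_claims_bundle(bundle: ClaimsBundle, directory: str | Path) -> list[Path]:
    """Write one CSV per event stream plus a JSON meta file; returns the paths.

    Output is deterministic for a given bundle (events are kept sorted), so
    write → read → write is byte-identical.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for table, cls in _TYPES.items():
        cols = _COLUMNS[table]
        rows = [
            {c: _serialize(getattr(ev, c)) for c in cols}
            for ev in getattr(bundle, table)
        ]
        df = pd.DataFrame(rows, columns=cols)
        path = directory / TABLE_FILES[table]
        df.to_csv(path, index=False, lineterminator="\n")
        written.append(path)
    meta_path = directory / TABLE_FILES["meta"]
    meta_path.write_text(
        json.dumps(
            {"data_start": bundle.data_start.isoformat(), "data_end": bundle.data_end.isoformat()},
            indent=2,
        )
        + "\n"
    )
    written.append(meta_path)
    return written


def read_adjudications(path: str | Path) -> list[AdjudicationRecord]:
    """Read an adjudication table (patient_id, outcome, incidence_class, onset_date)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        rec = dict(zip(df.columns, row))
        onset = rec.get("onset_date", "")
        records.append(
            AdjudicationRecord(
                patient_id=str(rec["patient_id"]).strip(),
                outcome=AdjudicationOutcome(rec["outcome"].strip()),
                incidence_class=IncidenceClass(
                    rec.get("incidence_class", "not_applicable").strip() or "not_applicable"
                ),
                onset_date=_parse_date(onset) if onset else None,
            )
        )
    return records


def write_adjudications(records: list[AdjudicationRecord], path: str | Path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "outcome": r.outcome.value,
            "incidence_class": r.incidence_class.value,
            "onset_date": r.onset_date.isoformat() if r.onset_date else "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["patient_id", "outcome", "incidence_class", "onset_date"]).to_csv(
        path, index=False, lineterminator="\n"
    )
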