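"""Reading and writing the per-sample measurement table.

The canonical on-disk format is a UTF-8, comma-separated CSV with a header
and '.' decimal separator, columns in a fixed order (see :data:`CSV_COLUMNS`).
Missing optional fields (Nugent score, SCI counts) are empty cells — never 0,
since 0 is a legal value for all of them.  Reals are written with 6
significant digits, so write -> read -> write is byte-stable.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Optional, Union

import yaml

from .errors import IntegrityError, ParseError, SchemaError
from .records import AmselGroup, CSTLabel, SmearRecord, StudyTable

log = logging.getLogger("smearshed")

#: Canonical column order of the measurement-table CSV.
CSV_COLUMNS = (
    "subject_id",
    "visit_week",
    "interim",
    "amsel_group",
    "nugent_score",
    "cst",
    "field_count_1",
    "field_count_2",
    "field_count_3",
    "aggregate_area_um2_1",
    "aggregate_area_um2_2",
    "aggregate_area_um2_3",
    "superficial_count",
    "total_cells_scored",
)


def _fmt_real(x: float) -> str:
    return format(float(x), ".6g")


def _parse_int(value: str, row: int, column: str) -> int:
    try:
        return int(value)
    except ValueError as exc:
        raise ParseError(f"row {row}, column '{column}': not an integer: {value!r}") from exc


def _parse_real(value: str, row: int, column: str) -> float:
    try:
        return float(value)
    except ValueError as exc:
        raise ParseError(f"row {row}, column '{column}': not a number: {value!r}") from exc


def _parse_opt_int(value: str, row: int, column: str) -> Optional[int]:
    value = value.strip()
    if value == "":
        return None
    return _parse_int(value, row, column)


def _parse_bool(value: str, row: int, column: str) -> bool:
    v = value.strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no", ""):
        return False
    raise ParseError(f"row {row}, column '{column}': not a boolean: {value!r}")


def _row_to_record(row: dict[str, str], rownum: int) -> SmearRecord:
    try:
        amsel = AmselGroup(row["amsel_group"].strip())
    except ValueError as exc:
        raise ParseError(
            f"row {rownum}, column 'amsel_group': unknown group {row['amsel_group']!r}"
        ) from exc
    try:
        cst = CSTLabel(row["cst"].strip())
    except ValueError as exc:
        raise ParseError(f"row {rownum}, column 'cst': unknown CST {row['cst']!r}") from exc
    return SmearRecord(
        subject_id=row["subject_id"].strip(),
        visit_week=_parse_int(row["visit_week"], rownum, "visit_week"),
        interim=_parse_bool(row.get("interim", ""), rownum, "interim"),
        amsel_group=amsel,
        nugent_score=_parse_opt_int(row["nugent_score"], rownum, "nugent_score"),
        cst=cst,
        field_counts=(
            _parse_int(row["field_count_1"], rownum, "field_count_1"),
            _parse_int(row["field_count_2"], rownum, "field_count_2"),
            _parse_int(row["field_count_3"], rownum, "field_count_3"),
        ),
        aggregate_areas_um2=(
            _parse_real(row["aggregate_area_um2_1"], rownum, "aggregate_area_um2_1"),
            _parse_real(row["aggregate_area_um2_2"], rownum, "aggregate_area_um2_2"),
            _parse_real(row["aggregate_area_um2_3"], rownum, "aggregate_area_um2_3"),
        ),
        superficial_count=_parse_opt_int(row["superficial_count"], rownum, "superficial_count"),
        total_cells_scored=_parse_opt_int(
            row["total_cells_scored"], rownum, "total_cells_scored"
        ),
    )


def read_study_table(path: Union[str, Path], strict: bool = True) -> StudyTable:
    """Read and validate a measurement table.

    Parameters
    ----------
    path
        CSV file with the canonical header (:data:`CSV_COLUMNS`).
    strict
        If True (default) any invariant violation aborts with an error.
        If False, offending rows are dropped and logged with their row
        numbers; only valid rows enter the returned table.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        records: list[SmearRecord] = []
        seen: set[tuple[str, int]] = set()
        for rownum, row in enumerate(reader, start=2):  # 1-based incl. header
            try:
                rec = _row_to_record(row, rownum)
                key = (rec.subject_id, rec.visit_week)
                if key in seen:
                    raise IntegrityError(
                        f"row {rownum}: duplicate (subject_id, visit_week) {key}"
                    )
            except (ParseError, IntegrityError) as exc:
                if strict:
                    raise
                log.warning("dropping row %d: %s", rownum, exc)
                continue
            seen.add(key)
            records.append(rec)
    return StudyTable(records, source=str(path))


def write_study_table(table: StudyTable, path: Union[str, Path]) -> Path:
    """Write a table as canonical CSV; re-reading yields an equal table.

    Integers are written plain, reals with 6 significant digits, missing
    optional values as empty cells.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in table.records:
            writer.writerow(
                [
                    rec.subject_id,
                    rec.visit_week,
                    "true" if rec.interim else "false",
                    rec.amsel_group.value,
                    "" if rec.nugent_score is None else rec.nugent_score,
                    rec.cst.value,
                    rec.field_counts[0],
                    rec.field_counts[1],
                    rec.field_counts[2],
                    _fmt_real(rec.aggregate_areas_um2[0]),
                    _fmt_real(rec.aggregate_areas_um2[1]),
                    _fmt_real(rec.aggregate_areas_um2[2]),
                    "" if rec.superficial_count is None else rec.superficial_count,
                    "" if rec.total_cells_scored is None else rec.total_cells_scored,
                ]
            )
    return path


def load_yaml_config(path: Union[str, Path]) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with Path(path).open("r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return data or {}


def setup_logging(level: str = "INFO", logfile: Union[str, Path, None] = None) -> None:
    """Configure package logging to stderr and optionally a file."""
    logger = logging.getLogger("smearshed")
    logger.setLevel(getattr(logging, level.upper()))
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    stream = logging.StreamHandler()
    stream.setFormatter(fmt)
    logger.addHandler(stream)
    if logfile is not None:
        fileh = logging.FileHandler(logfile)
        fileh.setFormatter(fmt)
        logger.addHandler(fileh)
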