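"""Brood CSV input/output and JSON report helpers.

The brood CSV dialect is comma-separated UTF-8 with a mandatory header and
the columns ``foundress_number,kinship,males,females`` (extra columns are
ignored); kinship takes the levels ``single``, ``sisters``, ``nonsisters``.
Validation errors name the offending line.  ``read_brood_csv`` also accepts
a column mapping so externally archived tables with different headers can be
ingested without editing the file.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np

from .broods import KINSHIP_LEVELS, BroodRecord

__all__ = ["BroodCSVError", "read_brood_csv", "write_brood_csv", "write_json_report"]

REQUIRED_COLUMNS = ("foundress_number", "kinship", "males", "females")


class BroodCSVError(ValueError):
    """A malformed brood CSV; the message names the offending line."""


def read_brood_csv(
    path: Union[str, Path],
    column_map: Optional[Dict[str, str]] = None,
) -> List[BroodRecord]:
    """Read and validate a brood CSV.

    ``column_map`` maps required column names to the names actually present
    in the file (for ingesting external tables).  Raises
    :class:`BroodCSVError` naming the line for missing columns, negative or
    non-integer counts, empty broods, unknown kinship levels, or a
    kinship/foundress-number mismatch.
    """
    path = Path(path)
    mapping = {c: c for c in REQUIRED_COLUMNS}
    if column_map:
        mapping.update(column_map)
    records: List[BroodRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise BroodCSVError(f"{path}: empty file (no header)")
        missing = [c for c in REQUIRED_COLUMNS if mapping[c] not in reader.fieldnames]
        if missing:
            raise BroodCSVError(f"{path}: missing column(s) {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                n = int(row[mapping["foundress_number"]])
                males = int(row[mapping["males"]])
                females = int(row[mapping["females"]])
            except (TypeError, ValueError) as exc:
                raise BroodCSVError(f"{path}, line {lineno}: non-integer count ({exc})") from None
            kinship = (row[mapping["kinship"]] or "").strip().lower()
            if kinship not in KINSHIP_LEVELS:
                raise BroodCSVError(
                    f"{path}, line {lineno}: kinship must be one of {KINSHIP_LEVELS}, "
                    f"got {kinship!r}"
                )
            try:
                records.append(BroodRecord(n, kinship, males, females))
            except ValueError as exc:
                raise BroodCSVError(f"{path}, line {lineno}: {exc}") from None
    return records


def write_brood_csv(records: Sequence[BroodRecord], path: Union[str, Path]) -> None:
    """Write broods in the canonical CSV dialect (round-trips exactly)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(REQUIRED_COLUMNS)
        for r in records:
            writer.writerow([r.foundress_number, r.kinship, r.males, r.females])


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "value") and not isinstance(obj, (int, float, str, bool)):
        return getattr(obj, "value")
    return obj


def write_json_report(
    payload: dict,
    path: Union[str, Path],
    seed: Optional[int] = None,
    config: Optional[dict] = None,
) -> dict:
    """Serialize a versioned report with seed and a config hash embedded.

    Numbers are written at full precision (Python repr via json).  Returns
    the report dict as written.
    """
    from . import __version__

    report = {"schema_version": 1, "package_version": __version__}
    if seed is not None:
        report["seed"] = int(seed)
    if config is not None:
        cfg = _jsonable(config)
        report["config"] = cfg
        digest = hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()
        report["config_sha256"] = digest
    report.update(_jsonable(payload))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=str)
        fh.write("\n")
    return report
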