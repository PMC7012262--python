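"""File I/O: canonical 2x2 CSV tables and JSON result documents."""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Any, Mapping

from .exceptions import RiskBridgeError
from .tables import ContingencyTable2x2

__all__ = ["read_table_csv", "write_results_json", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1"

_HEADER = ["group", "case", "noncase"]
_ROW_LABELS = ("exposed", "unexposed")


def read_table_csv(path: str | Path) -> ContingencyTable2x2:
    """Read a 2x2 table from the canonical CSV layout.

    The file must carry the header ``group,case,noncase`` followed by two
    data rows labelled ``exposed`` and ``unexposed`` (in that order).
    Validation errors report the offending line number.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        rows = list(csv.reader(handle))
    rows = [row for row in rows if row and any(cell.strip() for cell in row)]
    if not rows or [cell.strip().lower() for cell in rows[0]] != _HEADER:
        raise RiskBridgeError(
            f"{path}:1: expected canonical header {','.join(_HEADER)!r}"
        )
    if len(rows) != 3:
        raise RiskBridgeError(f"{path}: expected exactly 2 data rows, found {len(rows) - 1}")
    counts: dict[str, tuple[int, int]] = {}
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != 3:
            raise RiskBridgeError(f"{path}:{lineno}: expected 3 fields, found {len(row)}")
        label = row[0].strip().lower()
        if label != _ROW_LABELS[lineno - 2]:
            raise RiskBridgeError(
                f"{path}:{lineno}: expected group {_ROW_LABELS[lineno - 2]!r}, got {row[0]!r}"
            )
        parsed = []
        for col_name, cell in zip(("case", "noncase"), row[1:]):
            text = cell.strip()
            try:
                value = int(text)
            except ValueError:
                raise RiskBridgeError(
                    f"{path}:{lineno}: {col_name} count {cell!r} is not an integer"
                ) from None
            if value < 0:
                raise RiskBridgeError(
                    f"{path}:{lineno}: {col_name} count {value} is negative"
                )
            parsed.append(value)
        counts[label] = (parsed[0], parsed[1])
    a, b = counts["exposed"]
    c, d = counts["unexposed"]
    return ContingencyTable2x2(a=a, b=b, c=c, d=d)


def write_table_csv(table: ContingencyTable2x2, path: str | Path) -> None:
    """Write a 2x2 table in the canonical CSV layout."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(_HEADER)
        writer.writerow(["exposed", table.a, table.b])
        writer.writerow(["unexposed", table.c, table.d])


def _round2(value: Any) -> Any:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        return value
    # round half up at 2 dp, matching reported-value conventions
    return float(int(value * 100 + (0.5 if value >= 0 else -0.5))) / 100


def results_document(results: Mapping[str, Any]) -> dict[str, Any]:
    """Wrap computed results in the stable JSON document schema.

    Keys keep insertion order; every numeric entry is mirrored at two
    decimals under ``rounded_2dp``.
    """
    return {
        "schema_version": SCHEMA_VERSION,
        "results": dict(results),
        "rounded_2dp": {k: _round2(v) for k, v in results.items()},
    }


def write_results_json(results: Mapping[str, Any], path: str | Path) -> None:
    """Serialise a results mapping to ``path`` in the document schema."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        json.dump(results_document(results), handle, indent=2)
        handle.write("\n")
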