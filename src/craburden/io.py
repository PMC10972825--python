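"""Readers and writers for the GBD-results CSV dialect.

The dialect mirrors results-tool exports: one row per estimate with columns

    measure_name, location_name, sex_name, age_name, cause_name, rei_name,
    metric_name, year, val, upper, lower

UTF-8, comma-separated, quoted strings, mandatory header, floats serialised
at full precision (shortest repr).  Percent metrics are stored on the 0–100
scale in files and as proportions internally; the conversion happens here
and only here.  Malformed rows are collected into an error report carrying
line numbers; a missing column is a schema error.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "SchemaError",
    "RowError",
    "RESULT_COLUMNS",
    "write_results_csv",
    "read_results_csv",
]

RESULT_COLUMNS = ["measure_name", "location_name", "sex_name", "age_name",
                  "cause_name", "rei_name", "metric_name", "year",
                  "val", "upper", "lower"]

_SEXES = {"Male", "Female", "Both"}
_METRICS = {"Number", "Rate", "Percent"}


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class RowError:
    line: int
    message: str


_INTERNAL = {"measure_name": "measure", "location_name": "location",
             "sex_name": "sex", "age_name": "age_group",
             "cause_name": "cause", "rei_name": "risk",
             "metric_name": "metric", "year": "year"}


def write_results_csv(df: pd.DataFrame, path) -> None:
    """Write an internal results table in the dialect.

    Expects internal column names (measure, location, sex, age_group,
    cause, risk, metric, year, val, upper, lower); Percent rows are
    proportions internally and are scaled ×100 on the way out.
    """
    out = pd.DataFrame()
    for file_col, internal in _INTERNAL.items():
        out[file_col] = df[internal] if internal in df.columns else ""
    for c in ("val", "upper", "lower"):
        if c not in df.columns:
            raise SchemaError(f"results table lacks column {c!r}")
        out[c] = df[c].astype(float)
    if "metric" in df.columns:
        pct = (df["metric"] == "Percent").to_numpy()
        for c in ("val", "upper", "lower"):
            out.loc[pct, c] = out.loc[pct, c] * 100.0
    out.to_csv(path, index=False, quoting=csv.QUOTE_NONNUMERIC,
               float_format=None)  # pandas writes shortest repr by default


def read_results_csv(path) -> tuple[pd.DataFrame, list[RowError]]:
    """Read a dialect CSV into an internal table plus a row-error report.

    Returns (table, errors); rows failing validation (unparsable numbers,
    lower > upper, unknown sex/metric) are dropped from the table and
    reported with their 1-based file line numbers.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in RESULT_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing columns {missing} in {path}")
        records, errors = [], []
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = {internal: row[file_col]
                       for file_col, internal in _INTERNAL.items()}
                rec["year"] = int(row["year"])
                for c in ("val", "upper", "lower"):
                    rec[c] = float(row[c])
            except (TypeError, ValueError) as exc:
                errors.append(RowError(lineno, f"unparsable field: {exc}"))
                continue
            if rec["sex"] not in _SEXES:
                errors.append(RowError(lineno, f"unknown sex {rec['sex']!r}"))
                continue
            if rec["metric"] not in _METRICS:
                errors.append(
                    RowError(lineno, f"unknown metric {rec['metric']!r}"))
                continue
            if not rec["lower"] <= rec["val"] <= rec["upper"]:
                errors.append(RowError(
                    lineno, f"interval violation lower={rec['lower']} "
                            f"val={rec['val']} upper={rec['upper']}"))
                continue
            records.append(rec)
    df = pd.DataFrame(records, columns=list(_INTERNAL.values())
                      + ["val", "upper", "lower"])
    if len(df):
        pct = (df["metric"] == "Percent").to_numpy()
        for c in ("val", "upper", "lower"):
            df.loc[pct, c] = df.loc[pct, c] / 100.0
    return df, errors
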