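"""Readers and writers for the headered delimited tables the pipeline uses.

All tables are plain CSV with ISO-8601 dates.  Readers validate the schema
and value constraints up front and raise :class:`SchemaError` with the file,
column and (1-based, header-inclusive) line number of the first offence.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import SchemaError
from .exposures import validate_timelines

DATE_FORMAT = "%Y-%m-%d"

GEOGRAPHY_COLS = ("county", "state", "lat", "lon", "population", "mean_devices")
TIMELINE_COLS = ("state", "ip_date", "sh_date", "ro_date")
SCI_COLS = ("ego", "alter", "sci")
COUNTY_PANEL_CORE = ("county", "state", "date", "devices", "population")
DYAD_PANEL_CORE = (
    "origin", "dest", "o_state", "d_state", "date", "flow", "distance_km", "pair",
)


def _require(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _parse_dates(df: pd.DataFrame, col: str, path, allow_missing: bool = False) -> None:
    raw = df[col]
    parsed = pd.to_datetime(raw, format=DATE_FORMAT, errors="coerce")
    bad = parsed.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise SchemaError(
            f"{path}: column {col!r} line {line}: {raw[bad.idxmax()]!r} "
            f"is not an ISO-8601 date (expected YYYY-MM-DD)"
        )
    if not allow_missing and parsed.isna().any():
        line = int(parsed.isna().idxmax()) + 2
        raise SchemaError(f"{path}: column {col!r} line {line}: missing date")
    df[col] = parsed


def _check_nonnegative(df: pd.DataFrame, col: str, path) -> None:
    bad = df[col] < 0
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise SchemaError(
            f"{path}: column {col!r} line {line}: negative value {df[col][bad.idxmax()]}"
        )


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime(DATE_FORMAT)
    out.to_csv(path, index=False)
    return path


def read_geography(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, GEOGRAPHY_COLS, path)
    for col in ("population", "mean_devices"):
        _check_nonnegative(df, col, path)
    return df


def read_timelines(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, TIMELINE_COLS, path)
    # all three dates optional: a state may adopt nothing within the window
    for col in ("ip_date", "sh_date", "ro_date"):
        _parse_dates(df, col, path, allow_missing=True)
    return validate_timelines(df)


def read_sci(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, SCI_COLS, path)
    _check_nonnegative(df, "sci", path)
    return df


def read_county_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, COUNTY_PANEL_CORE, path)
    _parse_dates(df, "date", path)
    _check_nonnegative(df, "devices", path)
    _check_nonnegative(df, "population", path)
    return df


def read_dyad_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, DYAD_PANEL_CORE, path)
    _parse_dates(df, "date", path)
    _check_nonnegative(df, "flow", path)
    return df


_READERS = {
    "geography": read_geography,
    "timelines": read_timelines,
    "sci": read_sci,
    "county_panel": read_county_panel,
    "dyad_panel": read_dyad_panel,
}


def read_tables(paths: dict) -> dict:
    """Read and validate a keyed set of input tables.

    ``paths`` maps table kinds (geography, timelines, sci, county_panel,
    dyad_panel) to file paths.
    """
    unknown = set(paths) - set(_READERS)
    if unknown:
        raise SchemaError(f"unknown table kinds {sorted(unknown)}")
    return {kind: _READERS[kind](p) for kind, p in paths.items()}
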