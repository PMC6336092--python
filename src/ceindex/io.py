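"""Ingestion of tidy delimited input files (UTF-8, one header row)."""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import SchemaError

INDICATOR_COLUMNS = ["site_id", "service_id", "year", "value"]
FACTOR_COLUMNS = ["site_id", "service_id", "factor_id", "year", "value", "state"]


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_indicators(path) -> pd.DataFrame:
    """Indicator time series: one row per (site, service, year)."""
    df = pd.read_csv(path, dtype={"site_id": str, "service_id": str})
    _require(df, INDICATOR_COLUMNS, path)
    df = df[INDICATOR_COLUMNS].copy()
    df["year"] = df["year"].astype(int)
    df["value"] = pd.to_numeric(df["value"], errors="raise")
    if (df["value"].dropna() < 0).any():
        bad = df[df["value"] < 0].iloc[0]
        raise SchemaError(
            f"{path}: negative indicator value for "
            f"({bad['site_id']}, {bad['service_id']}, {bad['year']})"
        )
    dup = df.duplicated(subset=["site_id", "service_id", "year"])
    if dup.any():
        bad = df[dup].iloc[0]
        raise SchemaError(
            f"{path}: duplicate record for "
            f"({bad['site_id']}, {bad['service_id']}, {bad['year']})"
        )
    return df


def read_factors(path) -> pd.DataFrame:
    """Factor states: one row per (site, service, factor, year)."""
    df = pd.read_csv(
        path,
        dtype={"site_id": str, "service_id": str, "factor_id": str, "state": str},
        keep_default_na=False,
        na_values=[""],
    )
    _require(df, FACTOR_COLUMNS, path)
    df = df[FACTOR_COLUMNS].copy()
    df["year"] = df["year"].astype(int)
    df["value"] = pd.to_numeric(df["value"], errors="raise")
    dup = df.duplicated(subset=["site_id", "service_id", "factor_id", "year"])
    if dup.any():
        bad = df[dup].iloc[0]
        raise SchemaError(
            f"{path}: duplicate factor record for "
            f"({bad['site_id']}, {bad['service_id']}, {bad['factor_id']}, "
            f"{bad['year']})"
        )
    return df


def read_panel_dir(data_dir) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read ``indicators.csv`` and ``factors.csv`` from a data directory.

    A missing factors file yields an empty factor table (all PR defaulted).
    """
    d = Path(data_dir)
    indicators = read_indicators(d / "indicators.csv")
    fpath = d / "factors.csv"
    if fpath.exists():
        factors = read_factors(fpath)
    else:
        factors = pd.DataFrame(columns=FACTOR_COLUMNS)
    return indicators, factors
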