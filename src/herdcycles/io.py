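"""Delimited-text I/O with provenance headers.

All tabular artefacts are CSV with an optional block of ``# key: value``
comment lines up top (seed, config hash, package version); readers skip
comments.  Column schemas:

* series files: ``herd_id, year, abundance, observed`` (observed 0/1)
* covariate files: ``herd_id`` plus the `regression.HERD_COVARIATES` columns
* metrics files: ``herd_id, is_cyclic, period, amplitude, p_value`` plus
  bookkeeping columns
"""

from __future__ import annotations

import pandas as pd

from .cycles import TimeSeries
from .errors import SchemaError
from .imputation import RawHerdSeries
from .regression import HERD_COVARIATES

SERIES_COLUMNS = ["herd_id", "year", "abundance", "observed"]


def write_with_header(df: pd.DataFrame, path, header: dict | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def read_header(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition(":")
            out[key.strip()] = val.strip()
    return out


def _require(df, cols, path):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def read_raw_series(path) -> list[RawHerdSeries]:
    """Read survey series; rows are surveys (or rows with observed=1)."""
    df = pd.read_csv(path, comment="#")
    _require(df, ["herd_id", "year", "abundance"], path)
    if "observed" in df.columns:
        df = df[df["observed"].astype(int) == 1]
    herds = []
    for herd_id, g in df.groupby("herd_id", sort=True):
        g = g.sort_values("year")
        try:
            herds.append(RawHerdSeries(str(herd_id), g["year"].to_numpy(),
                                       g["abundance"].to_numpy()))
        except Exception as exc:
            raise SchemaError(f"{path}: herd {herd_id!r}: {exc}") from exc
    return herds


def write_series(entries, path, header: dict | None = None) -> None:
    """Write RawHerdSeries or (herd_id, TimeSeries) pairs to a series CSV."""
    frames = []
    for entry in entries:
        if isinstance(entry, RawHerdSeries):
            frames.append(pd.DataFrame({
                "herd_id": entry.herd_id, "year": entry.years,
                "abundance": entry.abundance, "observed": 1,
            }))
        else:
            herd_id, ts = entry
            frames.append(pd.DataFrame({
                "herd_id": herd_id, "year": ts.years,
                "abundance": ts.values, "observed": ts.observed.astype(int),
            }))
    write_with_header(pd.concat(frames, ignore_index=True), path, header)


def read_filled_series(path) -> dict:
    """Read an imputed series file into {herd_id: TimeSeries}."""
    df = pd.read_csv(path, comment="#")
    _require(df, SERIES_COLUMNS, path)
    out = {}
    for herd_id, g in df.groupby("herd_id", sort=True):
        g = g.sort_values("year")
        out[str(herd_id)] = TimeSeries(
            years=g["year"].to_numpy(),
            values=g["abundance"].to_numpy(),
            observed=g["observed"].to_numpy().astype(bool),
        )
    return out


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    _require(df, ["herd_id"] + HERD_COVARIATES, path)
    if df["herd_id"].duplicated().any():
        dup = df.loc[df["herd_id"].duplicated(), "herd_id"].iloc[0]
        raise SchemaError(f"{path}: duplicate herd_id {dup!r}")
    modeled = df[HERD_COVARIATES]
    if modeled.isna().any().any():
        col = modeled.columns[modeled.isna().any()][0]
        row = int(modeled[modeled[col].isna()].index[0])
        raise SchemaError(f"{path}: missing value in column {col!r} at row {row}")
    return df
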