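"""Readers, validators and the canonical on-disk dialect for the three input streams.

The pipeline consumes three delimited-text inputs:

* a detection log — one row per antenna read (timestamp, antenna id, tag code);
* a tagging registry — one row per tagged fish with its biology;
* an hourly water-temperature series.

PIT readers cycle at up to 10 energize/receive cycles per second, so a fish
holding position inside an antenna field produces a read every 0.1 s.
:func:`dedupe_detections` thins those bursts to a configurable spacing; bout
boundaries are unaffected because the spacing is far below the bout gap
threshold.

The canonical detection dialect is CSV with header
``timestamp,antenna_id,tag_code`` and ISO-8601 UTC timestamps at millisecond
precision. Vendor layouts are mapped onto it through a :class:`Dialect`.
All timestamps are converted to UTC at this boundary; everything downstream
is timezone-aware UTC.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from driftwatch.errors import IngestError, InvalidParameterError

CANONICAL_COLUMNS = ("timestamp", "antenna_id", "tag_code")

#: strftime pattern of the canonical dialect (UTC, millisecond precision).
CANONICAL_TIME_FORMAT = "%Y-%m-%dT%H:%M:%S.%f"

REGISTRY_COLUMNS = (
    "tag_code",
    "species",
    "sex",
    "total_length_cm",
    "weight_g",
    "age_years",
    "tagging_date",
    "recapture_length_cm",
    "recapture_date",
)

SPECIES = ("asp", "bleak")
SEXES = ("male", "female", "unknown")


@dataclass(frozen=True)
class Dialect:
    """Mapping from a vendor log layout onto the canonical detection dialect.

    ``timezone`` is the zone the log's timestamps are written in; readers
    convert to UTC immediately. ``timestamp_format`` of ``None`` means
    ISO-8601.
    """

    timestamp_col: str = "timestamp"
    antenna_col: str = "antenna_id"
    tag_col: str = "tag_code"
    timestamp_format: str | None = None
    timezone: str = "UTC"
    delimiter: str = ","
    antennas: tuple[int, ...] = (1, 2, 3)


class IngestResult(NamedTuple):
    """Well-formed events plus a row-level reject report."""

    events: pd.DataFrame
    rejects: pd.DataFrame


def _parse_timestamps(raw: pd.Series, dialect: Dialect) -> pd.Series:
    fmt = dialect.timestamp_format
    parsed = pd.to_datetime(raw, format=fmt, errors="coerce", utc=False)
    if parsed.dt.tz is None:
        parsed = parsed.dt.tz_localize(dialect.timezone)
    return parsed.dt.tz_convert("UTC")


def read_detections(
    path: str | Path,
    dialect: Dialect = Dialect(),
    max_reject_frac: float = 0.10,
) -> IngestResult:
    """Read a detection log and return canonical events sorted by (tag, time).

    Malformed rows (unparseable timestamp, empty tag, antenna outside the
    configured set) are collected into ``rejects`` with a reason, never
    silently dropped. The call aborts if more than ``max_reject_frac`` of
    data rows are rejected — a sign the dialect is wrong, not the data.
    """
    path = Path(path)
    if not path.exists():
        raise IngestError(f"detection file not found: {path}")
    raw = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    for col in (dialect.timestamp_col, dialect.antenna_col, dialect.tag_col):
        if col not in raw.columns:
            raise IngestError(f"detection file {path} is missing column {col!r}")
    ts = _parse_timestamps(raw[dialect.timestamp_col], dialect)
    antenna = pd.to_numeric(raw[dialect.antenna_col], errors="coerce")
    tag = raw[dialect.tag_col].str.strip()

    reason = pd.Series("", index=raw.index, dtype=object)
    reason[ts.isna()] = "unparseable timestamp"
    bad_ant = antenna.isna() | ~antenna.isin(dialect.antennas)
    reason[bad_ant & (reason == "")] = "antenna outside configured set"
    reason[(tag == "") & (reason == "")] = "empty tag code"

    bad = reason != ""
    rejects = raw.loc[bad].copy()
    rejects["reason"] = reason[bad]
    if len(raw) and bad.mean() > max_reject_frac:
        raise IngestError(
            f"{bad.sum()}/{len(raw)} rows rejected in {path} "
            f"(> {max_reject_frac:.0%}); check the dialect configuration"
        )
    events = pd.DataFrame(
        {
            "timestamp": ts[~bad],
            "antenna_id": antenna[~bad].astype(int),
            "tag_code": tag[~bad],
        }
    )
    events = events.sort_values(["tag_code", "timestamp"], kind="mergesort")
    return IngestResult(events.reset_index(drop=True), rejects.reset_index(drop=True))


def write_detections(events: pd.DataFrame, path: str | Path) -> None:
    """Write events in the canonical dialect (byte-stable for a given frame)."""
    out = pd.DataFrame(
        {
            "timestamp": events["timestamp"].dt.strftime(CANONICAL_TIME_FORMAT).str[:-3]
            + "Z",
            "antenna_id": events["antenna_id"].astype(int),
            "tag_code": events["tag_code"],
        }
    )
    out.to_csv(path, index=False, lineterminator="\n")


def dedupe_detections(events: pd.DataFrame, min_spacing_s: float = 1.0) -> pd.DataFrame:
    """Thin per-individual detection bursts to at most one read per ``min_spacing_s``.

    Greedy anchored rule: the first read of each individual is kept; any read
    strictly closer than ``min_spacing_s`` to the last *kept* read is dropped.
    Idempotent, order-preserving, applied per tag independently.
    """
    if min_spacing_s < 0:
        raise InvalidParameterError(f"min_spacing_s must be >= 0, got {min_spacing_s}")
    if min_spacing_s == 0 or events.empty:
        return events.copy()
    spacing_ns = int(round(min_spacing_s * 1e9))
    keep = np.zeros(len(events), dtype=bool)
    times = events["timestamp"].to_numpy(dtype="datetime64[ns]").astype(np.int64)
    tags = events["tag_code"].to_numpy()
    order = np.arange(len(events))
    for _, idx in pd.Series(order).groupby(tags, sort=False):
        last = None
        for i in idx.to_numpy():
            t = times[i]
            if last is None or t - last >= spacing_ns:
                keep[i] = True
                last = t
    return events.loc[keep].reset_index(drop=True)


def read_registry(path: str | Path) -> pd.DataFrame:
    """Read the tagging registry; one row per tagged fish.

    Duplicate tag codes and half-present recapture pairs are fatal — the
    registry is the key the whole analysis joins on.
    """
    path = Path(path)
    if not path.exists():
        raise IngestError(f"registry file not found: {path}")
    df = pd.read_csv(path, dtype={"tag_code": str})
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise IngestError(f"registry {path} is missing columns {missing}")
    dup = df["tag_code"][df["tag_code"].duplicated()]
    if len(dup):
        raise IngestError(f"duplicate tag codes in registry: {sorted(set(dup))}")
    bad_sp = set(df["species"]) - set(SPECIES)
    if bad_sp:
        raise IngestError(f"unknown species in registry: {sorted(bad_sp)}")
    df["sex"] = df["sex"].fillna("unknown")
    bad_sex = set(df["sex"]) - set(SEXES)
    if bad_sex:
        raise IngestError(f"unknown sex values in registry: {sorted(bad_sex)}")
    for col in ("total_length_cm", "weight_g", "age_years", "recapture_length_cm"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("tagging_date", "recapture_date"):
        df[col] = pd.to_datetime(df[col], errors="coerce", utc=True)
    half = df["recapture_length_cm"].notna() ^ df["recapture_date"].notna()
    if half.any():
        codes = df.loc[half, "tag_code"].tolist()
        raise IngestError(
            f"recapture length/date must be present together; offending tags: {codes}"
        )
    if (df["total_length_cm"] <= 0).any():
        bad = df.loc[df["total_length_cm"] <= 0, "tag_code"].tolist()
        raise IngestError(f"non-positive total length for tags: {bad}")
    return df.reset_index(drop=True)


def read_temperature(path: str | Path) -> pd.DataFrame:
    """Read the hourly temperature-logger series (UTC timestamps, °C).

    Timestamps must be strictly increasing; gaps are allowed and surface
    downstream when the design matrix is joined.
    """
    path = Path(path)
    if not path.exists():
        raise IngestError(f"temperature file not found: {path}")
    df = pd.read_csv(path)
    for col in ("timestamp", "temp_c"):
        if col not in df.columns:
            raise IngestError(f"temperature file {path} is missing column {col!r}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, errors="raise")
    df["temp_c"] = pd.to_numeric(df["temp_c"], errors="raise")
    if not df["timestamp"].is_monotonic_increasing or df["timestamp"].duplicated().any():
        raise IngestError(f"temperature timestamps in {path} are not strictly increasing")
    return df.reset_index(drop=True)
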