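"""Readers, writers and validation for the tabular pipeline inputs.

All tables are plain CSV with declared headers and are returned as typed
:class:`pandas.DataFrame` objects:

* detections:    ``tag_id,feeder_id,timestamp`` (ISO 8601)
* stations:      ``feeder_id,network_id,x,y`` (projected metres)
* tags:          ``tag_id,species,ringing_site_id,tag_date``
* ringing sites: ``site_id,network_id,x,y``

Detection streams from field RFID loggers contain ghost reads — unknown
tags, unknown feeders, corrupted timestamps.  Those rows are never silently
dropped: every reader returns (or enforces) a conservation identity
``rows_in == rows_kept + rows_rejected`` and detections come with a
:class:`RejectsReport` counting drops per reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from feedernet.errors import ValidationError

SPECIES_LEVELS = ("blue_tit", "great_tit")

DETECTION_COLUMNS = ["tag_id", "feeder_id", "timestamp"]
STATION_COLUMNS = ["feeder_id", "network_id", "x", "y"]
TAG_COLUMNS = ["tag_id", "species", "ringing_site_id", "tag_date"]
SITE_COLUMNS = ["site_id", "network_id", "x", "y"]


@dataclass
class RejectsReport:
    """Per-reason counts of detection rows dropped during ingest."""

    n_in: int = 0
    n_kept: int = 0
    reasons: dict[str, int] = field(default_factory=dict)

    @property
    def n_rejected(self) -> int:
        return sum(self.reasons.values())

    def add(self, reason: str, n: int) -> None:
        if n:
            self.reasons[reason] = self.reasons.get(reason, 0) + int(n)

    def to_dict(self) -> dict:
        return {
            "rows_in": self.n_in,
            "rows_kept": self.n_kept,
            "rows_rejected": self.n_rejected,
            "reasons": dict(self.reasons),
        }


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{what}: missing required column(s) {missing}; found {list(df.columns)}"
        )


def _check_unique(df: pd.DataFrame, col: str, what: str) -> None:
    dup = df[col][df[col].duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"{what}: duplicate {col} value(s): {dup}")


def read_stations(path) -> pd.DataFrame:
    """Read the feeder-station table and enforce its invariants.

    Each feeder belongs to one network; ids are unique, coordinates are
    finite projected metres, and every network has at least two stations
    (a single feeder cannot form a pair).
    """
    df = pd.read_csv(path, dtype={"feeder_id": str, "network_id": str})
    _require_columns(df, STATION_COLUMNS, "stations")
    df = df[STATION_COLUMNS].copy()
    _check_unique(df, "feeder_id", "stations")
    xy = df[["x", "y"]].to_numpy(float)
    if not np.all(np.isfinite(xy)):
        raise ValidationError("stations: non-finite coordinates")
    sizes = df.groupby("network_id").size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        raise ValidationError(f"stations: network(s) with <2 stations: {small}")
    return df


def read_tags(path) -> pd.DataFrame:
    """Read the tag registry (tag id, species, ringing site, tagging date)."""
    df = pd.read_csv(
        path, dtype={"tag_id": str, "species": str, "ringing_site_id": str}
    )
    _require_columns(df, TAG_COLUMNS, "tags")
    df = df[TAG_COLUMNS].copy()
    _check_unique(df, "tag_id", "tags")
    bad = sorted(set(df["species"]) - set(SPECIES_LEVELS))
    if bad:
        raise ValidationError(
            f"tags: unknown species {bad}; expected one of {list(SPECIES_LEVELS)}"
        )
    df["tag_date"] = pd.to_datetime(df["tag_date"], errors="raise").dt.date
    return df


def read_ringing_sites(path, stations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read ringing (bird-catching) site coordinates.

    When ``stations`` is given, checks that every station network has at
    least one ringing site.
    """
    df = pd.read_csv(path, dtype={"site_id": str, "network_id": str})
    _require_columns(df, SITE_COLUMNS, "ringing_sites")
    df = df[SITE_COLUMNS].copy()
    _check_unique(df, "site_id", "ringing_sites")
    if not np.all(np.isfinite(df[["x", "y"]].to_numpy(float))):
        raise ValidationError("ringing_sites: non-finite coordinates")
    if stations is not None:
        missing = sorted(
            set(stations["network_id"]) - set(df["network_id"])
        )
        if missing:
            raise ValidationError(
                f"ringing_sites: network(s) without a ringing site: {missing}"
            )
    return df


def validate_tags_sites(tags: pd.DataFrame, sites: pd.DataFrame) -> None:
    """Check every tag's ringing_site_id resolves to a known site."""
    unknown = sorted(set(tags["ringing_site_id"]) - set(sites["site_id"]))
    if unknown:
        raise ValidationError(f"tags: unresolved ringing_site_id(s): {unknown}")


def parse_timestamps(raw: pd.Series, timezone: str | None = None) -> pd.Series:
    """Parse ISO-8601 timestamps to naive UTC instants (second resolution).

    Timezone-aware inputs are converted to UTC.  Naive inputs are taken to
    be in ``timezone`` (the local study time; default: already UTC).
    Unparseable entries come back as NaT rather than raising, so callers
    can route them to a rejects report.
    """
    ts = pd.to_datetime(raw, errors="coerce", utc=False, format="ISO8601")
    if isinstance(ts.dtype, pd.DatetimeTZDtype):
        ts = ts.dt.tz_convert("UTC").dt.tz_localize(None)
    elif timezone not in (None, "UTC", "utc"):
        ts = ts.dt.tz_localize(timezone, ambiguous="NaT", nonexistent="NaT")
        ts = ts.dt.tz_convert("UTC").dt.tz_localize(None)
    return ts.dt.floor("s")


def read_detections(
    path,
    stations: pd.DataFrame,
    tags: pd.DataFrame,
    timezone: str | None = None,
    study_window: tuple | None = None,
) -> tuple[pd.DataFrame, RejectsReport]:
    """Read a raw detection log, validating against registry tables.

    Rows are rejected (and counted per reason) when the timestamp does not
    parse, the feeder id is not in ``stations``, the tag id is not in
    ``tags``, the instant falls outside ``study_window`` (a pair of
    inclusive bounds, optional), or the exact ``(tag, feeder, timestamp)``
    triple was already seen (loggers can emit duplicate reads within one
    polling cycle).

    Returns the kept detections sorted by ``(tag_id, timestamp)`` together
    with a :class:`RejectsReport`; ``rows_in == rows_kept + rows_rejected``
    always holds.
    """
    df = pd.read_csv(path, dtype={"tag_id": str, "feeder_id": str})
    _require_columns(df, DETECTION_COLUMNS, "detections")
    df = df[DETECTION_COLUMNS].copy()
    report = RejectsReport(n_in=len(df))

    ts = parse_timestamps(df["timestamp"].astype(str), timezone=timezone)
    bad_ts = ts.isna()
    report.add("bad_timestamp", bad_ts.sum())
    df = df.loc[~bad_ts].copy()
    df["timestamp"] = ts[~bad_ts]

    if study_window is not None:
        lo, hi = pd.Timestamp(study_window[0]), pd.Timestamp(study_window[1])
        out = (df["timestamp"] < lo) | (df["timestamp"] > hi)
        report.add("out_of_window", out.sum())
        df = df.loc[~out]

    unknown_feeder = ~df["feeder_id"].isin(set(stations["feeder_id"]))
    report.add("unknown_feeder", unknown_feeder.sum())
    df = df.loc[~unknown_feeder]

    unknown_tag = ~df["tag_id"].isin(set(tags["tag_id"]))
    report.add("unknown_tag", unknown_tag.sum())
    df = df.loc[~unknown_tag]

    dup = df.duplicated(subset=DETECTION_COLUMNS)
    report.add("duplicate_read", dup.sum())
    df = df.loc[~dup]

    df = df.sort_values(["tag_id", "timestamp"], kind="stable").reset_index(drop=True)
    report.n_kept = len(df)
    return df, report


def write_table(df: pd.DataFrame, path) -> None:
    """Write any pipeline table as CSV (round-trips with its reader)."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)
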