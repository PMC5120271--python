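"""Visit bouts and between-feeder connection events.

A *visit bout* is a maximal run of reads of one tag at one feeder with
inter-read gaps below a threshold; it is the unit between which movements
are defined.  A *connection event* is an ordered movement of a tagged bird
between two distinct feeders of one network: each pair of consecutive
bouts of the same tag at distinct feeders is a candidate, and candidates
are discarded (with per-reason counts) when they take longer than the
duration cutoff, straddle a season boundary, or cross networks.  The
cutoff defaults to 48 h — slower transits likely follow indirect routes
and say little about the corridor between the two feeders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from feedernet.seasons import STUDY_CALENDAR, SeasonCalendar

BOUT_COLUMNS = ["tag_id", "feeder_id", "start", "end", "n_reads"]
EVENT_COLUMNS = [
    "tag_id",
    "species",
    "network_id",
    "from_feeder",
    "to_feeder",
    "depart",
    "arrive",
    "duration_h",
    "season",
]


@dataclass
class DiscardReport:
    """Counts of candidate connections discarded per reason."""

    n_candidates: int = 0
    n_kept: int = 0
    reasons: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "candidates": self.n_candidates,
            "kept": self.n_kept,
            "discarded": sum(self.reasons.values()),
            "reasons": dict(self.reasons),
        }


def collapse_bouts(detections: pd.DataFrame, bout_gap_min: float = 5.0) -> pd.DataFrame:
    """Collapse a sorted detection stream into visit bouts.

    A new bout starts whenever the tag changes, the feeder changes, or the
    gap since the previous read exceeds ``bout_gap_min`` minutes.  The sum
    of ``n_reads`` over bouts equals the number of detections.
    """
    if len(detections) == 0:
        return pd.DataFrame(columns=BOUT_COLUMNS)
    df = detections.sort_values(["tag_id", "timestamp"], kind="stable")
    ts = df["timestamp"].to_numpy()
    gap = np.empty(len(df), dtype=bool)
    gap[0] = True
    same_tag = df["tag_id"].to_numpy()[1:] == df["tag_id"].to_numpy()[:-1]
    same_feeder = df["feeder_id"].to_numpy()[1:] == df["feeder_id"].to_numpy()[:-1]
    dt = (ts[1:] - ts[:-1]) / np.timedelta64(1, "m")
    gap[1:] = ~(same_tag & same_feeder & (dt <= bout_gap_min))
    bout_id = np.cumsum(gap)
    bouts = (
        df.assign(_bout=bout_id)
        .groupby("_bout", sort=True)
        .agg(
            tag_id=("tag_id", "first"),
            feeder_id=("feeder_id", "first"),
            start=("timestamp", "min"),
            end=("timestamp", "max"),
            n_reads=("timestamp", "size"),
        )
        .reset_index(drop=True)
    )
    return bouts[BOUT_COLUMNS]


def extract_connections(
    bouts: pd.DataFrame,
    stations: pd.DataFrame,
    tags: pd.DataFrame,
    calendar: SeasonCalendar = STUDY_CALENDAR,
    max_duration_h: float = 48.0,
) -> tuple[pd.DataFrame, DiscardReport]:
    """Extract connection events from consecutive bout pairs.

    For each tag, every ordered pair of *consecutive* bouts at distinct
    feeders yields a candidate event (``depart`` = end of the first bout,
    ``arrive`` = start of the second); a bird chaining F1→F2→F3 therefore
    produces F1→F2 and F2→F3 but never F1→F3.  Candidates are discarded
    and counted when the transit exceeds ``max_duration_h`` (``too_slow``),
    the feeders are in different networks (``cross_network``), or the
    departure and arrival fall in different seasons (``cross_season``).
    The event's season is that of the arrival instant.
    """
    report = DiscardReport()
    if len(bouts) == 0:
        return pd.DataFrame(columns=EVENT_COLUMNS), report

    b = bouts.sort_values(["tag_id", "start"], kind="stable").reset_index(drop=True)
    same_tag = b["tag_id"].to_numpy()[1:] == b["tag_id"].to_numpy()[:-1]
    first = b.iloc[:-1].reset_index(drop=True)
    second = b.iloc[1:].reset_index(drop=True)
    cand = pd.DataFrame(
        {
            "tag_id": first["tag_id"],
            "from_feeder": first["feeder_id"],
            "to_feeder": second["feeder_id"],
            "depart": first["end"],
            "arrive": second["start"],
        }
    )[same_tag & (first["feeder_id"].to_numpy() != second["feeder_id"].to_numpy())].copy()
    report.n_candidates = len(cand)
    if len(cand) == 0:
        return pd.DataFrame(columns=EVENT_COLUMNS), report

    net = stations.set_index("feeder_id")["network_id"]
    cand["net_from"] = cand["from_feeder"].map(net)
    cand["net_to"] = cand["to_feeder"].map(net)
    cand["duration_h"] = (
        (cand["arrive"] - cand["depart"]).dt.total_seconds() / 3600.0
    )
    cand["season_dep"] = calendar.season_of_series(cand["depart"])
    cand["season_arr"] = calendar.season_of_series(cand["arrive"])

    cross_net = cand["net_from"] != cand["net_to"]
    report.reasons["cross_network"] = int(cross_net.sum())
    cand = cand[~cross_net]

    too_slow = cand["duration_h"] > max_duration_h
    report.reasons["too_slow"] = int(too_slow.sum())
    cand = cand[~too_slow]

    out_window = cand["season_dep"].isna() | cand["season_arr"].isna()
    report.reasons["out_of_window"] = int(out_window.sum())
    cand = cand[~out_window]

    cross_season = cand["season_dep"] != cand["season_arr"]
    report.reasons["cross_season"] = int(cross_season.sum())
    cand = cand[~cross_season]

    species = tags.set_index("tag_id")["species"]
    events = pd.DataFrame(
        {
            "tag_id": cand["tag_id"],
            "species": cand["tag_id"].map(species),
            "network_id": cand["net_from"],
            "from_feeder": cand["from_feeder"],
            "to_feeder": cand["to_feeder"],
            "depart": cand["depart"],
            "arrive": cand["arrive"],
            "duration_h": cand["duration_h"],
            "season": cand["season_arr"],
        }
    ).reset_index(drop=True)
    report.n_kept = len(events)
    return events[EVENT_COLUMNS], report
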