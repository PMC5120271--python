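"""Structural and functional connectivity tables, plus network summaries.

Structural connectivity is the presence/absence of at least one connection
on a feeder pair (per species, per season); the table is a *complete*
species × pair × season grid with zeros filled in, because the binomial
model needs the absences as rows.  Functional connectivity is the count of
connections per individual bird on a pair in a season, recorded only where
the bird made at least one (the zero-truncated count model sees no zeros).
Direction is collapsed to unordered pairs throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from feedernet.io import SPECIES_LEVELS
from feedernet.seasons import STUDY_CALENDAR, SeasonCalendar

STRUCTURAL_COLUMNS = [
    "network_id",
    "feeder_a",
    "feeder_b",
    "season",
    "species",
    "presence",
]
FUNCTIONAL_COLUMNS = [
    "network_id",
    "feeder_a",
    "feeder_b",
    "season",
    "tag_id",
    "species",
    "count",
]

#: Edge-frequency display bins for connectivity maps.
EDGE_BINS = ((1, 10, "1-10"), (10, 50, ">10-50"), (50, 100, ">50-100"),
             (100, np.inf, ">100"))


def _unordered_pairs(events: pd.DataFrame) -> pd.DataFrame:
    """Add sorted feeder_a/feeder_b columns (unordered pair key)."""
    a = events["from_feeder"].to_numpy()
    b = events["to_feeder"].to_numpy()
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    out = events.copy()
    out["feeder_a"] = lo
    out["feeder_b"] = hi
    return out


def all_pairs(stations: pd.DataFrame) -> pd.DataFrame:
    """All C(n,2) unordered feeder pairs per network."""
    rows = []
    for net, group in stations.groupby("network_id"):
        ids = sorted(group["feeder_id"])
        for a, b in itertools.combinations(ids, 2):
            rows.append({"network_id": net, "feeder_a": a, "feeder_b": b})
    return pd.DataFrame(rows, columns=["network_id", "feeder_a", "feeder_b"])


def build_functional(events: pd.DataFrame) -> pd.DataFrame:
    """Per-tag, per-pair, per-season connection counts (count ≥ 1 rows
    only).  The counts sum to the number of retained events."""
    if len(events) == 0:
        return pd.DataFrame(columns=FUNCTIONAL_COLUMNS)
    ev = _unordered_pairs(events)
    out = (
        ev.groupby(
            ["network_id", "feeder_a", "feeder_b", "season", "tag_id", "species"],
            as_index=False,
        )
        .size()
        .rename(columns={"size": "count"})
    )
    return out[FUNCTIONAL_COLUMNS]


def build_structural(
    events: pd.DataFrame,
    stations: pd.DataFrame,
    tags: pd.DataFrame | None = None,
    calendar: SeasonCalendar = STUDY_CALENDAR,
) -> pd.DataFrame:
    """Complete presence/absence grid: species × pair × season per network.

    ``presence`` is 1 iff at least one connection event of that species
    occurred on that unordered pair in that season.
    """
    pairs = all_pairs(stations)
    seasons = calendar.labels
    species = list(SPECIES_LEVELS)
    grid = pairs.merge(pd.DataFrame({"season": seasons}), how="cross").merge(
        pd.DataFrame({"species": species}), how="cross"
    )
    if len(events):
        present = (
            _unordered_pairs(events)
            .groupby(
                ["network_id", "feeder_a", "feeder_b", "season", "species"],
                as_index=False,
            )
            .size()
        )
        present["presence"] = 1
        grid = grid.merge(
            present.drop(columns="size"),
            on=["network_id", "feeder_a", "feeder_b", "season", "species"],
            how="left",
        )
        grid["presence"] = grid["presence"].fillna(0).astype(int)
    else:
        grid["presence"] = 0
    return grid[STRUCTURAL_COLUMNS]


def edge_bin(count: int) -> str | None:
    """Display bin for a per-pair connection total (None for 0)."""
    if count <= 0:
        return None
    for lo, hi, label in EDGE_BINS:
        if lo <= count <= hi:
            return label
    return None


@dataclass
class NetworkSummary:
    """Per-network connectivity summary (per-feeder and per-pair views)."""

    network_id: str
    n_feeders: int
    n_events: int
    feeder_degree: pd.Series  # number of partner feeders, per feeder
    feeder_total: pd.Series  # total connections touching each feeder
    pair_counts: pd.DataFrame  # per-pair totals with display bins
    pct_pairs_connected: float
    mean_pair_distance: float | None = None
    retained_pairs: pd.DataFrame | None = None
    pct_events_excluded: float | None = None

    def to_dict(self) -> dict:
        d = {
            "network_id": self.network_id,
            "n_feeders": self.n_feeders,
            "n_events": self.n_events,
            "feeder_degree": self.feeder_degree.to_dict(),
            "feeder_total": self.feeder_total.to_dict(),
            "pct_pairs_connected": self.pct_pairs_connected,
        }
        if self.pct_events_excluded is not None:
            d["mean_pair_distance"] = self.mean_pair_distance
            d["pct_events_excluded"] = self.pct_events_excluded
        return d


def summarize_network(
    events: pd.DataFrame,
    stations: pd.DataFrame,
    network_id: str,
    mean_distance_filter: bool = False,
) -> NetworkSummary:
    """Per-feeder degrees/totals, per-pair counts with display bins, and
    the fraction of pairs connected.

    With ``mean_distance_filter`` set, also reports the edge set retained
    when showing only pairs closer than the mean distance over all pairs
    (a map-decluttering filter), and the percentage of connections that
    filter excludes.
    """
    st = stations[stations["network_id"] == network_id]
    feeders = sorted(st["feeder_id"])
    ev = events[events["network_id"] == network_id]
    ev = _unordered_pairs(ev) if len(ev) else ev

    pairs = all_pairs(st)
    if len(ev):
        counts = (
            ev.groupby(["feeder_a", "feeder_b"], as_index=False)
            .size()
            .rename(columns={"size": "count"})
        )
    else:
        counts = pd.DataFrame(columns=["feeder_a", "feeder_b", "count"])
    pair_counts = pairs.merge(counts, on=["feeder_a", "feeder_b"], how="left")
    pair_counts["count"] = pair_counts["count"].fillna(0).astype(int)
    pair_counts["bin"] = pair_counts["count"].map(edge_bin)

    degree = pd.Series(0, index=pd.Index(feeders, name="feeder_id"), dtype=int)
    total = degree.copy()
    connected = pair_counts[pair_counts["count"] > 0]
    for col in ("feeder_a", "feeder_b"):
        degree = degree.add(connected[col].value_counts(), fill_value=0).astype(int)
        total = total.add(
            connected.groupby(col)["count"].sum(), fill_value=0
        ).astype(int)

    summary = NetworkSummary(
        network_id=network_id,
        n_feeders=len(feeders),
        n_events=int(pair_counts["count"].sum()),
        feeder_degree=degree,
        feeder_total=total,
        pair_counts=pair_counts,
        pct_pairs_connected=100.0 * len(connected) / len(pairs) if len(pairs) else 0.0,
    )

    if mean_distance_filter:
        coords = st.set_index("feeder_id")[["x", "y"]]
        xy_a = coords.loc[pair_counts["feeder_a"]].to_numpy(float)
        xy_b = coords.loc[pair_counts["feeder_b"]].to_numpy(float)
        dist = np.hypot(*(xy_a - xy_b).T)
        mean_d = float(dist.mean())
        keep = dist < mean_d
        retained = pair_counts[keep]
        excluded = int(pair_counts.loc[~keep, "count"].sum())
        summary.mean_pair_distance = mean_d
        summary.retained_pairs = retained
        summary.pct_events_excluded = (
            100.0 * excluded / summary.n_events if summary.n_events else 0.0
        )
    return summary
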