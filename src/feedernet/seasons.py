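"""Season calendar: four equal seasons partitioning a study year.

The default calendar matches a September-to-August study year: autumn
(1 Sep-30 Nov), winter (1 Dec-28 Feb), spring (1 Mar-31 May) and summer
(1 Jun-31 Aug).  Seasons partition the study window exactly — no gaps, no
overlaps — so every in-window instant has exactly one season label.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from feedernet.errors import ValidationError

SEASON_LEVELS = ("summer", "autumn", "winter", "spring")  # baseline first


@dataclass(frozen=True)
class SeasonCalendar:
    """An ordered list of ``(label, start_date, end_date)`` entries.

    Dates are inclusive at both ends; entry *k*'s end must be the day
    before entry *k+1*'s start.
    """

    entries: tuple

    def __post_init__(self):
        entries = tuple(
            (label, pd.Timestamp(start), pd.Timestamp(end))
            for label, start, end in self.entries
        )
        object.__setattr__(self, "entries", entries)
        for label, start, end in entries:
            if end < start:
                raise ValidationError(f"season {label!r}: end before start")
        for (la, _, ea), (lb, sb, _) in zip(entries, entries[1:]):
            if sb != ea + pd.Timedelta(days=1):
                raise ValidationError(
                    f"seasons {la!r} and {lb!r} do not abut: gap or overlap"
                )

    @property
    def start(self) -> pd.Timestamp:
        return self.entries[0][1]

    @property
    def end(self) -> pd.Timestamp:
        """Last in-window instant (end of the final season's last day)."""
        return self.entries[-1][2] + pd.Timedelta(days=1) - pd.Timedelta(seconds=1)

    @property
    def labels(self) -> list[str]:
        return [label for label, _, _ in self.entries]

    def season_of(self, t) -> str:
        """Label of the single season containing instant ``t``.

        Raises :class:`ValidationError` for instants outside the window.
        """
        t = pd.Timestamp(t)
        for label, start, end in self.entries:
            if start <= t < end + pd.Timedelta(days=1):
                return label
        raise ValidationError(
            f"instant {t} outside study window [{self.start}, {self.end}]"
        )

    def season_of_series(self, ts: pd.Series) -> pd.Series:
        """Vectorised :meth:`season_of`; out-of-window instants map to NaN."""
        out = pd.Series(pd.NA, index=ts.index, dtype="object")
        for label, start, end in self.entries:
            mask = (ts >= start) & (ts < end + pd.Timedelta(days=1))
            out[mask] = label
        return out

    def bounds(self, label: str) -> tuple[pd.Timestamp, pd.Timestamp]:
        for lab, start, end in self.entries:
            if lab == label:
                return start, end + pd.Timedelta(days=1)
        raise KeyError(label)


#: The 2013-2014 study year (data collection started 1 September 2013).
STUDY_CALENDAR = SeasonCalendar(
    (
        ("autumn", "2013-09-01", "2013-11-30"),
        ("winter", "2013-12-01", "2014-02-28"),
        ("spring", "2014-03-01", "2014-05-31"),
        ("summer", "2014-06-01", "2014-08-31"),
    )
)


def season_of(t, calendar: SeasonCalendar = STUDY_CALENDAR) -> str:
    """Season label for instant ``t`` under ``calendar``."""
    return calendar.season_of(t)
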