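"""Selection of the 30-min analysis sub-periods around BET.

Motility is not analyzed over the whole 14-h recording but in six 30-min
windows anchored on the bulbous emptying time: three while the bolus is in
the bulbous (period I: t1 first 30 min, t2 halfway to BET, t3 last 30 min
before BET) and three after it left (period II: t4 first, t5 middle, t6
last 30 min before the horizon).  Intestines that empty within 1.5 h have
every period-I frame analyzed instead, as a single window.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Window", "SubperiodSet", "select_subperiods"]

HOUR = 3600.0


@dataclass(frozen=True)
class Window:
    label: str       #: t1..t6 or full_period_I
    start_s: float
    end_s: float
    period: str      #: "I" or "II"

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t_s: float) -> bool:
        return self.start_s <= t_s < self.end_s


@dataclass(frozen=True)
class SubperiodSet:
    windows: tuple[Window, ...]
    bet_s: float
    horizon_s: float

    def period_windows(self, period: str) -> tuple[Window, ...]:
        return tuple(w for w in self.windows if w.period == period)

    def analyzed_seconds(self, period: str) -> float:
        return sum(w.duration_s for w in self.period_windows(period))

    def window_of(self, t_s: float) -> Window | None:
        """Window containing analysis-clock time ``t_s`` (onset attribution)."""
        for w in self.windows:
            if w.contains(t_s):
                return w
        return None


def select_subperiods(
    bet_s: float,
    horizon_s: float = 14 * HOUR,
    window_s: float = 30 * 60.0,
    short_bet_cutoff_s: float = 1.5 * HOUR,
) -> SubperiodSet:
    """Build the analysis windows for one preparation.

    Period I (before ``bet_s``): when BET exceeds the cutoff, t1 is the
    first 30 min, t2 a 30-min window centred on BET/2 and t3 the last 30
    min before BET; otherwise all frames from 0 to BET form one window.
    Period II (after ``bet_s``): t4 the first 30 min after BET, t5 centred
    on the midpoint between BET and the horizon, t6 the last 30 min of the
    horizon.  Windows are truncated where they would overlap so every
    frame is analyzed at most once; an empty truncation drops the window.
    """
    if not 0 <= bet_s <= horizon_s:
        raise ValueError("bet_s must lie within [0, horizon_s]")
    half = window_s / 2.0

    windows: list[Window] = []
    if bet_s > short_bet_cutoff_s:
        mid = bet_s / 2.0
        windows += [
            Window("t1", 0.0, window_s, "I"),
            Window("t2", mid - half, mid + half, "I"),
            Window("t3", bet_s - window_s, bet_s, "I"),
        ]
    elif bet_s > 0:
        windows.append(Window("full_period_I", 0.0, bet_s, "I"))

    mid2 = (bet_s + horizon_s) / 2.0
    windows += [
        Window("t4", bet_s, min(bet_s + window_s, horizon_s), "II"),
        Window("t5", max(mid2 - half, bet_s), min(mid2 + half, horizon_s), "II"),
        Window("t6", max(horizon_s - window_s, bet_s), horizon_s, "II"),
    ]

    # enforce disjointness in chronological order, keeping truncated stubs
    out: list[Window] = []
    cursor = 0.0
    for w in sorted(windows, key=lambda w: (w.start_s, w.end_s)):
        start = max(w.start_s, cursor)
        if w.end_s - start <= 0:
            continue
        out.append(Window(w.label, start, w.end_s, w.period))
        cursor = w.end_s
    return SubperiodSet(tuple(out), bet_s, horizon_s)
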