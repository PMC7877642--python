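"""Aggregation of contraction events into motility parameters.

The motility parameters reported per (treatment x segment x period x
contraction kind) are:

* frequency in *cpm*: contractions per minute per mm of segment length,
  computed from the event count over the analyzed sub-period windows;
  group statistics (mean +- sd) are taken over per-preparation values;
* amplitude, duration, propagation distance and velocity: medians (with
  min/max) pooled over all events of the cell, the natural summary for
  these strongly right-skewed quantities;
* direction: the proportion of propulsive contractions travelling
  anterograde, among directed events only (standing contractions and
  exactly-symmetric spreads carry no direction).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .contractions import ContractionEvent, events_to_frame
from .diameter_map import SegmentPartition
from .subperiods import SubperiodSet

__all__ = [
    "compute_frequency",
    "anterograde_proportion",
    "summarize",
    "SUMMARY_COLUMNS",
]

KINDS = ("standing", "ripple", "slow_propulsive")
_PARAMS = ("amplitude_pct", "duration_s", "distance_pct", "velocity_mm_s")


def compute_frequency(events: Sequence[ContractionEvent] | int,
                      windows: Sequence, segment_length_mm: float) -> float:
    """Contractions per minute per mm: ``count / (window minutes x mm)``.

    ``events`` may be the filtered event list of one (segment, period)
    cell or directly the count; ``windows`` the analyzed windows of that
    period.
    """
    if segment_length_mm <= 0:
        raise ValueError("segment_length_mm must be positive")
    minutes = sum(w.duration_s for w in windows) / 60.0
    if minutes <= 0:
        raise ValueError("no analyzed time in the window set")
    n = events if isinstance(events, (int, np.integer)) else len(events)
    return n / (minutes * segment_length_mm)


def anterograde_proportion(events: Sequence[ContractionEvent]) -> float:
    """Anterograde / (anterograde + retrograde); NaN if no directed events."""
    a = sum(1 for e in events if e.direction == "anterograde")
    r = sum(1 for e in events if e.direction == "retrograde")
    if a + r == 0:
        return float("nan")
    return a / (a + r)


SUMMARY_COLUMNS = [
    "treatment", "segment", "period", "kind", "n_events", "n_preparations",
    "frequency_cpm_mm_mean", "frequency_cpm_mm_sd",
    "amplitude_pct_median", "amplitude_pct_min", "amplitude_pct_max",
    "duration_s_median", "duration_s_min", "duration_s_max",
    "distance_pct_median", "distance_pct_min", "distance_pct_max",
    "velocity_mm_s_median", "velocity_mm_s_min", "velocity_mm_s_max",
    "anterograde_prop_mean", "anterograde_prop_sd", "anterograde_prop_pooled",
]


def summarize(preparations: Sequence[dict]) -> pd.DataFrame:
    """Motility summary over analyzed preparations.

    Each element of ``preparations`` is one preparation's pipeline result:
    a mapping with ``events`` (measured :class:`ContractionEvent` list,
    carrying segment and window labels), ``windows`` (the
    :class:`SubperiodSet`) and ``partition`` (the
    :class:`SegmentPartition`).  Returns a long-format table with one row
    per (treatment, segment, period, kind) cell; empty cells keep
    ``n_events`` 0 and missing medians.
    """
    rows = []
    treatments = sorted({e.treatment for p in preparations for e in p["events"]}
                        or {p.get("treatment", "") for p in preparations})
    for treatment in treatments:
        preps = [p for p in preparations
                 if any(e.treatment == treatment for e in p["events"])
                 or p.get("treatment") == treatment]
        segments = range(1, 5)
        for segment in segments:
            for period in ("I", "II"):
                for kind in KINDS:
                    cell_events: list[ContractionEvent] = []
                    freqs: list[float] = []
                    props: list[float] = []
                    for p in preps:
                        windows: SubperiodSet = p["windows"]
                        part: SegmentPartition = p["partition"]
                        period_windows = windows.period_windows(period)
                        evs = [e for e in p["events"]
                               if e.segment == segment
                               and e.treatment == treatment
                               and _period_of(e, windows) == period]
                        cell_events += evs
                        if period_windows:
                            by_kind = [e for e in evs if e.kind == kind]
                            freqs.append(compute_frequency(
                                by_kind, period_windows,
                                part.segment_length_mm(segment)))
                            if kind != "standing":
                                pr = anterograde_proportion(by_kind)
                                if np.isfinite(pr):
                                    props.append(pr)
                    kind_events = [e for e in cell_events if e.kind == kind]
                    row = {
                        "treatment": treatment, "segment": segment,
                        "period": period, "kind": kind,
                        "n_events": len(kind_events),
                        "n_preparations": len(preps),
                        "frequency_cpm_mm_mean": _mean(freqs),
                        "frequency_cpm_mm_sd": _sd(freqs),
                        "anterograde_prop_mean": _mean(props),
                        "anterograde_prop_sd": _sd(props),
                        "anterograde_prop_pooled": (
                            anterograde_proportion(kind_events)
                            if kind != "standing" else float("nan")),
                    }
                    for param in _PARAMS:
                        vals = np.array([getattr(e, param) for e in kind_events])
                        vals = vals[np.isfinite(vals)]
                        row[f"{param}_median"] = _median(vals)
                        row[f"{param}_min"] = float(vals.min()) if len(vals) else float("nan")
                        row[f"{param}_max"] = float(vals.max()) if len(vals) else float("nan")
                    rows.append(row)
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def _period_of(event: ContractionEvent, windows: SubperiodSet) -> str | None:
    w = windows.window_of(event.onset_s)
    if w is None:
        # events are attributed by onset; detection windows coincide with
        # the subperiod windows so this only happens at float boundaries
        w = windows.window_of(event.onset_s - 1e-6)
    return w.period if w is not None else None


def _mean(xs) -> float:
    return float(np.mean(xs)) if len(xs) else float("nan")


def _sd(xs) -> float:
    return float(np.std(xs, ddof=1)) if len(xs) > 1 else float("nan")


def _median(xs) -> float:
    """Median as the midpoint of the two central order statistics."""
    return float(np.median(xs)) if len(xs) else float("nan")


def per_preparation_table(preparations: Sequence[dict]) -> pd.DataFrame:
    """Wide per-preparation table: BET plus per-cell frequencies."""
    rows = []
    for p in preparations:
        windows: SubperiodSet = p["windows"]
        part: SegmentPartition = p["partition"]
        events = p["events"]
        prep_id = events[0].preparation_id if events else p.get("preparation_id", "")
        row = {"preparation_id": prep_id,
               "bet_h": p["bet"].bet_h if "bet" in p else float("nan")}
        for segment in range(1, 5):
            for period in ("I", "II"):
                pw = windows.period_windows(period)
                for kind in KINDS:
                    evs = [e for e in events if e.segment == segment
                           and e.kind == kind
                           and _period_of(e, windows) == period]
                    key = f"s{segment}_{period}_{kind}_cpm"
                    row[key] = (compute_frequency(evs, pw,
                                                  part.segment_length_mm(segment))
                                if pw else float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)
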