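"""Contraction detection, measurement and classification.

A contraction is a transient local narrowing of the gut.  On the ST map it
is a connected region where the *relative constriction*

    depth(x, t) = (baseline(x, t) - diameter(x, t)) / baseline(x, t)

exceeds a threshold (default 7 %, just under the smallest amplitude the
three contraction archetypes reach).  The baseline is a rolling upper
envelope (95th percentile over a 2-min window) of each position's diameter
series, which tracks the resting width and the bolus-induced dilation
while ignoring the constrictions themselves.

Detection steps:

1. threshold the depth field and close gaps of up to ``gap_merge_frames``
   along the time axis;
2. label connected regions (8-neighbourhood in position x time);
3. split regions that contain several distinct constriction cores using
   marker-based watershed.  Markers are ratio-prominence maxima (h-maxima
   of the log depth: a core splits off only when its peak is a fixed
   factor above the saddle toward its neighbour, so one moving band stays
   one event even where frame sampling modulates its ridge), plus a
   second pass on a time-smoothed depth that restores markers of long
   shallow bands adjoining deeper brief events.  At the contraction rates
   seen in a fed wrasse intestine, events overlap often enough that plain
   connected components systematically undercount;
4. each region becomes one event with a per-frame *path*: the position of
   maximal constriction (minimum diameter, refined to sub-pixel precision
   by a parabolic fit) in every frame of substantial activity.

Classification follows the propagation of the path: events travelling at
most 1.0 mm are *standing* (non-propulsive); for the rest, ordinary least
squares of path position on time gives a slope whose linearity decides
between *ripples* (R^2 >= 0.8: straight, fast) and *slow propulsive*
contractions (R^2 < 0.8: meandering, slow).  Velocity is |slope| and the
sign of the slope gives the direction: positive = anterograde (oral to
anal), negative = retrograde.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats

from .diameter_map import DiameterMatrix, SegmentPartition, segment_of_position

__all__ = [
    "DetectionConfig",
    "RawEvent",
    "ContractionEvent",
    "estimate_baseline",
    "detect_events",
    "fit_propagation",
    "classify_event",
    "measure_events",
    "events_to_frame",
    "EVENT_COLUMNS",
]

KINDS = ("standing", "ripple", "slow_propulsive")
DIRECTIONS = ("anterograde", "retrograde", "none")


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable thresholds of the detector and classifier."""

    min_amplitude_frac: float = 0.07   #: detection threshold on relative constriction
    min_duration_s: float = 1.7        #: discard events shorter than this
    baseline_window_s: float = 1800.0  #: rolling window of the upper envelope
    baseline_quantile: float = 0.95    #: envelope quantile
    baseline_stride_s: float = 300.0   #: lattice step for envelope evaluation
    connectivity: int = 2              #: 2 = 8-neighbour in position x time
    standing_distance_mm: float = 1.0  #: propagation cut-off for standing
    ripple_r2: float = 0.8             #: linearity cut-off ripple vs slow propulsive
    gap_merge_frames: int = 1          #: close temporal gaps up to this many frames
    #: frames whose within-region constriction is weaker than this
    #: fraction of the event's *median* frame depth are trimmed from the
    #: path: when events overlap, the watershed region can annex a
    #: neighbour's shoulder cells in frames just outside the event's own
    #: activity, and a single annexed frame 1-2 mm off-core turns a
    #: standing contraction into a spurious propulsive one.  The median
    #: reference keeps events whose peak is transiently boosted by a
    #: crossing contraction intact.
    path_depth_frac: float = 0.5
    #: a constriction core is split off only when its peak depth exceeds
    #: the saddle toward its neighbour by this factor; ratio (not absolute)
    #: prominence keeps one moving band one event even where frame
    #: sampling modulates the ridge depth
    split_prominence_ratio: float = 1.8

    def __post_init__(self) -> None:
        if not 0 < self.min_amplitude_frac < 1:
            raise ValueError("min_amplitude_frac must be in (0, 1)")
        for name in ("min_duration_s", "baseline_window_s", "standing_distance_mm",
                     "ripple_r2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.split_prominence_ratio <= 1:
            raise ValueError("split_prominence_ratio must exceed 1")


@dataclass
class RawEvent:
    """Support of one detected constriction before classification."""

    frames: np.ndarray     #: frame indices (into the analyzed matrix) the event spans
    path_mm: np.ndarray    #: per-frame position of maximal constriction (mm)
    max_depth: float       #: maximal relative constriction over the support

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class ContractionEvent:
    """One measured and classified contraction."""

    event_id: int
    onset_s: float
    end_s: float
    duration_s: float
    path_mm: np.ndarray = field(repr=False)
    distance_mm: float = 0.0
    distance_pct: float = 0.0
    amplitude_pct: float = 0.0
    kind: str = "standing"
    slope_mm_s: float = float("nan")
    r_squared: float = float("nan")
    velocity_mm_s: float = float("nan")
    direction: str = "none"
    segment: int = 0
    window: str = ""
    preparation_id: str = ""
    treatment: str = ""

    @property
    def midpoint_mm(self) -> float:
        return 0.5 * (self.path_mm.min() + self.path_mm.max())


# ---------------------------------------------------------------------------
# Baseline
# ---------------------------------------------------------------------------

def estimate_baseline(dm: DiameterMatrix, cfg: DetectionConfig = DetectionConfig()) -> np.ndarray:
    """Rolling upper envelope of every position's diameter series.

    A centred rolling quantile (default the 95th percentile over 30 min):
    constrictions only ever lower the diameter, so as long as a position
    is at its resting/dilated width for at least ~5 % of the window the
    envelope recovers that width while following slow drifts such as the
    bolus.  The window must comfortably exceed the longest contractions
    (slow propulsive events can persist for several minutes at one spot),
    otherwise the envelope dives into them.

    For speed the windowed quantile is evaluated on a coarse time lattice
    (default every 300 s, clamped at the edges) and linearly interpolated
    between lattice points, which is exact whenever the envelope varies
    slowly relative to the stride.
    """
    w = int(round(cfg.baseline_window_s / dm.frame_interval_s))
    if w < 3:
        raise ValueError("baseline_window_s must cover at least 3 frames")
    n = dm.n_frames
    stride = max(1, int(round(cfg.baseline_stride_s / dm.frame_interval_s)))
    centers = np.arange(0, n, stride)
    if centers[-1] != n - 1:
        centers = np.append(centers, n - 1)
    env = np.empty((dm.n_positions, len(centers)))
    half = w // 2
    for k, c in enumerate(centers):
        lo = max(0, c - half)
        hi = min(n, c + half + 1)
        env[:, k] = np.quantile(dm.values[:, lo:hi], cfg.baseline_quantile, axis=1)
    if len(centers) == 1:
        return np.repeat(env, n, axis=1)
    frames = np.arange(n)
    out = np.empty_like(dm.values)
    for i in range(dm.n_positions):
        out[i] = np.interp(frames, centers, env[i])
    return out


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_events(
    dm: DiameterMatrix,
    cfg: DetectionConfig = DetectionConfig(),
    baseline: np.ndarray | None = None,
) -> list[RawEvent]:
    """Detect constriction events on one (windowed) diameter matrix."""
    from skimage.morphology import h_maxima
    from skimage.segmentation import watershed

    if baseline is None:
        baseline = estimate_baseline(dm, cfg)
    safe = np.maximum(baseline, 1e-9)
    depth = (baseline - dm.values) / safe

    mask = depth >= cfg.min_amplitude_frac
    if cfg.gap_merge_frames > 0:
        struct = np.ones((1, cfg.gap_merge_frames + 1), dtype=bool)
        mask = ndi.binary_closing(mask, structure=struct)
    if not mask.any():
        return []

    depth_m = np.where(mask, depth, 0.0)
    # ratio prominence: split at a saddle only when peak >= ratio * saddle.
    # An infinitesimal deterministic ramp breaks exact depth ties: a
    # noiseless pixel-aligned band attains its summit value in several
    # symmetric frames, and tied global maxima would each seed a marker.
    ramp = (np.arange(depth.shape[0])[:, None] * 1e-10
            + np.arange(depth.shape[1])[None, :] * 1e-13)
    h_log = float(np.log(cfg.split_prominence_ratio))
    conn = np.ones((3, 3), dtype=bool) if cfg.connectivity == 2 \
        else ndi.generate_binary_structure(2, 1)
    markers_bin = h_maxima(np.log(np.maximum(depth_m, 1e-6)) + ramp, h_log) & mask
    # second pass on a time-smoothed field: a long shallow band adjoining
    # deeper brief events loses its own maximum to them (prominence is
    # measured against the merge level with the higher peak); smoothing
    # over ~8 s attenuates brief events threefold while persistent bands
    # keep their depth, guaranteeing each band a marker of its own
    smooth = ndi.uniform_filter1d(depth_m, size=9, axis=1, mode="nearest")
    markers_slow = h_maxima(np.log(np.maximum(smooth, 1e-6)) + ramp, h_log) & mask
    near_primary = ndi.binary_dilation(markers_bin, structure=np.ones((11, 13), bool))
    lab2, n2 = ndi.label(markers_slow, structure=conn)
    if n2:
        # keep only whole secondary components that are clear of primaries
        # and persistent: smoothing also strews pointlike maxima around a
        # band that already carries a primary marker, while a genuinely
        # suppressed band leaves a long ridge
        touches = np.unique(lab2[near_primary & (lab2 > 0)])
        keep = np.ones(n2 + 1, dtype=bool)
        keep[touches] = False
        keep[0] = False
        for lab, sl in enumerate(ndi.find_objects(lab2), start=1):
            if sl is not None and keep[lab] and (sl[1].stop - sl[1].start) < 8:
                keep[lab] = False
        markers_bin |= keep[lab2]
    markers, n_mark = ndi.label(markers_bin, structure=conn)
    if n_mark == 0:
        return []
    labels = watershed(-depth_m, markers=markers, mask=mask,
                       connectivity=cfg.connectivity)

    events: list[RawEvent] = []
    dx = dm.position_spacing_mm
    min_frames = max(1, int(np.ceil(cfg.min_duration_s / dm.frame_interval_s - 1e-9)))
    for lab, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        region = labels[sl] == lab
        vals = np.where(region, dm.values[sl], np.inf)
        depth_reg = np.where(region, depth[sl], 0.0)
        frame_depth = depth_reg.max(axis=0)
        active = frame_depth > 0
        if not active.any():
            continue
        ref = np.median(frame_depth[active])
        cols = np.flatnonzero(frame_depth >= cfg.path_depth_frac * ref)
        if len(cols) < min_frames:
            continue
        # per-frame argmin of diameter; ties break to the smallest index
        rows = vals[:, cols].argmin(axis=0)
        frames = cols + sl[1].start
        path_px = rows + sl[0].start + 0.5
        # parabolic sub-pixel refinement of each frame's minimum
        r_abs = rows + sl[0].start
        ok = (r_abs > 0) & (r_abs < dm.n_positions - 1)
        if ok.any():
            f_abs = frames[ok]
            r_ok = r_abs[ok]
            vm = dm.values[r_ok - 1, f_abs]
            v0 = dm.values[r_ok, f_abs]
            vp = dm.values[r_ok + 1, f_abs]
            den = vm - 2 * v0 + vp
            delta = np.where(den > 1e-12, 0.5 * (vm - vp) / np.where(den > 1e-12, den, 1.0), 0.0)
            path_px = path_px.astype(float)
            path_px[ok] += np.clip(delta, -0.5, 0.5)
        path_mm = path_px * dx
        events.append(RawEvent(
            frames=frames,
            path_mm=path_mm,
            max_depth=float(depth[sl][region].max()),
        ))
    events.sort(key=lambda e: (e.frames[0], e.path_mm[0]))
    return events


# ---------------------------------------------------------------------------
# Propagation fit and classification
# ---------------------------------------------------------------------------

def fit_propagation(event: RawEvent, frame_interval_s: float) -> tuple[float, float]:
    """OLS of path position (response) on time: ``(slope mm/s, R^2)``.

    Returns ``(nan, nan)`` for degenerate events with fewer than two
    distinct time points (those are reclassified as standing).
    """
    t = event.frames * frame_interval_s
    if len(np.unique(t)) < 2:
        return float("nan"), float("nan")
    res = stats.linregress(t, event.path_mm)
    r2 = float(res.rvalue ** 2) if np.isfinite(res.rvalue) else 0.0
    return float(res.slope), r2


def classify_event(
    distance_mm: float,
    slope: float,
    r_squared: float,
    cfg: DetectionConfig = DetectionConfig(),
) -> tuple[str, str]:
    """Kind and direction from propagation distance, slope and linearity.

    Distance at or below the standing cut-off (1.0 mm) -> standing, with
    no direction.  Otherwise R^2 >= 0.8 -> ripple, below -> slow
    propulsive; direction follows the slope sign (exactly zero slope over
    more than 1 mm is recorded as direction 'none').
    """
    if distance_mm <= cfg.standing_distance_mm or not np.isfinite(slope):
        return "standing", "none"
    kind = "ripple" if r_squared >= cfg.ripple_r2 else "slow_propulsive"
    if slope > 0:
        return kind, "anterograde"
    if slope < 0:
        return kind, "retrograde"
    return kind, "none"


def measure_events(
    dm: DiameterMatrix,
    raw_events: Sequence[RawEvent],
    cfg: DetectionConfig = DetectionConfig(),
    part: SegmentPartition | None = None,
    window: str = "",
    id_offset: int = 0,
) -> list[ContractionEvent]:
    """Turn raw detections into fully measured, classified events.

    Times are reported on the analysis clock (``dm.t0_offset_s`` plus the
    frame offset); the segment is the one containing the path midpoint.
    """
    out: list[ContractionEvent] = []
    dt = dm.frame_interval_s
    for i, ev in enumerate(raw_events):
        distance_mm = float(ev.path_mm.max() - ev.path_mm.min())
        slope, r2 = (float("nan"), float("nan"))
        if distance_mm > cfg.standing_distance_mm:
            slope, r2 = fit_propagation(ev, dt)
        kind, direction = classify_event(distance_mm, slope, r2, cfg)
        if kind == "standing":
            slope, r2 = float("nan"), float("nan")
        mid = 0.5 * (ev.path_mm.min() + ev.path_mm.max())
        out.append(ContractionEvent(
            event_id=id_offset + i,
            onset_s=dm.t0_offset_s + float(ev.frames[0]) * dt,
            end_s=dm.t0_offset_s + float(ev.frames[-1] + 1) * dt,
            duration_s=ev.n_frames * dt,
            path_mm=ev.path_mm,
            distance_mm=distance_mm,
            distance_pct=100.0 * distance_mm / dm.intestine_length_mm,
            amplitude_pct=100.0 * ev.max_depth,
            kind=kind,
            slope_mm_s=slope,
            r_squared=r2,
            velocity_mm_s=abs(slope) if np.isfinite(slope) else float("nan"),
            direction=direction,
            segment=segment_of_position(part, mid) if part is not None else 0,
            window=window,
            preparation_id=dm.preparation_id,
            treatment=dm.treatment,
        ))
    return out


EVENT_COLUMNS = [
    "event_id", "preparation_id", "treatment", "onset_s", "duration_s",
    "segment", "window", "kind", "amplitude_pct", "distance_mm",
    "distance_pct", "velocity_mm_s", "direction", "r_squared",
]


def events_to_frame(events: Sequence[ContractionEvent]) -> pd.DataFrame:
    """Long-format table of events (one row each, TSV-ready)."""
    rows = [{c: getattr(e, c) for c in EVENT_COLUMNS} for e in events]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)
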