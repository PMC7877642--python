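"""Diameter-matrix data model and I/O.

The pipeline's universal input is a calibrated *diameter matrix*: the gut
width (mm) sampled at every position along an isolated intestine (rows,
oral end first) for every video frame (columns).  Rendered as an image it
is the spatiotemporal (ST) map, or kymograph, on which contractions appear
as dark bands.

Matrices are stored as plain TSV (one row per position) next to a flat
``<name>.meta`` key-value sidecar carrying the calibration: position
spacing, frame interval, analysis-clock origin, intestine length,
preparation id and treatment label.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "TREATMENTS",
    "DEFAULT_SEGMENT_FRACTIONS",
    "DiameterMatrix",
    "SegmentPartition",
    "read_diameter_matrix",
    "write_diameter_matrix",
    "subsample_frames",
    "slice_time",
    "partition_segments",
    "segment_of_position",
    "render_st_map",
    "FormatError",
]

#: Treatment labels used throughout (boluses of experiment plus 'empty').
TREATMENTS = ("lipid", "protein", "cellulose", "plastic_bead", "empty")

#: Segment length / total intestine length for Segments 1-4
#: (bulbous, two mid-gut segments, hindgut).
DEFAULT_SEGMENT_FRACTIONS = (0.39, 0.23, 0.23, 0.15)

_META_KEYS = (
    "position_spacing_mm",
    "frame_interval_s",
    "t0_offset_s",
    "intestine_length_mm",
    "preparation_id",
    "treatment",
)


class FormatError(ValueError):
    """Raised for missing or contradictory file metadata."""


@dataclass
class DiameterMatrix:
    """Position x time field of intestinal diameters.

    Parameters
    ----------
    values
        Dense ``(n_positions, n_frames)`` array of diameters in mm.  Row 0
        is the oral end; increasing row index runs toward the anal end.
    position_spacing_mm
        Distance between adjacent position samples.
    frame_interval_s
        Seconds between adjacent frames.
    t0_offset_s
        Analysis-clock time of the first frame.  The analysis clock starts
        (0 h) at the 21st minute after the 20-min post-mounting recovery
        period, so a full recording has ``t0_offset_s == 0``.
    intestine_length_mm
        Total length of the preparation; must agree with
        ``n_positions * position_spacing_mm`` within 1 %.
    preparation_id
        Free-form label of the preparation.
    treatment
        One of :data:`TREATMENTS`.
    """

    values: np.ndarray
    position_spacing_mm: float
    frame_interval_s: float
    t0_offset_s: float = 0.0
    intestine_length_mm: float | None = None
    preparation_id: str = "prep"
    treatment: str = "empty"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (positions x frames) array")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 frames")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("diameters must be finite")
        if np.any(self.values < 0):
            raise ValueError("diameters must be non-negative")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.position_spacing_mm <= 0:
            raise ValueError("position_spacing_mm must be positive")
        if self.intestine_length_mm is None:
            self.intestine_length_mm = self.n_positions * self.position_spacing_mm
        expected = self.n_positions * self.position_spacing_mm
        if abs(expected - self.intestine_length_mm) > 0.01 * self.intestine_length_mm:
            raise ValueError(
                f"intestine_length_mm {self.intestine_length_mm} inconsistent with "
                f"{self.n_positions} positions x {self.position_spacing_mm} mm"
            )
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")

    # -- geometry helpers -------------------------------------------------
    @property
    def n_positions(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def frame_rate(self) -> float:
        """Frames per second."""
        return 1.0 / self.frame_interval_s

    @property
    def positions_mm(self) -> np.ndarray:
        """Centre position (mm from the oral end) of every row."""
        return (np.arange(self.n_positions) + 0.5) * self.position_spacing_mm

    @property
    def times_s(self) -> np.ndarray:
        """Analysis-clock time of every frame."""
        return self.t0_offset_s + np.arange(self.n_frames) * self.frame_interval_s

    @property
    def span_s(self) -> float:
        """Recording span (first to last frame)."""
        return (self.n_frames - 1) * self.frame_interval_s


@dataclass(frozen=True)
class SegmentPartition:
    """Division of the intestine into four consecutive segments.

    Segment 1 is the bulbous (the dilated anterior foregut, the main site
    of digestion in the agastric wrasse), Segments 2-3 the mid intestine
    and Segment 4 the hindgut.
    """

    fractions: tuple[float, ...]
    boundaries_mm: tuple[float, ...]
    boundaries_idx: tuple[int, ...]

    @property
    def n_segments(self) -> int:
        return len(self.fractions)

    def segment_slice(self, segment: int) -> slice:
        """Row slice of 1-based ``segment`` (half-open interval)."""
        if not 1 <= segment <= self.n_segments:
            raise ValueError(f"segment must be in 1..{self.n_segments}")
        return slice(self.boundaries_idx[segment - 1], self.boundaries_idx[segment])

    def segment_length_mm(self, segment: int) -> float:
        return self.boundaries_mm[segment] - self.boundaries_mm[segment - 1]


def partition_segments(
    dm: DiameterMatrix, fractions: Sequence[float] = DEFAULT_SEGMENT_FRACTIONS
) -> SegmentPartition:
    """Partition the intestine into consecutive segments by length fractions.

    Boundaries fall at cumulative fractions of the intestine length;
    position rows are assigned by half-open interval so every row belongs
    to exactly one segment.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.ndim != 1 or len(fr) < 1:
        raise ValueError("fractions must be a 1-D sequence")
    if np.any(fr <= 0):
        raise ValueError("fractions must be strictly positive")
    if abs(fr.sum() - 1.0) > 1e-6:
        raise ValueError("fractions must sum to 1")
    cum = np.concatenate([[0.0], np.cumsum(fr)])
    cum[-1] = 1.0
    boundaries_mm = tuple(c * dm.intestine_length_mm for c in cum)
    # row i covers [i*dx, (i+1)*dx); assign rows by their centre
    centres = dm.positions_mm
    idx = [0]
    for b in boundaries_mm[1:-1]:
        idx.append(int(np.searchsorted(centres, b)))
    idx.append(dm.n_positions)
    if any(b - a <= 0 for a, b in zip(idx, idx[1:])):
        raise ValueError("a segment contains no position rows")
    return SegmentPartition(tuple(fr), boundaries_mm, tuple(idx))


def segment_of_position(part: SegmentPartition, position_mm: float) -> int:
    """1-based segment containing ``position_mm`` (half-open intervals)."""
    for s in range(1, part.n_segments + 1):
        if part.boundaries_mm[s - 1] <= position_mm < part.boundaries_mm[s]:
            return s
    if position_mm >= part.boundaries_mm[-1]:
        return part.n_segments
    return 1


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_diameter_matrix(dm: DiameterMatrix, path: str | os.PathLike) -> None:
    """Write ``dm`` as TSV with a ``.meta`` sidecar (inverse of read)."""
    path = os.fspath(path)
    np.savetxt(path, dm.values, fmt="%.10g", delimiter="\t")
    meta = {
        "position_spacing_mm": repr(dm.position_spacing_mm),
        "frame_interval_s": repr(dm.frame_interval_s),
        "t0_offset_s": repr(dm.t0_offset_s),
        "intestine_length_mm": repr(dm.intestine_length_mm),
        "preparation_id": dm.preparation_id,
        "treatment": dm.treatment,
    }
    with open(path + ".meta", "w") as fh:
        for k, v in meta.items():
            fh.write(f"{k}\t{v}\n")


def read_diameter_matrix(path: str | os.PathLike) -> DiameterMatrix:
    """Read a TSV diameter matrix with its ``.meta`` sidecar."""
    path = os.fspath(path)
    meta_path = path + ".meta"
    if not os.path.exists(meta_path):
        raise FormatError(f"missing metadata sidecar {meta_path}")
    meta: dict[str, str] = {}
    with open(meta_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if "\t" not in line:
                raise FormatError(f"malformed sidecar line: {line!r}")
            k, v = line.split("\t", 1)
            meta[k] = v
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise FormatError(f"sidecar missing keys: {missing}")
    values = np.loadtxt(path, delimiter="\t", ndmin=2)
    return DiameterMatrix(
        values=values,
        position_spacing_mm=float(meta["position_spacing_mm"]),
        frame_interval_s=float(meta["frame_interval_s"]),
        t0_offset_s=float(meta["t0_offset_s"]),
        intestine_length_mm=float(meta["intestine_length_mm"]),
        preparation_id=meta["preparation_id"],
        treatment=meta["treatment"],
    )


# ---------------------------------------------------------------------------
# Frame selection
# ---------------------------------------------------------------------------

def subsample_frames(dm: DiameterMatrix, stride: int) -> DiameterMatrix:
    """Keep frames ``0, stride, 2*stride, ...``.

    This mirrors the recording workflow: videos captured at 3.5 frames/s
    are reduced to 0.35 frames/s (stride 10) for the emptying-time series
    and to ~1.2 frames/s (stride 3) for motility analysis.
    """
    if int(stride) != stride or stride < 1:
        raise ValueError("stride must be a positive integer")
    stride = int(stride)
    if stride == 1:
        return dataclasses.replace(dm, values=dm.values.copy())
    return dataclasses.replace(
        dm,
        values=dm.values[:, ::stride].copy(),
        frame_interval_s=dm.frame_interval_s * stride,
    )


def slice_time(dm: DiameterMatrix, start_s: float, end_s: float) -> DiameterMatrix:
    """Frames whose analysis-clock time lies in ``[start_s, end_s)``."""
    if end_s <= start_s:
        raise ValueError("end_s must exceed start_s")
    t = dm.times_s
    i0 = int(np.searchsorted(t, start_s - 1e-9))
    i1 = int(np.searchsorted(t, end_s - 1e-9))
    if i1 - i0 < 2:
        raise ValueError("time slice contains fewer than 2 frames")
    return dataclasses.replace(
        dm,
        values=dm.values[:, i0:i1].copy(),
        t0_offset_s=float(t[i0]),
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_st_map(dm: DiameterMatrix, out: str | os.PathLike, cmap: str = "viridis") -> None:
    """Render the ST map to a PNG: x = time (h), y = oral->anal position.

    Intensity encodes diameter with a printed colour scale; contractions
    show up as dark oblique or vertical bands.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if dm.values.size == 0:
        raise ValueError("empty matrix")
    fig, ax = plt.subplots(figsize=(8, 4))
    extent = (
        dm.t0_offset_s / 3600.0,
        (dm.t0_offset_s + dm.n_frames * dm.frame_interval_s) / 3600.0,
        dm.intestine_length_mm,
        0.0,
    )
    im = ax.imshow(dm.values, aspect="auto", cmap=cmap, extent=extent,
                   interpolation="nearest")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("position from oral end (mm)")
    ax.set_title(f"{dm.preparation_id} ({dm.treatment})")
    fig.colorbar(im, ax=ax, label="diameter (mm)")
    fig.savefig(os.fspath(out), dpi=120, metadata={"Software": "gutmotion"})
    plt.close(fig)
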