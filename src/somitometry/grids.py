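"""Core containers for images, masks, curves and profiles.

Conventions used throughout the package:

* Arrays are indexed ``(row, col)`` for 2-D images, ``(plane, row, col)`` for
  3-D stacks, ``(channel, plane, row, col)`` for multi-channel stacks and
  ``(frame, row, col)`` for movies.
* Physical coordinates are in micrometres.  Pixel centres sit at integer
  indices and the physical position of index ``i`` along an axis is
  ``i * pixel_size`` for that axis (0-based).
* Point sets and curves are stored as ``(x, y)`` pairs in µm, where
  ``x = col * pixel_size_x`` and ``y = row * pixel_size_y``.
* Time is in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ImageGrid",
    "LabeledMask",
    "MidlineCurve",
    "WidthProfile",
    "SomiteCall",
    "FirstSomiteResult",
    "KymographData",
    "OscillationTrace",
    "EventSeries",
]


@dataclass
class ImageGrid:
    """An intensity lattice plus the physical metadata needed to interpret it.

    Parameters
    ----------
    data:
        2-D ``(row, col)``, 3-D ``(plane, row, col)``, multi-channel 3-D
        ``(channel, plane, row, col)`` or movie ``(frame, row, col)`` array.
    pixel_size:
        Physical size of one pixel per *spatial* axis, in µm, ordered like the
        spatial axes of ``data`` (e.g. ``(dz, dy, dx)`` for a stack).
    channel_names:
        Optional labels for the channel axis (multi-channel stacks only).
    frame_interval:
        Minutes between successive frames (movies only).
    """

    data: np.ndarray
    pixel_size: tuple[float, ...]
    channel_names: tuple[str, ...] | None = None
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.pixel_size = tuple(float(p) for p in np.atleast_1d(self.pixel_size))
        if any(p <= 0 for p in self.pixel_size):
            raise ValueError(f"pixel sizes must be positive, got {self.pixel_size}")
        if self.channel_names is not None:
            self.channel_names = tuple(str(c) for c in self.channel_names)
            if len(self.channel_names) != self.data.shape[0]:
                raise ValueError(
                    f"{len(self.channel_names)} channel names for "
                    f"{self.data.shape[0]} channels"
                )
        n_spatial = self.data.ndim
        if self.channel_names is not None or self.frame_interval is not None:
            n_spatial -= 1  # leading channel or frame axis
        if len(self.pixel_size) != n_spatial:
            raise ValueError(
                f"pixel_size has {len(self.pixel_size)} entries for "
                f"{n_spatial} spatial axes"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0] if self.channel_names is not None else 1

    def channel(self, name: str) -> np.ndarray:
        """Return one channel by (case-insensitive) name."""
        if self.channel_names is None:
            raise ValueError("image has no channel axis")
        lowered = [c.lower() for c in self.channel_names]
        try:
            return self.data[lowered.index(name.lower())]
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None


@dataclass
class LabeledMask:
    """A boolean lattice with physical pixel sizes and provenance.

    ``provenance`` records how the mask was made (method name, threshold,
    cleaning parameters, degeneracy flags) so downstream reports can state it.
    """

    mask: np.ndarray
    pixel_size: tuple[float, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.pixel_size = tuple(float(p) for p in np.atleast_1d(self.pixel_size))
        if any(p <= 0 for p in self.pixel_size):
            raise ValueError(f"pixel sizes must be positive, got {self.pixel_size}")
        if len(self.pixel_size) != self.mask.ndim:
            raise ValueError(
                f"pixel_size has {len(self.pixel_size)} entries for a "
                f"{self.mask.ndim}-D mask"
            )

    @property
    def degenerate(self) -> bool:
        return bool(self.provenance.get("degenerate", False))


@dataclass
class MidlineCurve:
    """Smoothed posterior->anterior midline, sampled uniformly in arc length.

    ``points[0]`` is at the posterior anchor end.  Tangents are unit vectors
    pointing anteriorly; normals are tangents rotated +90 degrees.
    """

    points: np.ndarray          # (n, 2) µm, (x, y)
    arc_length: np.ndarray      # (n,) cumulative µm, arc_length[0] == 0
    smoothing: float
    step: float                 # uniform sampling step, µm

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.arc_length = np.asarray(self.arc_length, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        if self.arc_length.shape[0] != self.points.shape[0]:
            raise ValueError("arc_length and points disagree in length")
        if abs(self.arc_length[0]) > 1e-9:
            raise ValueError("arc_length must start at 0")
        if np.any(np.diff(self.arc_length) <= 0):
            raise ValueError("arc_length must be strictly increasing")

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])

    def tangents(self) -> np.ndarray:
        """Unit tangent at every sample (central differences)."""
        t = np.gradient(self.points, self.arc_length, axis=0)
        norms = np.linalg.norm(t, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return t / norms

    def normals(self) -> np.ndarray:
        """Unit normals: tangents rotated +90 degrees ((x, y) -> (-y, x))."""
        t = self.tangents()
        return np.stack([-t[:, 1], t[:, 0]], axis=1)

    def point_at(self, s: float) -> np.ndarray:
        """Linearly interpolated point at arc length ``s``."""
        x = np.interp(s, self.arc_length, self.points[:, 0])
        y = np.interp(s, self.arc_length, self.points[:, 1])
        return np.array([x, y])

    def tangent_at(self, s: float) -> np.ndarray:
        t = self.tangents()
        tx = np.interp(s, self.arc_length, t[:, 0])
        ty = np.interp(s, self.arc_length, t[:, 1])
        v = np.array([tx, ty])
        return v / np.linalg.norm(v)


@dataclass
class WidthProfile:
    """Perpendicular body width as a function of midline arc length."""

    s: np.ndarray               # arc-length samples, µm
    w: np.ndarray               # width at each sample, µm
    step: float                 # sampling step, µm
    flags: np.ndarray | None = None  # samples where a ray hit the image border

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.s.shape != self.w.shape:
            raise ValueError("s and w must have equal length")
        if np.any(self.w < 0):
            raise ValueError("widths must be non-negative")


@dataclass
class SomiteCall:
    """One called somite.  ``index`` 1 is the most posterior (newest) somite."""

    index: int
    s_start: float              # posterior bounding minimum, µm
    s_end: float                # anterior bounding minimum, µm
    s_peak: float               # position of the width maximum, µm
    length: float               # inter-somite distance s_end - s_start, µm
    width: float                # profile maximum within [s_start, s_end], µm
    area: float                 # µm², ellipse model
    circularity: float          # dimensionless, in (0, 1]
    end_capped: bool = False    # anterior boundary is virtual (see docs)

    def __post_init__(self) -> None:
        if not (self.s_start < self.s_peak < self.s_end):
            raise ValueError("require s_start < s_peak < s_end")
        if not (0 < self.circularity <= 1 + 1e-9):
            raise ValueError(f"circularity {self.circularity} outside (0, 1]")


@dataclass
class FirstSomiteResult:
    """Geometry of the first somite relative to the somitoid midline."""

    relative_position: float    # arc fraction from the posterior anchor, 0-1
    angle: float                # degrees between LR-normal and tangent, 0-90
    point: np.ndarray           # intersection point P, µm
    exact_crossing: bool        # False if closest-approach fallback was used
    frame: int | None = None
    time: float | None = None   # minutes

    def __post_init__(self) -> None:
        if not (0.0 <= self.relative_position <= 1.0):
            raise ValueError("relative_position outside [0, 1]")
        if not (0.0 <= self.angle <= 90.0 + 1e-9):
            raise ValueError("angle outside [0, 90] degrees")


@dataclass
class KymographData:
    """Space-time intensity matrix: one row per frame, columns along the axis.

    Rows are in temporal order (top row = first frame).  Columns run from the
    posterior end of the sampling polyline to the anterior end.
    """

    matrix: np.ndarray          # (n_frames, n_positions)
    frame_interval: float       # minutes
    spatial_step: float         # µm between columns
    axis: np.ndarray            # (k, 2) polyline in µm, posterior -> anterior
    half_width: float           # transverse averaging half-width, µm

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("kymograph matrix must be 2-D")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.matrix.shape[0]) * self.frame_interval


@dataclass
class OscillationTrace:
    """A reporter trace with its detrended, phase and period derivatives."""

    times: np.ndarray           # minutes
    raw: np.ndarray
    detrended: np.ndarray | None = None
    phase: np.ndarray | None = None      # unwrapped radians
    peak_times: np.ndarray | None = None
    trough_times: np.ndarray | None = None
    period_hours: float | None = None    # mean peak-to-peak interval
    period_sd_hours: float | None = None
    n_intervals: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.times.shape != self.raw.shape:
            raise ValueError("times and raw must have equal length")


@dataclass
class EventSeries:
    """Strictly increasing somite-formation event times, in minutes."""

    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("event times must be one-dimensional")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)
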