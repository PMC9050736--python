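"""Segmentation-clock dynamics: kymographs, detrending, phase, periods.

A reporter movie is registered (translation only), median-filtered and
resliced along a posterior->anterior axis into a kymograph (one row per
frame).  Region traces are detrended by subtracting a centred moving average
(default 50 frames, the window used for clock traces in this system), the
instantaneous phase comes from the analytic signal, and the oscillation
period is the mean successive peak-to-peak interval.  The posterior-anterior
phase lag of the travelling wave is the circular mean phase difference
between two kymograph regions, converted to minutes via the period.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks, hilbert
from skimage import filters as skfilters
from skimage import morphology

from .grids import EventSeries, ImageGrid, KymographData

__all__ = [
    "register_frames",
    "build_kymograph",
    "detrend_trace",
    "interpolate_gaps",
    "instantaneous_phase",
    "peak_to_peak_period",
    "phase_lag",
    "event_period",
]


# ---------------------------------------------------------------------------
# registration and kymograph
# ---------------------------------------------------------------------------

def register_frames(movie: ImageGrid) -> tuple[ImageGrid, dict]:
    """Translation-only registration by foreground centroid.

    Each frame is thresholded and shifted so its foreground centroid matches
    the first frame's.  The threshold is Otsu on the *minimum* intensity
    projection over time: an oscillating reporter modulates the tissue's
    brightness, and thresholding each frame at a level derived from the
    dimmest state keeps the whole body foreground in every frame instead of
    tracking the travelling bright crests.  Frames whose foreground fraction
    is tiny (pure noise, empty field) are flagged low-confidence and left
    unshifted.  Returns the registered movie and a report with the per-frame
    drift vectors (row, col, px).
    """
    data = movie.data
    if data.ndim != 3:
        raise ValueError("register_frames expects a (frame, row, col) movie")
    if data.shape[0] < 2:
        raise ValueError("need at least two frames")
    if not np.any(data):
        raise ValueError("empty movie")
    min_proj = data.min(axis=0)
    if np.ptp(min_proj) == 0:
        min_proj = data.mean(axis=0)
    thr = skfilters.threshold_otsu(min_proj)
    shifts = np.zeros((data.shape[0], 2))
    low_confidence = np.zeros(data.shape[0], dtype=bool)
    ref = None
    out = np.empty_like(data, dtype=float)
    for i, frame in enumerate(data):
        fg = frame > thr
        frac = fg.mean()
        if frac >= 1e-3:
            # a real body is one coherent object standing out of background;
            # pure noise gives scattered specks with weak contrast
            labels, n_lab = ndimage.label(fg)
            largest = np.bincount(labels.ravel())[1:].max() if n_lab else 0
            mu_fg, mu_bg = frame[fg].mean(), frame[~fg].mean() if (~fg).any() \
                else 0.0
            michelson = (mu_fg - mu_bg) / (mu_fg + mu_bg + 1e-12)
            coherent = largest / fg.sum() >= 0.5 and michelson >= 0.3
        else:
            coherent = False
        if not coherent:
            low_confidence[i] = True
            out[i] = frame
            continue
        centroid = np.array(ndimage.center_of_mass(fg))
        if ref is None:
            ref = centroid
        shifts[i] = centroid - ref
        out[i] = ndimage.shift(frame.astype(float), -shifts[i], order=1,
                               mode="nearest")
    if ref is None:
        warnings.warn("no frame has a coherent foreground object; returning "
                      "the movie unregistered", stacklevel=2)
    elif low_confidence.any():
        warnings.warn(f"{int(low_confidence.sum())} frame(s) had no reliable "
                      "foreground; left unregistered", stacklevel=2)
    report = {"shifts_px": shifts, "low_confidence": low_confidence,
              "threshold": float(thr)}
    reg = ImageGrid(out, movie.pixel_size, frame_interval=movie.frame_interval)
    return reg, report


def build_kymograph(movie: ImageGrid, axis: np.ndarray, half_width: float = 0.0,
                    median_radius: int = 0,
                    spatial_step: float | None = None) -> KymographData:
    """Reslice a movie along a posterior->anterior polyline into a kymograph.

    Each frame is median-filtered (disk footprint of ``median_radius`` px,
    skipped when 0), then sampled along the axis at ``spatial_step`` µm
    (default: one pixel) with transverse averaging over +/- ``half_width`` µm
    along the local normal.  Rows are frames in temporal order.
    """
    data = movie.data
    if data.ndim != 3:
        raise ValueError("build_kymograph expects a (frame, row, col) movie")
    if movie.frame_interval is None:
        raise ValueError("movie needs a frame_interval")
    dy, dx = movie.pixel_size
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 2 or axis.shape[1] != 2 or len(axis) < 2:
        raise ValueError("axis must be a polyline of >= 2 (x, y) µm points")
    h, w = data.shape[1:]
    if (np.any(axis[:, 0] < 0) or np.any(axis[:, 0] > (w - 1) * dx)
            or np.any(axis[:, 1] < 0) or np.any(axis[:, 1] > (h - 1) * dy)):
        raise ValueError("axis exits the image")

    step = spatial_step if spatial_step is not None else min(dy, dx)
    seg = np.diff(axis, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    s_knots = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = s_knots[-1]
    n_pos = max(2, int(np.floor(total / step)) + 1)
    s = np.linspace(0.0, total, n_pos)
    px_pts = np.stack([np.interp(s, s_knots, axis[:, 0]),
                       np.interp(s, s_knots, axis[:, 1])], axis=1)
    tang = np.gradient(px_pts, s, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    norm = np.stack([-tang[:, 1], tang[:, 0]], axis=1)

    if half_width > 0:
        offs = np.arange(-half_width, half_width + 1e-9, min(dy, dx))
    else:
        offs = np.array([0.0])
    # sample positions (n_pos, n_offs, 2) in µm -> pixel coordinates
    pos = px_pts[:, None, :] + norm[:, None, :] * offs[None, :, None]
    rows = pos[..., 1] / dy
    cols = pos[..., 0] / dx

    footprint = morphology.disk(median_radius) if median_radius > 0 else None
    kymo = np.empty((data.shape[0], n_pos))
    for i, frame in enumerate(data):
        f = frame.astype(float)
        if footprint is not None:
            f = ndimage.median_filter(f, footprint=footprint)
        vals = ndimage.map_coordinates(f, [rows.ravel(), cols.ravel()],
                                       order=1, mode="nearest")
        kymo[i] = vals.reshape(rows.shape).mean(axis=1)
    return KymographData(matrix=kymo, frame_interval=movie.frame_interval,
                         spatial_step=float(s[1] - s[0]), axis=axis,
                         half_width=half_width)


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def interpolate_gaps(values: np.ndarray, max_gap: int = 3) -> np.ndarray:
    """Linearly fill NaN runs of length <= ``max_gap``; error on longer runs.

    Imaging pauses (sample repositioning) leave short gaps that are safe to
    bridge; longer gaps should be analysed as separate segments.
    """
    v = np.asarray(values, dtype=float).copy()
    isnan = np.isnan(v)
    if not isnan.any():
        return v
    idx = np.arange(len(v))
    # find runs of NaN
    edges = np.diff(isnan.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if isnan[0]:
        starts.insert(0, 0)
    if isnan[-1]:
        ends.append(len(v))
    for s0, e0 in zip(starts, ends):
        if e0 - s0 > max_gap:
            raise ValueError(f"gap of {e0 - s0} frames exceeds max_gap="
                             f"{max_gap}; split the trace instead")
    v[isnan] = np.interp(idx[isnan], idx[~isnan], v[~isnan])
    return v


def _centered_moving_average(v: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; the window shrinks symmetrically at the ends
    (no zero padding, so no edge artifacts)."""
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(v)])
    n = len(v)
    i = np.arange(n)
    k = np.minimum(half, np.minimum(i, n - 1 - i))
    lo, hi = i - k, i + k + 1
    return (csum[hi] - csum[lo]) / (hi - lo)


def detrend_trace(raw: np.ndarray, window: int = 50,
                  max_gap: int = 3) -> np.ndarray:
    """Subtract a centred moving average of ``window`` frames.

    At the edges the window shrinks symmetrically so the trend estimate stays
    centred.  Short NaN gaps are linearly interpolated first.  Note the
    moving-average filter attenuates oscillations: a sinusoid of period T
    frames keeps a fraction ``1 - sinc(W/T)`` of its amplitude after
    subtraction (W = window), so components with period >> window are largely
    removed — that is the detrending cut-off.
    """
    v = np.asarray(raw, dtype=float)
    if v.ndim != 1:
        raise ValueError("detrend_trace expects a 1-D series")
    if len(v) <= window:
        raise ValueError(f"series of {len(v)} frames is not longer than the "
                         f"window ({window})")
    v = interpolate_gaps(v, max_gap=max_gap)
    return v - _centered_moving_average(v, window)


def instantaneous_phase(detrended: np.ndarray) -> np.ndarray:
    """Unwrapped analytic-signal (Hilbert) phase of a zero-mean trace."""
    v = np.asarray(detrended, dtype=float)
    if not np.any(v):
        raise ValueError("all-zero series has no phase")
    return np.unwrap(np.angle(hilbert(v)))


def _coarse_period_frames(detrended: np.ndarray) -> float:
    """Dominant-FFT-bin period estimate in frames (used to seed peak search)."""
    v = np.asarray(detrended, dtype=float)
    spec = np.abs(np.fft.rfft(v - v.mean()))
    if len(spec) < 2:
        return float(len(v))
    k = 1 + int(np.argmax(spec[1:]))
    return len(v) / k


def peak_to_peak_period(detrended: np.ndarray, frame_interval: float,
                        min_prominence: float | None = None,
                        min_distance: float | None = None,
                        smooth_frames: int | None = None) -> dict:
    """Oscillation period from successive peak-to-peak intervals.

    The trace is low-passed before peak detection (a moving average of a
    quarter of the coarse period; symmetric, so peak positions do not move,
    and the imaging pipeline's median filter plays the same role on real
    movies) so that white noise cannot masquerade as peaks.  Defaults: ``min_distance`` is half the
    dominant-FFT-bin period, ``min_prominence`` 0.3 x the SD of the
    detrended trace.  Returns a dict with ``period_hours``, ``sd_hours``,
    ``n_intervals`` and the peak/trough times (minutes).  Raises if fewer
    than two peaks are found.
    """
    v = np.asarray(detrended, dtype=float)
    coarse = _coarse_period_frames(v)
    if smooth_frames is None:
        smooth_frames = max(1, int(round(coarse / 4)))
    if smooth_frames > 1:
        v = _centered_moving_average(v, smooth_frames)
    if min_distance is None:
        min_distance = 0.5 * coarse
    if min_prominence is None:
        min_prominence = 0.3 * float(np.std(v))
    distance = max(1, int(round(min_distance)))
    peaks, _ = find_peaks(v, prominence=min_prominence, distance=distance)
    troughs, _ = find_peaks(-v, prominence=min_prominence, distance=distance)
    # the shrinking smoothing window under-attenuates the first/last few
    # samples, which can fake an edge peak; keep only fully smoothed indices
    edge = smooth_frames // 2
    if edge:
        peaks = peaks[(peaks >= edge) & (peaks < len(v) - edge)]
        troughs = troughs[(troughs >= edge) & (troughs < len(v) - edge)]
    if len(peaks) < 2:
        raise ValueError(
            f"found {len(peaks)} peak(s) (prominence >= {min_prominence:.3g},"
            f" distance >= {distance} frames); need >= 2 for a period")
    intervals = np.diff(peaks) * frame_interval
    return {
        "period_hours": float(intervals.mean() / 60.0),
        "sd_hours": float(intervals.std(ddof=1) / 60.0) if len(intervals) > 1
        else 0.0,
        "n_intervals": int(len(intervals)),
        "peak_times": peaks * frame_interval,
        "trough_times": troughs * frame_interval,
    }


def phase_lag(kymo: KymographData, posterior_roi: tuple[int, int],
              anterior_roi: tuple[int, int], window: int = 50) -> dict:
    """Signed posterior-anterior wave lag in minutes.

    ROIs are column index ranges ``(start, stop)`` into the kymograph (column
    0 is the posterior end of the axis).  The mean trace of each ROI is
    detrended and its Hilbert phase taken; the lag is the circular mean of
    the phase difference over the window-trimmed interior, converted to
    minutes via the posterior trace's peak-to-peak period.  Positive lag
    means the posterior oscillates ahead (a posterior->anterior wave).
    """
    n_pos = kymo.matrix.shape[1]
    for name, (a, b) in (("posterior", posterior_roi),
                         ("anterior", anterior_roi)):
        if not (0 <= a < b <= n_pos):
            raise ValueError(f"{name} ROI {(a, b)} outside kymograph columns "
                             f"0..{n_pos}")
    win = min(window, kymo.matrix.shape[0] - 1)
    tr_post = kymo.matrix[:, posterior_roi[0]:posterior_roi[1]].mean(axis=1)
    tr_ant = kymo.matrix[:, anterior_roi[0]:anterior_roi[1]].mean(axis=1)
    det_post = detrend_trace(tr_post, window=win)
    det_ant = detrend_trace(tr_ant, window=win)
    period = peak_to_peak_period(det_post, kymo.frame_interval)
    ph_post = instantaneous_phase(det_post)
    ph_ant = instantaneous_phase(det_ant)
    trim = max(1, win // 4)
    dphi = (ph_post - ph_ant)[trim:-trim]
    mean_dphi = float(np.angle(np.mean(np.exp(1j * dphi))))
    lag_min = mean_dphi / (2 * np.pi) * period["period_hours"] * 60.0
    return {"lag_min": lag_min, "mean_phase_diff_rad": mean_dphi,
            "period_hours": period["period_hours"]}


def event_period(events: EventSeries) -> dict:
    """Somite-formation period: mean successive event interval, in hours."""
    t = events.times
    if len(t) < 2:
        raise ValueError("need at least two events for a period")
    intervals = np.diff(t)
    return {
        "period_hours": float(intervals.mean() / 60.0),
        "sd_hours": float(intervals.std(ddof=1) / 60.0) if len(intervals) > 1
        else 0.0,
        "n_intervals": int(len(intervals)),
    }
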