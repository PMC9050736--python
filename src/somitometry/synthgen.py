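"""Ground-truthed synthetic somitoid images, HCR stacks and clock movies.

Every generator emits the image together with a :class:`GroundTruthRecord`
holding the quantities the analysis modules are supposed to recover (true
mask, centerline, per-somite geometry, domain volumes, oscillation period,
wave lag, event times).  All randomness is drawn from a seeded generator, so
identical spec + seed gives bit-identical output.

The default geometry and dynamics sit in the regime of day-6/7 human
somitoids: somite diameters around 104-157 µm threaded on a body a few
hundred µm long, HCR stacks at Z = 2 µm / XY = 0.391 µm voxels, and a
segmentation clock with a ~5 h period travelling posterior to anterior,
imaged every 5-10 min.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .grids import EventSeries, ImageGrid

__all__ = [
    "SomitoidSpec",
    "HcrSpec",
    "ClockSpec",
    "GroundTruthRecord",
    "generate_somitoid",
    "generate_hcr_stack",
    "generate_clock_movie",
    "generate_event_times",
    "lr_segment_at_fraction",
]


@dataclass
class GroundTruthRecord:
    """Everything the generator knows that an analysis should recover."""

    spec: dict
    mask: np.ndarray | None = None              # noiseless body mask
    centerline_s: np.ndarray | None = None      # arc-length samples, µm
    centerline_points: np.ndarray | None = None  # (n, 2) µm
    posterior_anchor: np.ndarray | None = None
    anterior_anchor: np.ndarray | None = None
    somites: list = field(default_factory=list)  # per-somite geometry dicts
    channel_masks: dict = field(default_factory=dict)
    body_volume_um3: float | None = None
    domain_volumes_um3: dict = field(default_factory=dict)
    period_min: float | None = None
    wavelength_um: float | None = None
    direction: int | None = None                 # +1: posterior -> anterior
    lag_min_per_um: float | None = None
    event_times_min: np.ndarray | None = None
    frame_shifts_px: np.ndarray | None = None


# ---------------------------------------------------------------------------
# 2-D somitoid
# ---------------------------------------------------------------------------

@dataclass
class SomitoidSpec:
    """Geometry and imaging parameters of a synthetic 2-D somitoid.

    The somitoid is a tapered body (PSM + NMPs, posterior) followed by a
    string of ball-like somites threaded on a thin backbone.  ``spacing`` is
    the somite centre-to-centre distance; it defaults to
    ``somite_diameter + gap``.
    """

    n_somites: int = 8
    somite_diameter: float = 110.0      # µm, paired-somite scale
    somite_diameters: tuple[float, ...] | None = None  # per-somite override
    gap: float = 10.0                   # µm between somite surfaces
    spacing: float | None = None        # µm centre-to-centre; default d + gap
    body_length: float = 300.0          # µm of PSM+NMP body along the midline
    body_width: float = 150.0           # µm maximal body width
    taper: float = 0.5                  # posterior tip width as a fraction
    backbone_width: float = 40.0        # µm connecting-rod width
    paired: bool = False                # two mirrored somite rows
    midline_shape: str = "straight"     # or "sinusoidal"
    amplitude: float = 30.0             # µm, sinusoidal midline only
    wavelength: float = 500.0           # µm, sinusoidal midline only
    foreground: float = 200.0
    background: float = 20.0
    noise_sigma: float = 30.0           # SNR = contrast/sigma = 6 by default
    pixel_size: float = 1.0             # µm/px, isotropic
    margin: float = 40.0                # µm canvas padding
    seed: int = 0

    def __post_init__(self) -> None:
        if self.somite_diameters is not None:
            self.somite_diameters = tuple(float(d)
                                          for d in self.somite_diameters)
            self.n_somites = len(self.somite_diameters)
            self.somite_diameter = float(np.mean(self.somite_diameters))
        if self.spacing is None:
            self.spacing = self.somite_diameter + self.gap
        if min(self.somite_diameter, self.body_length, self.body_width,
               self.pixel_size, self.spacing) <= 0:
            raise ValueError("all lengths must be positive")
        if self.n_somites < 0:
            raise ValueError("n_somites must be >= 0")
        if self.spacing < 0.8 * self.somite_diameter:
            raise ValueError("somites overlap the chain beyond tolerance "
                             f"(spacing {self.spacing} < 0.8 x diameter)")

    @property
    def snr(self) -> float:
        return ((self.foreground - self.background) / self.noise_sigma
                if self.noise_sigma > 0 else np.inf)


def _centerline_fn(spec: SomitoidSpec, total_length: float):
    """Return arrays (s, x, y) of the midline in a local frame, plus tangents.

    The midline starts at the posterior tip (s = 0).  For the sinusoidal
    shape, the curve y = A sin(2 pi x / lambda) is reparameterised by arc
    length with a fine quadrature grid.
    """
    if spec.midline_shape == "straight":
        s = np.linspace(0.0, total_length, max(int(total_length) * 4, 64))
        return s, s.copy(), np.zeros_like(s)
    if spec.midline_shape != "sinusoidal":
        raise ValueError(f"unknown midline shape {spec.midline_shape!r}")
    # over-generate in x, then cut at the requested arc length
    x_fine = np.linspace(0.0, total_length * 1.5, int(total_length * 20))
    y_fine = spec.amplitude * np.sin(2 * np.pi * x_fine / spec.wavelength)
    ds = np.hypot(np.diff(x_fine), np.diff(y_fine))
    s_fine = np.concatenate([[0.0], np.cumsum(ds)])
    s = np.linspace(0.0, total_length, max(int(total_length) * 4, 64))
    x = np.interp(s, s_fine, x_fine)
    y = np.interp(s, s_fine, y_fine)
    return s, x, y


def generate_somitoid(spec: SomitoidSpec) -> tuple[ImageGrid, GroundTruthRecord]:
    """Render a synthetic somitoid image and its ground truth.

    Geometry along the midline (arc length s from the posterior tip):

    * body: union of discs on s in [0, body_length] whose radius tapers from
      ``taper * body_width/2`` at the posterior tip to ``body_width/2``;
    * somite k (k = 0..n-1): disc of the stated diameter centred at
      ``body_length + gap' + d/2 + k * spacing`` where ``gap' = spacing - d``;
      for ``paired``, two mirrored discs offset laterally by the somite radius;
    * a backbone rod of width ``backbone_width`` threads body and somites so
      the mask is a single connected component.

    True somite boundaries (the width-profile minima) sit at the midpoints
    between neighbouring somite surfaces, so the true inter-somite distance
    equals ``spacing`` and the true width equals the somite diameter (twice
    the lateral offset plus the diameter for pairs).
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.somite_diameter
    gap = spec.spacing - d
    diams = spec.somite_diameters or (d,) * spec.n_somites
    # sequential somite centres: half-diameters plus the surface gap
    centres_s: list[float] = []
    cursor = spec.body_length + gap
    for dk in diams:
        centres_s.append(cursor + dk / 2)
        cursor += dk + gap
    total = (centres_s[-1] + diams[-1] / 2) if centres_s else spec.body_length
    s_fine, xl, yl = _centerline_fn(spec, total)

    # place the local frame on the canvas
    d_max = max(diams) if diams else d
    pad = spec.margin + spec.body_width / 2 + (d_max if spec.paired
                                               else d_max / 2)
    x0 = spec.margin + spec.body_width / 2
    xs = xl + x0
    ys = yl - yl.min() + pad
    h = int(np.ceil((ys.max() + pad) / spec.pixel_size))
    w = int(np.ceil((xs.max() + spec.margin + d_max) / spec.pixel_size))
    mask = np.zeros((h, w), dtype=bool)
    px = spec.pixel_size

    def stamp(cx: float, cy: float, r: float) -> None:
        r0 = max(int((cy - r) / px) - 1, 0)
        r1 = min(int((cy + r) / px) + 2, h)
        c0 = max(int((cx - r) / px) - 1, 0)
        c1 = min(int((cx + r) / px) + 2, w)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        sel = (xx * px - cx) ** 2 + (yy * px - cy) ** 2 <= r ** 2
        mask[r0:r1, c0:c1] |= sel

    def at(s: float) -> tuple[float, float]:
        return (float(np.interp(s, s_fine, xs)),
                float(np.interp(s, s_fine, ys)))

    def normal_at(s: float) -> np.ndarray:
        eps = 1.0
        p0 = np.array(at(max(s - eps, 0.0)))
        p1 = np.array(at(min(s + eps, total)))
        t = p1 - p0
        t /= np.linalg.norm(t)
        return np.array([-t[1], t[0]])

    # body: tapered chain of discs whose *surface* spans s in [0, body_length]
    r_tip = spec.taper * spec.body_width / 2
    for s in np.arange(r_tip, spec.body_length + 1e-9, spec.pixel_size):
        r = r_tip + (spec.body_width / 2 - r_tip) * s / spec.body_length
        if s + r > spec.body_length:
            break
        cx, cy = at(s)
        stamp(cx, cy, r)

    # backbone rod threading body and somites (somite balls form the tip)
    if centres_s:
        rod_end = centres_s[-1]
        for s in np.arange(spec.body_length - spec.backbone_width,
                           rod_end + 1e-9, spec.pixel_size):
            cx, cy = at(s)
            stamp(cx, cy, spec.backbone_width / 2)

    somites = []
    for k, (s_c, dk) in enumerate(zip(centres_s, diams)):
        cx, cy = at(s_c)
        if spec.paired:
            n = normal_at(s_c)
            off = dk / 2
            stamp(cx + off * n[0], cy + off * n[1], dk / 2)
            stamp(cx - off * n[0], cy - off * n[1], dk / 2)
            true_width = 2 * off + dk
        else:
            stamp(cx, cy, dk / 2)
            true_width = dk
        somites.append({
            "index": k + 1,
            "s_center": s_c,
            "center_xy": [cx, cy],
            "diameter": dk,
            "s_start": s_c - dk / 2 - gap / 2,
            "s_end": s_c + dk / 2 + gap / 2,
            "length": dk + gap,
            "width": true_width,
        })

    img = (spec.background + (spec.foreground - spec.background) * mask
           + rng.normal(0.0, spec.noise_sigma, mask.shape))
    img = np.clip(img, 0.0, None)

    centerline = np.stack([np.interp(s_fine, s_fine, xs), ys], axis=1)
    truth = GroundTruthRecord(
        spec=asdict(spec),
        mask=mask,
        centerline_s=s_fine,
        centerline_points=np.stack([xs, ys], axis=1),
        posterior_anchor=np.array(at(0.0)),
        anterior_anchor=np.array(at(total)),
        somites=somites,
    )
    del centerline
    grid = ImageGrid(img.astype(np.float32),
                     (spec.pixel_size, spec.pixel_size))
    return grid, truth


def lr_segment_at_fraction(truth: GroundTruthRecord, fraction: float,
                           half_length: float = 120.0,
                           tilt_deg: float = 0.0) -> np.ndarray:
    """A left-right segment crossing the true centerline at an arc fraction.

    The segment is perpendicular to the true centerline tangent (rotated by
    ``tilt_deg`` if given), centred on the crossing point — the synthetic
    analogue of the manual LR annotation of a forming first somite.
    """
    s = truth.centerline_s
    pts = truth.centerline_points
    target = fraction * s[-1]
    p = np.array([np.interp(target, s, pts[:, 0]),
                  np.interp(target, s, pts[:, 1])])
    eps = 1.0
    p0 = np.array([np.interp(target - eps, s, pts[:, 0]),
                   np.interp(target - eps, s, pts[:, 1])])
    p1 = np.array([np.interp(target + eps, s, pts[:, 0]),
                   np.interp(target + eps, s, pts[:, 1])])
    t = p1 - p0
    t /= np.linalg.norm(t)
    n = np.array([-t[1], t[0]])
    a = np.radians(tilt_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    n = rot @ n
    return np.stack([p - half_length * n, p + half_length * n])


# ---------------------------------------------------------------------------
# 3-D HCR stack
# ---------------------------------------------------------------------------

@dataclass
class HcrSpec:
    """A compact 3-channel HCR stack with posterior->anterior marker domains.

    The body is a capsule along x.  Domains, by x-position as a fraction of
    the body length: a posterior SOX2+/BRACHYURY+ cap (NMPs), an optional
    SOX2-only band (neural), a BRACHYURY-only band (PSM), and UNCX4.1+
    spheres in the anterior remainder (somites).
    """

    body_length: float = 220.0          # µm along x
    body_radius: float = 30.0           # µm
    nmp_frac: float = 0.25
    neural_frac: float = 0.0
    psm_frac: float = 0.35
    somite_style: str = "spheres"       # "spheres" | "slab" (tiles the body)
    n_spheres: int = 2
    sphere_radius: float = 20.0         # µm
    voxel: tuple[float, float, float] = (2.0, 0.391, 0.391)  # (dz, dy, dx) µm
    foreground: float = 200.0
    background: float = 10.0
    noise_sigma: float = 10.0
    margin: float = 8.0                 # µm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nmp_frac + self.neural_frac + self.psm_frac > 1.0 + 1e-9:
            raise ValueError("domain fractions along the AP axis must sum <= 1")
        if self.sphere_radius > self.body_radius:
            raise ValueError("somite spheres must fit inside the body")
        if self.somite_style not in ("spheres", "slab"):
            raise ValueError(f"unknown somite_style {self.somite_style!r}")


def _capsule_cross_section_radius(x: np.ndarray, length: float,
                                  radius: float) -> np.ndarray:
    """Radius of the capsule cross-section at axial position x (µm)."""
    cx = np.clip(x, radius, length - radius)
    inside = np.clip(radius ** 2 - (x - cx) ** 2, 0.0, None)
    return np.sqrt(inside)


def _capsule_slab_volume(x0: float, x1: float, length: float,
                         radius: float, n: int = 20001) -> float:
    """Volume of the capsule between axial planes x0 and x1, by quadrature."""
    x = np.linspace(max(x0, 0.0), min(x1, length), n)
    area = np.pi * _capsule_cross_section_radius(x, length, radius) ** 2
    return float(np.trapezoid(area, x))


def generate_hcr_stack(spec: HcrSpec = HcrSpec()
                       ) -> tuple[ImageGrid, GroundTruthRecord]:
    """Render a 3-channel anisotropic HCR stack plus analytic truth volumes.

    Channels are ordered (SOX2, BRACHYURY, UNCX4.1).  Truth domain volumes
    are computed by quadrature on the capsule cross-section (slabs) and the
    sphere formula — independent of the rasterisation.
    """
    rng = np.random.default_rng(spec.seed)
    dz, dy, dx = spec.voxel
    L, R, m = spec.body_length, spec.body_radius, spec.margin
    nz = int(np.ceil((2 * R + 2 * m) / dz))
    ny = int(np.ceil((2 * R + 2 * m) / dy))
    nx = int(np.ceil((L + 2 * m) / dx))
    z = (np.arange(nz) * dz)[:, None, None]
    y = (np.arange(ny) * dy)[None, :, None]
    x = (np.arange(nx) * dx)[None, None, :]
    zc, yc = m + R, m + R
    x_body = x - m                       # axial position within the body

    cxa = np.clip(x_body, R, L - R)
    body = ((x_body - cxa) ** 2 + (y - yc) ** 2 + (z - zc) ** 2) <= R ** 2

    x_nmp = spec.nmp_frac * L
    x_neu = x_nmp + spec.neural_frac * L
    x_psm = x_neu + spec.psm_frac * L

    sox2 = body & (x_body <= x_neu)
    bra = body & ((x_body <= x_nmp) | ((x_body > x_neu) & (x_body <= x_psm)))

    centers: list[float] = []
    if spec.somite_style == "slab":
        # densely packed somites: the whole anterior slab is UNCX4.1+, so
        # the three channels jointly tile the body
        uncx = body & (x_body > x_psm)
        somite_volume = _capsule_slab_volume(x_psm, L, L, R)
        union_volume = _capsule_slab_volume(0.0, L, L, R)
    else:
        uncx = np.zeros_like(body)
        somite_volume = 0.0
        union_volume = _capsule_slab_volume(0.0, x_psm, L, R)
        if spec.n_spheres > 0:
            r_s = spec.sphere_radius
            lo, hi = x_psm + r_s, L - r_s
            if hi < lo or (spec.n_spheres > 1
                           and (hi - lo) < (spec.n_spheres - 1) * 2 * r_s):
                raise ValueError("somite spheres do not fit disjointly in "
                                 "the anterior body; reduce n_spheres or "
                                 "sphere_radius")
            cs = np.linspace(lo, hi, spec.n_spheres) if spec.n_spheres > 1 \
                else np.array([(lo + hi) / 2])
            for c in cs:
                uncx |= ((x_body - c) ** 2 + (y - yc) ** 2
                         + (z - zc) ** 2) <= r_s ** 2
                centers.append(float(c))
            somite_volume = spec.n_spheres * 4.0 / 3.0 * np.pi * r_s ** 3
            union_volume += somite_volume

    channels = []
    for chan_mask in (sox2, bra, uncx):
        img = (spec.background
               + (spec.foreground - spec.background) * chan_mask
               + rng.normal(0.0, spec.noise_sigma, body.shape))
        channels.append(np.clip(img, 0.0, None).astype(np.float32))

    stack = ImageGrid(np.stack(channels), spec.voxel,
                      channel_names=("SOX2", "BRACHYURY", "UNCX4.1"))

    vol_nmp = _capsule_slab_volume(0.0, x_nmp, L, R)
    vol_neural = _capsule_slab_volume(x_nmp, x_neu, L, R)
    vol_psm = _capsule_slab_volume(x_neu, x_psm, L, R)
    body_volume = _capsule_slab_volume(0.0, L, L, R)
    truth = GroundTruthRecord(
        spec=asdict(spec),
        mask=body,
        channel_masks={"SOX2": sox2, "BRACHYURY": bra, "UNCX4.1": uncx},
        body_volume_um3=body_volume,
        domain_volumes_um3={
            "NMP": vol_nmp,
            "Neural": vol_neural,
            "PSM": vol_psm,
            "Somite": somite_volume,
            "Total": union_volume,      # union of all expression domains
        },
    )
    truth.spec["sphere_centers_x"] = centers
    return stack, truth


# ---------------------------------------------------------------------------
# clock movies and event series
# ---------------------------------------------------------------------------

@dataclass
class ClockSpec:
    """A luminescence movie of a clock wave travelling along the body.

    Intensity inside the body is ``baseline(t) + A cos(2 pi (t/period -
    direction * x / wavelength))`` plus Gaussian noise; x is the distance (µm)
    from the posterior end.  ``direction = +1`` makes the wave travel
    posterior -> anterior (the posterior oscillates ahead of the anterior).
    With ``couple_events``, somite-formation events are emitted at successive
    oscillation peaks at the anterior PSM position (one event per cycle).
    """

    period: float = 300.0               # min (~5 h human segmentation clock)
    wavelength: float = 400.0           # µm phase wavelength
    direction: int = 1                  # +1 posterior -> anterior, -1 reversed
    amplitude: float = 100.0
    baseline: float = 200.0
    baseline_drift: float = 0.0         # intensity units per min
    noise_sigma: float = 0.0
    n_frames: int = 60
    frame_interval: float = 10.0        # min
    body_length: float = 400.0          # µm along x
    body_width: float = 80.0            # µm
    pixel_size: float = 2.0             # µm/px
    anterior_event_frac: float = 0.8    # event read-out position, fraction of L
    couple_events: bool = True
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0)  # (rows, cols)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period <= 2 * self.frame_interval:
            raise ValueError("period must exceed twice the frame interval")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")


def generate_clock_movie(spec: ClockSpec = ClockSpec()
                         ) -> tuple[ImageGrid, GroundTruthRecord]:
    """Render the clock movie and its truth (period, wave lag, events)."""
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size
    margin = 20.0
    h = int(np.ceil((spec.body_width + 2 * margin) / px))
    w = int(np.ceil((spec.body_length + 2 * margin) / px))
    yy, xx = np.mgrid[0:h, 0:w]
    frames = np.zeros((spec.n_frames, h, w), dtype=np.float32)
    shifts = np.zeros((spec.n_frames, 2))

    for i in range(spec.n_frames):
        t = i * spec.frame_interval
        dr = spec.drift_px_per_frame[0] * i
        dc = spec.drift_px_per_frame[1] * i
        shifts[i] = (dr, dc)
        x_um = (xx - dc) * px - margin          # distance from posterior end
        y_um = (yy - dr) * px - margin
        body = ((x_um >= 0) & (x_um <= spec.body_length)
                & (y_um >= 0) & (y_um <= spec.body_width))
        phase = 2 * np.pi * (t / spec.period
                             - spec.direction * x_um / spec.wavelength)
        sig = (spec.baseline + spec.baseline_drift * t
               + spec.amplitude * np.cos(phase))
        frame = np.where(body, sig, 5.0)
        if spec.noise_sigma > 0:
            frame = frame + rng.normal(0.0, spec.noise_sigma, frame.shape)
        frames[i] = np.clip(frame, 0.0, None)

    events = None
    if spec.couple_events:
        x_a = spec.anterior_event_frac * spec.body_length
        t_max = (spec.n_frames - 1) * spec.frame_interval
        # peaks at x_a: t = period * (k + direction * x_a / wavelength)
        offset = spec.direction * x_a / spec.wavelength
        k0 = int(np.ceil(-offset))
        times = []
        k = k0
        while True:
            t_k = spec.period * (k + offset)
            if t_k > t_max:
                break
            if t_k >= 0:
                times.append(t_k)
            k += 1
        events = np.asarray(times)

    movie = ImageGrid(frames, (px, px), frame_interval=spec.frame_interval)
    truth = GroundTruthRecord(
        spec=asdict(spec),
        period_min=spec.period,
        wavelength_um=spec.wavelength,
        direction=spec.direction,
        lag_min_per_um=spec.direction * spec.period / spec.wavelength,
        event_times_min=events,
        frame_shifts_px=shifts,
    )
    return movie, truth


def generate_event_times(period: float, jitter_sigma: float, n: int,
                         seed: int = 0, start: float | None = None
                         ) -> EventSeries:
    """Somite-formation event times ``t_k = k * period + noise``, sorted.

    ``start`` defaults to ``period`` (the first somite forms one cycle in).
    """
    if n < 1:
        raise ValueError("need at least one event")
    rng = np.random.default_rng(seed)
    base = (start if start is not None else period) \
        + period * np.arange(n, dtype=float)
    times = np.sort(base + rng.normal(0.0, jitter_sigma, n))
    # enforce strict monotonicity against coincidental ties
    eps = 1e-9 * max(period, 1.0)
    for i in range(1, n):
        if times[i] <= times[i - 1]:
            times[i] = times[i - 1] + eps
    return EventSeries(times)
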