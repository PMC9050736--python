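"""TIFF/CSV/JSON I/O, run configuration and the end-to-end pipeline.

Physical quantities are serialised in µm and minutes; pixel-denominated
parameters carry a ``_px`` suffix.  Every run writes a manifest with SHA-256
checksums of its outputs, so identical config + seed gives byte-identical
manifests.
"""

from __future__ import annotations

import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .grids import ImageGrid, LabeledMask

__all__ = [
    "read_image",
    "write_mask",
    "read_mask",
    "read_points_csv",
    "write_results",
    "RunConfig",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------

_OME_SIZE = re.compile(r'PhysicalSize([XYZ])="([\d.eE+-]+)"')


def _pixel_size_from_tiff(tf: tifffile.TiffFile) -> dict[str, float]:
    """Best-effort pixel sizes (µm) from OME metadata or resolution tags."""
    sizes: dict[str, float] = {}
    if tf.ome_metadata:
        for axis, value in _OME_SIZE.findall(tf.ome_metadata):
            sizes[axis.lower()] = float(value)
        return sizes
    page = tf.pages[0]
    try:
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        unit = page.tags.get("ResolutionUnit")
        scale = {2: 25400.0, 3: 10000.0}.get(
            getattr(unit, "value", 1) if unit else 1)  # inch / cm -> µm
        if scale:
            sizes["x"] = scale * xres[1] / xres[0]
            sizes["y"] = scale * yres[1] / yres[0]
    except (KeyError, ZeroDivisionError, TypeError):
        pass
    return sizes


def read_image(path, pixel_size=None, channel_names=None,
               frame_interval=None) -> ImageGrid:
    """Read a TIFF/OME-TIFF into an :class:`ImageGrid`.

    ``pixel_size`` (per spatial axis, µm) overrides anything found in the
    file metadata; when both are present the override wins with a warning.
    A pixel size must come from one of the two sources.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = _pixel_size_from_tiff(tf)
    n_spatial = data.ndim - (1 if channel_names or frame_interval else 0)
    if pixel_size is not None:
        px = tuple(float(p) for p in np.atleast_1d(pixel_size))
        if meta:
            warnings.warn("pixel-size override supersedes file metadata",
                          stacklevel=2)
    elif meta:
        order = {2: "yx", 3: "zyx", 4: "zyx"}.get(n_spatial, "yx")[-n_spatial:]
        try:
            px = tuple(meta[a] for a in order)
        except KeyError:
            raise ValueError(f"file metadata lacks pixel sizes for axes "
                             f"{order!r}; pass pixel_size") from None
    else:
        raise ValueError(f"{path} has no pixel-size metadata; pass pixel_size")
    return ImageGrid(data, px, channel_names=channel_names,
                     frame_interval=frame_interval)


def write_mask(path, mask: LabeledMask) -> None:
    """Write a mask as 8-bit TIFF (0/255) with a JSON provenance sidecar."""
    path = Path(path)
    tifffile.imwrite(path, (mask.mask.astype(np.uint8) * 255))
    sidecar = {"pixel_size_um": list(mask.pixel_size),
               "provenance": _jsonable(mask.provenance)}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True))


def read_mask(path, pixel_size) -> LabeledMask:
    """Read a 0/255 TIFF mask written by :func:`write_mask` (or elsewhere)."""
    data = tifffile.imread(Path(path))
    prov: dict = {"source": str(path)}
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        prov.update(json.loads(sidecar.read_text()).get("provenance", {}))
    return LabeledMask(data > 0, pixel_size, prov)


def read_points_csv(path) -> dict[str, np.ndarray]:
    """Read annotation points from a ``role,x_um,y_um`` CSV.

    Roles with one row (e.g. ``posterior``, ``anterior``) map to a single
    point; repeated roles (e.g. ``lr``) map to an ``(n, 2)`` array.
    """
    df = pd.read_csv(path)
    need = {"role", "x_um", "y_um"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path} must have columns {sorted(need)}")
    out: dict[str, np.ndarray] = {}
    for role, grp in df.groupby("role", sort=False):
        pts = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        out[str(role)] = pts[0] if len(pts) == 1 else pts
    return out


# ---------------------------------------------------------------------------
# results and manifests
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


SOMITE_COLUMNS = ["index", "s_start", "s_end", "length_um", "width_um",
                  "area_um2", "circularity", "end_capped"]


def somite_calls_to_frame(calls) -> pd.DataFrame:
    rows = [{"index": c.index, "s_start": c.s_start, "s_end": c.s_end,
             "length_um": c.length, "width_um": c.width, "area_um2": c.area,
             "circularity": c.circularity, "end_capped": c.end_capped}
            for c in calls]
    return pd.DataFrame(rows, columns=SOMITE_COLUMNS)


def write_results(results: dict, out_dir, config: dict | None = None,
                  seed: int | None = None) -> dict:
    """Write stage results to ``out_dir`` and return the manifest.

    ``results`` maps artifact names to pandas DataFrames (written as CSV with
    a fixed column order), dicts/lists (JSON, sorted keys) or numpy arrays
    (TIFF for >= 2-D, CSV for 1-D).  The manifest records inputs, parameters,
    seed and a SHA-256 checksum per artifact and is itself written as
    ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = {}
    for name, obj in sorted(results.items()):
        if isinstance(obj, pd.DataFrame):
            path = out / f"{name}.csv"
            obj.to_csv(path, index=False)
        elif isinstance(obj, np.ndarray) and obj.ndim >= 2:
            path = out / f"{name}.tif"
            tifffile.imwrite(path, obj)
        elif isinstance(obj, np.ndarray):
            path = out / f"{name}.csv"
            pd.DataFrame({name: obj}).to_csv(path, index=False)
        else:
            path = out / f"{name}.json"
            path.write_text(json.dumps(_jsonable(obj), indent=2,
                                       sort_keys=True))
        entries[path.name] = _sha256(path)
    from . import __version__
    manifest = {"version": __version__, "seed": seed,
                "parameters": _jsonable(config or {}), "outputs": entries}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One flat configuration for a reproducible pipeline run.

    Defaults are the parameters established for this quantification recipe:
    resample to 1 µm/px, 10000-px hole/debris threshold, disk radius 5 px
    opening, spline smoothing 10000, extrema prominence 10 µm / separation
    40 µm, voxel (2, 0.391, 0.391) µm, 50-frame detrending window.
    """

    input: str | None = None            # image path; None -> synthetic input
    stages: tuple[str, ...] = ("segment", "morph")
    out_dir: str = "results/run"
    seed: int = 0
    # segmentation
    method: str = "auto"                # otsu | triangle | yen | auto
    target_px: float = 1.0              # µm, working resolution
    min_size_px: int = 10000
    opening_radius_px: int = 5
    mask_override: str | None = None    # externally corrected mask TIFF
    # morphometry
    anchors: str | None = None          # CSV with posterior/anterior rows
    smoothing: float = 10000.0
    step_um: float = 1.0
    min_prominence_um: float = 10.0
    min_separation_um: float = 40.0
    # volumetry
    voxel_um: tuple[float, float, float] = (2.0, 0.391, 0.391)
    channels: tuple[str, ...] = ("SOX2", "BRACHYURY", "UNCX4.1")
    # oscillation
    frame_interval_min: float = 10.0
    detrend_window: int = 50
    kymo_half_width_um: float = 20.0
    kymo_median_px: int = 3
    # synthetic input (used when input is None)
    synth: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_jsonable(asdict(self)),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("stages", "voxel_um", "channels"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages in order and write one manifest.

    ``segment`` -> ``morph`` on a 2-D image (or a seeded synthetic somitoid
    when no input is given); ``volumes`` on a multi-channel stack; ``kymo``
    on a movie.  Any stage failure is re-raised with the stage name.
    """
    from . import midline as ml
    from . import oscillation as osc
    from . import segmentation as seg
    from . import synthgen
    from . import volumetry as vol

    results: dict = {}
    truth = None
    stage = "setup"
    try:
        # early validation: fail before any heavy work
        if "morph" in config.stages and config.input is not None \
                and config.anchors is None:
            stage = "morph"
            raise ValueError("an anchors CSV is required to run the morph "
                             "stage on a file input")
        stage = "setup"
        needs_2d = "segment" in config.stages or "morph" in config.stages
        if needs_2d:
            if config.input is None:
                spec = synthgen.SomitoidSpec(seed=config.seed, **config.synth)
                image, truth = synthgen.generate_somitoid(spec)
            else:
                image = read_image(config.input,
                                   pixel_size=(config.target_px,) * 2)

        mask = None
        if "segment" in config.stages:
            stage = "segment"
            if config.mask_override is not None:
                mask = read_mask(config.mask_override,
                                 (config.target_px,) * 2)
            else:
                mask = seg.segment(image, method=config.method,
                                   target_px=config.target_px,
                                   min_size=config.min_size_px,
                                   opening_radius=config.opening_radius_px)
            results["mask"] = mask.mask.astype(np.uint8) * 255
            results["mask_provenance"] = mask.provenance

        if "morph" in config.stages:
            stage = "morph"
            if mask is None:
                raise ValueError("morph stage requires the segment stage or "
                                 "a mask override")
            if config.anchors is not None:
                pts = read_points_csv(config.anchors)
                post, ant = pts["posterior"], pts["anterior"]
            elif truth is not None:
                post = truth.posterior_anchor
                ant = truth.anterior_anchor
            else:
                raise ValueError("morph stage needs an anchors CSV")
            curve = ml.extract_midline(mask, post, ant,
                                       smoothing=config.smoothing,
                                       step=config.step_um)
            profile = ml.compute_width_profile(mask, curve,
                                               step=config.step_um)
            extrema = ml.find_profile_extrema(
                profile, min_prominence=config.min_prominence_um,
                min_separation=config.min_separation_um)
            calls = ml.call_somites(profile, extrema)
            results["somites"] = somite_calls_to_frame(calls)
            results["width_profile"] = pd.DataFrame(
                {"s_um": profile.s, "w_um": profile.w})
            results["midline"] = pd.DataFrame(
                {"s_um": curve.arc_length, "x_um": curve.points[:, 0],
                 "y_um": curve.points[:, 1]})
            results["summary"] = {"n_somite_rows": ml.count_somite_rows(calls),
                                  "midline_length_um": curve.total_length}

        if "volumes" in config.stages:
            stage = "volumes"
            if config.input is None:
                stack, _ = synthgen.generate_hcr_stack(
                    synthgen.HcrSpec(seed=config.seed))
            else:
                stack = read_image(config.input, pixel_size=config.voxel_um,
                                   channel_names=config.channels)
            masks = vol.channel_masks_3d(stack)
            total = vol.total_reference_mask(stack)
            report = vol.lineage_domain_volumes(masks, total)
            results["volumes"] = report.as_dict()

        if "kymo" in config.stages:
            stage = "kymo"
            if config.input is None:
                movie, _ = synthgen.generate_clock_movie(
                    synthgen.ClockSpec(seed=config.seed))
            else:
                movie = read_image(
                    config.input, pixel_size=(config.target_px,) * 2,
                    frame_interval=config.frame_interval_min)
            reg, drift = osc.register_frames(movie)
            dy, dx = movie.pixel_size
            h, w = movie.data.shape[1:]
            axis = np.array([[dx, (h - 1) * dy / 2],
                             [(w - 2) * dx, (h - 1) * dy / 2]])
            kymo = osc.build_kymograph(reg, axis,
                                       half_width=config.kymo_half_width_um,
                                       median_radius=config.kymo_median_px)
            results["kymograph"] = kymo.matrix.astype(np.float32)
            trace = kymo.matrix.mean(axis=1)
            det = osc.detrend_trace(
                trace, window=min(config.detrend_window, len(trace) - 1))
            period = osc.peak_to_peak_period(det, kymo.frame_interval)
            results["trace"] = pd.DataFrame(
                {"t_min": kymo.times, "raw": trace, "detrended": det})
            results["oscillation"] = {
                "period_hours": period["period_hours"],
                "sd_hours": period["sd_hours"],
                "n_intervals": period["n_intervals"]}
    except Exception as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc

    return write_results(results, config.out_dir, config=asdict(config),
                         seed=config.seed)
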