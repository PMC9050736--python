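"""Seeded validation studies: parameter recovery and oracle equivalence.

Each study generates ground-truthed synthetic data, runs the corresponding
analysis stage, and reports recovery errors.  They are the package's own
benchmark harness — used by the test suite, the acceptance script and the
numbered analysis drivers — and every study is fully determined by its seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import midline as ml
from . import oscillation as osc
from . import segmentation as seg
from . import synthgen
from . import volumetry as vol
from .grids import EventSeries, LabeledMask

__all__ = [
    "somite_recovery_study",
    "width_oracle_study",
    "midline_fidelity_study",
    "volumetry_study",
    "oscillation_study",
    "first_somite_study",
    "determinism_study",
]


def _subseeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=n)


def _analyse_somitoid(spec: synthgen.SomitoidSpec):
    img, truth = synthgen.generate_somitoid(spec)
    mask = seg.segment(img, method="yen")
    curve = ml.extract_midline(mask, truth.posterior_anchor,
                               truth.anterior_anchor)
    profile = ml.compute_width_profile(mask, curve)
    calls = ml.call_somites(profile, ml.find_profile_extrema(profile))
    return truth, mask, curve, profile, calls


def somite_recovery_study(seed: int, n_cases: int = 20) -> dict:
    """Somite count/width/length recovery on randomized somitoids.

    Each case draws 5-10 somites with diameters in 90-160 µm (the printed
    somite size range) and an imaging SNR between 3 and 6; the morphometry
    pipeline runs end to end and its calls are compared with the generator
    truth.  Width/length errors are paired by somite index on cases where
    the count is recovered exactly.
    """
    rng = np.random.default_rng(seed)
    n_correct = 0
    width_err: list[float] = []
    length_err: list[float] = []
    cases = []
    for sub in _subseeds(rng.integers(0, 2 ** 31 - 1), n_cases):
        n_som = int(rng.integers(5, 11))
        diameter = float(rng.uniform(90.0, 160.0))
        snr = float(rng.uniform(3.0, 6.0))
        spec = synthgen.SomitoidSpec(seed=int(sub), n_somites=n_som,
                                     somite_diameter=diameter,
                                     noise_sigma=180.0 / snr)
        truth, _, _, _, calls = _analyse_somitoid(spec)
        correct = len(calls) == n_som
        n_correct += correct
        case = {"n_somites": n_som, "diameter": diameter, "snr": snr,
                "n_called": len(calls)}
        if correct:
            w = [abs(c.width - t["width"])
                 for c, t in zip(calls, truth.somites)]
            ln = [abs(c.length - t["length"])
                  for c, t in zip(calls, truth.somites)]
            width_err += w
            length_err += ln
            case.update(width_mae=float(np.mean(w)),
                        length_mae=float(np.mean(ln)))
        cases.append(case)
    return {
        "n_cases": n_cases,
        "n_count_correct": int(n_correct),
        "width_mae_um": float(np.mean(width_err)) if width_err else np.nan,
        "length_mae_um": float(np.mean(length_err)) if length_err else np.nan,
        "cases": cases,
    }


def width_oracle_study(seed: int, n_cases: int = 20, step: float = 2.0) -> dict:
    """Vectorised width profile vs the brute-force marching oracle."""
    rng = np.random.default_rng(seed)
    max_dev = 0.0
    per_case = []
    for sub in _subseeds(rng.integers(0, 2 ** 31 - 1), n_cases):
        shape = "sinusoidal" if rng.random() < 0.5 else "straight"
        spec = synthgen.SomitoidSpec(
            seed=int(sub), n_somites=3, body_length=200.0,
            somite_diameter=float(rng.uniform(90.0, 160.0)),
            midline_shape=shape)
        _, mask, curve, _, _ = _analyse_somitoid(spec)
        fast = ml.compute_width_profile(mask, curve, step=step)
        slow = ml.width_profile_bruteforce(mask, curve, step=step)
        dev = float(np.abs(fast.w - slow.w).max())  # px == µm at 1 µm/px
        per_case.append({"shape": shape, "max_dev_px": dev})
        max_dev = max(max_dev, dev)
    return {"n_cases": n_cases, "max_dev_px": max_dev, "cases": per_case}


def midline_fidelity_study(seed: int, n_per_shape: int = 3) -> dict:
    """RMS deviation of the fitted midline from the generator centerline."""
    from scipy.spatial import cKDTree
    subs = _subseeds(seed, 2 * n_per_shape)
    out = {"cases": []}
    worst = 0.0
    for i, sub in enumerate(subs):
        shape = "straight" if i < n_per_shape else "sinusoidal"
        spec = synthgen.SomitoidSpec(seed=int(sub), midline_shape=shape)
        _, _, curve, _, _ = _analyse_somitoid(spec)
        img_truth = synthgen.generate_somitoid(spec)[1]
        d, _ = cKDTree(img_truth.centerline_points).query(curve.points)
        rms = float(np.sqrt(np.mean(d ** 2)))
        out["cases"].append({"shape": shape, "rms_um": rms})
        worst = max(worst, rms)
    out["max_rms_um"] = worst
    return out


def volumetry_study(seed: int) -> dict:
    """Sphere-volume accuracy, Boolean identities and HCR domain recovery."""
    # rasterized 50-µm sphere at the light-sheet voxel size
    vox = (2.0, 0.391, 0.391)
    r = 50.0
    dims = [int(2.2 * r / d) for d in vox]
    z = (np.arange(dims[0]) * vox[0])[:, None, None]
    y = (np.arange(dims[1]) * vox[1])[None, :, None]
    x = (np.arange(dims[2]) * vox[2])[None, None, :]
    c = 1.1 * r
    sphere = ((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2) <= r ** 2
    v_raster = vol.mask_volume(LabeledMask(sphere, vox))
    v_true = 4.0 / 3.0 * np.pi * r ** 3
    sphere_err_pct = 100.0 * abs(v_raster - v_true) / v_true

    # noiseless HCR fixture: Otsu masks must recover the analytic volumes
    stack, truth = synthgen.generate_hcr_stack(
        synthgen.HcrSpec(seed=seed, noise_sigma=0.0))
    masks = vol.channel_masks_3d(stack)
    total = vol.total_reference_mask(stack)
    report = vol.lineage_domain_volumes(masks, total)
    domain_err = {}
    for name in ("NMP", "PSM", "Somite"):
        t = truth.domain_volumes_um3[name]
        domain_err[name] = 100.0 * abs(report.domain_volumes[name] - t) / t
    neural_abs = report.domain_volumes["Neural"]

    # exact voxel-set identities
    t = total.mask
    s = masks["SOX2"].mask & t
    b = masks["BRACHYURY"].mask & t
    neural = s & ~b
    nmp = s & b
    psm = b & ~s
    identities_exact = bool(
        (neural.sum() + nmp.sum()) == s.sum()
        and (psm.sum() + nmp.sum()) == b.sum()
        and not np.any(neural & nmp))
    return {
        "sphere_volume_um3": v_raster,
        "sphere_error_pct": float(sphere_err_pct),
        "domain_error_pct": domain_err,
        "max_domain_error_pct": float(max(domain_err.values())),
        "neural_volume_um3": float(neural_abs),
        "identities_exact": identities_exact,
    }


def _movie_period(movie, n_cols_frac=(0.0, 0.15), window=50) -> dict:
    axis = _axis_for(movie)
    kymo = osc.build_kymograph(movie, axis, half_width=10.0)
    n = kymo.matrix.shape[1]
    c0, c1 = int(n_cols_frac[0] * n), max(int(n_cols_frac[1] * n), 2)
    trace = kymo.matrix[:, c0:c1].mean(axis=1)
    det = osc.detrend_trace(trace, window=min(window, len(trace) - 1))
    return osc.peak_to_peak_period(det, kymo.frame_interval), kymo


def _axis_for(movie):
    h = movie.data.shape[1]
    px = movie.pixel_size[0]
    margin = 20.0
    length = movie.data.shape[2] * px - 2 * margin
    return np.array([[margin, h * px / 2], [margin + length, h * px / 2]])


def oscillation_study(seed: int, n_noisy: int = 10) -> dict:
    """Clock period, wave-lag sign and clock/segmentation coupling."""
    # noiseless movie: period exact to one frame
    spec0 = synthgen.ClockSpec(seed=seed, n_frames=120, noise_sigma=0.0)
    movie, truth = synthgen.generate_clock_movie(spec0)
    res0, kymo = _movie_period(movie)
    err0 = abs(res0["period_hours"] * 60.0 - truth.period_min)

    # noisy movies: 20 % amplitude noise, mean error over seeds
    errs = []
    for sub in _subseeds(seed + 1, n_noisy):
        spec = synthgen.ClockSpec(seed=int(sub), n_frames=120,
                                  noise_sigma=0.2 * 100.0)
        m, t = synthgen.generate_clock_movie(spec)
        res, _ = _movie_period(m)
        errs.append(res["period_hours"] * 60.0 - t.period_min)
    mean_noisy_err = float(np.mean(errs))

    # wave direction: lag sign must match in every movie
    signs_ok = 0
    rng = np.random.default_rng(seed + 2)
    for sub in _subseeds(seed + 2, n_noisy):
        direction = 1 if rng.random() < 0.5 else -1
        spec = synthgen.ClockSpec(seed=int(sub), n_frames=90,
                                  direction=direction, noise_sigma=10.0)
        m, t = synthgen.generate_clock_movie(spec)
        kym = osc.build_kymograph(m, _axis_for(m), half_width=10.0)
        n = kym.matrix.shape[1]
        lag = osc.phase_lag(kym, (0, n // 8),
                            (n // 2 - n // 16, n // 2 + n // 16))
        signs_ok += int(np.sign(lag["lag_min"]) == t.direction)

    # coupling: one somite per cycle -> the two periods agree
    ev = osc.event_period(EventSeries(truth.event_times_min))
    coupling_err = abs(ev["period_hours"] - res0["period_hours"]) * 60.0
    return {
        "noiseless_period_hours": res0["period_hours"],
        "noiseless_error_min": float(err0),
        "noisy_mean_error_min": mean_noisy_err,
        "n_noisy": n_noisy,
        "lag_sign_correct": int(signs_ok),
        "n_lag_movies": n_noisy,
        "event_period_hours": ev["period_hours"],
        "coupling_error_min": float(coupling_err),
        "frame_interval_min": spec0.frame_interval,
    }


def first_somite_study(seed: int) -> dict:
    """Analytic straight-midline geometry plus sinusoidal-arc recovery."""
    from .grids import MidlineCurve
    s = np.arange(0.0, 1001.0)
    straight = MidlineCurve(np.stack([s, np.full_like(s, 50.0)], axis=1),
                            s, smoothing=0.0, step=1.0)
    ortho = ml.first_somite_metrics(
        straight, np.array([[200.0, 0.0], [200.0, 100.0]]))
    t = np.radians(30.0)
    d = np.array([np.sin(t), np.cos(t)]) * 80.0
    p = np.array([300.0, 50.0])
    tilted = ml.first_somite_metrics(straight, np.stack([p - d, p + d]))

    spec = synthgen.SomitoidSpec(seed=seed, midline_shape="sinusoidal")
    img, truth = synthgen.generate_somitoid(spec)
    mask = seg.segment(img, method="yen")
    curve = ml.extract_midline(mask, truth.posterior_anchor,
                               truth.anterior_anchor)
    lr = synthgen.lr_segment_at_fraction(truth, 0.35)
    sine = ml.first_somite_metrics(curve, lr)
    return {
        "straight_relative_position": ortho.relative_position,
        "straight_angle_deg": ortho.angle,
        "tilted_angle_deg": tilted.angle,
        "sinusoidal_fraction": sine.relative_position,
        "sinusoidal_fraction_error": abs(sine.relative_position - 0.35),
    }


def determinism_study(seed: int, out_dir) -> dict:
    """Rerun the end-to-end pipeline and compare output manifests byte-wise."""
    from .io import RunConfig, run_pipeline
    out = Path(out_dir)
    cfg = RunConfig(out_dir=str(out / "run"), seed=seed,
                    synth={"n_somites": 5})
    run_pipeline(cfg)
    first = (out / "run" / "manifest.json").read_bytes()
    run_pipeline(cfg)
    second = (out / "run" / "manifest.json").read_bytes()
    identical = first == second
    checksums = json.loads(first)["outputs"]
    return {"identical": bool(identical), "n_outputs": len(checksums)}
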