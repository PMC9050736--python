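#!/usr/bin/env python
"""Segmentation-clock dynamics on synthetic reporter movies.

Generates luminescence movies with a ~5 h oscillation travelling posterior
to anterior, builds kymographs, and measures the peak-to-peak period (clean
and under 20 % amplitude noise), the posterior-anterior phase lag sign, and
the agreement between the oscillation period and the somite-formation event
period (one somite per cycle).  Writes an example kymograph trace and the
summary under results/.
"""

import argparse
import json
import warnings
from pathlib import Path

import pandas as pd

from somitometry import oscillation as osc
from somitometry import studies, synthgen


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    warnings.simplefilter("ignore")
    args.out_dir.mkdir(parents=True, exist_ok=True)

    res = studies.oscillation_study(args.seed)
    print(f"noiseless period estimate : {res['noiseless_period_hours']:.2f} h"
          f"  (error {res['noiseless_error_min']:.1f} min)")
    print(f"noisy mean period error   : {res['noisy_mean_error_min']:.1f} min"
          f"  over {res['n_noisy']} movies")
    print(f"wave-lag sign correct     : {res['lag_sign_correct']}"
          f"/{res['n_lag_movies']} movies")
    print(f"somite-formation period   : {res['event_period_hours']:.2f} h"
          f"  (clock coupling error {res['coupling_error_min']:.1f} min)")

    # worked example: one movie -> registered kymograph -> detrended trace
    movie, truth = synthgen.generate_clock_movie(
        synthgen.ClockSpec(seed=args.seed, n_frames=120))
    reg, _ = osc.register_frames(movie)
    kymo = osc.build_kymograph(reg, studies._axis_for(reg), half_width=10.0,
                               median_radius=2)
    trace = kymo.matrix[:, : kymo.matrix.shape[1] // 8].mean(axis=1)
    det = osc.detrend_trace(trace, window=50)
    phase = osc.instantaneous_phase(det)
    pd.DataFrame({"t_min": kymo.times, "raw": trace, "detrended": det,
                  "phase_rad": phase}).to_csv(
        args.out_dir / "clock_trace.csv", index=False)
    (args.out_dir / "clock_summary.json").write_text(
        json.dumps(res, indent=2, sort_keys=True))
    print(f"wrote {args.out_dir / 'clock_trace.csv'}")


if __name__ == "__main__":
    main()
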