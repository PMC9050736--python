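#!/usr/bin/env python
"""Somite morphometry recovery study.

Generates 20 randomized synthetic somitoids (5-10 somites, diameters
spanning the 90-160 µm range of human somitoid somites, imaging SNR 3-6),
runs segmentation -> midline -> width profile -> somite calling, and compares
the called somite counts, widths and inter-somite distances with the
generator ground truth.  Writes a per-case table and a summary under
results/.
"""

import argparse
import json
import warnings
from pathlib import Path

import pandas as pd

from somitometry import studies


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    warnings.simplefilter("ignore")

    res = studies.somite_recovery_study(args.seed, n_cases=20)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(res["cases"]).to_csv(
        args.out_dir / "somite_recovery_cases.csv", index=False)
    summary = {k: res[k] for k in
               ("n_cases", "n_count_correct", "width_mae_um",
                "length_mae_um")}
    (args.out_dir / "somite_recovery_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))

    print(f"somite count recovered exactly in "
          f"{res['n_count_correct']}/{res['n_cases']} somitoids")
    print(f"mean |width error|              {res['width_mae_um']:.2f} µm")
    print(f"mean |inter-somite dist error|  {res['length_mae_um']:.2f} µm")


if __name__ == "__main__":
    main()
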