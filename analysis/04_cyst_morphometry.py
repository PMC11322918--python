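#!/usr/bin/env python
"""Cyst morphometry recovery study.

Validates the shape metrics on rasterized reference shapes (circle and 2:1
ellipse closed forms), measures protrusion-detection accuracy on seeded
cysts with known protrusions, and quantifies the top/bottom curvature
ratio on directionally vs symmetrically ruffled populations (the readout
that reports gradient-biased ruffling).  Writes
results/morphometric_closed_forms.csv, results/protrusion_recovery.csv and
results/curvature_ratio_study.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from morphflow import experiments as ex


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--n-cysts", type=int, default=200)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    m = ex.morphometric_closed_forms()
    pd.DataFrame([m]).to_csv(args.out / "morphometric_closed_forms.csv",
                             index=False)
    print("closed forms:", {k: round(v, 4) for k, v in m.items()})

    rec = ex.protrusion_recovery(n_cysts=args.n_cysts, base_seed=args.seed)
    pd.DataFrame([rec]).to_csv(args.out / "protrusion_recovery.csv", index=False)
    print(f"protrusions over {rec['n_cysts']} cysts: median angle error "
          f"{rec['median_angle_err_deg']:.2f} deg, F1 {rec['f1']:.3f}")

    ruffle = ex.ruffling_ratio_study(base_seed=args.seed)
    pd.DataFrame([ruffle]).to_csv(args.out / "curvature_ratio_study.csv",
                                  index=False)
    print(f"top-only ruffling: ratio > 1 in "
          f"{100 * ruffle['frac_directional_gt1']:.0f}% of seeds "
          f"(median ratio {ruffle['directional_median_ratio']:.2f}); "
          f"symmetric populations: mean ratio "
          f"{ruffle['symmetric_mean_ratio']:.3f} -> the ratio reports "
          "directional ruffling without bias")


if __name__ == "__main__":
    main()
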