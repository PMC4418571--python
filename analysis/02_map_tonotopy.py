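#!/usr/bin/env python
"""Travelling-wave tonotopic mapping of the synthetic hemispheres.

Simulates the ascending and descending runs, assigns per-voxel best
frequencies by lagged cross-correlation, combines the directions and
thresholds at r > 0.13 (p <= 0.05 at 240 frames).  Writes per-frequency
voxel counts and recovery/coverage summaries under results/.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from tonorep import (
    FrequencyProgression,
    SheetSpec,
    best_frequency_map,
    combine_directions,
    make_tonotopic_sheet,
    r_to_p,
    simulate_tonotopy_run,
    threshold_map,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)

    prog = FrequencyProgression()
    rng = np.random.default_rng(args.seed)
    rows, summaries = [], {}
    for hemi in ("LH", "RH"):
        gt = make_tonotopic_sheet(SheetSpec(hemisphere=hemi), seed=args.seed)
        asc = simulate_tonotopy_run(gt, prog, seed=int(rng.integers(2**31 - 1)))
        desc = simulate_tonotopy_run(gt, prog.reversed(), seed=int(rng.integers(2**31 - 1)))
        combined = combine_directions(
            best_frequency_map(asc, prog), best_frequency_map(desc, prog.reversed())
        )
        thr = threshold_map(combined, 0.13)
        resp = gt.responsive
        correct = np.isclose(combined.best_frequency, gt.best_frequency) & resp
        for f in combined.frequencies:
            sel = thr.mask & np.isclose(combined.best_frequency, f)
            rows.append({"hemisphere": hemi, "frequency_hz": f, "n_voxels": int(sel.sum())})
        summaries[hemi] = {
            "median_r_responsive": float(np.nanmedian(combined.r[resp])),
            "mask_coverage_of_responsive": float(thr.mask[resp].mean()),
            "correct_frequency_fraction": float(correct[resp & thr.mask].mean()),
        }
        print(f"{hemi}: r>0.13 covers {summaries[hemi]['mask_coverage_of_responsive']:.1%} "
              f"of responsive voxels; "
              f"{summaries[hemi]['correct_frequency_fraction']:.1%} assigned the true tone.")

    pd.DataFrame(rows).to_csv(RESULTS / "tonotopy_frequency_counts.tsv", sep="\t", index=False)
    summaries["r_threshold"] = 0.13
    summaries["p_at_threshold_n240"] = float(r_to_p(0.13, 240))
    (RESULTS / "tonotopy_summary.json").write_text(json.dumps(summaries, indent=2))
    print(f"r = 0.13 at n = 240 frames corresponds to p = {summaries['p_at_threshold_n240']:.4f}.")


if __name__ == "__main__":
    main()
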