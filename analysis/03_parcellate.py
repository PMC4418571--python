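#!/usr/bin/env python
"""Parcellate the tonotopic patch into the 10 early-stage areas.

Re-runs the mapping of step 02, delineates A1 and R from the
mirror-symmetric frequency reversal and subdivides the surround into
M1-M4 and L1-L4.  Writes the ROI table (voxel counts, centroids, Dice
against the generator's ground truth) under results/.
"""

import argparse
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from tonorep import (
    FrequencyProgression,
    SheetSpec,
    best_frequency_map,
    combine_directions,
    delineate_core,
    extract_patch,
    make_tonotopic_sheet,
    simulate_tonotopy_run,
    subdivide_surround,
    threshold_map,
)
from tonorep.sheet import LABEL_OF, ROI_NAMES

RESULTS = Path(__file__).resolve().parent.parent / "results"


def dice(a, b):
    return 2 * np.sum(a & b) / (np.sum(a) + np.sum(b))


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)

    prog = FrequencyProgression()
    rng = np.random.default_rng(args.seed)
    rows = []
    for hemi in ("LH", "RH"):
        gt = make_tonotopic_sheet(SheetSpec(hemisphere=hemi), seed=args.seed)
        asc = simulate_tonotopy_run(gt, prog, seed=int(rng.integers(2**31 - 1)))
        desc = simulate_tonotopy_run(gt, prog.reversed(), seed=int(rng.integers(2**31 - 1)))
        thr = threshold_map(
            combine_directions(
                best_frequency_map(asc, prog), best_frequency_map(desc, prog.reversed())
            ),
            0.13,
        )
        patch = extract_patch(thr.mask)
        core = delineate_core(thr, patch=patch)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rois = subdivide_surround(thr, core, patch=patch, hemisphere=hemi)
        centroids = rois.centroids
        for name in ROI_NAMES:
            rows.append(
                {
                    "hemisphere": hemi,
                    "roi": name,
                    "n_voxels": rois.counts[name],
                    "centroid_xyz": json.dumps(
                        [round(c, 2) for c in centroids[name]] if centroids[name] else None
                    ),
                    "dice_vs_truth": round(
                        float(dice(rois.labels == LABEL_OF[name], gt.roi_mask(name))), 3
                    ),
                }
            )
        n_areas = rois.n_areas
        print(f"{hemi}: {n_areas} areas; A1 Dice "
              f"{dice(core.a1_mask, gt.roi_mask('A1')):.3f}, "
              f"R Dice {dice(core.r_mask, gt.roi_mask('R')):.3f}")
    pd.DataFrame(rows).to_csv(RESULTS / "parcellation_rois.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
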