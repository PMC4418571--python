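#!/usr/bin/env python
"""Generate the synthetic study inputs.

Builds the default left- and right-hemisphere tonotopic sheets, the
travelling-wave progression and the 16-block REP/CTRL design, and records
their ground truth under results/.  Volumes are only written (to scratch/)
with --write-volumes; every later analysis step regenerates them from the
same seeds, so nothing downstream depends on large files.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from tonorep import FrequencyProgression, SheetSpec, make_block_design, make_tonotopic_sheet
from tonorep.io import write_design, write_ground_truth, write_progression
from tonorep.sheet import ROI_NAMES

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--write-volumes", action="store_true")
    args = ap.parse_args()

    RESULTS.mkdir(exist_ok=True)
    prog = FrequencyProgression()
    design = make_block_design(8, tr=2.0)
    write_progression(prog, RESULTS / "progression.json")
    write_design(design, RESULTS / "block_design.json")

    rows = []
    for hemi in ("LH", "RH"):
        gt = make_tonotopic_sheet(SheetSpec(hemisphere=hemi), seed=args.seed)
        for name in ROI_NAMES:
            mask = gt.roi_mask(name)
            rows.append(
                {
                    "hemisphere": hemi,
                    "roi": name,
                    "n_voxels": int(mask.sum()),
                    "volume_mm3": float(mask.sum() * gt.spec.voxel_size_mm**3),
                }
            )
        if args.write_volumes:
            scratch = Path(__file__).resolve().parent.parent / "scratch"
            scratch.mkdir(exist_ok=True)
            write_ground_truth(gt, scratch / f"ground_truth_{hemi}")
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "ground_truth_rois.tsv", sep="\t", index=False)

    summary = {
        "seed": args.seed,
        "progression": prog.to_dict(),
        "design": {"n_blocks": len(design.blocks), "run_duration_s": design.run_duration},
        "n_rois_per_hemisphere": len(ROI_NAMES),
    }
    (RESULTS / "simulation_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"Tonotopy: {prog.n_steps} tones, {prog.cycle_duration:.0f}-s cycle, "
          f"{prog.n_cycles} cycles per run.")
    print(f"Repetition design: {len(design.blocks)} blocks, "
          f"{design.run_duration:.0f} s, {design.n_frames} frames.")
    print(table.groupby('hemisphere')['n_voxels'].sum().to_string())


if __name__ == "__main__":
    main()
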