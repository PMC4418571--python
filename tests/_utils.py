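"""Shared helpers for the test suite."""

import numpy as np

from tonorep import TonotopicMap


def map_from_ground_truth(gt) -> TonotopicMap:
    """Ideal tonotopic map carrying the ground-truth frequencies."""
    asc = np.array(sorted(gt.spec.frequencies))
    bf = gt.best_frequency
    with np.errstate(invalid="ignore"):
        idx = np.nanargmin(
            np.abs(np.log2(np.where(np.isfinite(bf), bf, 1.0))[..., None]
                   - np.log2(asc)[None, None, None, :]),
            axis=-1,
        ).astype(float)
    idx[~np.isfinite(bf)] = np.nan
    return TonotopicMap(
        best_frequency=bf.copy(),
        r=np.where(gt.responsive, 0.9, np.nan),
        time_to_peak=np.full(gt.shape, np.nan),
        ascending_index=idx,
        mask=gt.responsive.copy(),
        frequencies=tuple(asc),
        tr=2.0,
        step_duration=2.0,
    )


def dice(a, b):
    return 2 * np.sum(a & b) / (np.sum(a) + np.sum(b))
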