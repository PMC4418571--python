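"""4D BOLD volume container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeSeries"]


@dataclass
class VolumeSeries:
    """A 4D image series (x, y, z, frame) with acquisition metadata.

    ``affine`` maps voxel indices to mm (RAS+); ``tr`` is the repetition
    time in seconds.  ``meta`` carries free-form provenance (design
    reference, generator parameters).
    """

    data: np.ndarray
    tr: float
    affine: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"VolumeSeries requires a 4D array, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("VolumeSeries contains non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.tr
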