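"""Synthetic tonotopic cortical sheet with known ground truth.

The sheet is a flat 3D slab standing in for the supratemporal plane.  Its
core holds two mirror-symmetric primary gradients: A1 runs high-to-low along
the posterior-to-anterior axis, R runs low-to-high, and the two share a
low-frequency ridge ("high-low-low-high").  The core is enclosed by a
frequency-selective surround divided into four antero-posterior sectors,
each with a medial and a lateral part (M1-M4, L1-L4, numbered posterior to
anterior), and an optional non-responsive background margin.

Axis conventions: array axis 0 is posterior-to-anterior, axis 1 runs from
the medial to the lateral edge for a left-hemisphere sheet (mirrored for the
right hemisphere), axis 2 is depth through the slab.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .designs import TONOTOPY_FREQUENCIES

__all__ = [
    "ROI_NAMES",
    "LABEL_OF",
    "NAME_OF",
    "SheetSpec",
    "GroundTruthMap",
    "make_tonotopic_sheet",
]

#: In-patch region names, in label order (label 0 is background).
ROI_NAMES: tuple[str, ...] = ("A1", "R", "M1", "M2", "M3", "M4", "L1", "L2", "L3", "L4")
LABEL_OF: dict[str, int] = {name: i + 1 for i, name in enumerate(ROI_NAMES)}
NAME_OF: dict[int, str] = {v: k for k, v in LABEL_OF.items()}


@dataclass(frozen=True)
class SheetSpec:
    """Geometry and frequency layout of a synthetic tonotopic sheet.

    ``gradient_signs`` encodes the high-low-low-high layout as the sign of
    the log-frequency gradient along the posterior-to-anterior axis for the
    posterior (A1) and anterior (R) primary field.
    """

    core_length: int = 14          # voxels per primary gradient along the AP axis
    core_width: int = 10           # voxels across the core (medial-lateral)
    surround: int = 6              # surround extent around the core, voxels
    margin: int = 1                # non-responsive background margin, voxels
    depth: int = 2                 # slab thickness, voxels
    hemisphere: str = "LH"
    frequencies: tuple[float, ...] = TONOTOPY_FREQUENCIES
    gradient_signs: tuple[int, int] = (-1, 1)   # posterior high->low, anterior low->high
    voxel_size_mm: float = 1.5
    amplitude_jitter: float = 0.2  # half-width of U[1-j, 1+j] per-voxel response gain

    def __post_init__(self) -> None:
        if self.hemisphere not in ("LH", "RH"):
            raise ValueError("hemisphere must be 'LH' or 'RH'")
        if self.gradient_signs != (-1, 1):
            raise ValueError("gradient layout must be high-low-low-high: signs (-1, 1)")
        freqs = tuple(float(f) for f in self.frequencies)
        object.__setattr__(self, "frequencies", freqs)
        if min(freqs) < 88.0 - 1e-9 or max(freqs) > 8000.0 + 1e-9:
            raise ValueError("frequency range must lie within [88, 8000] Hz")
        if self.core_length < len(freqs):
            raise ValueError(
                "grid too small: core_length must cover one voxel per frequency "
                f"({len(freqs)} needed, got {self.core_length})"
            )
        if self.core_width < 2 or self.depth < 1:
            raise ValueError("grid too small to host two gradients plus surround")
        if self.surround < 1:
            raise ValueError("surround must fully enclose the core (surround >= 1)")
        if self.margin < 0:
            raise ValueError("margin must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        nx = 2 * (self.margin + self.surround) + 2 * self.core_length
        ny = 2 * (self.margin + self.surround) + self.core_width
        return (nx, ny, self.depth)

    @property
    def n_steps(self) -> int:
        return len(self.frequencies)


@dataclass
class GroundTruthMap:
    """Per-voxel ground truth of a synthetic sheet.

    ``best_frequency`` is NaN for non-responsive (background) voxels;
    ``labels`` uses 0 for background and :data:`LABEL_OF` for the 10
    in-patch regions; ``amplitude`` is the per-voxel response gain.
    """

    best_frequency: np.ndarray
    labels: np.ndarray
    amplitude: np.ndarray
    spec: SheetSpec
    seed: int

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def responsive(self) -> np.ndarray:
        return self.labels > 0

    def roi_mask(self, name: str) -> np.ndarray:
        return self.labels == LABEL_OF[name]

    @property
    def label_names_present(self) -> set[str]:
        return {NAME_OF[v] for v in np.unique(self.labels) if v != 0}


def make_tonotopic_sheet(spec: SheetSpec = SheetSpec(), seed: int = 0) -> GroundTruthMap:
    """Generate a ground-truth sheet for the given spec.

    Core voxels carry the mirror-symmetric A1/R gradients; surround voxels
    are frequency-selective without an orderly gradient (each voxel draws
    its best frequency from the progression set, seeded); the margin is
    non-responsive.  The same (spec, seed) always yields the same map.
    """
    rng = np.random.default_rng(seed)
    nx, ny, nz = spec.shape
    m, s = spec.margin, spec.surround
    n_steps = spec.n_steps
    asc = np.array(sorted(spec.frequencies))

    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    bf = np.full((nx, ny, nz), np.nan)

    # patch bounds (inclusive-exclusive) and core bounds
    x_patch0, x_patch1 = m, nx - m
    y_patch0, y_patch1 = m, ny - m
    x_core0 = m + s
    x_core1 = x_core0 + 2 * spec.core_length
    x_mid = x_core0 + spec.core_length       # first R voxel
    y_core0 = m + s
    y_core1 = y_core0 + spec.core_width

    # --- core: A1 descends 8000 -> 88, R mirrors it
    for i in range(spec.core_length):
        step = int(np.floor(i * n_steps / spec.core_length))
        f_a1 = asc[n_steps - 1 - step]       # posterior high -> low
        f_r = asc[n_steps - 1 - step]        # mirrored: anterior low -> high
        labels[x_core0 + i, y_core0:y_core1, :] = LABEL_OF["A1"]
        bf[x_core0 + i, y_core0:y_core1, :] = f_a1
        labels[x_core1 - 1 - i, y_core0:y_core1, :] = LABEL_OF["R"]
        bf[x_core1 - 1 - i, y_core0:y_core1, :] = f_r

    # --- surround: four AP sectors x {medial, lateral}
    xs, ys, zs = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    in_patch = (
        (xs >= x_patch0) & (xs < x_patch1) & (ys >= y_patch0) & (ys < y_patch1)
    )
    in_core = labels > 0
    surround_mask = in_patch & ~in_core

    sector = np.zeros((nx, ny, nz), dtype=np.int8)
    sector[xs < x_core0] = 1
    sector[(xs >= x_core0) & (xs < x_mid)] = 2
    sector[(xs >= x_mid) & (xs < x_core1)] = 3
    sector[xs >= x_core1] = 4
    y_centre = (y_core0 + y_core1 - 1) / 2.0
    medial = ys < y_centre                    # canonical LH orientation

    for sec in (1, 2, 3, 4):
        msk = surround_mask & (sector == sec) & medial
        labels[msk] = LABEL_OF[f"M{sec}"]
        msk = surround_mask & (sector == sec) & ~medial
        labels[msk] = LABEL_OF[f"L{sec}"]

    n_surround = int(surround_mask.sum())
    bf[surround_mask] = rng.choice(asc, size=n_surround)

    amplitude = np.zeros((nx, ny, nz))
    j = spec.amplitude_jitter
    responsive = labels > 0
    amplitude[responsive] = rng.uniform(1.0 - j, 1.0 + j, size=int(responsive.sum()))

    if spec.hemisphere == "RH":               # mirror the medial-lateral axis
        labels = labels[:, ::-1, :].copy()
        bf = bf[:, ::-1, :].copy()
        amplitude = amplitude[:, ::-1, :].copy()

    return GroundTruthMap(
        best_frequency=bf, labels=labels, amplitude=amplitude, spec=spec, seed=seed
    )
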