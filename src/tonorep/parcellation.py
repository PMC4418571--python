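"""Parcellation of a tonotopic patch into the 10 early-stage areas.

The primary core is found from the mirror-symmetric frequency reversal: in
every medial-lateral column of the suprathreshold patch the log-frequency
profile along the posterior-to-anterior axis is tested for a
high-to-low-to-high "V" with near-monotone flanks spanning at least half of
the frequency range.  The trough line of qualifying columns is the A1/R
border (A1 posterior, R anterior); the outer borders sit at the outer
high-frequency representations.  The three border lines are then extended
straight across the patch, cutting the surround into four antero-posterior
sectors, and each sector is split into a medial and a lateral part at the
core's mid-line, yielding M1-M4 and L1-L4 (posterior to anterior) around A1
and R.

The drawing rules mirror a manual delineation protocol; automation makes
them deterministic: ties at borders go to the more posterior / more medial
label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .sheet import LABEL_OF, NAME_OF, ROI_NAMES
from .tonotopy import TonotopicMap

__all__ = [
    "NoCoreFoundError",
    "CoreDelineation",
    "RoiSet",
    "extract_patch",
    "delineate_core",
    "subdivide_surround",
    "roiset_to_label_volume",
]


class NoCoreFoundError(ValueError):
    """Raised when no mirror-symmetric frequency reversal is present."""


@dataclass
class CoreDelineation:
    """A1 and R masks plus the low-frequency border ridge between them."""

    a1_mask: np.ndarray
    r_mask: np.ndarray
    ridge_mask: np.ndarray
    posterior_border: float      # x of the posterior outer high-frequency border
    ar_border: float             # x between the last A1 and first R voxel
    anterior_border: float       # x of the anterior outer high-frequency border
    axis: int

    @property
    def core_mask(self) -> np.ndarray:
        return self.a1_mask | self.r_mask


@dataclass
class RoiSet:
    """Disjoint labelling of a patch into the 10 early-stage areas."""

    labels: np.ndarray
    names: tuple[str, ...] = ROI_NAMES
    provenance: dict = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {name: int((self.labels == LABEL_OF[name]).sum()) for name in self.names}

    @property
    def centroids(self) -> dict[str, tuple[float, ...] | None]:
        out: dict[str, tuple[float, ...] | None] = {}
        for name in self.names:
            idx = np.argwhere(self.labels == LABEL_OF[name])
            out[name] = tuple(idx.mean(axis=0)) if idx.size else None
        return out

    def mask(self, name: str) -> np.ndarray:
        return self.labels == LABEL_OF[name]

    @property
    def n_areas(self) -> int:
        return int(np.sum([c > 0 for c in self.counts.values()]))


def extract_patch(mask: np.ndarray) -> np.ndarray:
    """Largest 26-connected component of a boolean mask, with interior holes
    filled per depth slice — the outlined patch is a contiguous region, and
    isolated subthreshold voxels inside it still belong to the patch."""
    lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    patch = lab == (1 + int(np.argmax(sizes)))
    for z in range(patch.shape[2]):
        patch[:, :, z] = ndimage.binary_fill_holes(patch[:, :, z])
    return patch


def _smooth_logf(tmap: TonotopicMap, patch: np.ndarray) -> np.ndarray:
    """Median-smoothed log2 best frequency over the patch (NaN elsewhere).

    The median runs over the 3x3 neighbourhood orthogonal to the
    posterior-to-anterior axis, so single-voxel estimation errors are
    suppressed without blurring the frequency gradient itself.
    """
    valid = patch & tmap.mask & np.isfinite(tmap.best_frequency)
    logf = np.full(tmap.shape, np.nan)
    logf[valid] = np.log2(tmap.best_frequency[valid])

    def nanmed(values: np.ndarray) -> float:
        v = values[np.isfinite(values)]
        return float(np.median(v)) if v.size else np.nan

    footprint = np.ones((1, 3, 3), dtype=bool)
    out = ndimage.generic_filter(logf, nanmed, footprint=footprint, mode="constant", cval=np.nan)
    # isolated excluded voxels inside the patch take their neighbourhood
    # median, so single masked voxels do not cut a column profile in two
    out[~patch] = np.nan
    return out


def _column_core(
    v: np.ndarray,
    half_span: float,
    flank_length: int,
    min_flank_steps: int = 3,
    corr_min: float = 0.8,
) -> tuple[int, int, int, int] | None:
    """Detect the high-low-high reversal in one column profile.

    The profile around the global log-frequency trough is compared to a
    symmetric V template over a window of ``flank_length`` voxels per side
    (the span of one full gradient).  A column qualifies as core when the
    V correlation reaches ``corr_min`` and both flanks rise by at least
    ``half_span`` octaves within the window.  Returns the window maxima as
    (posterior_border, trough_start, trough_end, anterior_border), or None.
    """
    finite = np.isfinite(v)
    if finite.sum() < 2 * min_flank_steps + 1:
        return None
    t0 = int(np.nanargmin(v))
    vmin = v[t0]
    t1 = t0
    while t1 + 1 < v.size and np.isfinite(v[t1 + 1]) and v[t1 + 1] == vmin:
        t1 += 1

    lo = max(0, t0 - flank_length)
    hi = min(v.size - 1, t1 + flank_length)
    post = v[lo : t0 + 1]
    ant = v[t1 : hi + 1]
    if np.isfinite(post).sum() < min_flank_steps + 1:
        return None
    if np.isfinite(ant).sum() < min_flank_steps + 1:
        return None
    if np.nanmax(post) - vmin < half_span or np.nanmax(ant) - vmin < half_span:
        return None

    window = v[lo : hi + 1]
    template = np.abs(np.arange(lo, hi + 1) - (t0 + t1) / 2.0)
    use = np.isfinite(window)
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(template[use], window[use])[0, 1]
    if not (np.isfinite(c) and c >= corr_min):
        return None

    # borders at the outermost window maxima (ties resolve outward)
    p = lo + int(np.nanargmax(post))
    ant_rev = ant[::-1]
    a = hi - int(np.nanargmax(ant_rev))
    return p, t0, t1, a


def delineate_core(
    tmap: TonotopicMap,
    patch: np.ndarray | None = None,
    axis: int = 0,
    min_flank_steps: int = 3,
) -> CoreDelineation:
    """Delineate A1 and R from the frequency reversal of a masked map.

    ``axis`` is the posterior-to-anterior array axis.  Columns whose profile
    shows the full reversal (both flanks spanning at least half the
    log-frequency range) anchor the three border lines — the posterior and
    anterior outer high-frequency borders and the A1/R border along the
    low-frequency trough — as medians across columns, i.e. the borders are
    drawn straight.  The core's width additionally includes contiguous
    columns meeting a weaker reversal criterion (half the span requirement),
    which keeps the medial/lateral extent stable when edge columns are
    noisy.  A1 is the region between the posterior border and the trough
    (the posterior half of the trough run included), R the region between
    trough and anterior border.
    """
    if patch is None:
        patch = extract_patch(tmap.mask)
    if axis != 0:
        raise NotImplementedError("posterior-to-anterior axis must be axis 0")
    if not patch.any():
        raise NoCoreFoundError("empty patch: no core found")

    logf = _smooth_logf(tmap, patch)
    freqs = np.asarray(tmap.frequencies)
    half_span = (np.log2(freqs.max()) - np.log2(freqs.min())) / 2.0
    flank_length = len(freqs) - 1              # voxel span of one full gradient

    nx, ny, nz = logf.shape
    col_strong = np.zeros((ny, nz), dtype=bool)
    col_weak = np.zeros((ny, nz), dtype=bool)
    col_res: dict[tuple[int, int], tuple[int, int, int, int]] = {}

    for y in range(ny):
        for z in range(nz):
            res = _column_core(
                logf[:, y, z], half_span, flank_length, min_flank_steps, corr_min=0.8
            )
            if res is not None:
                col_strong[y, z] = True
                col_res[(y, z)] = res
            else:
                res = _column_core(
                    logf[:, y, z], half_span / 2.0, flank_length, min_flank_steps,
                    corr_min=0.6,
                )
                if res is not None:
                    col_weak[y, z] = True
                    col_res[(y, z)] = res

    if not col_strong.any():
        raise NoCoreFoundError("no mirror-symmetric frequency reversal found")

    # the largest connected block of strong columns anchors the core
    eight = np.ones((3, 3), dtype=int)
    lab, n = ndimage.label(col_strong, structure=eight)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    anchor = lab == (1 + int(np.argmax(sizes)))

    posts, ars, ants = [], [], []
    for (y, z), (p, t0, t1, a) in col_res.items():
        if anchor[y, z]:
            mid = t0 + (t1 - t0) // 2          # posterior-biased split of the trough run
            posts.append(p)
            ars.append(mid + 0.5)
            ants.append(a)
    x_post = float(np.median(posts))
    x_ar = float(np.median(ars))
    x_ant = float(np.median(ants))

    # weak columns widen the core only where their trough sits on the same
    # ridge as the strong block (keeps median-filter bleed at the core's
    # flanks from recruiting surround columns)
    for (y, z), (p, t0, t1, a) in col_res.items():
        if col_weak[y, z] and abs((t0 + t1) / 2.0 - x_ar) > 1.0:
            col_weak[y, z] = False
    lab_all, _ = ndimage.label(anchor | col_weak, structure=eight)
    anchor_labels = np.unique(lab_all[anchor])
    col_keep = np.isin(lab_all, anchor_labels) & (lab_all > 0)

    a1 = np.zeros_like(patch, dtype=bool)
    rr = np.zeros_like(patch, dtype=bool)
    ridge = np.zeros_like(patch, dtype=bool)
    xs = np.arange(nx)
    a1_span = (xs >= x_post) & (xs < x_ar)
    r_span = (xs > x_ar) & (xs <= x_ant)
    for y in range(ny):
        for z in range(nz):
            if not col_keep[y, z]:
                continue
            a1[a1_span, y, z] = True
            rr[r_span, y, z] = True
            if (y, z) in col_res:
                _, t0, t1, _ = col_res[(y, z)]
                ridge[t0 : t1 + 1, y, z] = True

    a1 &= patch
    rr &= patch
    return CoreDelineation(
        a1_mask=a1,
        r_mask=rr,
        ridge_mask=ridge & patch,
        posterior_border=x_post,
        ar_border=x_ar,
        anterior_border=x_ant,
        axis=axis,
    )


def subdivide_surround(
    tmap: TonotopicMap,
    core: CoreDelineation,
    patch: np.ndarray | None = None,
    hemisphere: str = "LH",
) -> RoiSet:
    """Split the suprathreshold surround of A1/R into the 8 non-primary areas.

    The A1/R border and the outer core borders are extended straight across
    the patch, cutting it into four antero-posterior sectors; each sector's
    surround is split into a medial and a lateral part at the core
    mid-line.  Labels are numbered posterior to anterior: sector 1 is
    posterior of the core (M1/L1), sectors 2 and 3 flank A1 and R (M2/L2,
    M3/L3) and sector 4 is anterior (M4/L4).
    """
    if patch is None:
        patch = extract_patch(tmap.mask)
    labels = np.zeros(patch.shape, dtype=np.int16)
    labels[core.a1_mask] = LABEL_OF["A1"]
    labels[core.r_mask] = LABEL_OF["R"]

    core_idx = np.argwhere(core.core_mask)
    if core_idx.size == 0:
        raise NoCoreFoundError("core masks are empty")
    y_mid = core_idx[:, 1].mean()

    xs, ys, _ = np.meshgrid(
        np.arange(patch.shape[0]), np.arange(patch.shape[1]), np.arange(patch.shape[2]),
        indexing="ij",
    )
    sector = np.full(patch.shape, 0, dtype=np.int8)
    sector[xs < core.posterior_border] = 1
    sector[(xs >= core.posterior_border) & (xs < core.ar_border)] = 2
    sector[(xs >= core.ar_border) & (xs <= core.anterior_border)] = 3
    sector[xs > core.anterior_border] = 4

    if hemisphere == "LH":
        medial = ys <= y_mid                   # ties go to the medial label
    elif hemisphere == "RH":
        medial = ys >= y_mid
    else:
        raise ValueError("hemisphere must be 'LH' or 'RH'")

    surround = patch & (labels == 0)
    for sec in (1, 2, 3, 4):
        labels[surround & (sector == sec) & medial] = LABEL_OF[f"M{sec}"]
        labels[surround & (sector == sec) & ~medial] = LABEL_OF[f"L{sec}"]

    rois = RoiSet(
        labels=labels,
        provenance={
            "hemisphere": hemisphere,
            "axis": core.axis,
            "posterior_border": core.posterior_border,
            "ar_border": core.ar_border,
            "anterior_border": core.anterior_border,
            "y_midline": float(y_mid),
        },
    )
    # core touching the patch edge medially/laterally starves the strip ROIs
    for name, count in rois.counts.items():
        if count == 0:
            warnings.warn(f"ROI {name} is empty", stacklevel=2)
    return rois


def roiset_to_label_volume(
    rois: RoiSet, slab_halfwidth_mm: float = 1.0, voxel_size_mm: float = 1.0
) -> np.ndarray:
    """Label volume restricted to a slab around the sheet's mid-plane.

    Depth slices whose centre lies farther than ``slab_halfwidth_mm`` from
    the mid-plane are cleared; the nearest slice(s) are always kept, so a
    half-width of 0 yields single-voxel-thick labels.
    """
    if slab_halfwidth_mm < 0:
        raise ValueError("slab halfwidth must be >= 0")
    nz = rois.labels.shape[2]
    zc = (nz - 1) / 2.0
    dist = np.abs(np.arange(nz) - zc) * voxel_size_mm
    keep = dist <= max(slab_halfwidth_mm, dist.min() + 1e-9)
    out = rois.labels.copy()
    out[:, :, ~keep] = 0
    return out
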