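"""Travelling-wave tonotopic mapping by lagged cross-correlation.

Each voxel's time course is correlated against a canonical single-step
response shifted by every lag of one stimulus cycle; the best lag dates the
stimulus step that drove the voxel, and hence its best frequency.  Because
the reference is the HRF-convolved step, the hemodynamic delay of the
assumed model is already discounted at this stage; any residual delay bias
(a wrong assumed HRF) shifts ascending- and descending-run estimates in
opposite directions along the frequency axis and cancels when the two maps
are combined on the log-frequency scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .designs import FrequencyProgression
from .hrf import DEFAULT_HRF, HemodynamicModel
from .volume import VolumeSeries

__all__ = [
    "TonotopicMap",
    "build_reference_cycle",
    "best_frequency_map",
    "combine_directions",
    "r_to_p",
    "threshold_map",
]


@dataclass
class TonotopicMap:
    """Per-voxel best frequency, peak correlation and time-to-peak.

    ``ascending_index`` is the real-valued position of the estimate on the
    ascending half-octave step axis (it may extend half a cycle beyond the
    band edges when the best lag falls in the silent pause; the snapped
    ``best_frequency`` is always one of the presented tones).  ``mask``
    marks voxels with a valid estimate; ``excluded`` records why voxels
    were dropped.
    """

    best_frequency: np.ndarray
    r: np.ndarray
    time_to_peak: np.ndarray
    ascending_index: np.ndarray
    mask: np.ndarray
    frequencies: tuple[float, ...]
    tr: float
    step_duration: float
    excluded: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.r.shape


def build_reference_cycle(
    prog: FrequencyProgression,
    hrf: HemodynamicModel = DEFAULT_HRF,
    tr: float = 2.0,
    dt: float = 0.1,
) -> np.ndarray:
    """Steady-state periodic response to one 2-s step at cycle start, sampled at ``tr``."""
    cycle = prog.cycle_duration
    n_samples = cycle / tr
    if abs(n_samples - round(n_samples)) > 1e-9:
        raise ValueError(f"tr={tr} does not divide the cycle duration {cycle}")
    n_samples = int(round(n_samples))
    # simulate a few cycles and keep the last one so wrap-around is steady-state
    n_warm = max(3, int(np.ceil(hrf.duration / cycle)) + 1)
    t = np.arange(0.0, n_warm * cycle, dt)
    neural = ((np.mod(t, cycle)) < prog.step_duration).astype(float)
    resp = hrf.convolve(neural, dt)
    idx = np.round(((n_warm - 1) * cycle + np.arange(n_samples) * tr) / dt).astype(int)
    return resp[idx]


def _virtual_step_position(pos: np.ndarray, n_steps: int, positions_per_cycle: float) -> np.ndarray:
    """Resolve lag positions falling in the silent pause.

    ``pos`` is the lag expressed in step units.  Positions beyond the last
    step are mapped to whichever band edge is circularly closer: kept as an
    extrapolation above the top step, or wrapped below the first one.
    """
    pos = pos.astype(float).copy()
    in_pause = pos >= n_steps
    dist_top = pos - (n_steps - 1)
    dist_wrap = positions_per_cycle - pos
    wrap = in_pause & (dist_wrap < dist_top)
    pos[wrap] = pos[wrap] - positions_per_cycle
    return pos


def best_frequency_map(
    run: VolumeSeries,
    prog: FrequencyProgression,
    hrf: HemodynamicModel = DEFAULT_HRF,
) -> TonotopicMap:
    """Assign a best frequency to every voxel of a travelling-wave run.

    For each voxel, the Pearson correlation against the reference cycle is
    evaluated at every lag of one cycle (ties broken toward the earliest
    lag); the winning lag dates the driving stimulus step.  Voxels with a
    constant time course have no defined correlation and are excluded from
    the mask with reason ``"constant"``.
    """
    cycle = prog.cycle_duration
    n_per_cycle = int(round(cycle / run.tr))
    ref_cycle = build_reference_cycle(prog, hrf, tr=run.tr)
    n_frames = run.n_frames
    if n_frames % n_per_cycle != 0:
        raise ValueError(
            f"run frame count {n_frames} is not a whole number of {n_per_cycle}-frame cycles"
        )
    n_cycles = n_frames // n_per_cycle

    refs = np.empty((n_per_cycle, n_frames))
    base = np.tile(ref_cycle, n_cycles)
    for lag in range(n_per_cycle):
        refs[lag] = np.roll(base, lag)
    refs_z = (refs - refs.mean(axis=1, keepdims=True)) / refs.std(axis=1, keepdims=True)

    spatial_shape = run.data.shape[:3]
    flat = run.data.reshape(-1, n_frames).astype(float)
    mean = flat.mean(axis=1, keepdims=True)
    sd = flat.std(axis=1, keepdims=True)
    constant = (sd[:, 0] == 0)
    sd[constant] = 1.0
    z = (flat - mean) / sd
    r_all = z @ refs_z.T / n_frames            # voxels x lags
    best_lag = np.argmax(r_all, axis=1)        # first maximum -> earliest lag
    r = r_all[np.arange(r_all.shape[0]), best_lag]
    r[constant] = np.nan

    ttp = best_lag * run.tr
    pos = ttp / prog.step_duration
    positions_per_cycle = cycle / prog.step_duration
    vpos = _virtual_step_position(pos, prog.n_steps, positions_per_cycle)

    if prog.direction == "ascending":
        asc_index = vpos
    else:
        asc_index = (prog.n_steps - 1) - vpos

    asc_freqs = np.array(sorted(prog.frequencies))
    snap = np.clip(np.floor(vpos + 1e-9), 0, prog.n_steps - 1).astype(int)
    presented = np.array(prog.frequencies)[snap]

    mask = ~constant
    excluded = {"constant": constant.reshape(spatial_shape)}
    bf = presented.astype(float)
    bf[constant] = np.nan

    return TonotopicMap(
        best_frequency=bf.reshape(spatial_shape),
        r=r.reshape(spatial_shape),
        time_to_peak=ttp.reshape(spatial_shape).astype(float),
        ascending_index=asc_index.reshape(spatial_shape),
        mask=mask.reshape(spatial_shape),
        frequencies=tuple(asc_freqs),
        tr=run.tr,
        step_duration=prog.step_duration,
        excluded=excluded,
    )


def combine_directions(
    asc: TonotopicMap, desc: TonotopicMap, max_disagreement_steps: float = 2.0
) -> TonotopicMap:
    """Average an ascending-run and a descending-run map.

    Best frequencies are combined as the mean position on the (log-scaled)
    half-octave step axis — i.e. the geometric mean frequency — and snapped
    to the nearest presented tone (exact half-step ties round toward the
    lower frequency).  A residual hemodynamic-delay bias shifts the two
    directions' positions by opposite amounts, so it cancels here.  Voxels
    whose direction estimates disagree by more than
    ``max_disagreement_steps`` half-octave steps are flagged unreliable and
    excluded from the mask.
    """
    if asc.shape != desc.shape:
        raise ValueError("maps come from different grids")
    if asc.frequencies != desc.frequencies:
        raise ValueError("maps use different frequency sets")
    n_steps = len(asc.frequencies)
    combined = (asc.ascending_index + desc.ascending_index) / 2.0
    disagree = np.abs(asc.ascending_index - desc.ascending_index) > max_disagreement_steps
    idx = np.ceil(combined - 0.5)              # round, half-ties toward lower index
    idx = np.clip(idx, 0, n_steps - 1)
    valid = asc.mask & desc.mask & ~disagree
    bf = np.where(valid, np.array(asc.frequencies)[idx.astype(int)], np.nan)
    r = (asc.r + desc.r) / 2.0
    excluded = {
        "constant": asc.excluded.get("constant", ~asc.mask) | desc.excluded.get("constant", ~desc.mask),
        "disagreement": disagree,
    }
    return TonotopicMap(
        best_frequency=bf,
        r=r,
        time_to_peak=(asc.time_to_peak + desc.time_to_peak) / 2.0,
        ascending_index=combined,
        mask=valid,
        frequencies=asc.frequencies,
        tr=asc.tr,
        step_duration=asc.step_duration,
        excluded=excluded,
    )


def r_to_p(r, n: int):
    """Two-tailed p-value of a Pearson correlation under the exact null.

    Uses the t transform with n-2 degrees of freedom.  ``|r| >= 1`` maps to
    p = 0.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    r_arr = np.asarray(r, dtype=float)
    out = np.empty_like(r_arr)
    extreme = np.abs(r_arr) >= 1.0
    out[extreme] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r_arr * np.sqrt((n - 2) / (1.0 - r_arr**2))
    ok = ~extreme
    out[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n - 2)
    return out if out.ndim else float(out)


def threshold_map(tmap: TonotopicMap, r_min: float) -> TonotopicMap:
    """Restrict the mask to voxels with r strictly above ``r_min``."""
    with np.errstate(invalid="ignore"):
        above = tmap.r > r_min
    return TonotopicMap(
        best_frequency=tmap.best_frequency,
        r=tmap.r,
        time_to_peak=tmap.time_to_peak,
        ascending_index=tmap.ascending_index,
        mask=tmap.mask & above,
        frequencies=tmap.frequencies,
        tr=tmap.tr,
        step_duration=tmap.step_duration,
        excluded=dict(tmap.excluded),
    )
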