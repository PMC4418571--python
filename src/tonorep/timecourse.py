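"""Block time-course extraction and repetition-effect statistics.

ROI time courses are built by averaging the signal over the ROI's voxels,
cutting a 15-frame window from each 30-s block, converting to % signal
change against the mean of the two pre-onset frames, averaging blocks of
the same condition across runs and subtracting the first frame.

Segmentation into rise / plateau / decay follows the consecutive-frame
slope logic: the 14 frame-to-frame differences are tested against zero
with paired t-tests across subjects (two-sided, alpha 0.05, uncorrected);
significantly positive slopes mark a rise, significantly negative ones a
decay, anything else a plateau, and a phase is only reported where at
least two consecutive transitions agree (isolated singletons are absorbed
into their surroundings, ties toward plateau).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .designs import BlockDesign
from .hrf import DEFAULT_HRF, HemodynamicModel
from .parcellation import RoiSet
from .volume import VolumeSeries

__all__ = [
    "FRAMES_PER_BLOCK",
    "RoiTimeCourse",
    "SegmentLabels",
    "ContrastResult",
    "AnovaResult",
    "ExtremaStats",
    "extract_block_timecourses",
    "timecourses_to_frame",
    "segment_phases",
    "contrast_conditions",
    "anova_2x2_timepoint",
    "extrema_stats",
    "glm_sound_vs_rest",
]

FRAMES_PER_BLOCK = 15
_BASELINE_FRAMES = 2


@dataclass
class RoiTimeCourse:
    """Condition-specific block-averaged % signal change of one ROI."""

    roi: str
    condition: str
    values: np.ndarray
    n_blocks: int
    subject: str | None = None
    hemisphere: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != FRAMES_PER_BLOCK:
            raise ValueError(f"a block time course has {FRAMES_PER_BLOCK} frames")
        if abs(self.values[0]) > 1e-9:
            raise ValueError("time course must be normalised to the first frame")


def extract_block_timecourses(
    runs: VolumeSeries | list[VolumeSeries],
    rois: RoiSet,
    design: BlockDesign,
    subject: str | None = None,
    hemisphere: str | None = None,
) -> list[RoiTimeCourse]:
    """Per-ROI, per-condition block-averaged time courses of one or more runs.

    Blocks whose window extends past the end of a run are dropped with a
    warning.  The baseline of each block is the mean of the two frames
    preceding its onset (the first block, which has none, uses the first
    frames of the run).
    """
    if isinstance(runs, VolumeSeries):
        runs = [runs]
    tr = design.tr
    frames_per_block = int(round((design.blocks[0].duration) / tr))
    if frames_per_block != FRAMES_PER_BLOCK:
        raise ValueError(
            f"block duration / tr must give {FRAMES_PER_BLOCK} frames, got {frames_per_block}"
        )

    out: list[RoiTimeCourse] = []
    roi_names = [n for n, c in rois.counts.items() if c > 0]
    for name in roi_names:
        mask = rois.mask(name)
        per_cond: dict[str, list[np.ndarray]] = {"REP": [], "CTRL": []}
        for run in runs:
            if run.data.shape[:3] != rois.labels.shape:
                raise ValueError("run and ROI set use different grids")
            ts = run.data[mask].mean(axis=0)
            for block in design.blocks:
                onset = int(round(block.onset / tr))
                stop = onset + FRAMES_PER_BLOCK
                if stop > ts.size:
                    warnings.warn(
                        f"block at {block.onset}s extends past the run end; dropped",
                        stacklevel=2,
                    )
                    continue
                if onset >= _BASELINE_FRAMES:
                    baseline = ts[onset - _BASELINE_FRAMES : onset].mean()
                else:
                    baseline = ts[:_BASELINE_FRAMES].mean()
                psc = (ts[onset:stop] - baseline) / baseline * 100.0
                per_cond[block.condition].append(psc)
        for cond, windows in per_cond.items():
            if not windows:
                continue
            mean = np.mean(windows, axis=0)
            mean = mean - mean[0]              # normalise to the first time point
            out.append(
                RoiTimeCourse(
                    roi=name,
                    condition=cond,
                    values=mean,
                    n_blocks=len(windows),
                    subject=subject,
                    hemisphere=hemisphere,
                )
            )
    return out


def timecourses_to_frame(tcs: list[RoiTimeCourse]) -> pd.DataFrame:
    """Tidy DataFrame (subject, hemisphere, roi, condition, frame, value)."""
    rows = []
    for tc in tcs:
        for i, v in enumerate(tc.values):
            rows.append(
                {
                    "subject": tc.subject,
                    "hemisphere": tc.hemisphere,
                    "roi": tc.roi,
                    "condition": tc.condition,
                    "frame": i,
                    "value": v,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SegmentLabels:
    """Slope tests and phase labels of the 14 frame transitions."""

    slope_t: np.ndarray
    slope_p: np.ndarray
    labels: list[str]                  # per transition: rise | plateau | decay
    windows: dict[str, tuple[float, float] | None]
    tr: float
    alpha: float

    def phase_of_frame_time(self, t: float) -> str | None:
        for phase in ("rise", "plateau", "decay"):
            w = self.windows.get(phase)
            if w is not None and w[0] <= t <= w[1]:
                return phase
        return None


def _absorb_singletons(labels: list[str]) -> list[str]:
    """Absorb isolated interior labels into their surroundings.

    A transition whose label differs from both neighbours takes their
    common label, or 'plateau' when the neighbours disagree.
    """
    out = list(labels)
    for _ in range(len(out)):                  # bounded: each pass must change something
        changed = False
        for i in range(1, len(out) - 1):
            left, mid, right = out[i - 1], out[i], out[i + 1]
            if mid != left and mid != right:
                new = left if left == right else "plateau"
                if new != mid:
                    out[i] = new
                    changed = True
        if not changed:
            break
    return out


def _runs_of(labels: list[str], phase: str) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, lab in enumerate(labels + ["__end__"]):
        if lab == phase and start is None:
            start = i
        elif lab != phase and start is not None:
            runs.append((start, i - 1))
            start = None
    return runs


def segment_phases(
    values: np.ndarray, tr: float = 2.0, alpha: float = 0.05, min_run: int = 2
) -> SegmentLabels:
    """Segment block time courses into rise, plateau and decay.

    ``values`` is (n_subjects, 15).  Transition ``i`` covers the interval
    [i*tr, (i+1)*tr] after block onset.  The reported rise window is the
    first run of >= ``min_run`` rise transitions, the decay window the
    first run of >= ``min_run`` decay transitions after the rise, and the
    plateau spans the interval between them.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != FRAMES_PER_BLOCK:
        raise ValueError(f"values must be (n_subjects, {FRAMES_PER_BLOCK})")
    n_subjects = values.shape[0]
    if n_subjects < 3:
        raise ValueError("segmentation needs at least 3 subjects")

    slopes = np.diff(values, axis=1)           # (n, 14)
    res = stats.ttest_1samp(slopes, 0.0, axis=0)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isfinite(p), p, 1.0)
    mean_slope = slopes.mean(axis=0)

    raw = []
    for i in range(slopes.shape[1]):
        if p[i] < alpha and mean_slope[i] > 0:
            raw.append("rise")
        elif p[i] < alpha and mean_slope[i] < 0:
            raw.append("decay")
        else:
            raw.append("plateau")
    labels = _absorb_singletons(raw)

    def window(run: tuple[int, int]) -> tuple[float, float]:
        return (run[0] * tr, (run[1] + 1) * tr)

    # windows come from runs of >= min_run consecutive agreeing raw
    # transitions; shorter episodes are not reported as phases
    windows: dict[str, tuple[float, float] | None] = {
        "rise": None, "plateau": None, "decay": None
    }
    rise_runs = [r for r in _runs_of(raw, "rise") if r[1] - r[0] + 1 >= min_run]
    if rise_runs:
        windows["rise"] = window(rise_runs[0])
    rise_end_idx = rise_runs[0][1] if rise_runs else -1
    # a decay phase follows the plateau: require at least one transition
    # between the end of the rise and the start of the decay
    decay_runs = [
        r
        for r in _runs_of(raw, "decay")
        if r[1] - r[0] + 1 >= min_run and r[0] > rise_end_idx + 1
    ]
    if decay_runs:
        windows["decay"] = window(decay_runs[0])
    if rise_runs and decay_runs:
        windows["plateau"] = ((rise_runs[0][1] + 1) * tr, decay_runs[0][0] * tr)
    elif rise_runs:
        plateau_runs = [
            r for r in _runs_of(labels, "plateau")
            if r[0] > rise_end_idx and r[1] - r[0] + 1 >= min_run
        ]
        if plateau_runs:
            windows["plateau"] = window(plateau_runs[0])

    return SegmentLabels(
        slope_t=t, slope_p=p, labels=labels, windows=windows, tr=tr, alpha=alpha
    )


@dataclass
class ContrastResult:
    """Per-frame paired REP-vs-CTRL comparison and the repetition verdict."""

    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    windows: list[tuple[float, float]]         # >=2 consecutive significant frames
    repetition_effect: bool
    alpha: float


def contrast_conditions(
    rep: np.ndarray,
    ctrl: np.ndarray,
    segments: SegmentLabels,
    alpha: float = 0.05,
    tr: float = 2.0,
) -> ContrastResult:
    """Per-frame paired t-tests between conditions across subjects.

    The repetition-effect verdict requires at least two consecutive
    significant frames with CTRL > REP lying inside the plateau window.
    """
    rep = np.asarray(rep, dtype=float)
    ctrl = np.asarray(ctrl, dtype=float)
    if rep.shape != ctrl.shape:
        raise ValueError("REP and CTRL must be paired by subject (same shape)")
    res = stats.ttest_rel(ctrl, rep, axis=0)
    t = np.asarray(res.statistic, dtype=float)
    p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    sig = p < alpha
    diff = (ctrl - rep).mean(axis=0)

    sig_windows = []
    for start, stop in _runs_of(["s" if s else "n" for s in sig], "s"):
        if stop - start + 1 >= 2:
            sig_windows.append((start * tr, stop * tr))

    verdict = False
    plateau = segments.windows.get("plateau")
    if plateau is not None:
        frames = np.arange(rep.shape[1]) * tr
        eligible = sig & (diff > 0) & (frames >= plateau[0]) & (frames <= plateau[1])
        for start, stop in _runs_of(["s" if s else "n" for s in eligible], "s"):
            if stop - start + 1 >= 2:
                verdict = True
    return ContrastResult(
        t=t, p=p, significant=sig, windows=sig_windows,
        repetition_effect=verdict, alpha=alpha,
    )


@dataclass
class AnovaResult:
    """Per-frame 2x2 repeated-measures ANOVA (condition x hemisphere)."""

    f_condition: np.ndarray
    p_condition: np.ndarray
    f_hemisphere: np.ndarray
    p_hemisphere: np.ndarray
    f_interaction: np.ndarray
    p_interaction: np.ndarray


def _rm_anova_2x2(y: np.ndarray) -> tuple[tuple[float, float], ...]:
    """Two-way fully within-subject ANOVA for a (n, 2, 2) cell array.

    Factors: axis 1 (hemisphere), axis 2 (condition); each effect is tested
    against its interaction with subjects, df (1, n-1).  Degenerate cases
    with zero effect and zero error variance return F = 0, p = 1.
    """
    n = y.shape[0]
    g = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_h = y.mean(axis=(0, 2))
    m_c = y.mean(axis=(0, 1))
    m_sh = y.mean(axis=2)
    m_sc = y.mean(axis=1)
    m_hc = y.mean(axis=0)

    out = []
    # hemisphere
    ss_h = 2 * n * np.sum((m_h - g) ** 2)
    ss_hs = 2 * np.sum((m_sh - m_s[:, None] - m_h[None, :] + g) ** 2)
    # condition
    ss_c = 2 * n * np.sum((m_c - g) ** 2)
    ss_cs = 2 * np.sum((m_sc - m_s[:, None] - m_c[None, :] + g) ** 2)
    # interaction
    ss_hc = n * np.sum((m_hc - m_h[:, None] - m_c[None, :] + g) ** 2)
    resid = (
        y
        - m_sh[:, :, None]
        - m_sc[:, None, :]
        - m_hc[None, :, :]
        + m_s[:, None, None]
        + m_h[None, :, None]
        + m_c[None, None, :]
        - g
    )
    ss_hcs = np.sum(resid**2)

    for ss_eff, ss_err in ((ss_c, ss_cs), (ss_h, ss_hs), (ss_hc, ss_hcs)):
        ms_eff = ss_eff / 1.0
        ms_err = ss_err / (n - 1)
        if ms_err == 0:
            f = 0.0 if ms_eff == 0 else np.inf
            p = 1.0 if ms_eff == 0 else 0.0
        else:
            f = ms_eff / ms_err
            p = float(stats.f.sf(f, 1, n - 1))
        out.append((float(f), p))
    return tuple(out)


def anova_2x2_timepoint(cells: np.ndarray) -> AnovaResult:
    """Frame-by-frame 2x2 repeated-measures ANOVA.

    ``cells`` is (n_subjects, 2 hemispheres, 2 conditions, 15 frames); both
    factors are within-subject, subjects are the random factor.
    """
    cells = np.asarray(cells, dtype=float)
    if cells.ndim != 4 or cells.shape[1] != 2 or cells.shape[2] != 2:
        raise ValueError("cells must be (n_subjects, 2, 2, n_frames)")
    if not np.all(np.isfinite(cells)):
        raise ValueError("missing cells: every subject must contribute all 4 cells")
    n_frames = cells.shape[3]
    fc = np.empty(n_frames); pc = np.empty(n_frames)
    fh = np.empty(n_frames); ph = np.empty(n_frames)
    fi = np.empty(n_frames); pi = np.empty(n_frames)
    for j in range(n_frames):
        (fc[j], pc[j]), (fh[j], ph[j]), (fi[j], pi[j]) = _rm_anova_2x2(cells[:, :, :, j])
    return AnovaResult(
        f_condition=fc, p_condition=pc,
        f_hemisphere=fh, p_hemisphere=ph,
        f_interaction=fi, p_interaction=pi,
    )


@dataclass
class ExtremaStats:
    """Maxima, minima and amplitudes of REP/CTRL time courses."""

    rep_max: np.ndarray
    rep_min: np.ndarray
    ctrl_max: np.ndarray
    ctrl_min: np.ndarray
    p_maxima: float
    p_minima: float
    p_amplitude: float

    @property
    def rep_amplitude(self) -> np.ndarray:
        return self.rep_max - self.rep_min

    @property
    def ctrl_amplitude(self) -> np.ndarray:
        return self.ctrl_max - self.ctrl_min


def extrema_stats(rep: np.ndarray, ctrl: np.ndarray) -> ExtremaStats:
    """Per-subject extrema and paired tests between conditions."""
    rep = np.asarray(rep, dtype=float)
    ctrl = np.asarray(ctrl, dtype=float)
    if rep.shape != ctrl.shape:
        raise ValueError("REP and CTRL must be paired by subject (same shape)")
    rep_max, rep_min = rep.max(axis=1), rep.min(axis=1)
    ctrl_max, ctrl_min = ctrl.max(axis=1), ctrl.min(axis=1)

    def paired_p(a, b):
        diff = np.asarray(a) - np.asarray(b)
        if np.std(diff) == 0:
            # exactly constant difference: no evidence (p=1) when zero,
            # unambiguous difference (p=0) otherwise
            return 0.0 if diff.mean() != 0 else 1.0
        res = stats.ttest_rel(a, b)
        return float(res.pvalue) if np.isfinite(res.pvalue) else 1.0

    return ExtremaStats(
        rep_max=rep_max, rep_min=rep_min, ctrl_max=ctrl_max, ctrl_min=ctrl_min,
        p_maxima=paired_p(rep_max, ctrl_max),
        p_minima=paired_p(rep_min, ctrl_min),
        p_amplitude=paired_p(rep_max - rep_min, ctrl_max - ctrl_min),
    )


def glm_sound_vs_rest(
    run: VolumeSeries,
    design: BlockDesign,
    hrf: HemodynamicModel = DEFAULT_HRF,
    dt: float = 0.1,
) -> np.ndarray:
    """Per-voxel t map of the sounds-vs-rest contrast.

    A single-regressor linear model: the HRF-convolved stimulation boxcar
    (REP and CTRL pooled) plus an intercept.
    """
    t_fine = np.arange(0.0, design.run_duration, dt)
    boxcar = np.zeros_like(t_fine)
    for b in design.blocks:
        boxcar[(t_fine >= b.onset) & (t_fine < b.onset + b.stimulation_duration)] = 1.0
    if not boxcar.any():
        raise ValueError("degenerate design: no stimulation periods")
    reg = hrf.convolve(boxcar, dt)
    frame_idx = np.round(np.arange(design.n_frames) * design.tr / dt).astype(int)
    reg = reg[frame_idx]
    if np.ptp(reg) == 0:
        raise ValueError("degenerate design: constant regressor")

    n = design.n_frames
    X = np.column_stack([np.ones(n), reg])
    xtx_inv = np.linalg.inv(X.T @ X)
    flat = run.data.reshape(-1, n).astype(float).T     # frames x voxels
    beta = xtx_inv @ X.T @ flat
    resid = flat - X @ beta
    dof = n - 2
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = beta[1] / se
    t_stat = np.where(np.isfinite(t_stat), t_stat, 0.0)
    return t_stat.reshape(run.data.shape[:3])
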