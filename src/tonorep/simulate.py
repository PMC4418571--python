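"""Simulators for travelling-wave tonotopy runs and REP/CTRL repetition runs.

Signal model (per voxel, in arbitrary scanner units):

    data = baseline + amplitude * gain_voxel * bold(t) + global(t) + noise

``bold`` is the hemodynamic convolution of the voxel's neural drive,
normalised so a sustained unit drive saturates at ``amplitude`` (the default
baseline of 100 makes amplitude 1.0 correspond to a 1% signal change).
Noise has two components: white thermal noise per voxel and frame
(``noise_sd``) and a global fluctuation shared by all voxels of a frame
(``global_noise_sd``), standing in for physiological noise that does not
average out over voxels within an ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .designs import BlockDesign, FrequencyProgression
from .hrf import DEFAULT_HRF, HemodynamicModel
from .sheet import NAME_OF, ROI_NAMES, GroundTruthMap
from .volume import VolumeSeries

__all__ = [
    "SuppressionProfile",
    "simulate_tonotopy_run",
    "simulate_repetition_run",
    "simulate_repetition_cohort",
    "DEFAULT_NOISE_SD",
    "DEFAULT_GLOBAL_NOISE_SD",
    "DEFAULT_BASELINE",
]

DEFAULT_NOISE_SD = 0.8          # thermal noise per voxel/frame (tSNR 125 at baseline 100)
DEFAULT_GLOBAL_NOISE_SD = 0.15  # shared fluctuation per frame
DEFAULT_BASELINE = 100.0
_DT = 0.1                       # fine time grid for neural/hemodynamic convolution, s


@dataclass(frozen=True)
class SuppressionProfile:
    """Repetition-suppression parameters of the generator.

    ``factors`` maps ROI names to the multiplicative factor applied to the
    sustained neural drive of REP blocks (1.0 = no suppression).  ``advance``
    is the initial unsuppressed period in seconds: the response to the first
    sound(s) of a REP block is unaffected, after which the drive drops to the
    suppressed level, producing an earlier saturation of the REP response.
    """

    factors: dict[str, float] = field(default_factory=dict)
    advance: float = 2.0

    def __post_init__(self) -> None:
        for name, f in self.factors.items():
            if not (0.0 < f <= 1.0):
                raise ValueError(f"suppression factor for {name} must be in (0, 1]")
        if self.advance < 0:
            raise ValueError("advance must be >= 0")

    @classmethod
    def default(cls) -> "SuppressionProfile":
        """Suppression in all areas except L2 and L3, where REP equals CTRL."""
        factors = {name: (1.0 if name in ("L2", "L3") else 0.8) for name in ROI_NAMES}
        return cls(factors=factors, advance=2.0)

    @classmethod
    def null(cls) -> "SuppressionProfile":
        return cls(factors={name: 1.0 for name in ROI_NAMES}, advance=0.0)

    def factor_of(self, roi: str) -> float:
        return self.factors.get(roi, 1.0)


def _frame_samples(n_frames: int, tr: float) -> np.ndarray:
    idx = np.round(np.arange(n_frames) * tr / _DT).astype(int)
    return idx


def simulate_tonotopy_run(
    gt: GroundTruthMap,
    prog: FrequencyProgression,
    hrf: HemodynamicModel = DEFAULT_HRF,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    *,
    tr: float = 2.0,
    amplitude: float = 1.0,
    baseline: float = DEFAULT_BASELINE,
    global_noise_sd: float = DEFAULT_GLOBAL_NOISE_SD,
    tuning_octaves: float = 0.5,
) -> VolumeSeries:
    """Simulate one travelling-wave run.

    Each responsive voxel responds to the progression steps with a Gaussian
    tuning profile around its best frequency (``tuning_octaves`` standard
    deviation on the log2-frequency axis), convolved with the HRF.
    """
    asc = np.array(sorted(prog.frequencies))
    bf_values = gt.best_frequency[gt.responsive]
    present = np.unique(bf_values[np.isfinite(bf_values)])
    if present.size and (present.min() < asc.min() or present.max() > asc.max()):
        raise ValueError("progression frequencies must span the map's frequency range")

    duration = prog.run_duration
    n_frames = int(round(duration / tr))
    t = np.arange(0.0, duration, _DT)
    t_in_cycle = np.mod(t, prog.cycle_duration)
    step_at_t = np.floor(t_in_cycle / prog.step_duration).astype(int)
    in_pause = t_in_cycle >= prog.n_steps * prog.step_duration
    step_at_t[in_pause] = -1

    log_steps = np.log2(np.array(prog.frequencies))
    frame_idx = _frame_samples(n_frames, tr)

    rng = np.random.default_rng(seed)
    responses: dict[float, np.ndarray] = {}
    for f in present:
        w = np.exp(-((np.log2(f) - log_steps) ** 2) / (2.0 * tuning_octaves**2))
        neural = np.where(step_at_t >= 0, w[np.clip(step_at_t, 0, None)], 0.0)
        resp = hrf.convolve(neural, _DT)[frame_idx]
        responses[f] = resp

    nx, ny, nz = gt.shape
    data = np.empty((nx, ny, nz, n_frames))
    data[...] = baseline
    signal = np.zeros((nx, ny, nz, n_frames))
    for f, resp in responses.items():
        mask = gt.responsive & np.isclose(gt.best_frequency, f)
        signal[mask] = resp
    signal *= (amplitude * gt.amplitude)[..., None]
    data += signal
    if global_noise_sd > 0:
        data += global_noise_sd * rng.standard_normal(n_frames)[None, None, None, :]
    if noise_sd > 0:
        data += noise_sd * rng.standard_normal(data.shape)

    affine = np.diag([gt.spec.voxel_size_mm] * 3 + [1.0])
    return VolumeSeries(
        data=data,
        tr=tr,
        affine=affine,
        meta={
            "kind": "tonotopy",
            "direction": prog.direction,
            "progression": prog.to_dict(),
            "seed": seed,
            "noise_sd": noise_sd,
            "global_noise_sd": global_noise_sd,
        },
    )


def _repetition_neural(
    design: BlockDesign, factor: float, advance: float, t: np.ndarray
) -> np.ndarray:
    """Neural drive of one ROI over a repetition run, on the fine grid."""
    neural = np.zeros_like(t)
    for b in design.blocks:
        on = (t >= b.onset) & (t < b.onset + b.stimulation_duration)
        if b.condition == "CTRL" or factor >= 1.0:
            neural[on] = 1.0
        else:
            early = on & (t < b.onset + advance)
            late = on & ~early
            neural[early] = 1.0
            neural[late] = factor
    return neural


def simulate_repetition_run(
    gt: GroundTruthMap,
    design: BlockDesign,
    hrf: HemodynamicModel = DEFAULT_HRF,
    profile: SuppressionProfile | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    *,
    amplitude: float = 1.0,
    baseline: float = DEFAULT_BASELINE,
    global_noise_sd: float = DEFAULT_GLOBAL_NOISE_SD,
) -> VolumeSeries:
    """Simulate one REP/CTRL block run.

    CTRL blocks drive a 16-s unit boxcar in every responsive voxel; REP
    blocks drive the same boxcar scaled by the voxel's ROI suppression
    factor after the profile's initial unsuppressed period.
    """
    if profile is None:
        profile = SuppressionProfile.default()
    present = {NAME_OF[v] for v in np.unique(gt.labels) if v != 0}
    unknown = set(profile.factors) - present
    if unknown:
        raise ValueError(f"suppression profile references ROIs absent from the map: {sorted(unknown)}")

    n_frames = design.n_frames
    t = np.arange(0.0, design.run_duration, _DT)
    frame_idx = _frame_samples(n_frames, design.tr)

    rng = np.random.default_rng(seed)
    nx, ny, nz = gt.shape
    data = np.empty((nx, ny, nz, n_frames))
    data[...] = baseline
    signal = np.zeros((nx, ny, nz, n_frames))

    resp_cache: dict[float, np.ndarray] = {}
    for name in sorted(present):
        factor = profile.factor_of(name)
        if factor not in resp_cache:
            neural = _repetition_neural(design, factor, profile.advance, t)
            resp_cache[factor] = hrf.convolve(neural, _DT)[frame_idx]
        mask = gt.roi_mask(name)
        signal[mask] = resp_cache[factor]
    signal *= (amplitude * gt.amplitude)[..., None]
    data += signal
    if global_noise_sd > 0:
        data += global_noise_sd * rng.standard_normal(n_frames)[None, None, None, :]
    if noise_sd > 0:
        data += noise_sd * rng.standard_normal(data.shape)

    affine = np.diag([gt.spec.voxel_size_mm] * 3 + [1.0])
    return VolumeSeries(
        data=data,
        tr=design.tr,
        affine=affine,
        meta={
            "kind": "repetition",
            "design": design.to_dict(),
            "seed": seed,
            "noise_sd": noise_sd,
            "global_noise_sd": global_noise_sd,
            "suppression": {"factors": dict(profile.factors), "advance": profile.advance},
        },
    )


def simulate_repetition_cohort(
    gt: GroundTruthMap,
    design: BlockDesign,
    n_subjects: int = 9,
    n_runs: int = 2,
    hrf: HemodynamicModel = DEFAULT_HRF,
    profile: SuppressionProfile | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    *,
    amplitude: float = 1.0,
    subject_gain_sd: float = 0.15,
    hrf_peak_jitter: float = 0.2,
    global_noise_sd: float = DEFAULT_GLOBAL_NOISE_SD,
) -> list[list[VolumeSeries]]:
    """Simulate a cohort of subjects, each with several repetition runs.

    Between-subject variability: a multiplicative response gain drawn from
    N(1, subject_gain_sd^2) (clipped to be positive) and a uniform jitter of
    the HRF peak delay within +/- ``hrf_peak_jitter`` seconds (clipped to
    the model's valid range).
    """
    if profile is None:
        profile = SuppressionProfile.default()
    master = np.random.default_rng(seed)
    cohort: list[list[VolumeSeries]] = []
    for _ in range(n_subjects):
        gain = max(0.1, 1.0 + subject_gain_sd * master.standard_normal())
        delta = master.uniform(-hrf_peak_jitter, hrf_peak_jitter)
        peak = float(np.clip(hrf.peak_delay + delta, 4.0, 7.0))
        subj_hrf = HemodynamicModel(
            peak_delay=peak,
            peak_dispersion=hrf.peak_dispersion,
            undershoot_delay=hrf.undershoot_delay,
            undershoot_dispersion=hrf.undershoot_dispersion,
            undershoot_ratio=hrf.undershoot_ratio,
        )
        runs = []
        for _ in range(n_runs):
            run_seed = int(master.integers(0, 2**31 - 1))
            runs.append(
                simulate_repetition_run(
                    gt,
                    design,
                    hrf=subj_hrf,
                    profile=profile,
                    noise_sd=noise_sd,
                    seed=run_seed,
                    amplitude=amplitude * gain,
                    global_noise_sd=global_noise_sd,
                )
            )
        cohort.append(runs)
    return cohort
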