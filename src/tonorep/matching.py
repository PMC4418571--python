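"""Acoustic profiling and iterative REP/CTRL stimulus-set matching.

Candidate REP and CTRL sets are drawn repeatedly from a sound pool and
compared point by point — every envelope time point and every amplitude-
spectrum bin — with two-sided unpaired Student t-tests at alpha = 0.05,
deliberately without any multiple-comparison correction (correcting would
hide real differences between the sets, which is the opposite of what a
matching control wants).  The first draw for which fewer than 1% of
comparison points differ significantly is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SAMPLE_RATE",
    "N_SAMPLES",
    "RAMP_SAMPLES",
    "N_ENVELOPE_POINTS",
    "N_SPECTRUM_BINS",
    "SoundStimulus",
    "AcousticProfile",
    "CandidatePool",
    "CompareResult",
    "MatchedSets",
    "acoustic_profile",
    "compare_sets",
    "select_matched_sets",
    "compare_mean_spectra",
]

SAMPLE_RATE = 44100
N_SAMPLES = 22050            # 500 ms
RAMP_SAMPLES = 2205          # 50 ms linear rise/fall
N_ENVELOPE_POINTS = 500      # 1-ms envelope resolution
N_SPECTRUM_BINS = N_SAMPLES // 2  # 11025 one-sided bins, zero-frequency bin dropped


@dataclass
class SoundStimulus:
    """A 500-ms waveform at 44.1 kHz with identifier and optional category tag."""

    waveform: np.ndarray
    identifier: str
    category: str | None = None

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.waveform.ndim != 1 or self.waveform.size != N_SAMPLES:
            raise ValueError(
                f"waveform must be {N_SAMPLES} samples (500 ms at 44.1 kHz), "
                f"got {self.waveform.shape}"
            )
        if np.max(np.abs(self.waveform)) > 1.0 + 1e-9:
            raise ValueError("peak amplitude must not exceed 1")


@dataclass
class AcousticProfile:
    """Envelope and one-sided amplitude spectrum of a sound."""

    envelope: np.ndarray
    spectrum: np.ndarray

    def __post_init__(self) -> None:
        self.envelope = np.asarray(self.envelope, dtype=float)
        self.spectrum = np.asarray(self.spectrum, dtype=float)
        if np.any(self.envelope < 0):
            raise ValueError("envelope must be non-negative")
        if self.spectrum.size != N_SPECTRUM_BINS:
            raise ValueError(f"spectrum must have {N_SPECTRUM_BINS} bins")


@dataclass
class CandidatePool:
    """A pool of candidate sounds."""

    sounds: list[SoundStimulus]

    def __post_init__(self) -> None:
        if len(self.sounds) < 2:
            raise ValueError("a pool needs at least 2 sounds")

    def __len__(self) -> int:
        return len(self.sounds)

    @property
    def categories(self) -> list[str | None]:
        return [s.category for s in self.sounds]


def acoustic_profile(sound: SoundStimulus, n_envelope: int = N_ENVELOPE_POINTS) -> AcousticProfile:
    """Envelope (rectified amplitude, ``n_envelope`` bin means) and one-sided
    amplitude spectrum (magnitude of the DFT, zero-frequency bin dropped)."""
    x = sound.waveform
    edges = np.floor(np.arange(x.size) * n_envelope / x.size).astype(int)
    env = np.bincount(edges, weights=np.abs(x), minlength=n_envelope)
    env /= np.bincount(edges, minlength=n_envelope)
    spectrum = np.abs(np.fft.rfft(x))[1 : N_SPECTRUM_BINS + 1]
    return AcousticProfile(envelope=env, spectrum=spectrum)


@dataclass
class CompareResult:
    """Per-point unpaired t-test comparison of two profile sets."""

    envelope_p: np.ndarray
    spectrum_p: np.ndarray
    alpha: float

    @property
    def envelope_fraction(self) -> float:
        return float(np.mean(self.envelope_p < self.alpha))

    @property
    def spectrum_fraction(self) -> float:
        return float(np.mean(self.spectrum_p < self.alpha))

    @property
    def n_significant(self) -> int:
        return int((self.envelope_p < self.alpha).sum() + (self.spectrum_p < self.alpha).sum())

    @property
    def fraction(self) -> float:
        total = self.envelope_p.size + self.spectrum_p.size
        return self.n_significant / total


def _pointwise_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided pooled-variance t-test p-values along axis 0.

    Points with zero variance in both sets are assigned p = 1 (no evidence
    of a difference at a constant point).
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=0, equal_var=True)
        p = np.asarray(res.pvalue)
    return np.where(np.isfinite(p), p, 1.0)


def compare_sets(
    a: list[AcousticProfile], b: list[AcousticProfile], alpha: float = 0.05
) -> CompareResult:
    """Compare two profile sets at every envelope point and spectrum bin."""
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each set needs at least 2 profiles")
    env_a = np.array([p.envelope for p in a])
    env_b = np.array([p.envelope for p in b])
    spec_a = np.array([p.spectrum for p in a])
    spec_b = np.array([p.spectrum for p in b])
    if env_a.shape[1] != env_b.shape[1] or spec_a.shape[1] != spec_b.shape[1]:
        raise ValueError("profile lengths differ between sets")
    return CompareResult(
        envelope_p=_pointwise_t(env_a, env_b),
        spectrum_p=_pointwise_t(spec_a, spec_b),
        alpha=alpha,
    )


@dataclass
class MatchedSets:
    """Outcome of the iterative matching procedure."""

    status: str                       # "accepted" | "failed"
    rep_ids: list[str]
    ctrl_ids: list[str]
    result: CompareResult | None
    iterations: int
    best_fraction: float
    threshold: float

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "rep_ids": self.rep_ids,
            "ctrl_ids": self.ctrl_ids,
            "iterations": self.iterations,
            "best_fraction": self.best_fraction,
            "threshold": self.threshold,
            "fraction": self.result.fraction if self.result is not None else None,
            "envelope_fraction": self.result.envelope_fraction if self.result else None,
            "spectrum_fraction": self.result.spectrum_fraction if self.result else None,
        }


def _stratified_split(
    rng: np.random.Generator,
    categories: list[str | None],
    n_rep: int,
    n_ctrl: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw disjoint REP/CTRL index sets, stratified by category when tagged."""
    n = len(categories)
    if any(c is None for c in categories):
        perm = rng.permutation(n)
        return perm[:n_rep], perm[n_rep : n_rep + n_ctrl]
    # proportional allocation per category, largest remainder
    rep_idx: list[int] = []
    ctrl_idx: list[int] = []
    cats = sorted(set(categories))
    members = {c: rng.permutation([i for i, ci in enumerate(categories) if ci == c]) for c in cats}
    for want, out in ((n_rep, rep_idx), (n_ctrl, ctrl_idx)):
        exact = {c: want * len(members[c]) / n for c in cats}
        take = {c: int(np.floor(exact[c])) for c in cats}
        rem = want - sum(take.values())
        for c in sorted(cats, key=lambda c: exact[c] - take[c], reverse=True)[:rem]:
            take[c] += 1
        taken = set(rep_idx)
        for c in cats:
            avail = [i for i in members[c] if i not in taken]
            out.extend(avail[: take[c]])
    # top up if remainder rounding left a set short
    used = set(rep_idx) | set(ctrl_idx)
    spare = [i for i in rng.permutation(n) if i not in used]
    while len(rep_idx) < n_rep:
        rep_idx.append(spare.pop())
    while len(ctrl_idx) < n_ctrl:
        ctrl_idx.append(spare.pop())
    return np.array(rep_idx), np.array(ctrl_idx)


def select_matched_sets(
    pool: CandidatePool,
    n_rep: int = 64,
    n_ctrl: int = 236,
    max_iter: int = 1000,
    threshold: float = 0.01,
    seed: int = 0,
    alpha: float = 0.05,
) -> MatchedSets:
    """Iteratively draw disjoint REP/CTRL sets until acoustically matched.

    Accepts the first draw whose fraction of significantly different points
    (envelope points plus spectrum bins, p < alpha, uncorrected) is below
    ``threshold``.  If no draw qualifies within ``max_iter`` iterations the
    result is flagged failed (carrying the best fraction found), never a
    silently unmatched set.
    """
    if n_rep + n_ctrl > len(pool):
        raise ValueError("pool too small for the requested set sizes")
    if n_rep < 2 or n_ctrl < 2:
        raise ValueError("each set needs at least 2 sounds")
    rng = np.random.default_rng(seed)
    profiles = [acoustic_profile(s) for s in pool.sounds]
    ids = [s.identifier for s in pool.sounds]
    categories = pool.categories

    best = np.inf
    best_sets: tuple[np.ndarray, np.ndarray] | None = None
    best_result: CompareResult | None = None
    for it in range(1, max_iter + 1):
        rep_i, ctrl_i = _stratified_split(rng, categories, n_rep, n_ctrl)
        result = compare_sets(
            [profiles[i] for i in rep_i], [profiles[i] for i in ctrl_i], alpha=alpha
        )
        if result.fraction < best:
            best = result.fraction
            best_sets = (rep_i, ctrl_i)
            best_result = result
        if result.fraction < threshold:
            return MatchedSets(
                status="accepted",
                rep_ids=[ids[i] for i in rep_i],
                ctrl_ids=[ids[i] for i in ctrl_i],
                result=result,
                iterations=it,
                best_fraction=float(result.fraction),
                threshold=threshold,
            )
    assert best_sets is not None
    return MatchedSets(
        status="failed",
        rep_ids=[ids[i] for i in best_sets[0]],
        ctrl_ids=[ids[i] for i in best_sets[1]],
        result=best_result,
        iterations=max_iter,
        best_fraction=float(best),
        threshold=threshold,
    )


@dataclass
class MeanSpectrumComparison:
    """Per-bin comparison of the amplitude spectra of two conditions."""

    p_values: np.ndarray
    n_significant: int
    n_significant_bonferroni: int
    fraction: float


def compare_mean_spectra(
    rep: list[AcousticProfile], ctrl: list[AcousticProfile], alpha: float = 0.05
) -> MeanSpectrumComparison:
    """Unpaired t-test per spectrum bin between the two conditions.

    Reports the raw significant-bin count, the count surviving Bonferroni
    correction over all bins, and the raw count as a fraction of the
    spectrum length.
    """
    spec_a = np.array([p.spectrum for p in rep])
    spec_b = np.array([p.spectrum for p in ctrl])
    if spec_a.shape[1] != spec_b.shape[1]:
        raise ValueError("spectral lengths differ")
    p = _pointwise_t(spec_a, spec_b)
    n_sig = int((p < alpha).sum())
    n_bonf = int((p < alpha / p.size).sum())
    return MeanSpectrumComparison(
        p_values=p,
        n_significant=n_sig,
        n_significant_bonferroni=n_bonf,
        fraction=n_sig / p.size,
    )
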