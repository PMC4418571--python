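"""Hemodynamic response model.

The BOLD impulse response is modelled as a double-gamma function: a positive
gamma lobe followed by an optional undershoot lobe.  Both lobes are
parameterised by their peak delay (the mode of the gamma density, in seconds)
and their temporal dispersion (the standard deviation, in seconds), which is
more direct for reasoning about when a sustained block response saturates
than the shape/scale parameterisation.

The default response is deliberately compact (peak 4.2 s, dispersion 0.7 s,
no undershoot): convolved with a 16-s stimulation boxcar it saturates by
~6 s after block onset and returns to baseline between ~18 and 22 s, which
is the empirical rise/plateau/decay timing of auditory-cortex block
responses that the synthetic cohort is meant to emulate.  A slower textbook
variant is available through :meth:`HemodynamicModel.canonical`.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

__all__ = ["HemodynamicModel", "DEFAULT_HRF"]


def _gamma_from_mode_sd(mode: float, sd: float) -> tuple[float, float]:
    """Shape/scale of a gamma density with the given mode and standard deviation."""
    theta = (-mode + np.sqrt(mode * mode + 4.0 * sd * sd)) / 2.0
    k = mode / theta + 1.0
    return k, theta


@dataclass(frozen=True)
class HemodynamicModel:
    """Double-gamma BOLD impulse response.

    Parameters
    ----------
    peak_delay:
        Mode of the positive lobe in seconds.  Must lie in [4, 7].
    peak_dispersion:
        Standard deviation of the positive lobe in seconds.
    undershoot_delay:
        Mode of the undershoot lobe in seconds.
    undershoot_dispersion:
        Standard deviation of the undershoot lobe in seconds.
    undershoot_ratio:
        Amplitude of the undershoot relative to the positive lobe
        (0 disables the undershoot).
    """

    peak_delay: float = 4.2
    peak_dispersion: float = 0.7
    undershoot_delay: float = 12.0
    undershoot_dispersion: float = 2.0
    undershoot_ratio: float = 0.0

    def __post_init__(self) -> None:
        if not (4.0 <= self.peak_delay <= 7.0):
            raise ValueError(f"peak_delay must be in [4, 7] s, got {self.peak_delay}")
        if self.peak_dispersion <= 0:
            raise ValueError("peak_dispersion must be positive")
        if self.undershoot_ratio < 0:
            raise ValueError("undershoot_ratio must be non-negative")

    @classmethod
    def canonical(cls) -> "HemodynamicModel":
        """Slow textbook response (peak 5 s, undershoot peaking near 15 s)."""
        return cls(
            peak_delay=5.0,
            peak_dispersion=1.8,
            undershoot_delay=15.0,
            undershoot_dispersion=3.5,
            undershoot_ratio=1.0 / 6.0,
        )

    @property
    def duration(self) -> float:
        """Effective support of the kernel in seconds."""
        return float(
            max(
                self.peak_delay + 8.0 * self.peak_dispersion,
                (self.undershoot_delay + 8.0 * self.undershoot_dispersion)
                if self.undershoot_ratio > 0
                else 0.0,
            )
        )

    def kernel(self, dt: float = 0.1) -> np.ndarray:
        """Impulse response sampled at ``dt``, normalised to unit integral.

        With unit integral, the convolution of the kernel with an indefinitely
        sustained unit boxcar saturates at 1, so neural amplitudes carry
        directly into plateau amplitudes.
        """
        return _kernel_cached(
            self.peak_delay,
            self.peak_dispersion,
            self.undershoot_delay,
            self.undershoot_dispersion,
            self.undershoot_ratio,
            dt,
        )

    def rise_time_to_saturation(self, dt: float = 0.1, level: float = 0.95) -> float:
        """Time for the sustained-boxcar response to reach ``level`` of its plateau."""
        h = self.kernel(dt)
        cum = np.cumsum(h) * dt
        plateau = cum[-1]
        idx = int(np.searchsorted(cum, level * plateau))
        return idx * dt

    def convolve(self, neural: np.ndarray, dt: float = 0.1) -> np.ndarray:
        """Convolve a neural time course (sampled at ``dt``) with the kernel."""
        h = self.kernel(dt)
        return np.convolve(neural, h)[: neural.size] * dt


@lru_cache(maxsize=32)
def _kernel_cached(
    peak_delay: float,
    peak_dispersion: float,
    undershoot_delay: float,
    undershoot_dispersion: float,
    undershoot_ratio: float,
    dt: float,
) -> np.ndarray:
    duration = max(
        peak_delay + 8.0 * peak_dispersion,
        (undershoot_delay + 8.0 * undershoot_dispersion) if undershoot_ratio > 0 else 0.0,
    )
    t = np.arange(0.0, duration + dt, dt)
    k1, th1 = _gamma_from_mode_sd(peak_delay, peak_dispersion)
    h = stats.gamma.pdf(t, a=k1, scale=th1)
    if undershoot_ratio > 0:
        k2, th2 = _gamma_from_mode_sd(undershoot_delay, undershoot_dispersion)
        u = stats.gamma.pdf(t, a=k2, scale=th2)
        h = h - undershoot_ratio * u / u.max() * h.max()
    integral = h.sum() * dt
    if not np.isfinite(integral) or integral <= 0:
        raise ValueError("hemodynamic kernel has non-positive integral")
    h = h / integral
    h.setflags(write=False)
    return h


DEFAULT_HRF = HemodynamicModel()
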