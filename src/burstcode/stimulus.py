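"""Spatially uniform sample-and-hold stimulus generation and characterization.

The stimulus emulated here is a full-field Gaussian white-noise light whose
intensity is redrawn at a fixed refresh rate (default 30 Hz) and held constant
between refreshes.  Such a signal has a triangular autocorrelation whose base
equals one hold period, so the width of the central peak at half maximum is
exactly the hold period (33.3 ms at 30 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StimulusTrace", "generate_uniform_stimulus", "autocorrelation_width"]


@dataclass
class StimulusTrace:
    """A normalized 1-D light-intensity trace sampled on a regular grid.

    Attributes
    ----------
    values : np.ndarray
        Intensity per sample, normalized to mean 0 and SD 1 (dimensionless).
    dt : float
        Sampling period in ms.
    refresh_period : float or None
        Hold period of the generator in ms (None for externally loaded traces
        whose refresh rate is unknown).
    """

    values: np.ndarray
    dt: float = 1.0
    refresh_period: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("stimulus values must be one-dimensional")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def T(self) -> float:
        """Duration of one repeat in ms."""
        return len(self.values) * self.dt

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def normalized(self) -> "StimulusTrace":
        """Return a copy normalized to mean 0, SD 1."""
        v = self.values
        sd = v.std()
        if sd == 0:
            raise ValueError("cannot normalize a constant stimulus")
        return StimulusTrace((v - v.mean()) / sd, self.dt, self.refresh_period)


def generate_uniform_stimulus(
    T: float, refresh_hz: float = 30.0, seed: int | np.random.Generator = 0, dt: float = 1.0
) -> StimulusTrace:
    """Generate sample-and-hold Gaussian white-noise intensity of duration ``T`` ms.

    A new independent standard-normal value is drawn every ``1000 / refresh_hz``
    ms and held constant between refreshes; the trace is then normalized to
    mean 0, SD 1.

    Parameters
    ----------
    T : float
        Duration in ms.
    refresh_hz : float
        Refresh rate of the intensity in Hz.
    seed : int or numpy Generator
        Source of randomness.
    dt : float
        Sampling period in ms (default 1 ms).
    """
    if T <= 0:
        raise ValueError(f"T must be positive, got {T}")
    if refresh_hz <= 0:
        raise ValueError(f"refresh_hz must be positive, got {refresh_hz}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    hold_ms = 1000.0 / refresh_hz
    n_samples = int(round(T / dt))
    # frame index of each sample; a new value is drawn at each frame onset
    t = np.arange(n_samples) * dt
    frame = np.floor(t / hold_ms).astype(np.int64)
    n_frames = int(frame[-1]) + 1
    held = rng.standard_normal(n_frames)
    values = held[frame]
    values = (values - values.mean()) / values.std()
    return StimulusTrace(values, dt=dt, refresh_period=hold_ms)


def autocorrelation(trace: StimulusTrace, max_lag_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """Normalized autocorrelation of the trace for lags 0..max_lag_ms.

    Returns ``(lags_ms, acf)`` with ``acf[0] == 1``.
    """
    v = trace.values - trace.values.mean()
    n = len(v)
    max_lag = int(round(max_lag_ms / trace.dt))
    if max_lag >= n:
        raise ValueError("max_lag exceeds trace length")
    denom = np.dot(v, v)
    acf = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        acf[k] = np.dot(v[: n - k], v[k:]) / denom
    lags = np.arange(max_lag + 1) * trace.dt
    return lags, acf


def autocorrelation_width(trace: StimulusTrace, max_lag_ms: float | None = None) -> float:
    """Width of the central autocorrelation peak at half its maximum, in ms.

    The width is measured across the peak (i.e. the full width between the
    half-maximum crossings on both sides of lag 0); for sample-and-hold noise
    this equals the hold period.  The crossing is located by linear
    interpolation between the two lag samples that bracket half maximum.
    """
    if max_lag_ms is None:
        hold = trace.refresh_period if trace.refresh_period is not None else 100.0
        max_lag_ms = 5.0 * hold
    if trace.refresh_period is not None and trace.T < 10 * trace.refresh_period:
        raise ValueError("trace too short: need at least 10 hold periods")
    lags, acf = autocorrelation(trace, max_lag_ms)
    half = 0.5 * acf[0]
    below = np.nonzero(acf < half)[0]
    if len(below) == 0:
        raise ValueError(
            "autocorrelation never drops below half maximum within "
            f"{max_lag_ms} ms; increase max_lag_ms"
        )
    i = below[0]
    # linear interpolation between samples i-1 and i
    x0, x1 = lags[i - 1], lags[i]
    y0, y1 = acf[i - 1], acf[i]
    lag_half = x0 + (half - y0) * (x1 - x0) / (y1 - y0)
    return 2.0 * lag_half
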