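"""Projection of the stimulus onto feature waveforms and conditional densities.

The raw projection is the windowed inner product

    s*(t) = (1/300 ms) * sum_tau St(t + tau) f(tau) dt,   tau in [-300, 0] ms,

defined for all t >= 300 ms.  Projections are standardized either over all
time points ("all-time" scope) or over the values sampled at a set of trigger
times ("at-burst" scope, used when comparing burst classes against the
population of bursts rather than against all time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .stimulus import StimulusTrace

__all__ = ["ProjectionSample", "project", "normalize_projection", "conditional_density"]

WINDOW_MS = 300


def project(stimulus: StimulusTrace, feature: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw projection series s*(t) for t = 300 .. T-1 ms.

    ``feature`` must be defined on the inclusive [-300, 0] ms grid
    (301 samples at dt = 1 ms).  Returns ``(times_ms, values)``.
    """
    if stimulus.dt != 1.0:
        raise ValueError("projection requires dt = 1 ms")
    f = np.asarray(feature, dtype=float)
    if len(f) != WINDOW_MS + 1:
        raise ValueError(f"feature must have {WINDOW_MS + 1} samples on [-300, 0] ms")
    if stimulus.n_samples <= WINDOW_MS:
        raise ValueError("stimulus shorter than the 300 ms projection window")
    raw = np.convolve(stimulus.values, f[::-1], mode="valid") / WINDOW_MS
    times = np.arange(WINDOW_MS, stimulus.n_samples, dtype=float)
    return times, raw


@dataclass
class ProjectionSample:
    """Normalized projection values with their normalization scope."""

    times: np.ndarray
    values: np.ndarray
    scope: str  # "all-time" | "at-burst"
    mean: float
    sd: float

    def at(self, sample_times: np.ndarray) -> np.ndarray:
        """Normalized values at the given times (rounded to the ms grid)."""
        idx = np.round(np.asarray(sample_times, dtype=float)).astype(int) - int(self.times[0])
        if idx.min() < 0 or idx.max() >= len(self.values):
            raise ValueError("sample time outside the projection range")
        return self.values[idx]


def normalize_projection(
    times: np.ndarray,
    raw: np.ndarray,
    scope: str = "all-time",
    sample_times: np.ndarray | None = None,
) -> ProjectionSample:
    """Standardize a raw projection series to mean 0, SD 1.

    With ``scope='all-time'`` the moments are taken over every time point;
    with ``scope='at-burst'`` they are taken over the values at
    ``sample_times`` only (the series is still returned at all times, shifted
    and scaled by the at-burst moments).
    """
    raw = np.asarray(raw, dtype=float)
    if scope == "all-time":
        mu, sd = raw.mean(), raw.std()
    elif scope == "at-burst":
        if sample_times is None:
            raise ValueError("at-burst scope requires sample_times")
        idx = np.round(np.asarray(sample_times, dtype=float)).astype(int) - int(times[0])
        vals = raw[idx]
        mu, sd = vals.mean(), vals.std()
    else:
        raise ValueError(f"unknown scope '{scope}'")
    if sd == 0:
        raise ValueError("zero standard deviation; cannot normalize projection")
    return ProjectionSample(times=times, values=(raw - mu) / sd, scope=scope,
                            mean=float(mu), sd=float(sd))


def _scott_bins(x: np.ndarray) -> np.ndarray:
    n = len(x)
    h = 3.49 * x.std(ddof=1) / n ** (1 / 3) if n > 1 else 1.0
    if h <= 0:
        h = 1.0
    lo, hi = x.min(), x.max()
    n_bins = max(int(np.ceil((hi - lo) / h)), 1)
    return np.linspace(lo, hi, n_bins + 1)


def conditional_density(
    samples: np.ndarray,
    group_labels: np.ndarray,
    min_group: int = 20,
    grid: np.ndarray | None = None,
) -> dict:
    """Per-group density estimates with group means and SDs.

    Groups smaller than ``min_group`` are dropped with a warning.  All groups
    are histogrammed on a common grid (Scott-rule bin width on the pooled
    sample unless ``grid`` is given) and the densities are normalized to unit
    integral.  Returns a dict mapping group label to
    ``{"grid", "density", "mean", "sd", "n"}``.
    """
    samples = np.asarray(samples, dtype=float)
    group_labels = np.asarray(group_labels)
    if grid is None:
        grid = _scott_bins(samples)
    out: dict = {}
    for g in np.unique(group_labels):
        x = samples[group_labels == g]
        if len(x) < min_group:
            warnings.warn(f"group {g!r} has {len(x)} < {min_group} samples; dropped")
            continue
        counts, edges = np.histogram(x, bins=grid)
        widths = np.diff(edges)
        density = counts / (counts.sum() * widths)
        out[g] = {
            "grid": 0.5 * (edges[:-1] + edges[1:]),
            "density": density,
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
            "n": len(x),
        }
    return out
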