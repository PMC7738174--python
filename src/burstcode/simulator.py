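"""Synthetic ganglion-cell simulator with full ground-truth annotation.

Generative model
----------------
The simulator plants the coding scheme that the analysis pipeline is built to
recover:

1.  *Events.*  The stimulus is filtered with a slow OFF kernel ``f_num``; the
    (standardized) filtered signal's prominent peaks, spaced more than
    ``2 * t_gap`` apart, define candidate event times.  Events are a
    deterministic function of the stimulus, hence identical across repeats.
2.  *Spike count.*  At each event and repeat, the count drive is the filtered
    value at the event time plus Gaussian noise; thresholds (quantiles of the
    noiseless drive) map it to a count k in {1..4}.  The count therefore
    encodes the amplitude of the slow stimulus modulation.
3.  *Intraburst ISIs.*  Two orthonormal fast oscillatory kernels ``f_w1`` and
    ``f_w2`` (quadrature Gabors, ~8 Hz) drive two latents
    ``z_d = <S, f_wd>_std + eps_d`` with ``eps_d ~ N(0, sigma_d^2)`` and
    ``sigma_1 < sigma_2``.  The planted plane coordinates are the rotation
    ``(u1, u2) = z1 (cos a, sin a) + z2 (-sin a, cos a)`` with planted angle
    ``a = theta_star``.  ISIs follow the log-linear law
    ``ISI_d = m_d + 10 ** (beta0 + beta1 * u_d)`` so that the trial-to-trial
    ISI SD grows linearly with the trial mean.  Two-spike bursts use ``z1``
    alone — the mechanism shared with three-spike bursts.
4.  *Spike placement.*  First-spike times get N(0, 2 ms) jitter; remaining
    spikes are placed at cumulative ISIs.

Parameter values are a stand-in consistent with the qualitative structure of
real ganglion-cell recordings, not claims about the retina.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .stimulus import StimulusTrace

__all__ = ["SimulationParams", "GroundTruth", "simulate_ganglion_cell", "default_kernels"]

TAU_GRID = np.arange(-300, 1, 1.0)  # inclusive integer-ms kernel support


def _gabor(tau: np.ndarray, freq_hz: float, center: float, width: float, phase: float) -> np.ndarray:
    env = np.exp(-0.5 * ((tau - center) / width) ** 2)
    return env * np.cos(2 * np.pi * freq_hz * (tau - center) / 1000.0 + phase)


def default_kernels() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (f_num, f_w1, f_w2) on the inclusive [-300, 0] ms grid.

    ``f_num`` is a slow biphasic OFF kernel (OFF trough near -50 ms, ON hump
    near -160 ms, ~5 Hz time scale).  ``f_w1``/``f_w2`` are quadrature ~8 Hz
    Gabors, numerically orthogonalized and normalized to equal unit norm.
    """
    tau = TAU_GRID
    # lobe widths are broad enough that the kernel has negligible power in
    # the ~8 Hz band of the oscillatory features (spectral separation of the
    # count mechanism from the ISI mechanisms)
    f_num = -np.exp(-0.5 * ((tau + 70.0) / 50.0) ** 2) + 0.5 * np.exp(
        -0.5 * ((tau + 190.0) / 60.0) ** 2
    )
    f_num = f_num / np.linalg.norm(f_num)
    f_w1 = _gabor(tau, 8.0, -100.0, 55.0, 0.0)
    f_w2 = _gabor(tau, 8.0, -100.0, 55.0, -np.pi / 2)
    # Gram-Schmidt: enforce exact orthogonality and equal norms
    f_w1 = f_w1 / np.linalg.norm(f_w1)
    f_w2 = f_w2 - np.dot(f_w2, f_w1) * f_w1
    f_w2 = f_w2 / np.linalg.norm(f_w2)
    return f_num, f_w1, f_w2


@dataclass
class SimulationParams:
    """Tunable parameters of the generative model (times in ms)."""

    n_rep: int = 30
    theta_star: float = 30.0  # planted angle, deg
    sigma1: float = 0.5  # trial-to-trial SD of latent 1 (the shared, precise one)
    sigma2: float = 1.0  # trial-to-trial SD of latent 2
    sigma_num: float = 0.25  # count-drive noise SD (z-scored filter units)
    m1: float = 2.0  # ISI offset, ms
    m2: float = 2.0
    beta0: float = float(np.log10(6.0))  # log10 scale: median 2-spike ISI ~ 8 ms
    beta1: float = 0.12  # log10 slope per latent unit
    jitter_sd: float = 2.0  # first-spike timing jitter, ms
    t_gap: float = 150.0  # events spaced > 2 * t_gap
    peak_height: float = 0.8  # event threshold on the z-scored filtered signal (SD units)
    count_quantiles: tuple[float, float, float] = (0.15, 0.40, 0.82)

    def validate(self) -> None:
        if self.n_rep < 2:
            raise ValueError("n_rep must be >= 2")
        if self.sigma1 < 0 or self.sigma2 < 0 or self.sigma_num < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.m1 <= 0 or self.m2 <= 0:
            raise ValueError("ISI offsets m_d must be positive")


@dataclass
class GroundTruth:
    """Planted quantities of a simulation, for parameter-recovery checks."""

    tau_grid: np.ndarray
    f_num: np.ndarray
    f_w1: np.ndarray
    f_w2: np.ndarray
    theta_star: float
    event_times: np.ndarray  # nominal event onsets, ms
    z1: np.ndarray  # (n_events, n_rep) latent 1
    z2: np.ndarray  # (n_events, n_rep) latent 2
    count_drive: np.ndarray  # (n_events, n_rep)
    counts: np.ndarray  # (n_events, n_rep) spike counts k
    u1: np.ndarray  # (n_events, n_rep) planted plane coordinates
    u2: np.ndarray
    params: SimulationParams

    def params_dict(self) -> dict:
        return asdict(self.params)


def _filter_stimulus(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Projection <S(t+tau), f(tau)> for t >= 300 ms; NaN-padded head."""
    out = np.full(len(values), np.nan)
    # kernel on tau = -300..0 -> correlate: out[t] = sum_j values[t-300+j] * kernel[j]
    valid = np.convolve(values, kernel[::-1], mode="valid")
    out[len(kernel) - 1 :] = valid
    return out


def simulate_ganglion_cell(
    trace: StimulusTrace,
    n_rep: int | None = None,
    params: SimulationParams | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate repeated-trial spike trains of one model OFF ganglion cell.

    Parameters
    ----------
    trace : StimulusTrace
        Normalized intensity trace of one stimulus repeat (dt must be 1 ms).
    n_rep : int, optional
        Number of repeats; overrides ``params.n_rep``.
    params : SimulationParams, optional
        Generative-model parameters (defaults used when omitted).
    seed : int or Generator
        Source of randomness.

    Returns
    -------
    spikes : pandas.DataFrame
        Columns ``repeat`` (0-based) and ``time_ms``, sorted within repeat.
    truth : GroundTruth
        All planted kernels, event times, latents and counts.
    """
    params = params or SimulationParams()
    if n_rep is not None:
        params = SimulationParams(**{**asdict(params), "n_rep": n_rep})
    params.validate()
    if trace.dt != 1.0:
        raise ValueError("simulator requires dt = 1 ms")
    if trace.n_samples < len(TAU_GRID) + 400:
        raise ValueError("stimulus too short for the [-300, 0] ms kernel window")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    f_num, f_w1, f_w2 = default_kernels()
    s = trace.values

    drive = _filter_stimulus(s, f_num)
    ok = ~np.isnan(drive)
    drive_z = np.full_like(drive, np.nan)
    drive_z[ok] = (drive[ok] - np.nanmean(drive)) / np.nanstd(drive)

    min_spacing = int(round(2 * params.t_gap)) + 1
    peaks, _ = find_peaks(np.nan_to_num(drive_z, nan=-np.inf),
                          height=params.peak_height, distance=min_spacing)
    # keep events whose full analysis window fits inside the repeat
    peaks = peaks[(peaks >= 310) & (peaks <= trace.n_samples - 100)]
    if len(peaks) < 5:
        raise ValueError("fewer than 5 candidate events; stimulus too short or threshold too high")
    event_times = peaks.astype(float)
    n_ev = len(event_times)

    # standardized latent drives across events (identical across repeats)
    proj1 = _filter_stimulus(s, f_w1)[peaks]
    proj2 = _filter_stimulus(s, f_w2)[peaks]
    proj1 = (proj1 - proj1.mean()) / proj1.std()
    proj2 = (proj2 - proj2.mean()) / proj2.std()

    x_event = drive_z[peaks]
    thr = np.quantile(x_event, params.count_quantiles)

    th = np.deg2rad(params.theta_star)
    nr = params.n_rep
    # Signal gains chosen so the total latent variance (signal + trial noise)
    # is equal along both directions: the planted (u1, u2) cloud is then
    # circularly symmetric, as observed for the whitened coordinates of real
    # cells, and the low-noise component carries the larger signal share.
    v_tot = 1.0 + max(params.sigma1, params.sigma2) ** 2
    g1 = np.sqrt(v_tot - params.sigma1**2)
    g2 = np.sqrt(v_tot - params.sigma2**2)
    z1 = g1 * proj1[:, None] + params.sigma1 * rng.standard_normal((n_ev, nr))
    z2 = g2 * proj2[:, None] + params.sigma2 * rng.standard_normal((n_ev, nr))
    count_drive = x_event[:, None] + params.sigma_num * rng.standard_normal((n_ev, nr))
    counts = 1 + (count_drive[:, :, None] > thr[None, None, :]).sum(axis=2)

    u1 = z1 * np.cos(th) - z2 * np.sin(th)
    u2 = z1 * np.sin(th) + z2 * np.cos(th)
    jitter = params.jitter_sd * rng.standard_normal((n_ev, nr))

    isi_3_1 = params.m1 + 10.0 ** (params.beta0 + params.beta1 * u1)
    isi_3_2 = params.m2 + 10.0 ** (params.beta0 + params.beta1 * u2)
    isi_2sp = params.m1 + 10.0 ** (params.beta0 + params.beta1 * z1)

    rep_col: list[int] = []
    time_col: list[float] = []
    for e in range(n_ev):
        t0s = event_times[e] + jitter[e]
        for r in range(nr):
            k = counts[e, r]
            t0 = t0s[r]
            if k == 1:
                ts = [t0]
            elif k == 2:
                ts = [t0, t0 + isi_2sp[e, r]]
            else:
                i1, i2 = isi_3_1[e, r], isi_3_2[e, r]
                ts = [t0, t0 + i1, t0 + i1 + i2]
                if k == 4:
                    ts.append(ts[-1] + i2)
            rep_col.extend([r] * len(ts))
            time_col.extend(ts)

    spikes = pd.DataFrame({"repeat": rep_col, "time_ms": time_col})
    spikes = spikes.sort_values(["repeat", "time_ms"], kind="stable").reset_index(drop=True)

    truth = GroundTruth(
        tau_grid=TAU_GRID.copy(),
        f_num=f_num,
        f_w1=f_w1,
        f_w2=f_w2,
        theta_star=params.theta_star,
        event_times=event_times,
        z1=z1,
        z2=z2,
        count_drive=count_drive,
        counts=counts,
        u1=u1,
        u2=u2,
        params=params,
    )
    return spikes, truth
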