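"""Linear-reconstruction null model for 3-spike burst patterns.

The within-burst spike-triggered average STA_3spike is the average stimulus
around all spikes of 3-spike bursts, scaled by 1/3 so that the simplest
reconstruction, three superimposed copies, matches the 3-BTA amplitude.  The
reconstructed "stimulus" preceding a burst is the sum of three STA copies
shifted to its three spike times; it depends only on the STA and the burst's
ISIs, never on the actual stimulus, which is what makes it a null model: any
phase structure of the actual deviations that the reconstruction cannot
reproduce is evidence of coding beyond a linear spike-by-spike readout.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import mannwhitneyu

from .stimulus import StimulusTrace
from .triggered import (
    DEFAULT_WINDOW,
    RMS_WINDOW,
    TriggeredAverage,
    deviation_by_phase,
    extract_sequences,
    f16_smooth,
    mean_rms_deviation,
)

__all__ = [
    "compute_sta_3spike",
    "linear_reconstruct",
    "reconstructed_sequences",
    "compare_deviation_amplitude",
]

STA_SUPPORT = (-300, 0)  # STA is defined on [-300, 0] ms and zero outside


def compute_sta_3spike(
    stimulus: StimulusTrace,
    first_spike: np.ndarray,
    isi1: np.ndarray,
    isi2: np.ndarray,
) -> TriggeredAverage:
    """Within-burst STA: mean stimulus around all 3N spikes, times 1/3, smoothed."""
    t1 = np.asarray(first_spike, dtype=float)
    all_spikes = np.concatenate([t1, t1 + isi1, t1 + isi1 + isi2])
    seqs, _ = extract_sequences(stimulus, all_spikes, STA_SUPPORT)
    tau = np.arange(STA_SUPPORT[0], STA_SUPPORT[1] + 1, dtype=float)
    values = f16_smooth(seqs.mean(axis=0)) / 3.0
    return TriggeredAverage(tau=tau, values=values, n_triggers=len(seqs), label="STA_3spike")


def _sta_at(sta: TriggeredAverage, tau: np.ndarray, shift_ms: float) -> np.ndarray:
    """STA(tau - shift), zero outside its [-300, 0] support, on an integer grid."""
    shifted = np.round(tau - shift_ms).astype(int)
    out = np.zeros_like(tau, dtype=float)
    lo, hi = int(sta.tau[0]), int(sta.tau[-1])
    ok = (shifted >= lo) & (shifted <= hi)
    out[ok] = sta.values[shifted[ok] - lo]
    return out


def linear_reconstruct(
    sta: TriggeredAverage,
    isi1: float,
    isi2: float,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> np.ndarray:
    """Reconstruction for one burst: STA(tau) + STA(tau - ISI_1) + STA(tau - ISI_1 - ISI_2).

    Shifts are rounded to the 1-ms grid.  The waveform is returned on the
    inclusive ``window`` tau grid relative to the first spike.
    """
    tau = np.arange(window[0], window[1] + 1, dtype=float)
    return (
        _sta_at(sta, tau, 0.0)
        + _sta_at(sta, tau, float(isi1))
        + _sta_at(sta, tau, float(isi1) + float(isi2))
    )


def reconstructed_sequences(
    sta: TriggeredAverage,
    isi1: np.ndarray,
    isi2: np.ndarray,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> np.ndarray:
    """Stack of per-burst reconstructions, (n_bursts, n_tau)."""
    return np.vstack(
        [linear_reconstruct(sta, a, b, window) for a, b in zip(isi1, isi2)]
    )


def compare_deviation_amplitude(
    actual_devs: list,
    recon_devs: list,
    rms_window: tuple[float, float] = RMS_WINDOW,
) -> tuple[float, float]:
    """Mean-over-phase-bins RMS of actual vs reconstructed deviations (one cell).

    Both deviation sets must come from the same bursts and phase bins.
    """
    pop_a = [i for i, d in enumerate(actual_devs) if d is not None]
    pop_r = [i for i, d in enumerate(recon_devs) if d is not None]
    if pop_a != pop_r:
        raise ValueError("actual and reconstructed deviations use different phase bins")
    return (
        mean_rms_deviation(actual_devs, rms_window),
        mean_rms_deviation(recon_devs, rms_window),
    )


def population_rank_test(rms_actual: np.ndarray, rms_recon: np.ndarray) -> float:
    """Two-sided Mann-Whitney-Wilcoxon test across cells on the paired RMS sets."""
    if len(rms_actual) < 2 or len(rms_recon) < 2:
        raise ValueError("rank test needs at least 2 cells per group")
    return float(mannwhitneyu(rms_actual, rms_recon, alternative="two-sided").pvalue)
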