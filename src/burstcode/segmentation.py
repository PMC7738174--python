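"""Burst identification from repeated-trial spike trains.

Bursts are defined by an ISI threshold ``T_thresh`` placed at the trough
between the intra- and interburst peaks of the ISI histogram: consecutive
spikes closer than ``T_thresh`` join the same burst; a gap of ``T_thresh`` or
more starts a new burst (ties split).  Single spikes are 1-spike "isolated"
bursts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "BurstTrain",
    "isi_histogram",
    "find_threshold",
    "segment_bursts",
    "threshold_robustness",
]

MAX_SPIKES_PER_BURST = 16  # ISI columns materialized in the burst table


@dataclass
class BurstTrain:
    """Per-repeat bursts plus the threshold that produced them.

    ``table`` has one row per burst with columns ``repeat``, ``burst_id``
    (global, in (repeat, time) order), ``first_spike_ms``, ``n_spikes`` and
    ``isi1_ms``, ``isi2_ms``, ... (NaN where the burst has fewer ISIs).
    """

    table: pd.DataFrame
    T_thresh: float
    spikes: pd.DataFrame  # the input spikes (repeat, time_ms)

    @property
    def n_bursts(self) -> int:
        return len(self.table)

    def isis(self, row: pd.Series) -> np.ndarray:
        """ISIs of one burst row, in order, without NaNs."""
        k = int(row["n_spikes"])
        return np.array([row[f"isi{i}_ms"] for i in range(1, k)], dtype=float)

    def spike_times(self, row: pd.Series) -> np.ndarray:
        return row["first_spike_ms"] + np.concatenate([[0.0], np.cumsum(self.isis(row))])

    def of_count(self, k: int) -> pd.DataFrame:
        return self.table[self.table["n_spikes"] == k]


def _per_repeat(spikes: pd.DataFrame):
    for rep, grp in spikes.groupby("repeat", sort=True):
        yield int(rep), np.sort(grp["time_ms"].to_numpy(dtype=float))


def isi_histogram(
    spikes: pd.DataFrame,
    bin_ms: float = 1.0,
    range_ms: tuple[float, float] = (0.0, 300.0),
    log_bins: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of all within-repeat consecutive ISIs.

    Returns ``(bin_edges, counts)``.  With ``log_bins`` set, that many
    log-spaced bins over ``range_ms`` (lower edge floored at 0.5 ms) replace
    the default linear ``bin_ms`` grid.
    """
    isis: list[np.ndarray] = []
    for _, times in _per_repeat(spikes):
        if len(times) >= 2:
            isis.append(np.diff(times))
    if not isis:
        raise ValueError("need at least 2 spikes in one repeat to form ISIs")
    all_isis = np.concatenate(isis)
    lo, hi = range_ms
    if log_bins is not None:
        edges = np.geomspace(max(lo, 0.5), hi, log_bins + 1)
    else:
        edges = np.arange(lo, hi + bin_ms, bin_ms)
    counts, edges = np.histogram(all_isis, bins=edges)
    return edges, counts


def find_threshold(
    edges: np.ndarray,
    counts: np.ndarray,
    smooth_bins: int = 5,
    prominence_frac: float = 0.05,
    override_ms: float | None = None,
) -> float:
    """Locate ``T_thresh`` at the trough between the two largest histogram peaks.

    The histogram is smoothed with a ``smooth_bins``-wide moving average;
    peaks are local maxima with prominence at least ``prominence_frac`` of the
    global maximum.  ``override_ms`` short-circuits the search (manual
    threshold).
    """
    if override_ms is not None:
        return float(override_ms)
    centers = 0.5 * (edges[:-1] + edges[1:])
    kernel = np.ones(smooth_bins) / smooth_bins
    smoothed = np.convolve(counts.astype(float), kernel, mode="same")
    peaks, props = find_peaks(smoothed, prominence=prominence_frac * smoothed.max())
    if len(peaks) < 2:
        raise ValueError(
            "ISI histogram is not bimodal (fewer than 2 prominent peaks); "
            "set a manual threshold override"
        )
    # the two largest peaks bracket the trough
    order = np.argsort(smoothed[peaks])[::-1]
    p1, p2 = sorted(peaks[order[:2]])
    trough = p1 + int(np.argmin(smoothed[p1 : p2 + 1]))
    return float(centers[trough])


def segment_bursts(spikes: pd.DataFrame, T_thresh: float) -> BurstTrain:
    """Greedy left-to-right segmentation: gaps < ``T_thresh`` join a burst."""
    if T_thresh <= 0:
        raise ValueError("T_thresh must be positive")
    rows = []
    burst_id = 0
    for rep, times in _per_repeat(spikes):
        if len(times) == 0:
            continue
        # indices where a new burst starts
        starts = np.concatenate([[0], np.nonzero(np.diff(times) >= T_thresh)[0] + 1])
        ends = np.concatenate([starts[1:], [len(times)]])
        for s, e in zip(starts, ends):
            burst = times[s:e]
            isis = np.diff(burst)
            row = {
                "repeat": rep,
                "burst_id": burst_id,
                "first_spike_ms": burst[0],
                "n_spikes": len(burst),
            }
            for i in range(1, MAX_SPIKES_PER_BURST):
                row[f"isi{i}_ms"] = isis[i - 1] if i - 1 < len(isis) else np.nan
            rows.append(row)
            burst_id += 1
    table = pd.DataFrame(rows)
    return BurstTrain(table=table, T_thresh=float(T_thresh), spikes=spikes)


def burst_rate(train: BurstTrain, k: int, total_time_ms: float) -> float:
    """Rate (Hz) of k-spike bursts over the total recording time across repeats."""
    n = int((train.table["n_spikes"] == k).sum())
    return n / (total_time_ms / 1000.0)


def threshold_robustness(
    spikes: pd.DataFrame, T_thresh: float, k: int, total_time_ms: float
) -> float:
    """Maximum relative change of the k-spike burst rate under a +/-10 ms
    threshold perturbation: ``max(|r_-10 - r_0|, |r_+10 - r_0|) / r_0``.

    Returns NaN (with a warning) when the reference rate is zero.
    """
    if T_thresh <= 10:
        raise ValueError("T_thresh must exceed 10 ms for the +/-10 ms perturbation")
    rates = {}
    for d in (-10.0, 0.0, 10.0):
        rates[d] = burst_rate(segment_bursts(spikes, T_thresh + d), k, total_time_ms)
    r0 = rates[0.0]
    if r0 == 0:
        warnings.warn(f"no {k}-spike bursts at T_thresh={T_thresh}; robustness undefined")
        return float("nan")
    return max(abs(rates[-10.0] - r0), abs(rates[10.0] - r0)) / r0
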