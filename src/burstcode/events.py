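"""Cross-repeat assignment of bursts to events.

Bursts recur at similar times across repeats of the identical stimulus.  The
first spikes of all bursts, merged across repeats and sorted, form discrete
clusters; clusters are cut wherever consecutive merged first spikes are
``T_thresh`` or more apart, and each cluster defines one event.  When a single
repeat contributes two or more bursts to one event (rare, large-jitter cases)
they are concatenated into a single burst whose joining ISI is the inter-burst
gap — an exceptionally long intraburst ISI — and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import BurstTrain, MAX_SPIKES_PER_BURST

__all__ = ["EventTable", "merge_first_spikes", "cluster_events", "merge_exceptional"]


@dataclass
class EventTable:
    """Burst table augmented with event assignment.

    ``table`` carries the burst columns plus ``event_id`` and
    ``exceptional_flag``; after :func:`merge_exceptional` every
    (event, repeat) pair holds at most one burst.
    """

    table: pd.DataFrame
    T_thresh: float
    exceptional_fraction: float = 0.0

    @property
    def n_events(self) -> int:
        return int(self.table["event_id"].max()) + 1 if len(self.table) else 0

    def event_summary(self, min_bursts: int = 2) -> pd.DataFrame:
        """Per-event mean spike count ``n`` and mean 2-spike ISI ``m``.

        Events with fewer than ``min_bursts`` member bursts are dropped from
        per-event statistics.
        """
        rows = []
        for ev, grp in self.table.groupby("event_id"):
            if len(grp) < min_bursts:
                continue
            two = grp[grp["n_spikes"] == 2]
            rows.append(
                {
                    "event_id": ev,
                    "n_bursts": len(grp),
                    "mean_count": grp["n_spikes"].mean(),
                    "mean_2spike_isi": two["isi1_ms"].mean() if len(two) else np.nan,
                    "n_2spike": len(two),
                    "n_3spike": int((grp["n_spikes"] == 3).sum()),
                }
            )
        return pd.DataFrame(rows)


def merge_first_spikes(bursts: BurstTrain) -> pd.DataFrame:
    """Sorted multiset of all first-spike times across repeats.

    Returns a DataFrame with columns ``first_spike_ms``, ``repeat``,
    ``burst_id`` sorted by time (ties preserved as separate rows).
    """
    if bursts.n_bursts == 0:
        raise ValueError("no bursts to merge")
    cols = bursts.table[["first_spike_ms", "repeat", "burst_id"]]
    return cols.sort_values("first_spike_ms", kind="stable").reset_index(drop=True)


def cluster_events(merged: pd.DataFrame, T_thresh: float) -> np.ndarray:
    """Assign an event index to each merged first spike.

    Consecutive first spikes closer than ``T_thresh`` share an event; a gap of
    ``T_thresh`` or more starts a new event (equality splits, consistent with
    the burst rule).
    """
    t = merged["first_spike_ms"].to_numpy()
    new_event = np.concatenate([[True], np.diff(t) >= T_thresh])
    return np.cumsum(new_event) - 1


def assign_events(bursts: BurstTrain) -> EventTable:
    """Cluster bursts into events and resolve exceptional multi-burst repeats."""
    merged = merge_first_spikes(bursts)
    merged = merged.assign(event_id=cluster_events(merged, bursts.T_thresh))
    table = bursts.table.merge(merged[["burst_id", "event_id"]], on="burst_id", how="left")
    table["exceptional_flag"] = False
    et = EventTable(table=table, T_thresh=bursts.T_thresh)
    return merge_exceptional(et)


def _concat_bursts(rows: pd.DataFrame) -> dict:
    """Concatenate >= 2 bursts of one repeat (time order) into one burst row."""
    rows = rows.sort_values("first_spike_ms")
    times: list[float] = []
    for _, r in rows.iterrows():
        k = int(r["n_spikes"])
        isis = [r[f"isi{i}_ms"] for i in range(1, k)]
        t = r["first_spike_ms"] + np.concatenate([[0.0], np.cumsum(isis)]) if k > 1 else [
            r["first_spike_ms"]
        ]
        times.extend(np.atleast_1d(t))
    times = np.sort(np.asarray(times))
    isis = np.diff(times)
    out = {
        "repeat": int(rows.iloc[0]["repeat"]),
        "burst_id": int(rows.iloc[0]["burst_id"]),
        "first_spike_ms": times[0],
        "n_spikes": len(times),
        "event_id": int(rows.iloc[0]["event_id"]),
        "exceptional_flag": True,
    }
    for i in range(1, MAX_SPIKES_PER_BURST):
        out[f"isi{i}_ms"] = isis[i - 1] if i - 1 < len(isis) else np.nan
    return out


def merge_exceptional(event_table: EventTable) -> EventTable:
    """Merge multiple bursts of one repeat within one event into a single burst.

    Merging chains left-to-right when a repeat contributes three or more
    bursts.  The fraction of bursts involved in a merge is recorded in
    ``exceptional_fraction``.
    """
    table = event_table.table
    dup = table.groupby(["event_id", "repeat"]).size()
    dup_pairs = dup[dup > 1].index
    if len(dup_pairs) == 0:
        return EventTable(table=table, T_thresh=event_table.T_thresh, exceptional_fraction=0.0)
    n_before = len(table)
    merged_rows = []
    n_merged_members = 0
    drop_ids: set[int] = set()
    for (ev, rep) in dup_pairs:
        rows = table[(table["event_id"] == ev) & (table["repeat"] == rep)]
        n_merged_members += len(rows)
        merged_rows.append(_concat_bursts(rows))
        drop_ids.update(rows["burst_id"].tolist())
    out = table[~table["burst_id"].isin(drop_ids)]
    out = pd.concat([out, pd.DataFrame(merged_rows)], ignore_index=True)
    out = out.sort_values(["repeat", "first_spike_ms"], kind="stable").reset_index(drop=True)
    frac = n_merged_members / n_before
    return EventTable(table=out, T_thresh=event_table.T_thresh, exceptional_fraction=frac)
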