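import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import expon, norm

from burstcode.segmentation import (
    find_threshold,
    isi_histogram,
    segment_bursts,
    threshold_robustness,
)


def spikes_df(times_by_repeat):
    rows = [(r, t) for r, ts in times_by_repeat.items() for t in ts]
    return pd.DataFrame(rows, columns=["repeat", "time_ms"])


class TestIsiHistogram:
    def test_counts_consecutive_isis(self):
        edges, counts = isi_histogram(spikes_df({0: [0, 5, 10]}), bin_ms=1.0)
        # ISIs {5, 5}: two counts in the 5 ms bin
        centers = 0.5 * (edges[:-1] + edges[1:])
        assert counts[np.argmin(np.abs(centers - 5.5))] == 2
        assert counts.sum() == 2

    def test_isis_do_not_cross_repeats(self):
        edges, counts = isi_histogram(spikes_df({0: [0, 100], 1: [0, 100]}), bin_ms=1.0)
        assert counts.sum() == 2  # one 100 ms ISI per repeat, nothing between repeats

    def test_needs_two_spikes(self):
        with pytest.raises(ValueError):
            isi_histogram(spikes_df({0: [5.0], 1: [7.0]}))

    def test_simulator_histogram_is_bimodal(self, default_run):
        edges, counts = isi_histogram(
            default_run.spikes, range_ms=(0.5, 2000), log_bins=80
        )
        thr = find_threshold(edges, counts)
        assert 20 < thr < 400


class TestFindThreshold:
    def test_trough_of_exponential_normal_mixture(self, rng):
        # oracle: brute-force scan of the analytic mixture density minimum
        x = np.linspace(1, 300, 3000)
        dens = 0.5 * expon(scale=6).pdf(x) + 0.5 * norm(200, 30).pdf(x)
        lo = np.argmax(dens < dens.max())  # first index past the intra peak
        oracle_min = x[lo + np.argmin(dens[lo : np.argmin(np.abs(x - 200))])]
        assert 20 < oracle_min < 120
        isis = np.concatenate(
            [expon(scale=6).rvs(4000, random_state=1), norm(200, 30).rvs(4000, random_state=2)]
        )
        counts, edges = np.histogram(isis, bins=np.arange(0, 301.0, 1.0))
        thr = find_threshold(edges, counts)
        assert 20 < thr < 120

    def test_manual_override(self):
        assert find_threshold(np.array([0, 1]), np.array([5]), override_ms=42.0) == 42.0

    def test_unimodal_errors(self):
        isis = expon(scale=6).rvs(5000, random_state=0)
        counts, edges = np.histogram(isis, bins=np.arange(0, 301.0, 1.0))
        with pytest.raises(ValueError, match="manual threshold"):
            find_threshold(edges, counts)

    def test_recovered_threshold_separates_ground_truth(self, default_run):
        # every intraburst ISI < thr; every between-event gap >= thr
        thr = default_run.result.summary["T_thresh_ms"]
        tab = default_run.result.train.table
        isi_cols = [c for c in tab.columns if c.startswith("isi")]
        intra = tab[isi_cols].to_numpy().ravel()
        intra = intra[~np.isnan(intra)]
        assert intra.max() < thr
        ev_gaps = np.diff(np.sort(default_run.truth.event_times))
        assert ev_gaps.min() > thr


class TestSegmentBursts:
    def test_basic_split(self):
        train = segment_bursts(spikes_df({0: [0, 5, 10, 100, 105]}), 40.0)
        assert list(train.table["n_spikes"]) == [3, 2]
        b0 = train.table.iloc[0]
        assert (b0["isi1_ms"], b0["isi2_ms"]) == (5.0, 5.0)
        assert train.table.iloc[1]["first_spike_ms"] == 100.0

    def test_small_threshold_isolates_all(self):
        train = segment_bursts(spikes_df({0: [0, 5, 10, 100, 105]}), 3.0)
        assert list(train.table["n_spikes"]) == [1] * 5

    def test_gap_equal_to_threshold_splits(self):
        train = segment_bursts(spikes_df({0: [0.0, 40.0]}), 40.0)
        assert len(train.table) == 2

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        times=st.lists(
            st.floats(0, 10_000, allow_nan=False), min_size=1, max_size=60, unique=True
        ),
        thr=st.floats(0.5, 500),
    )
    def test_spike_conservation_and_idempotence(self, times, thr):
        df = spikes_df({0: sorted(times)})
        train = segment_bursts(df, thr)
        recovered = np.sort(
            np.concatenate([train.spike_times(row) for _, row in train.table.iterrows()])
        )
        np.testing.assert_allclose(recovered, np.sort(times), atol=1e-9)
        # re-segmenting any single burst returns it unchanged
        for _, row in train.table.iterrows():
            sub = segment_bursts(spikes_df({0: train.spike_times(row)}), thr)
            assert len(sub.table) == 1
            assert sub.table.iloc[0]["n_spikes"] == row["n_spikes"]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        times=st.lists(
            st.floats(0, 10_000, allow_nan=False), min_size=2, max_size=60, unique=True
        ),
        thr_pair=st.tuples(st.floats(0.5, 400), st.floats(0.5, 400)),
    )
    def test_raising_threshold_never_adds_bursts(self, times, thr_pair):
        lo, hi = sorted(thr_pair)
        df = spikes_df({0: sorted(times)})
        assert len(segment_bursts(df, hi).table) <= len(segment_bursts(df, lo).table)


class TestThresholdRobustness:
    def test_zero_when_gaps_are_well_separated(self):
        # intra ISIs all < thr-10, inter gaps all > thr+10
        df = spikes_df({0: [0, 5, 300, 306, 600, 604]})
        assert threshold_robustness(df, 50.0, 2, 1000.0) == 0.0

    def test_undefined_when_no_bursts(self):
        df = spikes_df({0: [0, 500]})
        with pytest.warns(UserWarning):
            out = threshold_robustness(df, 50.0, 3, 1000.0)
        assert np.isnan(out)

    def test_small_on_simulator_defaults(self, default_run):
        assert default_run.result.summary["threshold_robustness_2spike"] < 0.1
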