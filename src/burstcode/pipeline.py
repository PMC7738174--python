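"""End-to-end analysis: segmentation -> events -> information -> triggered
averages -> projections -> ISI geometry -> linear-reconstruction comparison.

``analyze`` runs every stage on one cell's spike trains and returns both the
intermediate objects (for further inspection) and a flat summary dict.  When
the data come from the built-in simulator, ground-truth comparisons (kernel
recovery, planted-angle recovery, offset recovery) are added to the summary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import events as ev
from . import geometry as geo
from . import information as info
from . import reconstruction as rec
from . import segmentation as seg
from . import triggered as trg
from .io import RunConfig, write_bursts, write_kernel, write_spikes, write_stimulus, write_waveform
from .projection import conditional_density, normalize_projection, project
from .simulator import GroundTruth, SimulationParams, simulate_ganglion_cell
from .stimulus import StimulusTrace, generate_uniform_stimulus

__all__ = ["AnalysisResult", "analyze", "run_pipeline"]


@dataclass
class AnalysisResult:
    """All stage outputs of one cell's analysis."""

    config: RunConfig
    stimulus: StimulusTrace
    spikes: pd.DataFrame
    train: seg.BurstTrain
    event_table: ev.EventTable
    coords: geo.ISICoordinates
    coords_event_ids: np.ndarray  # event id per included 3-spike burst
    theta_deg: float
    components: geo.IndependentComponents
    bta: dict  # k -> TriggeredAverage
    dev_long: trg.TriggeredAverage
    dev_short: trg.TriggeredAverage
    phase_centers: np.ndarray
    phase_devs: list
    recon_devs: list
    sta: trg.TriggeredAverage
    summary: dict


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __init__(self, n):
            self.n = n

        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc_val, tb):
            if exc_val is not None:
                raise RuntimeError(f"pipeline stage '{self.n}' failed: {exc_val}") from exc_val
            return False

    return _Ctx(name)


def analyze(
    spikes: pd.DataFrame,
    stimulus: StimulusTrace,
    config: RunConfig | None = None,
    truth: GroundTruth | None = None,
) -> AnalysisResult:
    cfg = config or RunConfig()
    T = stimulus.T
    n_rep = int(spikes["repeat"].nunique())
    total_time = T * n_rep
    window = tuple(cfg.bta_window)
    rms_window = tuple(cfg.rms_window)
    summary: dict = {"n_rep": n_rep, "T_ms": T}

    with _stage("segmentation"):
        edges, counts = seg.isi_histogram(
            spikes, range_ms=tuple(cfg.hist_range_ms), log_bins=cfg.hist_log_bins
        )
        T_thresh = seg.find_threshold(
            edges, counts, smooth_bins=cfg.hist_smooth_bins, override_ms=cfg.threshold_ms
        )
        train = seg.segment_bursts(spikes, T_thresh)
        summary["T_thresh_ms"] = T_thresh
        summary["n_bursts"] = train.n_bursts
        summary["threshold_robustness_2spike"] = seg.threshold_robustness(
            spikes, T_thresh, 2, total_time
        )
        counts_by_k = train.table["n_spikes"].value_counts().to_dict()
        summary["bursts_by_count"] = {int(k): int(v) for k, v in counts_by_k.items()}
        n_sp = len(spikes)
        n_in_multi = int(
            (train.table["n_spikes"] * (train.table["n_spikes"] >= 2)).sum()
        )
        summary["fraction_spikes_in_bursts"] = n_in_multi / n_sp

    with _stage("event clustering"):
        etab = ev.assign_events(train)
        tab = etab.table
        summary["n_events"] = etab.n_events
        summary["exceptional_fraction"] = etab.exceptional_fraction

    tab2 = tab[tab["n_spikes"] == 2]
    tab3 = tab[tab["n_spikes"] == 3]
    if len(tab2) < cfg.min_2spike:
        warnings.warn(
            f"only {len(tab2)} 2-spike bursts (< {cfg.min_2spike}); "
            "population-level criteria may be unreliable"
        )
    if len(tab3) < cfg.min_3spike:
        warnings.warn(f"only {len(tab3)} 3-spike bursts (< {cfg.min_3spike})")

    with _stage("ISI geometry"):
        isi1 = tab3["isi1_ms"].to_numpy()
        isi2 = tab3["isi2_ms"].to_numpy()
        ev_ids3 = tab3["event_id"].to_numpy()
        fit1, fit2 = geo.fit_sd_vs_mean_from_events(isi1, isi2, ev_ids3)
        coords = geo.transform_to_u(isi1, isi2, fit1, fit2)
        ev_ids_inc = ev_ids3[coords.included]
        theta, resid_var, theta_unstable = geo.trial_to_trial_pca(
            coords.u1, coords.u2, ev_ids_inc, min_bursts=cfg.min_event_bursts
        )
        summary["m1_ms"] = fit1.m
        summary["m2_ms"] = fit2.m
        summary["sd_mean_slope_1"] = fit1.a
        summary["sd_mean_slope_2"] = fit2.a
        summary["n_3spike_included"] = int(coords.n)
        summary["n_3spike_excluded_short"] = int((~coords.included).sum())
        summary["theta_deg"] = theta
        summary["theta_unstable"] = theta_unstable
        summary["residual_variances"] = [float(v) for v in resid_var]

        ev_sum = etab.event_summary(min_bursts=cfg.min_event_bursts)
        both = ev_sum.dropna(subset=["mean_2spike_isi"])
        both = both[both["n_3spike"] >= 1]
        # event means of u over included bursts
        u1bar, u2bar, m_ev, n_ev_count = [], [], [], []
        for _, row in both.iterrows():
            sel = ev_ids_inc == row["event_id"]
            if sel.sum() == 0:
                continue
            u1bar.append(coords.u1[sel].mean())
            u2bar.append(coords.u2[sel].mean())
            m_ev.append(row["mean_2spike_isi"])
            n_ev_count.append(row["mean_count"])
        u1bar = np.asarray(u1bar)
        u2bar = np.asarray(u2bar)
        m_ev = np.asarray(m_ev)
        grad_dir, grad_coef = geo.steepest_gradient(m_ev, u1bar, u2bar)
        summary["gradient_direction_deg"] = grad_dir
        # fix the w1 sign: the 2-spike ISI must increase along +w1
        d = (grad_dir - theta + 180.0) % 360.0 - 180.0
        theta_w = theta if abs(d) <= 90 else (theta + 180.0) % 360.0
        comps = geo.independent_components(coords.u1, coords.u2, theta_w, resid_var)
        summary["theta_w_deg"] = theta_w

        ev2 = ev_sum.dropna(subset=["mean_2spike_isi"])
        summary["count_isi_correlation"] = geo.spike_count_isi_correlation(
            ev2["mean_count"].to_numpy(), ev2["mean_2spike_isi"].to_numpy()
        )

    with _stage("information"):
        times_by_k = {
            int(k): grp["first_spike_ms"].to_numpy()
            for k, grp in tab.groupby("n_spikes")
        }
        summary["I_number_bits"] = info.info_burst_number(times_by_k, T, cfg.time_bin_ms)
        if len(tab2) >= 50:
            res2 = info.info_isi(
                tab2["first_spike_ms"].to_numpy(),
                tab2["isi1_ms"].to_numpy(),
                T,
                dt_grid=tuple(cfg.dt_grid),
                time_bin=cfg.time_bin_ms,
            )
            summary["I_isi_2spike_bits"] = res2.info_bits
            summary["I_isi_2spike_fit_r2"] = res2.r_squared
        if len(tab3) >= 50:
            res3 = info.info_isi(
                tab3["first_spike_ms"].to_numpy(),
                tab3[["isi1_ms", "isi2_ms"]].to_numpy(),
                T,
                dt_grid=tuple(cfg.dt_grid),
                time_bin=cfg.time_bin_ms,
            )
            summary["I_isi_3spike_joint_bits"] = res3.info_bits

    with _stage("triggered averages"):
        bta = {}
        for k in sorted(times_by_k):
            if k > 4 or len(times_by_k[k]) < 10:
                continue
            bta[k] = trg.compute_bta(stimulus, times_by_k[k], window, label=f"{k}-BTA")
        dev_long, dev_short = trg.deviation_by_isi_split(
            stimulus, tab2["first_spike_ms"].to_numpy(), tab2["isi1_ms"].to_numpy(), window
        )
        dls = dev_long.values - dev_short.values
        summary["dev2_peak_freq_hz"] = trg.peak_frequency(dls)

        # 3-spike phase-binned deviations against the all-3-spike BTA
        tab3_inc = tab3[coords.included]
        trig3 = trg.aligned_triggers(
            tab3_inc["first_spike_ms"].to_numpy(),
            tab3_inc["isi1_ms"].to_numpy(),
            tab3_inc["isi2_ms"].to_numpy(),
            cfg.alignment,
        )
        seqs3, ok3 = trg.extract_sequences(stimulus, trig3, window)
        phases = coords.phase_deg[ok3]
        u1_ok, u2_ok = coords.u1[ok3], coords.u2[ok3]
        ref3 = trg.f16_smooth(seqs3.mean(axis=0))
        centers, devs = trg.deviation_by_phase(
            seqs3, phases, reference=ref3, n_bins=cfg.phase_bins, window=window
        )
        summary["rms_actual"] = trg.mean_rms_deviation(devs, rms_window)
        r_centers, r_rms = trg.amplitude_vs_distance(
            seqs3, u1_ok, u2_ok, reference=ref3, window=window, rms_window=rms_window
        )
        summary["amplitude_vs_distance"] = {
            "r": [float(x) for x in r_centers],
            "rms": [float(x) for x in r_rms],
        }
        summary["amplitude_distance_spearman"] = trg.monotonic_spearman(r_centers, r_rms)
        # deviations at the independent-component phases (theta_w +/- 15 deg etc.)
        w_sets = geo.phase_sets(phases, theta_w, 15.0)
        w_devs = {}
        for name, mask in w_sets.items():
            if mask.sum() < 10:
                continue
            w_devs[name] = trg.f16_smooth(seqs3[mask].mean(axis=0)) - ref3
        if "w1_plus" in w_devs:
            summary["w1_peak_freq_hz"] = trg.peak_frequency(w_devs["w1_plus"])
        if "w2_plus" in w_devs:
            summary["w2_peak_freq_hz"] = trg.peak_frequency(w_devs["w2_plus"])

    with _stage("projections"):
        tau = np.arange(window[0], window[1] + 1)
        neg = tau <= 0  # projection features live on [-300, 0]
        proj_summary = {}
        if 1 in bta and 3 in bta:
            f31 = (bta[3].values - bta[1].values)[neg]
            t_p, raw = project(stimulus, f31)
            all_trig = tab["first_spike_ms"].to_numpy()
            all_trig = all_trig[(all_trig >= t_p[0]) & (all_trig <= t_p[-1])]
            ps = normalize_projection(t_p, raw, scope="at-burst", sample_times=all_trig)
            sel = (tab["first_spike_ms"] >= t_p[0]) & (tab["first_spike_ms"] <= t_p[-1])
            vals = ps.at(tab.loc[sel, "first_spike_ms"].to_numpy())
            dens = conditional_density(vals, tab.loc[sel, "n_spikes"].to_numpy())
            proj_summary["s_3m1_burst_means"] = {
                int(k): d["mean"] for k, d in dens.items() if k <= 4
            }
        # s_D2 conditioned on ISI percentile groups
        fD2 = (dev_long.values - dev_short.values)[neg]
        t_p, raw = project(stimulus, fD2)
        t2 = tab2["first_spike_ms"].to_numpy()
        isi2sp = tab2["isi1_ms"].to_numpy()
        in_rng = (t2 >= t_p[0]) & (t2 <= t_p[-1])
        t2, isi2sp = t2[in_rng], isi2sp[in_rng]
        psd2 = normalize_projection(t_p, raw, scope="at-burst", sample_times=t2)
        vals2 = psd2.at(t2)
        pct = 100.0 * (np.argsort(np.argsort(isi2sp)) / max(len(isi2sp) - 1, 1))
        group_means = {}
        for lo, hi in cfg.percentile_groups:
            sel = (pct >= lo) & (pct < hi) if hi < 100 else (pct >= lo)
            if sel.sum() >= 5:
                group_means[f"{int(lo)}-{int(hi)}"] = float(vals2[sel].mean())
        proj_summary["s_D2_isi_group_means"] = group_means
        # w1 / w2 features from the quadrant partition
        d_sets = geo.phase_sets(phases, theta_w, 45.0)
        w_feat = {}
        for dname in ("1", "2"):
            plus, minus = d_sets[f"w{dname}_plus"], d_sets[f"w{dname}_minus"]
            if plus.sum() < 10 or minus.sum() < 10:
                continue
            f = (
                trg.f16_smooth(seqs3[plus].mean(axis=0))
                - trg.f16_smooth(seqs3[minus].mean(axis=0))
            )[neg]
            w_feat[dname] = f
        w_groups = {}
        for dname, f in w_feat.items():
            t_p, raw = project(stimulus, f)
            t3 = trig3[ok3]
            in3 = (t3 >= t_p[0]) & (t3 <= t_p[-1])
            psw = normalize_projection(t_p, raw, scope="at-burst", sample_times=t3[in3])
            valsw = psw.at(t3[in3])
            w_val = (comps.w1 if dname == "1" else comps.w2)[ok3][in3]
            for gname, gsel in (
                ("low", w_val < -2),
                ("mid", (w_val >= -0.5) & (w_val < 0.5)),
                ("high", w_val >= 2),
            ):
                if gsel.sum() >= 5:
                    w_groups[f"s_w{dname}|w{dname}_{gname}"] = float(valsw[gsel].mean())
        proj_summary["s_w_group_means"] = w_groups
        summary["projections"] = proj_summary

    with _stage("linear reconstruction"):
        sta = rec.compute_sta_3spike(
            stimulus,
            tab3["first_spike_ms"].to_numpy(),
            tab3["isi1_ms"].to_numpy(),
            tab3["isi2_ms"].to_numpy(),
        )
        recon_seqs = rec.reconstructed_sequences(
            sta, coords.isi1[ok3], coords.isi2[ok3], window
        )
        _, recon_devs = trg.deviation_by_phase(
            recon_seqs, phases, n_bins=cfg.phase_bins, window=window
        )
        rms_a, rms_r = rec.compare_deviation_amplitude(devs, recon_devs, rms_window)
        summary["rms_actual"] = rms_a
        summary["rms_reconstructed"] = rms_r
        summary["rms_ratio"] = rms_a / rms_r if rms_r > 0 else float("inf")

    if truth is not None:
        with _stage("ground-truth recovery"):
            gt: dict = {}
            gt["theta_star_deg"] = truth.theta_star
            gt["theta_error_deg"] = float(
                abs((summary["theta_deg"] - truth.theta_star + 90) % 180 - 90)
            )
            gt["gradient_error_deg"] = float(
                abs((summary["gradient_direction_deg"] - truth.theta_star + 90) % 180 - 90)
            )
            gt["m1_error_ms"] = abs(fit1.m - truth.params.m1)
            gt["m2_error_ms"] = abs(fit2.m - truth.params.m2)
            # the deviation estimate is F16-smoothed, so compare against the
            # equally smoothed planted kernel
            kern = trg.f16_smooth(truth.f_w1)
            dls_neg = (dev_long.values - dev_short.values)[neg]
            gt["dev2_fw1_correlation"] = float(np.corrcoef(dls_neg, kern)[0, 1])
            n_post = window[1] - 0  # kernels live on [-300, 0]; zero-pad past 0
            fw1_pad = np.concatenate([truth.f_w1, np.zeros(n_post)])
            fw2_pad = np.concatenate([truth.f_w2, np.zeros(n_post)])
            r_track, p_track = trg.phase_tracking(
                devs, centers, fw1_pad, fw2_pad, np.arange(window[0], window[1] + 1)
            )
            gt["phase_tracking_R"] = r_track
            gt["phase_tracking_p"] = p_track
            summary["ground_truth"] = gt

    return AnalysisResult(
        config=cfg,
        stimulus=stimulus,
        spikes=spikes,
        train=train,
        event_table=etab,
        coords=coords,
        coords_event_ids=ev_ids_inc,
        theta_deg=theta,
        components=comps,
        bta=bta,
        dev_long=dev_long,
        dev_short=dev_short,
        phase_centers=centers,
        phase_devs=devs,
        recon_devs=recon_devs,
        sta=sta,
        summary=summary,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline from a config; write outputs when out_dir is set.

    Returns the summary dict (also written as ``summary.json``).
    """
    cfg = config
    if cfg.simulate:
        stimulus = generate_uniform_stimulus(cfg.T_ms, cfg.refresh_hz, seed=cfg.seed)
        params = SimulationParams(n_rep=cfg.n_rep)
        spikes, truth = simulate_ganglion_cell(stimulus, params=params, seed=cfg.seed + 1)
    else:
        from .io import read_spikes, read_stimulus

        if cfg.spikes_path is None or cfg.stimulus_path is None:
            raise ValueError("non-simulation runs need spikes_path and stimulus_path")
        spikes = read_spikes(cfg.spikes_path)
        stimulus = read_stimulus(cfg.stimulus_path).normalized()
        truth = None

    result = analyze(spikes, stimulus, cfg, truth=truth)
    summary = dict(result.summary)
    summary["config_hash"] = cfg.config_hash()
    summary["seed"] = cfg.seed

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_spikes(spikes, out / "spikes.csv")
        write_stimulus(stimulus, out / "stimulus.csv")
        write_bursts(result.event_table.table, out / "bursts.csv")
        result.event_table.event_summary(cfg.min_event_bursts).to_csv(
            out / "events.csv", index=False
        )
        for k, ta in result.bta.items():
            write_waveform(ta, out / f"bta_{k}spike.csv")
        write_waveform(result.dev_long, out / "dev2_long.csv")
        write_waveform(result.dev_short, out / "dev2_short.csv")
        write_waveform(result.sta, out / "sta_3spike.csv")
        for m, d in enumerate(result.phase_devs):
            if d is not None:
                write_waveform(d, out / f"dev3_phase{m:02d}.csv")
        if truth is not None:
            write_kernel(truth.tau_grid, truth.f_num, out / "true_f_num.csv")
            write_kernel(truth.tau_grid, truth.f_w1, out / "true_f_w1.csv")
            write_kernel(truth.tau_grid, truth.f_w2, out / "true_f_w2.csv")
            prov = {"generation_params": truth.params_dict(), "seed": cfg.seed,
                    "theta_star_deg": truth.theta_star,
                    "event_times_ms": [float(t) for t in truth.event_times]}
            (out / "ground_truth.json").write_text(json.dumps(prov, indent=1))
        (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
        cfg.to_yaml(out / "config.yaml")
    return summary
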