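# burstcode

Retinal ganglion cells fire bursts — clusters of spikes separated by longer
silences — and a burst with *k* spikes has *k* degrees of freedom: the spike
count and the *k*−1 intraburst interspike intervals (ISIs).  `burstcode` is an
analysis pipeline for repeated-trial spike recordings that tests whether these
degrees of freedom *combinatorially* encode distinct stimulus features: the
spike count tracking the amplitude of slow (~5 Hz) light-intensity modulation,
and the intraburst ISIs tracking the amplitude and phase of much faster
(~8 Hz) oscillatory components.  It is aimed at sensory-coding labs working
with repeated identical stimulation (e.g. full-field Gaussian-noise light) and
sorted single-unit spike times.

Because such analyses are easy to get subtly wrong, the package ships a
synthetic ganglion-cell simulator whose generative model plants every quantity
the pipeline is supposed to recover (kernels, coding angle, ISI offsets),
making each stage verifiable by parameter recovery.

## The analysis

1. **Burst segmentation.** The ISI histogram of a bursting cell is bimodal;
   the threshold *T*<sub>thresh</sub> is placed at the trough, and consecutive
   spikes closer than *T*<sub>thresh</sub> join one burst.
2. **Events.** Bursts recur at the same stimulus times across repeats; the
   merged, sorted train of first spikes forms clusters (cut at
   *T*<sub>thresh</sub>), each defining one *event*.
3. **Information.** With a uniform stimulus prior over one repeat [0, *T*),
   the information carried by a burst attribute *X* is the plug-in estimate
   *I* = *S*[*P*(*t*|burst)] − Σ<sub>x</sub> *P*(x) *S*[*P*(*t*|x)].
   ISI information is computed at resolution Δ*t* and extrapolated linearly to
   Δ*t* → 0 over Δ*t* = 1.5–4 ms.
4. **Burst-triggered averages.** *k*-BTA(τ) is the mean stimulus on
   τ ∈ [−300, 0] ms before *k*-spike bursts, smoothed by a 16-ms boxcar (F16).
   *Deviations* condition on an ISI group or phase bin and subtract the BTA.
5. **ISI geometry.** For 3-spike bursts, *v<sub>d</sub>* =
   log₁₀(ISI<sub>d</sub> − *m<sub>d</sub>*) homogenizes trial-to-trial
   variability (*m<sub>d</sub>* from the per-event SD-vs-mean line); the
   standardized pair is whitened (symmetric/ZCA) into (*u*₁, *u*₂), and the
   burst phase is φ = Arg(*u*₁ + *i·u*₂).  PCA of within-event residuals
   gives the angle θ of the low-variance axis; *w*₁ = *u*₁cos θ + *u*₂sin θ
   and its orthogonal partner *w*₂ are the approximately independent
   components, *w*₁ being shared with 2-spike-burst ISIs.
6. **Linear-reconstruction null.** Per burst, three copies of the within-burst
   STA shifted to the three spike times; phase-binned deviations of this
   reconstruction are compared (RMS over [−200, +25] ms) with the actual ones.

## Worked example

```python
from burstcode import RunConfig, run_pipeline

summary = run_pipeline(RunConfig(seed=0, out_dir="demo"))
```

This simulates the default cell (30 repeats × 120 s of 30 Hz sample-and-hold
Gaussian noise, planted coding angle θ\* = 30°, ISI offsets
m₁ = m₂ = 2 ms), runs every stage, and writes tables plus `summary.json`.
Key numbers from this run and what they mean:

| quantity | value | meaning |
|---|---|---|
| `T_thresh_ms` | 33.4 | ISI-histogram trough used for segmentation |
| `threshold_robustness_2spike` | 0.001 | rate change under a ±10 ms threshold shift — segmentation is stable |
| `I_number_bits` | 1.05 | stimulus information per burst in the spike count |
| `I_isi_2spike_bits` | 1.90 | ISI information of 2-spike bursts, extrapolated to Δt → 0 |
| `I_isi_3spike_joint_bits` | 3.18 | joint (ISI₁, ISI₂) information of 3-spike bursts |
| `theta_deg` | 34.9 | low-variance residual axis (planted at 30°) |
| `gradient_direction_deg` | 34.6 | steepest gradient of the 2-spike ISI on the u-plane — aligned with θ, i.e. the shared mechanism |
| `dev2_peak_freq_hz` | 8.3 | peak frequency of the ISI-encoded oscillatory feature |
| `rms_actual` / `rms_reconstructed` | 0.322 / 0.020 | phase-binned deviation amplitude, data vs linear-reconstruction null (ratio ≈ 16: the phase code is not linearly decodable) |

The `ground_truth` block reports recovery errors against the planted model,
e.g. `theta_error_deg: 4.9`, `m1_error_ms: 0.46`, and
`dev2_fw1_correlation: 0.89` (waveform match between the recovered 2-spike
deviation difference and the planted oscillatory kernel).

The same stages are available from the shell:

```bash
burstcode simulate --duration-s 120 --n-rep 30 --seed 0 --out-dir demo
burstcode detect-bursts --spikes demo/spikes.csv --threshold-ms AUTO --out demo/bursts.csv
burstcode run-all --out-dir demo --seed 0
```

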