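# Methods

## Scope and data model

`burstcode` analyzes repeated-trial spike-time data: one set of spike times
(ms) per repeat of an identical stimulus, all aligned to stimulus onset,
together with a 1-D normalized light-intensity trace (mean 0, SD 1) and its
sampling period.  All internal analyses run on a 1 ms grid; every τ window is
an inclusive integer-ms grid (so [−300, 0] ms has 301 samples).  The pipeline
accepts any 1-D intensity trace, including one pre-extracted at a receptive
field center; receptive-field estimation and spike sorting are out of scope.

## Burst and event identification

Within-repeat ISIs of a bursting cell form a bimodal histogram (intra- vs
interburst intervals).  `find_threshold` smooths the histogram with a moving
average (default 5 bins), finds local maxima with prominence ≥ 5% of the
global maximum, and places T_thresh at the minimum between the two largest
peaks; a manual override is available because real histograms can be messy.
The histogram binning is configurable (the pipeline default is 80 log-spaced
bins over 0.5–2000 ms, which resolves both the few-ms intraburst peak and the
long interburst tail); linear 1 ms bins over 0–300 ms are the low-level
default.  Segmentation is greedy left-to-right: a gap < T_thresh joins,
a gap ≥ T_thresh splits (ties split; the underlying description leaves
equality open, and the same convention is used for event clustering).

Events are clusters of the merged cross-repeat train of burst first spikes,
cut at gaps ≥ T_thresh.  When one repeat contributes ≥ 2 bursts to one event
(large-jitter cases) they are concatenated into one burst whose joining ISI is
the inter-burst gap; merges chain left-to-right if a repeat contributes ≥ 3.
Merged bursts are retained but flagged, and the flagged fraction is reported;
events with fewer than 2 member bursts are excluded from per-event statistics.

Threshold robustness is max(|r₋₁₀ − r₀|, |r₊₁₀ − r₀|)/r₀ where r are the
2-spike burst rates at T_thresh ∓ 10 ms, with rates defined as counts over
the total recording time across repeats.

## Information estimates

The stimulus prior is uniform over one repeat [0, T).  Posteriors P(t | X)
are rate-based: trigger times pooled across repeats, histogrammed into bins
of one stimulus frame (33.3 ms) by default.  The reported values are plug-in
entropy differences in bits per burst; they depend on the time bin, which is
exposed in the config (the formulation is continuous in t, but any finite-
repeat estimate discretizes; absolute bit values are therefore
discretization-dependent and only differences and orderings are interpreted).
No sampling-bias correction is applied; `shuffle_null` quantifies the
finite-sampling bias by destroying the time–ISI association.

ISI information uses bins [lΔt, (l+1)Δt) — a 2-D product grid for the two
ISIs of 3-spike bursts — computed on Δt ∈ {1.5, 2.0, 2.5, 3.0, 3.5, 4.0} ms
(the fit range where the Δt dependence is linear; the exact grid is a
package choice) and extrapolated linearly to Δt = 0.  Negative intercepts are
clamped to 0 with a warning.  Empty bins contribute 0·log 0 := 0.

## Triggered averages and deviations

BTAs average the stimulus around the reference spike (first spike by default;
second/third/middle alignments available) and are smoothed with F16, a
centered boxcar over ±8 ms — 17 taps at 1 ms, normalized by 1/17, with
truncated-window renormalization at edges so constants pass through.  BTAs
extend internally to τ = +25 ms so deviation amplitudes can be summarized by
the RMS over [−200, +25] ms; displayed windows are [−300, 0] unless the +25 ms
extension is needed.  SEMs are computed across smoothed per-trigger sequences.

Deviations subtract the unconditional BTA from a conditional one: the
longest/shortest-50%-ISI split for 2-spike bursts, and twelve 30° phase bins
(M·30° ± 15°, wrapping at 360°) for 3-spike bursts.  Because F16 is linear,
the count-weighted sum of phase-bin deviations is identically zero when the
reference BTA comes from the same bursts.

The amplitude-vs-distance curve bins bursts by r = (u₁² + u₂²)^½
(equal-count bins) and, *within* each r bin, sub-groups by phase before
computing deviations — averaging across phases without sub-grouping would
cancel oscillations of opposite phase and flatten the curve.  Cell RMS values
are count-weighted averaged across phases per r bin.

Peak frequency is the maximum of the periodogram of the mean-subtracted,
Hann-windowed waveform, zero-padded to 4096 samples (resolution ≈ 0.24 Hz);
the spectral method is a package choice.  DC-only waveforms return NaN.

## ISI geometry

Per event, the SD of each ISI grows linearly with its mean; the OLS
x-intercept m_d and slope a_d define v_d = log₁₀(ISI_d − m_d), which has
approximately uniform trial-to-trial variability across events.  Events need
≥ 2 3-spike bursts to contribute (SD undefined otherwise, sample SD with
n−1).  If the fitted m_d is not below the smallest ISI it is shrunk to
(min ISI − 0.1 ms) with a warning.  Bursts with ISI_d ≤ m_d are excluded and
logged; `short_isi_replacement` re-incorporates them by substituting the
smallest included ISI_d, which on synthetic data leaves the phase-binned
deviations essentially unchanged (waveform correlation > 0.95).

Each v_d is standardized (linear map to mean 0, SD 1) and the pair whitened
symmetrically: rotate into the principal axes of (v*₁, v*₂), scale by the
inverse axis SDs, rotate back (ZCA).  The sample covariance of (u₁, u₂) is
the identity to 1e-9 by construction.  Burst phase is atan2(u₂, u₁) in
[0°, 360°); the origin is flagged NaN.

Within-event residuals (u − event mean), pooled over events with ≥ 2 bursts,
are subjected to PCA; θ ∈ [0°, 180°) is the angle of the smaller-variance
axis (flagged unstable if the variance ratio is within 1e-6 of 1).  The
independent components are w₁ = u₁cos θ + u₂sin θ and the orthogonal w₂.
Since PCA axis signs are conventional, the w₁ sign is fixed by requiring the
2-spike ISI to increase along +w₁ (via the steepest-gradient fit
m⁽ʲ⁾ = α₀ + α₁ū₁⁽ʲ⁾ + α₂ū₂⁽ʲ⁾ over events containing both burst types);
when no 2-spike bursts exist the u₁-positive convention applies.

Circular statistics use vector averaging with SD = √(−2 ln R̄); axial data
(fold 180°) are doubled first and folded back.

## Linear-reconstruction null

STA_3spike is the mean stimulus around all 3N spikes of 3-spike bursts,
multiplied by 1/3 (so that three superimposed copies match the 3-BTA
amplitude; the factor resolves an ambiguity in the printed prefactor of the
source analysis) and F16-smoothed; it is zero outside [−300, 0] ms.  The
reconstruction for a burst is the sum of three STA copies shifted by 0, ISI₁
and ISI₁+ISI₂ (shifts rounded to the ms grid).  It depends only on the STA
and the burst's ISIs — never on the stimulus — which is what makes it a null
model: the reconstructed phase-binned deviations are nearly identical across
phase bins, so any large actual-vs-reconstructed RMS ratio demonstrates
coding that a linear spike-by-spike readout cannot express.  Across cells the
comparison uses a two-sided Mann–Whitney–Wilcoxon test; single-cell runs
report the RMS pair without a p-value.

## The synthetic ganglion cell

The simulator implements the coding scheme the pipeline targets, so that
every stage has a recoverable planted quantity.  It emulates a full-field
30 Hz sample-and-hold Gaussian-noise stimulus (triangular autocorrelation,
width at half maximum = hold period = 33.3 ms) and an OFF cell with:

- **Events**: peaks of the stimulus filtered with a slow biphasic OFF kernel
  f_num (OFF lobe at −70 ms, σ = 50 ms; ON lobe at −190 ms, σ = 60 ms),
  above 0.8 SD, spaced > 2·t_gap = 300 ms.  Deterministic in the stimulus,
  hence identical across repeats.  The lobe widths make f_num's power at
  ~8 Hz negligible: the count mechanism and the ISI mechanisms must be
  spectrally separated, otherwise conditioning on event times leaks the slow
  structure into the fast-feature estimates.
- **Counts** k ∈ {1..4}: the filtered drive at the event time plus
  N(0, 0.25²) noise, thresholded at the 15/40/82% quantiles of the noiseless
  event drives (majority of bursts have ≥ 2 spikes).
- **ISI latents**: two orthonormal quadrature ~8 Hz Gabor kernels f_w1, f_w2
  (envelope center −100 ms, σ = 55 ms) drive z_d = g_d·⟨S, f_wd⟩ + ε_d with
  ε_d ~ N(0, σ_d²), σ₁ = 0.5 < σ₂ = 1.0.  The gains
  g_d = √(v_tot − σ_d²), v_tot = 1 + max(σ_d)², make the total latent
  variance isotropic: the planted (u₁, u₂) cloud is circularly symmetric —
  matching the whitened coordinates of real cells — so the analysis frame is
  not rotated relative to the planted frame, and the low-noise component
  (shared with 2-spike bursts) carries the larger signal share, i.e. w₁ is
  the more informative component.
- **Planted plane**: (u₁, u₂) = z₁(cos θ\*, sin θ\*) + z₂(−sin θ\*, cos θ\*),
  θ\* = 30°.
- **ISIs**: ISI_d = m_d + 10^(β₀ + β₁·u_d) with m₁ = m₂ = 2 ms,
  β₀ = log₁₀ 6 (median 2-spike ISI ≈ 8 ms, a realistic intraburst scale) and
  β₁ = 0.12; the log-linear law makes the trial SD grow linearly with the
  trial mean, which is exactly what the v-transform undoes.  2-spike bursts
  use z₁ alone; 4-spike bursts duplicate ISI₂ as ISI₃.
- **Timing**: first spikes get N(0, 2 ms) jitter; spikes at cumulative ISIs.

Defaults are 30 repeats × 120 s, giving ≈ 200 events, ≈ 5800 bursts and
≈ 2500–2800 3-spike bursts — enough for each recovery check while a full
pipeline run stays around one second.  What the simulator does *not* emulate:
biophysics (no conductances, refractoriness or adaptation), spatial stimuli,
natural-scene temporal correlations, rate nonstationarity, spike-sorting
errors, and any cross-cell diversity.  Passing recovery tests therefore
demonstrates the correctness of the estimators under the stated generative
assumptions, not that real retinal data will show these codes.

## Degenerate inputs and numerical conventions

Explicitly handled: unimodal ISI histograms (error + manual override), zero
burst rates (robustness undefined, NaN), all-identical ISIs (degenerate
deviations, warning), the (0,0) phase origin (NaN), isotropic residuals
(θ flagged unstable), perfectly correlated ISI coordinates (whitening error),
constant projections (error), DC-only waveforms (NaN peak frequency),
negative extrapolated information (clamped to 0).  Whitening and PCA use
sample (n−1) covariances throughout.  The phase-tracking check used in
recovery tests is direction-agnostic (resultant length of recovered-phase
minus-or-plus bin-phase, permutation p-value) because whitening sign
conventions make the rotation sense arbitrary.

## Reported problem sizes

The test suite runs the default simulation once (session fixture); the
stimulus-autocorrelation reference uses a 600 s trace; estimator-oracle
equivalences use small random instances (hundreds of samples).  These sizes
were chosen so the whole verification cycle runs on a laptop in well under a
minute while keeping every recovery margin comfortable.
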