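# Methods

This note documents the models, numerical choices and limitations behind
`hippotheta`. It is written for users who need to know exactly what the
pipeline computes and what passing its tests does and does not establish.

## Oscillation detection

**Spectral estimate.** Welch PSD with 4-s Hann windows, 50% overlap,
zero-padded to a 0.1-Hz grid over 1–30 Hz. Artifact-masked stretches are cut
out first; Welch estimates from the remaining contiguous stretches are
averaged with length weights. The averaged spectrum is smoothed across
frequency with a 0.5-Hz Daniell (moving-average) window: with ~4-s windows
the per-bin estimator noise is otherwise comparable to the excursion of a
weak narrowband peak, and the light smoothing suppresses single-bin noise
runs without displacing peaks (symmetric kernel) or blurring structure
beyond the ~0.25-Hz natural resolution of the windows.

**Background fit.** log10(power) is regressed on log10(frequency) over
2–30 Hz; points more than one residual SD *above* the line are excluded and
the line refit, so narrowband peaks do not bias the aperiodic slope or
intercept. The `residual_sd` used in the detection threshold is then
computed over **all** grid points relative to the refit line. This choice is
deliberate: if the SD were computed only on the retained (sub-threshold)
points it would track pure estimator noise, and a threshold of "fit + 1 SD"
would by construction pass ~16% of grid points on any spectrum, flooding
the detector with spurious bands. Computing the SD over all points lets
genuine peaks raise the threshold, which matches the regime the method is
intended for: spectra in which narrowband oscillations visibly stand out of
the 1/f background.

**Band definition.** Bands are maximal runs of grid points with log-power
above fit + 1·residual_sd, clipped to 2–14 Hz; runs narrower than 2 grid
points are discarded and runs separated by less than 0.5 Hz are merged (the
same 0.5-Hz rule that separates dual-oscillator bands). The band peak is the
frequency of maximal power in the run.

**Temporal corroboration.** A candidate band is retained only if at least
40% of the nonoverlapping 10-s gating windows show a local spectral maximum
inside the band exceeding the whole-recording threshold. Genuine
oscillations recur across a recording; isolated estimator excursions do not.
The 40% value was chosen from pilot simulations in which true bands
corroborated in ≳ 50–100% of windows and noise runs in ≲ 40%.

**Instantaneous trace.** 2nd-order Butterworth band-pass applied
forward–backward (zero phase), phase from the Hilbert analytic signal,
instantaneous frequency as the derivative of unwrapped phase smoothed with
an 11-sample median filter. A sample is *present* when its instantaneous
frequency lies inside the band (hard invariant) and its 10-s window shows a
local spectral peak at the band; artifact-masked samples are never present.

## Preprocessing

Re-referencing defaults to `none` in the synthetic pipeline (channels are
generated independently, so a common-average reference would only mix
signals across electrodes); for clinical recordings `common_average` or an
explicit `weighted` scheme is available. Line noise is removed with a
4th-order Butterworth band-stop at 58–62 Hz applied forward–backward
(zero phase; ≥ 20 dB attenuation at 60 Hz, gain within 1% of unity outside
60 ± 5 Hz). Artifact screening masks samples whose amplitude or
first-difference z-score exceeds 5, dilated ±250 ms; masking flags samples
but never alters them.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated.

* **Task.** 70-unit track in three thirds; per-third speeds i.i.d. uniform
  on 2–12 units/s; 1-s linear acceleration ramps at speed changes; a 4-s
  countdown before movement; object positions uniform on (12, 58) — with
  this zone, always answering the track midpoint gives a mean error of
  11.5 units, the correctness threshold. Recall responses are the object
  position plus Gaussian error (SD 8.2 units, making ~84% of recalls
  correct at the 11.5-unit threshold); the first two trials are learning
  trials.
* **LFP.** 1/f^α noise (α = 2) by FFT spectral shaping of white noise, plus
  sinusoidal bouts. Bout start times follow exponential gaps and durations a
  gamma distribution (shape 2) with mean `bout_mean_cycles`/f seconds
  (default 3 cycles), giving ~50% duty cycle. Bout edges carry 1-cycle Hann
  tapers. Within a bout the instantaneous frequency is the band center plus
  `speed_slope`·(speed − 7) for speed-coupled bands (default
  0.1 Hz/(unit/s)) plus per-bout Gaussian jitter (SD 0.2 Hz), clipped to the
  band.
* **Oscillation amplitude.** `osc_snr` is a *spectral* SNR: bout amplitude
  is scaled so the oscillation's time-averaged PSD at the band center equals
  `osc_snr` × the background PSD there (default 2, i.e. the peak stands 3×
  above the background). An amplitude-domain convention (oscillation
  amplitude relative to in-band noise RMS) was evaluated and rejected:
  with ~3-cycle bouts it produces spectra with no discernible narrowband
  peak, which is not the regime the supra-background detection method —
  or the real recordings it was designed for — operates in.
* **Anatomy.** Per subject, A–P fractions are spread over [0.1, 0.9];
  P(single oscillator) = logistic(−1.5 + 5·ap); the high-theta base
  frequency is 6 + 3·ap Hz with 0.8-Hz across-electrode scatter (clipped to
  ≥ 6.4 Hz); dual oscillators add an uncoupled low band centered near 3 Hz.
  Dual-band nearest-edge gaps are kept ≥ 1.5 Hz: pilot simulations show
  bands closer than that are not spectrally resolvable at 3-cycle bout
  lengths (the bout-limited bandwidth ~f/3 Hz fills the trough), mirroring
  the empirically typical ~3 vs ~8 Hz dual pattern.
* **Determinism.** All draws derive from `SimConfig.seed` through a
  `SeedSequence` tree (per subject, behavior/electrode/channel streams);
  identical configs give byte-identical outputs.

What the generator does **not** emulate: epileptiform discharges and other
clinical artifacts (only a test spike injector), non-sinusoidal waveform
shape, volume conduction and phase coupling between electrodes,
learning-related performance dynamics, and any relation between memory
performance and oscillations. Passing the synthetic tests shows the
pipeline recovers known structure under these idealized conditions; it does
not certify performance on clinical recordings with unmodeled artifacts.

A further caveat: *measured* bout lengths are properties of the detector's
presence signal, not of the generative bouts. Presence runs are terminated
by instantaneous-frequency excursions out of the band, and narrow relative
bandwidths (low theta) produce slower band-passed envelopes and hence longer
runs; the measured low/high bout-cycle ordering therefore need not track the
generative cycle counts, which are equal across bands by default.

## Statistical conventions

* Binomial prevalence and two-proportion z-tests are one-sided (upper tail);
  the binomial tail is an exact sum.
* The per-electrode speed–frequency test is a two-sided Pearson correlation
  (t transform, n − 2 df) on one randomly chosen epoch per trial, requiring
  ≥ 10 epochs and ≥ 2 cycles of presence per epoch (at the band center) for
  a valid epoch mode frequency. Mode frequencies are bin centers of 0.1-Hz
  histograms aligned to 0 Hz, ties toward the lower bin.
* Bout group comparisons use the pooled-variance two-sample t-test (integer
  degrees of freedom); groups with zero variance and equal means give t = 0,
  p = 1 by convention.
* The two-way region × band ANOVA on subject-level cells uses Type II sums
  of squares (appropriate for unbalanced subject tables); a subject's cell
  value is the fraction of its electrodes with r > 0 and p < 0.05.
* The harmonic permutation test shuffles the high-band frequencies across
  dual oscillators, 10⁴ permutations by default, add-one p-value
  convention (p ≥ 1/(n_perm + 1)).
* Co-occurrence statistic per dual electrode: P(both bands present) −
  P(low)·P(high), tested against zero with a two-sided Wilcoxon signed-rank
  across electrodes.
* Degenerate inputs (zero variance, perfect separation, empty strata,
  too-few observations) are flagged in the results rather than raised,
  except where the operation is meaningless (no bands, empty cohort).

## Problem sizes

Validation uses 200-s single-electrode recordings at 1000 Hz for detector
recovery (50 seeds per condition), 500 simulated electrodes for type-I
calibration of the speed–frequency test, 600-s recordings for bout-duration
recovery, and 60-electrode cohorts for anatomical-gradient recovery. The
end-to-end acceptance run uses 6 subjects × 5 electrodes × 40 trials
(~700-s recordings per subject). Cohort-level calibration uses the
generator's fast path (`signals=False`), which draws the same anatomical
and behavioral structure without synthesizing LFP; detector-dependent
checks always run on full signals.

## Known limitations

* The anatomically weighted referencing scheme used for the original
  clinical data is not public; the package offers common-average and
  explicit weights instead, and results on re-referenced clinical data may
  differ.
* The artifact criterion (amplitude/gradient z-scores at 5, ±250 ms
  dilation) is a generic transient detector, not an epileptiform-discharge
  classifier.
* The 1-SD supra-background threshold is inherently permissive; the
  all-points residual SD and the 40% temporal-corroboration rule are what
  make it usable at realistic SNR. Electrodes whose spectra contain no
  genuine peak (not expected in this application domain, where every
  hippocampal electrode shows at least one narrowband oscillation) would
  still yield occasional narrow false bands.
* Bands separated by less than ~1.5 Hz edge-to-edge are not reliably
  resolved as dual at short bout lengths.
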