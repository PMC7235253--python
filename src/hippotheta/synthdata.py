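"""Seeded synthetic cohorts: behavior logs, electrode metadata, and LFP signals.

The generator emulates the statistical structure the analysis assumes: subjects
traverse a 70-unit virtual track in three constant-speed thirds (speeds i.i.d.
uniform on 2-12 units/s, 1-s linear acceleration ramps between thirds, a 4-s
pre-movement countdown); each electrode carries one or two narrowband
oscillations riding on 1/f background noise; the high-theta base frequency
rises linearly with anterior-posterior (A-P) position; the probability of
being a single oscillator follows a logistic function of A-P position; and,
within oscillatory bouts, the instantaneous high-theta frequency tracks the
momentary movement speed.  Every draw is reproducible from ``SimConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from hippotheta.types import Epoch, Recording, TrialLog

__all__ = [
    "SimConfig",
    "ElectrodeSpec",
    "TrueBout",
    "ElectrodeTruth",
    "GroundTruth",
    "Cohort",
    "simulate_behavior",
    "simulate_ieeg",
    "make_cohort",
    "speed_profile",
    "colored_noise",
]

#: inter-trial interval between the end of one trial and the next button press
ITI_S = 2.0
#: pre-movement countdown shown at the start of every trial
COUNTDOWN_S = 4.0

SUBREGIONS = ("CA1", "DG", "SUB", "CA2")
SUBREGION_WEIGHTS = (0.5, 0.2, 0.2, 0.1)


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort, with task-faithful defaults.

    Defaults mirror the task design (70-unit track, speeds uniform on
    2-12 units/s, 1-s ramps) and plausible electrophysiology (1/f^2 background,
    ~3-cycle bouts, SNR 2 narrowband oscillations, a 3 Hz/A-P-fraction
    high-theta gradient starting at 6 Hz, 0.1 Hz per unit/s speed coupling).
    """

    n_subjects: int = 8
    electrodes_per_subject: int = 5
    n_trials: int = 60
    track_length: float = 70.0  # VR units
    speed_range: tuple[float, float] = (2.0, 12.0)  # VR units / s
    ramp_duration: float = 1.0  # s
    sampling_rate: float = 1000.0  # Hz
    noise_exponent: float = 2.0  # 1/f^alpha slope
    line_noise_amplitude: float = 0.0  # signal units (60 Hz)
    gradient_intercept: float = 6.0  # Hz at ap_fraction 0
    gradient_slope: float = 3.0  # Hz per A-P fraction
    speed_slope: float = 0.1  # Hz per (VR unit / s)
    freq_jitter_sd: float = 0.2  # Hz, per-bout frequency jitter
    electrode_freq_sd: float = 0.8  # Hz, across-electrode base-frequency scatter
    bout_mean_cycles: float = 3.0  # expected cycles per bout
    osc_snr: float = 2.0  # oscillation amplitude / in-band noise RMS
    p_single_logit: tuple[float, float] = (-1.5, 5.0)  # (beta0, beta1) on ap
    object_zone: tuple[float, float] = (12.0, 58.0)  # VR units
    # 11.5 / PhiInv(0.92) ~= 8.2 makes ~84% of recalls land within the
    # 11.5-unit correctness threshold
    response_error_sd: float = 8.2  # VR units
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.speed_range
        if not (0 < lo <= hi):
            raise ValueError("speed_range requires 0 < min <= max")
        if self.track_length <= 0:
            raise ValueError("track_length must be positive")
        if self.sampling_rate < 200:
            raise ValueError("sampling_rate must be >= 200 Hz")
        if self.response_error_sd < 0:
            raise ValueError("response_error_sd must be >= 0")
        zlo, zhi = self.object_zone
        if not (0 <= zlo < zhi <= self.track_length):
            raise ValueError("object_zone must lie within the track")


@dataclass
class ElectrodeSpec:
    """Declared oscillations of one synthetic electrode.

    ``bands`` holds one or two ``(f_lo, f_hi)`` ranges in Hz; the bout carrier
    frequency sits at each band's center.  ``speed_coupled`` marks which bands
    follow movement speed (matched by index; a single bool applies to all).
    """

    bands: list[tuple[float, float]]
    speed_coupled: list[bool] | bool = False

    def __post_init__(self) -> None:
        if not 1 <= len(self.bands) <= 2:
            raise ValueError("an electrode carries 1 or 2 bands")
        for lo, hi in self.bands:
            if not (1.0 < lo < hi < 20.0):
                raise ValueError(f"band ({lo}, {hi}) outside the supported (1, 20) Hz")
        self.bands = sorted(self.bands)
        if len(self.bands) == 2:
            gap = self.bands[1][0] - self.bands[0][1]
            if gap < 0.5:
                raise ValueError(
                    "dual bands must be separated by >= 0.5 Hz between nearest "
                    f"edges (the dual-oscillator classification rule); gap = {gap:.2f} Hz"
                )
        if isinstance(self.speed_coupled, bool):
            self.speed_coupled = [self.speed_coupled] * len(self.bands)
        if len(self.speed_coupled) != len(self.bands):
            raise ValueError("speed_coupled must match bands")


@dataclass
class TrueBout:
    """One ground-truth oscillatory bout."""

    start_s: float
    end_s: float
    freq: np.ndarray  # per-sample true frequency, Hz

    @property
    def mean_freq(self) -> float:
        return float(np.mean(self.freq))

    @property
    def n_cycles(self) -> float:
        return (self.end_s - self.start_s) * self.mean_freq


@dataclass
class ElectrodeTruth:
    """Ground truth for one electrode: bands, bouts, per-epoch frequencies."""

    bands: list[tuple[float, float]]
    speed_coupled: list[bool]
    bouts: list[list[TrueBout]]  # one list per band
    # (trial_id, epoch_index) -> noiseless mean frequency of the coupled band
    epoch_freq: dict[tuple[int, int], float] = field(default_factory=dict)


@dataclass
class GroundTruth:
    """Cohort-level ground truth keyed by electrode id."""

    electrodes: dict[str, ElectrodeTruth] = field(default_factory=dict)


@dataclass
class Cohort:
    """Everything one synthetic cohort comprises."""

    recordings: dict[str, Recording]  # subject_id -> Recording
    electrodes: list  # list[ElectrodeRecord]
    trials: dict[str, list[TrialLog]]  # subject_id -> trials
    truth: GroundTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def _trial_kinematics(
    speeds: tuple[float, float, float], config: SimConfig
) -> tuple[list[float], list[tuple[float, float, float, float, float]]]:
    """Boundary-crossing times and piecewise speed segments for one trial.

    Returns ``(third_entry_times, segments)`` where times are relative to
    movement onset, and each segment is ``(t0, t1, v0, v1, x0)``: linear speed
    from ``v0`` at ``t0`` to ``v1`` at ``t1`` starting at track position ``x0``.
    """
    third = config.track_length / 3.0
    segments: list[tuple[float, float, float, float, float]] = []
    t = 0.0
    x = 0.0
    entries = [0.0]
    for i, v in enumerate(speeds):
        if i > 0 and speeds[i - 1] != v and config.ramp_duration > 0:
            # linear ramp from the previous speed, entered at the third boundary
            r = config.ramp_duration
            d_ramp = 0.5 * (speeds[i - 1] + v) * r
            if d_ramp >= third:
                raise ValueError("ramp cannot span an entire track third")
            segments.append((t, t + r, speeds[i - 1], v, x))
            t += r
            x += d_ramp
            remaining = (i + 1) * third - x
        else:
            remaining = third
        segments.append((t, t + remaining / v, v, v, x))
        t += remaining / v
        x = (i + 1) * third
        if i < 2:
            entries.append(t)
    return entries, segments


def _time_at_position(
    segments: list[tuple[float, float, float, float, float]], pos: float
) -> float:
    """Invert the piecewise kinematics: movement time at track position."""
    for t0, t1, v0, v1, x0 in segments:
        x1 = x0 + 0.5 * (v0 + v1) * (t1 - t0)
        if pos <= x1 + 1e-9:
            if v0 == v1:
                return t0 + (pos - x0) / v0
            # solve x0 + v0*dt + 0.5*a*dt^2 = pos
            a = (v1 - v0) / (t1 - t0)
            dt = (-v0 + math.sqrt(v0 * v0 + 2 * a * (pos - x0))) / a
            return t0 + dt
    return segments[-1][1]


def simulate_behavior(config: SimConfig, rng: np.random.Generator | None = None) -> list[TrialLog]:
    """Generate the trial log of one subject.

    Each trial starts with a 4-s countdown, then three constant-speed thirds
    of the track with speeds drawn i.i.d. uniform on ``config.speed_range``
    and 1-s linear ramps inserted at speed changes.  The first two trials are
    learning trials (object visible, no recall response); the rest are recall
    trials whose response position is the object position plus truncated
    Gaussian error.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.speed_range
    trials: list[TrialLog] = []
    t_cursor = 0.0
    for k in range(config.n_trials):
        speeds = tuple(rng.uniform(lo, hi, size=3)) if hi > lo else (lo, lo, lo)
        entries, segments = _trial_kinematics(speeds, config)
        t_move = t_cursor + COUNTDOWN_S
        boundaries = entries + [segments[-1][1]]
        epochs = [
            Epoch(t_move + boundaries[i], t_move + boundaries[i + 1], speeds[i])
            for i in range(3)
        ]
        object_pos = float(rng.uniform(*config.object_zone))
        trial_type = "learn" if k < 2 else "recall"
        response_pos = response_time = None
        if trial_type == "recall":
            err = rng.normal(0.0, config.response_error_sd) if config.response_error_sd > 0 else 0.0
            response_pos = float(np.clip(object_pos + err, 0.0, config.track_length))
            response_time = t_move + _time_at_position(segments, response_pos)
        trials.append(
            TrialLog(
                trial_id=k,
                trial_type=trial_type,
                epochs=epochs,
                object_pos=object_pos,
                response_pos=response_pos,
                response_time_s=response_time,
            )
        )
        t_cursor = epochs[-1].t_end_s + ITI_S
    return trials


def speed_profile(trials: list[TrialLog], n_samples: int, sampling_rate: float,
                  ramp_duration: float = 1.0) -> np.ndarray:
    """Per-sample movement speed (0 when stationary), with linear ramps.

    Epoch boundaries mark entry into each track third; when the speed changes,
    the first ``ramp_duration`` seconds of the new epoch interpolate linearly
    from the previous speed.
    """
    t = np.arange(n_samples) / sampling_rate
    v = np.zeros(n_samples)
    for trial in trials:
        prev_speed = None
        for ep in trial.epochs:
            sel = (t >= ep.t_start_s) & (t < ep.t_end_s)
            v[sel] = ep.speed
            if prev_speed is not None and prev_speed != ep.speed and ramp_duration > 0:
                ramp = sel & (t < ep.t_start_s + ramp_duration)
                v[ramp] = prev_speed + (ep.speed - prev_speed) * (
                    t[ramp] - ep.t_start_s
                ) / ramp_duration
            prev_speed = ep.speed
    return v


# ---------------------------------------------------------------------------
# LFP synthesis
# ---------------------------------------------------------------------------

def colored_noise(n: int, sampling_rate: float, exponent: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f^alpha noise by spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=n)
    return x / np.std(x)


def _psd_at(x: np.ndarray, fs: float, freq: float, half_width: float = 0.3) -> float:
    """Mean Welch PSD of ``x`` within ``freq`` +- ``half_width`` Hz."""
    nperseg = min(int(4 * fs), x.size)
    f, p = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2)
    sel = (f >= freq - half_width) & (f <= freq + half_width)
    return float(np.mean(p[sel]))


def _draw_bouts(duration: float, f_center: float, config: SimConfig,
                rng: np.random.Generator) -> list[tuple[float, float]]:
    """Bout (start, end) times: gamma durations (shape 2, mean = cycles/f),
    exponential gaps with the same mean (~50% duty cycle)."""
    mean_dur = config.bout_mean_cycles / f_center
    out = []
    t = float(rng.exponential(mean_dur / 2.0))  # burn-in gap
    while True:
        dur = float(rng.gamma(shape=2.0, scale=mean_dur / 2.0))
        if t + dur > duration:
            break
        if dur > 2.0 / config.sampling_rate:  # skip sub-2-sample degenerates
            out.append((t, t + dur))
        t += dur + float(rng.exponential(mean_dur))
    return out


def simulate_ieeg(
    electrode_spec: ElectrodeSpec,
    trials: list[TrialLog],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    channel_id: str = "E0",
) -> tuple[Recording, ElectrodeTruth]:
    """Synthesize one electrode's LFP aligned to a behavior log.

    The signal is 1/f^alpha noise plus amplitude-modulated sinusoidal bouts.
    Within a bout the instantaneous frequency is the band center plus
    ``speed_slope * (speed(t) - mid_speed)`` (for speed-coupled bands) plus a
    per-bout Gaussian jitter, clipped to the band.  Bout edges carry Hann
    tapers one cycle long.  ``osc_snr`` is a spectral SNR: the bout amplitude
    is scaled so the oscillation's time-averaged PSD at the band center is
    ``osc_snr`` times the background PSD there, i.e. the narrowband peak
    stands ``(1 + osc_snr)x`` above the 1/f background.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    duration = trials[-1].t_end + ITI_S if trials else 10.0
    n = int(round(duration * fs))
    x = colored_noise(n, fs, config.noise_exponent, rng)
    if config.line_noise_amplitude > 0:
        t = np.arange(n) / fs
        x = x + config.line_noise_amplitude * np.sin(2 * np.pi * 60.0 * t)

    v = speed_profile(trials, n, fs, config.ramp_duration)
    v_mid = 0.5 * (config.speed_range[0] + config.speed_range[1])

    truth = ElectrodeTruth(
        bands=list(electrode_spec.bands),
        speed_coupled=list(electrode_spec.speed_coupled),
        bouts=[[] for _ in electrode_spec.bands],
    )
    for b_idx, (f_lo, f_hi) in enumerate(electrode_spec.bands):
        f0 = 0.5 * (f_lo + f_hi)
        coupled = electrode_spec.speed_coupled[b_idx]
        osc = np.zeros(n)
        for start, end in _draw_bouts(duration, f0, config, rng):
            i0, i1 = int(round(start * fs)), int(round(end * fs))
            i1 = min(i1, n)
            if i1 - i0 < 2:
                continue
            freq = np.full(i1 - i0, f0)
            if coupled and config.speed_slope != 0:
                freq = freq + config.speed_slope * (v[i0:i1] - v_mid)
            if config.freq_jitter_sd > 0:
                freq = freq + rng.normal(0.0, config.freq_jitter_sd)
            freq = np.clip(freq, f_lo, f_hi)
            phase = 2 * np.pi * np.cumsum(freq) / fs + rng.uniform(0, 2 * np.pi)
            env = np.ones(i1 - i0)
            taper = min(int(round(fs / f0)), (i1 - i0) // 2)
            if taper > 1:
                h = np.hanning(2 * taper)
                env[:taper] = h[:taper]
                env[-taper:] = h[taper:]
            osc[i0:i1] += env * np.sin(phase)
            truth.bouts[b_idx].append(TrueBout(i0 / fs, i1 / fs, freq))
        if config.osc_snr > 0 and truth.bouts[b_idx]:
            p_osc = _psd_at(osc, fs, f0)
            p_bg = _psd_at(x, fs, f0)
            if p_osc > 0:
                x += np.sqrt(config.osc_snr * p_bg / p_osc) * osc
        if coupled:
            for trial in trials:
                for e_idx, ep in enumerate(trial.epochs):
                    t0 = ep.t_start_s + (config.ramp_duration if e_idx > 0 else 0.0)
                    if t0 >= ep.t_end_s:
                        continue
                    truth.epoch_freq[(trial.trial_id, e_idx)] = float(
                        np.clip(f0 + config.speed_slope * (ep.speed - v_mid), f_lo, f_hi)
                    )
    rec = Recording(x[np.newaxis, :], fs, [channel_id])
    return rec, truth


def ground_truth_trace(
    electrode_spec: ElectrodeSpec,
    trials: list[TrialLog],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    band_index: int = 0,
) -> "object":
    """Oscillatory trace built directly from ground truth (no LFP synthesis).

    Presence marks the true bouts and the instantaneous frequency is the true
    per-sample frequency (band center + speed coupling + per-bout jitter).
    Useful for calibrating the epoch-frequency and bout statistics independent
    of the detector.
    """
    from hippotheta.types import Band, OscillatoryTrace

    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    duration = trials[-1].t_end + ITI_S if trials else 10.0
    n = int(round(duration * fs))
    v = speed_profile(trials, n, fs, config.ramp_duration)
    v_mid = 0.5 * (config.speed_range[0] + config.speed_range[1])
    f_lo, f_hi = electrode_spec.bands[band_index]
    f0 = 0.5 * (f_lo + f_hi)
    coupled = electrode_spec.speed_coupled[band_index]
    inst_freq = np.full(n, f0)
    presence = np.zeros(n, dtype=bool)
    for start, end in _draw_bouts(duration, f0, config, rng):
        i0, i1 = int(round(start * fs)), min(int(round(end * fs)), n)
        if i1 - i0 < 2:
            continue
        freq = np.full(i1 - i0, f0)
        if coupled and config.speed_slope != 0:
            freq = freq + config.speed_slope * (v[i0:i1] - v_mid)
        if config.freq_jitter_sd > 0:
            freq = freq + rng.normal(0.0, config.freq_jitter_sd)
        inst_freq[i0:i1] = np.clip(freq, f_lo, f_hi)
        presence[i0:i1] = True
    return OscillatoryTrace(
        band=Band(f_lo, f_hi, f0),
        inst_freq=inst_freq,
        phase=np.zeros(n),
        presence=presence,
        sampling_rate=fs,
    )


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _logistic(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


def sample_electrode_specs(
    config: SimConfig, rng: np.random.Generator
) -> list[tuple[float, str, str, ElectrodeSpec]]:
    """Draw one subject's electrodes: (ap_fraction, hemisphere, subregion, spec).

    A-P fractions are spread over [0.1, 0.9] with jitter; P(single oscillator)
    follows the configured logistic in A-P position; the high-theta base
    frequency follows the configured linear A-P gradient with across-electrode
    scatter; dual oscillators add an uncoupled ~3 Hz low-theta band.
    """
    m = config.electrodes_per_subject
    beta0, beta1 = config.p_single_logit
    centers = np.linspace(0.1, 0.9, m) if m > 1 else np.array([0.5])
    out = []
    for j in range(m):
        ap = float(np.clip(centers[j] + rng.normal(0, 0.05), 0.0, 1.0))
        hemi = "L" if j % 2 == 0 else "R"
        subregion = str(rng.choice(SUBREGIONS, p=SUBREGION_WEIGHTS))
        f_high = config.gradient_intercept + config.gradient_slope * ap
        if config.electrode_freq_sd > 0:
            f_high += rng.normal(0.0, config.electrode_freq_sd)
        # keep low/high edge gaps >= 1.5 Hz (the ~3 vs ~8 Hz dual pattern);
        # closer bands are not spectrally resolvable at these bout lengths
        f_high = float(np.clip(f_high, 6.4, 13.0))
        bands = [(f_high - 1.0, f_high + 1.0)]
        coupled = [True]
        if rng.uniform() >= _logistic(beta0 + beta1 * ap):  # dual oscillator
            f_low = float(np.clip(rng.normal(3.0, 0.4), 2.4, 3.2))
            bands.insert(0, (f_low - 0.7, f_low + 0.7))
            coupled.insert(0, False)
        out.append((ap, hemi, subregion, ElectrodeSpec(bands, coupled)))
    return out


def make_cohort(config: SimConfig, signals: bool = True,
                outdir: str | None = None) -> Cohort:
    """Build a full synthetic cohort (recordings, metadata, behavior, truth).

    With ``signals=False`` only behavior, electrode metadata and ground truth
    are generated (fast path for cohort-level statistical calibration).  With
    ``outdir`` set, all files are written in the package's on-disk formats
    (HDF5 signals, CSV events, TSV electrode metadata, JSON ground truth).
    """
    from hippotheta.types import ElectrodeRecord

    if config.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if config.electrodes_per_subject < 1:
        raise ValueError("electrodes_per_subject must be >= 1")
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(config.n_subjects)

    recordings: dict[str, Recording] = {}
    electrodes: list[ElectrodeRecord] = []
    trials: dict[str, list[TrialLog]] = {}
    truth = GroundTruth()
    for s, sseq in enumerate(subject_seeds):
        subject_id = f"S{s}"
        beh_rng, elec_rng, *chan_seqs = [
            np.random.default_rng(q) for q in sseq.spawn(2 + config.electrodes_per_subject)
        ]
        subj_trials = simulate_behavior(config, beh_rng)
        trials[subject_id] = subj_trials
        specs = sample_electrode_specs(config, elec_rng)
        chans = []
        chan_ids = []
        for j, (ap, hemi, subregion, spec) in enumerate(specs):
            eid = f"S{s}_E{j}"
            record = ElectrodeRecord(
                subject_id=subject_id,
                electrode_id=eid,
                hemisphere=hemi,
                subregion=subregion,
                ap_fraction=ap,
            )
            electrodes.append(record)
            if signals:
                rec, et = simulate_ieeg(spec, subj_trials, config, chan_seqs[j], eid)
                chans.append(rec.data[0])
                chan_ids.append(eid)
            else:
                # fast path: classification taken from ground truth, no LFP
                from hippotheta.electrodes import band_label, split_region
                from hippotheta.types import Band

                record.region = split_region(ap)
                record.bands = [
                    Band(lo, hi, 0.5 * (lo + hi)) for lo, hi in spec.bands
                ]
                record.band_labels = [band_label(b) for b in record.bands]
                record.oscillator_class = (
                    "dual" if len(spec.bands) == 2 else "single"
                )
                et = ElectrodeTruth(
                    bands=list(spec.bands),
                    speed_coupled=list(spec.speed_coupled),
                    bouts=[[] for _ in spec.bands],
                )
                v_mid = 0.5 * sum(config.speed_range)
                for b, (f_lo, f_hi) in enumerate(spec.bands):
                    if not spec.speed_coupled[b]:
                        continue
                    f0 = 0.5 * (f_lo + f_hi)
                    for trial in subj_trials:
                        for e_idx, ep in enumerate(trial.epochs):
                            et.epoch_freq[(trial.trial_id, e_idx)] = float(
                                np.clip(f0 + config.speed_slope * (ep.speed - v_mid),
                                        f_lo, f_hi)
                            )
            truth.electrodes[eid] = et
        if signals:
            recordings[subject_id] = Recording(
                np.vstack(chans), config.sampling_rate, chan_ids
            )
    cohort = Cohort(recordings, electrodes, trials, truth, config)
    if outdir is not None:
        from hippotheta import io

        io.write_cohort(cohort, outdir)
    return cohort
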