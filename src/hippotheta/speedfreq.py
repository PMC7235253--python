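"""Speed-frequency coupling: per-epoch mode frequency vs movement speed.

Each trial has three constant-speed epochs.  For every epoch the oscillation
frequency is summarized as the mode of the 0.1-Hz histogram of instantaneous
frequency over presence-gated samples; to keep observations independent, one
epoch per trial is then chosen at random before computing the per-electrode
Pearson correlation between movement speed and mode frequency.  Behavioral
accuracy counts recall trials whose response-object error is below 11.5 VR
units (the mean error of always answering the track midpoint).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from hippotheta.types import OscillatoryTrace, TrialLog

__all__ = [
    "parse_epochs",
    "epoch_mode_frequency",
    "epoch_frequency_table",
    "subsample_epochs",
    "speed_frequency_correlation",
    "behavioral_accuracy",
]

MODE_BIN_HZ = 0.1
MIN_PRESENT_CYCLES = 2.0
N_MIN_EPOCHS = 10
ACCURACY_THRESHOLD = 11.5  # VR units

EPOCH_FREQ_COLUMNS = ["electrode_id", "label", "trial_id", "epoch_index",
                      "speed", "mode_freq_hz"]


def parse_epochs(trial: TrialLog, exclude_ramps: bool = True,
                 ramp_duration: float = 1.0) -> list[tuple[float, float, float]]:
    """Constant-speed analysis windows ``(t_start, t_end, speed)`` of a trial.

    With ``exclude_ramps``, the 1-s acceleration period entering each third
    whose speed differs from the previous third is removed from that epoch.
    """
    if len(trial.epochs) != 3:
        raise ValueError(f"trial {trial.trial_id} has {len(trial.epochs)} epochs, expected 3")
    windows = []
    prev_speed = None
    for ep in trial.epochs:
        t0 = ep.t_start_s
        if exclude_ramps and prev_speed is not None and prev_speed != ep.speed:
            t0 = min(t0 + ramp_duration, ep.t_end_s)
        windows.append((t0, ep.t_end_s, ep.speed))
        prev_speed = ep.speed
    return windows


def epoch_mode_frequency(trace: OscillatoryTrace, window: tuple[float, float],
                         bin_hz: float = MODE_BIN_HZ,
                         min_present_cycles: float = MIN_PRESENT_CYCLES
                         ) -> float | None:
    """Mode of the instantaneous-frequency histogram within a time window.

    Histogram bins are ``bin_hz`` wide and aligned to 0 Hz; the returned value
    is the center of the most populated bin, ties broken toward the lower bin.
    Returns ``None`` (missing) when the presence-gated time in the window is
    shorter than ``min_present_cycles`` cycles at the band center.
    """
    fs = trace.sampling_rate
    i0 = max(int(np.ceil(window[0] * fs)), 0)
    i1 = min(int(np.floor(window[1] * fs)), len(trace.presence))
    if i1 <= i0:
        return None
    sel = trace.presence[i0:i1]
    freqs = trace.inst_freq[i0:i1][sel]
    if freqs.size / fs < min_present_cycles / trace.band.center:
        return None
    idx = np.floor(freqs / bin_hz + 1e-9).astype(int)
    counts = np.bincount(idx)
    mode_bin = int(np.argmax(counts))  # argmax returns the first (lowest) tie
    return (mode_bin + 0.5) * bin_hz


def epoch_frequency_table(trace: OscillatoryTrace, trials: list[TrialLog],
                          electrode_id: str = "", label: str = "",
                          exclude_ramps: bool = True,
                          ramp_duration: float = 1.0) -> pd.DataFrame:
    """Per-trial, per-epoch mode frequencies for one electrode band."""
    rows = []
    for trial in trials:
        for e_idx, (t0, t1, speed) in enumerate(
            parse_epochs(trial, exclude_ramps, ramp_duration)
        ):
            mode = epoch_mode_frequency(trace, (t0, t1))
            rows.append(
                {
                    "electrode_id": electrode_id,
                    "label": label,
                    "trial_id": trial.trial_id,
                    "epoch_index": e_idx,
                    "speed": speed,
                    "mode_freq_hz": np.nan if mode is None else mode,
                }
            )
    return pd.DataFrame(rows, columns=EPOCH_FREQ_COLUMNS)


def subsample_epochs(epoch_freq: pd.DataFrame,
                     rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Select one non-missing epoch per trial, uniformly at random.

    Trials whose three epochs are all missing are dropped.  Deterministic for
    a given seed/generator.
    """
    if epoch_freq.empty:
        raise ValueError("empty epoch-frequency table")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rows = []
    for _, g in epoch_freq.groupby("trial_id", sort=True):
        valid = g[g["mode_freq_hz"].notna()]
        if valid.empty:
            continue
        rows.append(valid.iloc[int(rng.integers(len(valid)))])
    if not rows:
        return epoch_freq.iloc[0:0]
    return pd.DataFrame(rows).reset_index(drop=True)


def speed_frequency_correlation(subsampled: pd.DataFrame,
                                n_min: int = N_MIN_EPOCHS) -> dict:
    """Pearson correlation between movement speed and epoch mode frequency.

    Returns a dict with ``r``, ``p`` (two-sided, from the t transform with
    n - 2 df), ``n_epochs`` and a ``flag`` that is set when the correlation is
    undefined (too few epochs, or zero variance in speed or frequency).
    """
    x = subsampled["speed"].to_numpy(dtype=float)
    y = subsampled["mode_freq_hz"].to_numpy(dtype=float)
    out = {"r": np.nan, "p": np.nan, "n_epochs": int(x.size), "flag": None}
    if x.size < n_min:
        out["flag"] = "too_few_epochs"
        return out
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        out["flag"] = "zero_variance"
        return out
    r, p = stats.pearsonr(x, y)
    out["r"], out["p"] = float(r), float(p)
    return out


def behavioral_accuracy(trials: list[TrialLog],
                        threshold: float = ACCURACY_THRESHOLD
                        ) -> tuple[pd.DataFrame, float]:
    """Response-object error distances and the fraction of correct trials.

    Only recall trials with a response are scored; a trial is correct when its
    absolute error is strictly below ``threshold`` VR units.
    """
    rows = []
    for tr in trials:
        if tr.trial_type != "recall" or tr.response_pos is None:
            continue
        err = abs(tr.response_pos - tr.object_pos)
        rows.append({"trial_id": tr.trial_id, "error_vru": err,
                     "correct": err < threshold})
    df = pd.DataFrame(rows, columns=["trial_id", "error_vru", "correct"])
    frac = float(df["correct"].mean()) if len(df) else float("nan")
    return df, frac
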