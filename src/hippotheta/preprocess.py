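"""Re-referencing, line-noise removal and artifact masking of raw iEEG.

The clinical recordings the pipeline targets arrive referenced to a common
intracranial or scalp contact; before spectral analysis they are re-referenced
(common average by default, or explicit per-channel weights), notch filtered
at the 60 Hz line frequency with a zero-phase Butterworth band-stop, and
screened for large transients that could reflect epileptiform activity.
Masking never alters sample values — it only flags samples for exclusion from
all downstream spectral, presence and bout computations.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from hippotheta.types import Recording

__all__ = ["rereference", "notch_filter", "exclude_artifacts", "resample_if_needed"]

NATIVE_RATES = (1000.0, 2000.0)


def resample_if_needed(recording: Recording, target: float = 1000.0) -> Recording:
    """Resample to a native rate if the input rate is neither 1000 nor 2000 Hz."""
    if recording.sampling_rate in NATIVE_RATES:
        return recording
    warnings.warn(
        f"sampling rate {recording.sampling_rate} Hz is not native; "
        f"resampling to {target} Hz",
        stacklevel=2,
    )
    n_out = int(round(recording.n_samples * target / recording.sampling_rate))
    data = sps.resample(recording.data, n_out, axis=1)
    return Recording(data, target, list(recording.channel_ids), recording.start_time)


def rereference(recording: Recording, scheme: str = "common_average",
                weights: np.ndarray | None = None) -> Recording:
    """Re-reference all channels.

    ``common_average`` subtracts the cross-channel mean at every sample;
    ``none`` is the identity; ``weighted`` subtracts a user-supplied weighted
    channel combination (weights are normalized to sum to 1).
    """
    if recording.n_channels < 1:
        raise ValueError("recording has no channels")
    if scheme == "none":
        return recording
    if scheme == "common_average":
        ref = recording.data.mean(axis=0, keepdims=True)
    elif scheme == "weighted":
        if weights is None:
            raise ValueError("scheme 'weighted' requires a weight vector")
        w = np.asarray(weights, dtype=float)
        if w.size != recording.n_channels:
            raise ValueError(
                f"weight vector length {w.size} != {recording.n_channels} channels"
            )
        w = w / w.sum()
        ref = (w[:, None] * recording.data).sum(axis=0, keepdims=True)
    else:
        raise ValueError(f"unknown reference scheme {scheme!r}")
    return Recording(
        recording.data - ref,
        recording.sampling_rate,
        list(recording.channel_ids),
        recording.start_time,
    )


def notch_filter(recording: Recording, freq: float = 60.0,
                 half_width: float = 2.0, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-stop around the line frequency.

    The filter is applied forward-backward (``sosfiltfilt``), so the passband
    is phase-distortion free; the default stopband is 58-62 Hz.
    """
    nyq = recording.sampling_rate / 2.0
    if freq >= nyq:
        raise ValueError(f"notch frequency {freq} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(
        order, [freq - half_width, freq + half_width],
        btype="bandstop", fs=recording.sampling_rate, output="sos",
    )
    data = sps.sosfiltfilt(sos, recording.data, axis=1)
    return Recording(data, recording.sampling_rate, list(recording.channel_ids),
                     recording.start_time)


def exclude_artifacts(recording: Recording, z_thresh: float = 5.0,
                      dilate_s: float = 0.25) -> np.ndarray:
    """Flag high-amplitude / high-slope transients per channel.

    A sample is masked when the z-score of its amplitude or of its first
    difference exceeds ``z_thresh``; masked stretches are dilated by
    ``dilate_s`` seconds on each side.  Returns a boolean array of the
    recording's shape (True = excluded).  A zero-variance channel yields an
    empty mask with a warning.
    """
    if recording.n_samples == 0:
        raise ValueError("empty recording")
    fs = recording.sampling_rate
    pad = int(round(dilate_s * fs))
    mask = np.zeros_like(recording.data, dtype=bool)
    for c, x in enumerate(recording.data):
        sd = np.std(x)
        if sd == 0:
            warnings.warn(
                f"channel {recording.channel_ids[c]} is constant; empty artifact mask",
                stacklevel=2,
            )
            continue
        z_amp = np.abs(x - np.mean(x)) / sd
        dx = np.diff(x, prepend=x[0])
        dsd = np.std(dx)
        z_grad = np.abs(dx - np.mean(dx)) / dsd if dsd > 0 else np.zeros_like(dx)
        bad = (z_amp > z_thresh) | (z_grad > z_thresh)
        if pad > 0 and bad.any():
            from scipy.ndimage import binary_dilation

            bad = binary_dilation(bad, structure=np.ones(2 * pad + 1, dtype=bool))
        mask[c] = bad
    return mask
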