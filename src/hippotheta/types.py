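"""Shared data containers for recordings, spectra, traces and metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Recording:
    """Multichannel iEEG time series.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)``, amplitude in arbitrary
        units (microvolt semantics).
    sampling_rate
        Samples per second.  1000 and 2000 Hz are the native clinical rates.
    channel_ids
        One identifier per channel.
    start_time
        Recording start in seconds (offset applied to all event times).
    """

    data: np.ndarray
    sampling_rate: float
    channel_ids: list[str]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.channel_ids):
            raise ValueError(
                f"{self.data.shape[0]} channels but {len(self.channel_ids)} ids"
            )
        if self.sampling_rate < 200:
            raise ValueError("sampling_rate must be >= 200 Hz")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, channel_id: str) -> np.ndarray:
        return self.data[self.channel_ids.index(channel_id)]


@dataclass
class Epoch:
    """One constant-speed segment of a trial (a third of the track)."""

    t_start_s: float
    t_end_s: float
    speed: float  # VR units / s


@dataclass
class TrialLog:
    """Behavioral log of one traversal of the virtual track."""

    trial_id: int
    trial_type: str  # "learn" or "recall"
    epochs: list[Epoch]
    object_pos: float
    response_pos: float | None = None
    response_time_s: float | None = None

    @property
    def t_start(self) -> float:
        return self.epochs[0].t_start_s

    @property
    def t_end(self) -> float:
        return self.epochs[-1].t_end_s


@dataclass
class PowerSpectrum:
    """Power spectral density on a fixed frequency grid."""

    frequencies: np.ndarray  # Hz, strictly increasing
    power: np.ndarray  # units^2 / Hz, >= 0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.ndim != 1 or self.frequencies.size != self.power.size:
            raise ValueError("frequencies and power must be 1-D and equal length")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")


@dataclass
class BackgroundFit:
    """Robust line fit of log10(power) on log10(frequency) — the 1/f background."""

    slope: float
    intercept: float
    residual_sd: float

    def predict_log10(self, frequencies: np.ndarray) -> np.ndarray:
        """Background log10-power at the given frequencies (Hz)."""
        return self.intercept + self.slope * np.log10(np.asarray(frequencies, float))


@dataclass(frozen=True)
class Band:
    """A detected narrowband oscillation: frequency range and spectral peak."""

    f_lo: float
    f_hi: float
    peak_freq: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(f"invalid band edges ({self.f_lo}, {self.f_hi})")
        if not self.f_lo <= self.peak_freq <= self.f_hi:
            raise ValueError("peak_freq must lie inside the band")

    @property
    def center(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)


@dataclass
class OscillatoryTrace:
    """Per-sample instantaneous frequency, phase and presence for one band."""

    band: Band
    inst_freq: np.ndarray  # Hz
    phase: np.ndarray  # radians, wrapped to (-pi, pi]
    presence: np.ndarray  # bool
    sampling_rate: float

    def __post_init__(self) -> None:
        n = len(self.inst_freq)
        if len(self.phase) != n or len(self.presence) != n:
            raise ValueError("inst_freq, phase, presence must have equal length")
        self.presence = np.asarray(self.presence, dtype=bool)


@dataclass
class ElectrodeRecord:
    """Electrode identity, anatomy, and oscillation classification."""

    subject_id: str
    electrode_id: str
    hemisphere: str  # "L" or "R"
    subregion: str  # CA1, CA2, DG, SUB
    ap_fraction: float  # 0 = anterior tip, 1 = posterior tip
    region: str | None = None  # "anterior" / "posterior"
    bands: list[Band] = field(default_factory=list)
    oscillator_class: str | None = None  # "single" / "dual"
    band_labels: list[str] = field(default_factory=list)  # "low" / "high"
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.hemisphere not in ("L", "R"):
            raise ValueError("hemisphere must be 'L' or 'R'")
        if not 0.0 <= self.ap_fraction <= 1.0:
            raise ValueError("ap_fraction must be in [0, 1]")
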