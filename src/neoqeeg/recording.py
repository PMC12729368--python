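"""In-memory containers for multi-channel EEG.

Signals are stored as a ``(n_channels, n_samples)`` float array in microvolts.
A recording may represent a time-compressed simulation: ``time_compression``
gives the number of nominal (experiment-clock) seconds represented by one
actual second of signal, so burden/onset summaries can be reported on the
nominal 48 h timeline while the waveform itself stays at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Fronto-parieto-centro-occipital eight-electrode montage used throughout.
DEFAULT_MONTAGE = ("Fp1", "Fp2", "C3", "C4", "P3", "P4", "O1", "O2")


@dataclass(frozen=True)
class Annotation:
    """A labelled interval, in actual seconds on the recording clock."""

    label: str
    start_s: float
    end_s: float
    channel_scope: str = "all"

    def __post_init__(self) -> None:
        if self.end_s < self.start_s:
            raise ValueError(f"annotation end {self.end_s} precedes start {self.start_s}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class EEGRecording:
    """Multi-channel EEG with montage, sampling rate and annotations.

    Parameters
    ----------
    signal
        ``(n_channels, n_samples)`` array, microvolts.
    sampling_rate
        Samples per actual second (Hz).
    channel_labels
        Unique electrode labels, one per row of ``signal``.
    start_offset_s
        Start of the record relative to reventilation onset, in *nominal*
        seconds (negative for a pre-asphyxia baseline segment).
    annotations
        Labelled intervals on the actual-time axis of the record.
    time_compression
        Nominal seconds represented by one actual second (>= 1).
    """

    signal: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...] = DEFAULT_MONTAGE
    start_offset_s: float = 0.0
    annotations: list[Annotation] = field(default_factory=list)
    time_compression: float = 1.0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a (channels, samples) matrix")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.signal.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.time_compression < 1:
            raise ValueError("time_compression must be >= 1")
        for ann in self.annotations:
            if ann.start_s < 0 or ann.end_s > self.duration_s + 1e-9:
                raise ValueError(f"annotation {ann} outside record bounds")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        """Record length in actual seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def nominal_duration_s(self) -> float:
        """Record length on the experiment clock."""
        return self.duration_s * self.time_compression

    def time_axis(self) -> np.ndarray:
        """Actual-time sample instants in seconds."""
        return np.arange(self.n_samples) / self.sampling_rate

    def nominal_time_axis_h(self) -> np.ndarray:
        """Nominal time of each sample in hours relative to reventilation."""
        return (self.start_offset_s + self.time_axis() * self.time_compression) / 3600.0

    def copy(self) -> "EEGRecording":
        return replace(self, signal=self.signal.copy(), annotations=list(self.annotations))

    def with_signal(self, signal: np.ndarray) -> "EEGRecording":
        return replace(self, signal=signal, annotations=list(self.annotations))

    def annotations_with_label(self, label: str) -> list[Annotation]:
        return [a for a in self.annotations if a.label == label]


@dataclass(frozen=True)
class Epoch:
    """A windowed slice of one channel of a parent recording."""

    channel: int
    start_s: float
    duration_s: float
    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("epoch duration must be positive")

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))
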