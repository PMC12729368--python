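"""Entropy-feature electrographic seizure detection and burden summaries.

Rhythmic discharges concentrate spectral power, so their spectral entropy
drops well below the running background while their amplitude rises. An
epoch (default 2 s, half-overlapped) is flagged on a channel when its
entropy z-score against a trailing robust background falls below ``-z_thr``
AND its RMS exceeds ``a_thr`` times the background median RMS. Flagged
epochs are pooled across channels, merged over short gaps and reported as
events with a dominant frequency read off the interval's PSD. Summaries
rescale a compressed timeline back to nominal hours post-reventilation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import warnings

import numpy as np
import pandas as pd

from .preprocess import sliding_epoch_matrix
from .recording import EEGRecording
from .spectral import QEEGConfig, compute_psd, instantaneous_spectral_entropy


@dataclass(frozen=True)
class DetectionConfig:
    """Detector settings; durations in actual seconds of signal.

    On a record compressed by factor C, nominal-duration settings (minimum
    event length, merge gap, background window) should be divided by C —
    :meth:`scaled` does this with floors that keep the epoch grid sane.
    """

    epoch_s: float = 2.0
    overlap_fraction: float = 0.5
    band: tuple[float, float] = (1.0, 30.0)
    suppressed_rms_uv: float = 2.0
    z_thr: float = 2.0
    a_thr: float = 3.0
    background_s: float = 600.0
    gap_s: float = 10.0
    min_duration_s: float = 10.0
    min_channel_fraction: float = 0.25
    generalized_fraction: float = 0.75

    def scaled(self, compression: float) -> "DetectionConfig":
        """Rescale nominal-duration settings for a compressed timeline.

        The background window keeps a 120 s actual-time floor so a single
        compressed episode cannot dominate its own reference statistics.
        """
        hop = self.epoch_s * (1.0 - self.overlap_fraction)
        return replace(
            self,
            background_s=max(self.background_s / compression, min(self.background_s, 120.0)),
            gap_s=max(self.gap_s / compression, hop),
            min_duration_s=max(self.min_duration_s / compression, self.epoch_s + hop),
        )


@dataclass(frozen=True)
class SeizureEvent:
    """One detected episode, on the actual-time axis of the record."""

    start_s: float
    end_s: float
    channel_scope: str
    dominant_frequency_hz: float
    peak_amplitude_uv: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("event must have positive duration")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class SeizureSummary:
    """Per-animal burden/onset on the nominal clock (hours)."""

    animal_id: str
    group: str
    total_duration_h: float
    onset_latency_h: float | None
    event_count: int

    @property
    def seizure_free(self) -> bool:
        return self.event_count == 0


def entropy_feature_series(
    recording: EEGRecording, cfg: DetectionConfig | None = None
) -> pd.DataFrame:
    """Per-channel, per-epoch detection features.

    Columns: channel (index), epoch_start_s, entropy, rms_uv, line_length,
    suppressed. Suppressed (isoelectric) epochs carry NaN entropy.
    """
    cfg = cfg or DetectionConfig()
    starts, feats = _feature_arrays(recording, cfg)
    n_ch, n_ep = feats["rms"].shape
    return pd.DataFrame(
        {
            "channel": np.repeat(np.arange(n_ch), n_ep),
            "epoch_start_s": np.tile(starts, n_ch),
            "entropy": feats["entropy"].ravel(),
            "rms_uv": feats["rms"].ravel(),
            "line_length": feats["line_length"].ravel(),
            "suppressed": feats["suppressed"].ravel(),
        }
    )


def _feature_arrays(
    recording: EEGRecording, cfg: DetectionConfig
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    starts, epochs = sliding_epoch_matrix(
        recording.signal, recording.sampling_rate, cfg.epoch_s, cfg.overlap_fraction
    )
    # half-epoch Welch segments average three periodograms per epoch,
    # stabilizing the entropy feature at 2 Hz resolution
    qcfg = QEEGConfig(
        window_s=cfg.epoch_s,
        segment_s=cfg.epoch_s / 2.0,
        band=cfg.band,
        suppressed_rms_uv=cfg.suppressed_rms_uv,
    )
    est = compute_psd(epochs, recording.sampling_rate, qcfg)
    entropy = np.asarray(instantaneous_spectral_entropy(est))
    rms = np.sqrt(np.mean(np.square(epochs), axis=-1))
    line_length = np.mean(np.abs(np.diff(epochs, axis=-1)), axis=-1)
    suppressed = rms < cfg.suppressed_rms_uv
    entropy = np.where(suppressed, np.nan, entropy)
    return starts, {
        "entropy": entropy,
        "rms": rms,
        "line_length": line_length,
        "suppressed": suppressed,
    }


def _trailing_windows(values: np.ndarray, exclude: np.ndarray, w: int) -> np.ndarray:
    """(channels, epochs, w) view of the w epochs strictly before each epoch,
    with excluded epochs set to NaN."""
    n_ch, n_ep = values.shape
    masked = np.where(exclude, np.nan, values)
    pad = np.full((n_ch, w), np.nan)
    hist = np.concatenate([pad, masked[:, :-1]], axis=1) if n_ep > 1 else pad
    return np.lib.stride_tricks.sliding_window_view(hist, w, axis=1)[:, :n_ep, :]


def _rolling_stat(
    values: np.ndarray, exclude: np.ndarray, w: int, quantile: float = 0.5
) -> np.ndarray:
    """Trailing quantile per epoch, ignoring excluded epochs.

    Falls back to the global (non-excluded) statistic where the trailing
    window holds fewer than five usable epochs.
    """
    masked = np.where(exclude, np.nan, values)
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        g_stat = np.nanquantile(masked, quantile, axis=1)
        g_stat = np.where(np.isnan(g_stat), np.nanquantile(values, quantile, axis=1), g_stat)
        windows = _trailing_windows(values, exclude, max(w, 1))
        stat = np.nanquantile(windows, quantile, axis=-1)
        counts = np.sum(~np.isnan(windows), axis=-1)
    use_global = (counts < 5) | np.isnan(stat)
    return np.where(use_global, g_stat[:, None], stat)


def _rolling_median_mad(
    values: np.ndarray, exclude: np.ndarray, w: int
) -> tuple[np.ndarray, np.ndarray]:
    """Trailing median and MAD per epoch, ignoring excluded epochs."""
    masked = np.where(exclude, np.nan, values)
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        g_med = np.nanmedian(masked, axis=1)
        g_med = np.where(np.isnan(g_med), np.nanmedian(values, axis=1), g_med)
        g_mad = np.nanmedian(np.abs(masked - g_med[:, None]), axis=1)
        windows = _trailing_windows(values, exclude, max(w, 1))
        med = np.nanmedian(windows, axis=-1)
        mad = np.nanmedian(np.abs(windows - med[..., None]), axis=-1)
        counts = np.sum(~np.isnan(windows), axis=-1)
    use_global = (counts < 5) | np.isnan(med)
    med = np.where(use_global, g_med[:, None], med)
    mad = np.where(use_global, g_mad[:, None], mad)
    return med, np.maximum(mad, 1e-12)


def _flag_epochs(
    feats: dict[str, np.ndarray], starts: np.ndarray, cfg: DetectionConfig
) -> np.ndarray:
    """Two-pass robust thresholding; returns per-channel boolean flags.

    The provisional pass flags high-amplitude epochs against a trailing low
    quantile of epoch RMS (robust even when discharges dominate the
    window); the final pass re-estimates entropy/amplitude background with
    those epochs excluded and applies the joint entropy-drop AND
    amplitude-rise criterion.
    """
    hop = starts[1] - starts[0] if len(starts) > 1 else cfg.epoch_s
    w = int(round(cfg.background_s / hop))
    entropy, rms, suppressed = feats["entropy"], feats["rms"], feats["suppressed"]

    base_rms = _rolling_stat(rms, suppressed, w, quantile=0.3)
    provisional = (~suppressed) & (rms >= cfg.a_thr * base_rms)
    exclude = suppressed | provisional
    med_h, mad_h = _rolling_median_mad(entropy, exclude, w)
    med_r = _rolling_stat(rms, exclude, w, quantile=0.5)
    z = (entropy - med_h) / (1.4826 * mad_h)
    with np.errstate(invalid="ignore"):
        return (~suppressed) & (z <= -cfg.z_thr) & (rms >= cfg.a_thr * med_r)


def detect_events(
    recording: EEGRecording,
    cfg: DetectionConfig | None = None,
) -> list[SeizureEvent]:
    """Detect electrographic seizure episodes in a preprocessed record.

    Epochs flagged on at least ``min_channel_fraction`` of channels form
    candidate runs; runs merged across gaps up to ``gap_s`` and at least
    ``min_duration_s`` long become events. Never fires inside suppressed
    (isoelectric) spans. Returns events sorted by start time.
    """
    cfg = cfg or DetectionConfig()
    starts, feats = _feature_arrays(recording, cfg)
    flags = _flag_epochs(feats, starts, cfg)
    frac = flags.mean(axis=0)
    epoch_on = frac >= cfg.min_channel_fraction

    intervals = _merge_runs(starts, cfg.epoch_s, epoch_on, cfg.gap_s, cfg.min_duration_s)
    events = []
    for a, b in intervals:
        events.append(_characterize(recording, a, b, flags, starts, cfg))
    return events


def _merge_runs(
    starts: np.ndarray, epoch_s: float, on: np.ndarray, gap_s: float, min_dur_s: float
) -> list[tuple[float, float]]:
    intervals: list[list[float]] = []
    for i in np.flatnonzero(on):
        a, b = float(starts[i]), float(starts[i] + epoch_s)
        if intervals and a - intervals[-1][1] <= gap_s:
            intervals[-1][1] = max(intervals[-1][1], b)
        else:
            intervals.append([a, b])
    return [(a, b) for a, b in intervals if b - a >= min_dur_s - 1e-9]


def _characterize(
    recording: EEGRecording,
    start_s: float,
    end_s: float,
    flags: np.ndarray,
    starts: np.ndarray,
    cfg: DetectionConfig,
) -> SeizureEvent:
    fs = recording.sampling_rate
    i0, i1 = int(round(start_s * fs)), int(round(end_s * fs))
    seg = recording.signal[:, i0:i1]
    est = compute_psd(
        seg, fs, QEEGConfig(segment_s=min(1.0, (i1 - i0) / fs), band=cfg.band)
    )
    mean_psd = est.power.mean(axis=0)
    dom = float(est.frequencies[int(np.argmax(mean_psd))])
    in_event = (starts + cfg.epoch_s > start_s) & (starts < end_s)
    ch_frac = flags[:, in_event].mean(axis=1) if in_event.any() else np.zeros(flags.shape[0])
    overall = float(np.mean(ch_frac >= 0.5))
    if overall >= cfg.generalized_fraction:
        scope = "generalized"
    else:
        scope = ",".join(
            recording.channel_labels[c] for c in np.flatnonzero(ch_frac >= 0.5)
        ) or "focal"
    return SeizureEvent(
        start_s=start_s,
        end_s=end_s,
        channel_scope=scope,
        dominant_frequency_hz=dom,
        peak_amplitude_uv=float(np.max(np.abs(seg))),
    )


def summarize(
    events: list[SeizureEvent],
    animal_id: str,
    group: str,
    time_compression: float = 1.0,
    start_offset_s: float = 0.0,
) -> SeizureSummary:
    """Per-animal totals in nominal hours; onset undefined when seizure-free.

    ``events`` must be non-overlapping (as produced by the detector).
    """
    ordered = sorted(events, key=lambda e: e.start_s)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start_s < prev.end_s - 1e-9:
            raise ValueError(f"overlapping events: {prev} / {cur}")
    total_h = sum(e.duration_s for e in ordered) * time_compression / 3600.0
    onset = None
    if ordered:
        onset = (start_offset_s + ordered[0].start_s * time_compression) / 3600.0
    return SeizureSummary(
        animal_id=animal_id,
        group=group,
        total_duration_h=total_h,
        onset_latency_h=onset,
        event_count=len(ordered),
    )


def events_table(
    events: list[SeizureEvent],
    animal_id: str,
    time_compression: float = 1.0,
    start_offset_s: float = 0.0,
) -> pd.DataFrame:
    """Events as a tidy frame on the nominal clock (seconds)."""
    rows = [
        {
            "animal": animal_id,
            "start_s": start_offset_s + e.start_s * time_compression,
            "end_s": start_offset_s + e.end_s * time_compression,
            "duration_s": e.duration_s * time_compression,
            "channel_scope": e.channel_scope,
            "dominant_hz": e.dominant_frequency_hz,
            "peak_amplitude_uv": e.peak_amplitude_uv,
        }
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "animal", "start_s", "end_s", "duration_s",
            "channel_scope", "dominant_hz", "peak_amplitude_uv",
        ],
    )


def group_onset_profile(summaries: list[SeizureSummary]) -> pd.DataFrame:
    """Per-group incidence, median onset and burden table."""
    if not summaries:
        raise ValueError("need at least one summary")
    df = pd.DataFrame(
        [
            {
                "group": s.group,
                "seizing": not s.seizure_free,
                "onset_h": s.onset_latency_h,
                "burden_h": s.total_duration_h,
            }
            for s in summaries
        ]
    )
    rows = []
    for group, sub in df.groupby("group", sort=False):
        seizing = sub[sub["seizing"]]
        n = len(sub)
        rows.append(
            {
                "group": group,
                "n": n,
                "n_seizing": int(sub["seizing"].sum()),
                "incidence": float(sub["seizing"].mean()),
                "median_onset_h": float(seizing["onset_h"].median()) if len(seizing) else np.nan,
                "mean_burden_h": float(seizing["burden_h"].mean()) if len(seizing) else 0.0,
                "sem_burden_h": (
                    float(seizing["burden_h"].std(ddof=1) / np.sqrt(len(seizing)))
                    if len(seizing) > 1
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
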