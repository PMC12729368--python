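"""Power spectra and quantitative EEG markers (band powers, SEF, entropy).

PSDs are Welch estimates with a Gaussian taper on 30 s analysis epochs.
The two scalar markers are the 95% spectral edge frequency (SEF) — the
lowest frequency below which 95% of the 1-30 Hz power lies — and the
normalized Shannon spectral entropy, 0 for a single-frequency spectrum and
1 for a flat one. Isoelectric (suppressed) epochs yield NaN sentinels and
are excluded from group summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import DEFAULT_BANDS, sliding_epoch_matrix
from .recording import EEGRecording


@dataclass(frozen=True)
class QEEGConfig:
    """Spectral-analysis configuration.

    ``gaussian_k`` is the ratio of Welch segment length to the Gaussian
    taper's standard deviation (kernel size; 3-5 is sensible, default 4).
    Durations are in actual seconds of signal; on a time-compressed
    simulation choose windows long enough to resolve the 1 Hz grid
    (>= ~2 s) rather than scaling the 30 s default down.
    """

    window_s: float = 30.0
    overlap_fraction: float = 0.5
    segment_s: float = 4.0
    segment_overlap: float = 0.5
    gaussian_k: float = 4.0
    band: tuple[float, float] = (1.0, 30.0)
    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BANDS))
    edge: float = 0.95
    suppressed_rms_uv: float = 2.0


@dataclass
class SpectralEstimate:
    """One-sided PSD restricted to the analysis band.

    ``power`` may be any shape ending in ``len(frequencies)``; helper
    functions broadcast over leading axes.
    """

    frequencies: np.ndarray
    power: np.ndarray
    suppressed: np.ndarray | bool = False
    window_descriptor: str = ""

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < -1e-12):
            raise ValueError("PSD must be nonnegative")


def _gaussian_window(nperseg: int, k: float) -> np.ndarray:
    return sps.windows.gaussian(nperseg, std=nperseg / k)


def compute_psd(
    samples: np.ndarray, sampling_rate: float, cfg: QEEGConfig | None = None
) -> SpectralEstimate:
    """Welch PSD of one epoch (or a stack of epochs on the last axis).

    The estimate is restricted to ``cfg.band``; integrated power matches the
    band-limited time-domain variance to within the windowing tolerance.
    All-zero (suppressed) epochs return an all-zero PSD flagged suppressed.
    """
    cfg = cfg or QEEGConfig()
    samples = np.asarray(samples, dtype=float)
    nperseg = min(int(round(cfg.segment_s * sampling_rate)), samples.shape[-1])
    noverlap = int(round(nperseg * cfg.segment_overlap))
    freqs, psd = sps.welch(
        samples,
        fs=sampling_rate,
        window=_gaussian_window(nperseg, cfg.gaussian_k),
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        axis=-1,
    )
    lo, hi = cfg.band
    keep = (freqs >= lo) & (freqs <= hi)
    rms = np.sqrt(np.mean(np.square(samples), axis=-1))
    return SpectralEstimate(
        frequencies=freqs[keep],
        power=psd[..., keep],
        suppressed=rms < cfg.suppressed_rms_uv,
        window_descriptor=f"gaussian(k={cfg.gaussian_k}) welch {cfg.segment_s}s/{cfg.segment_overlap}",
    )


def spectral_edge_frequency(
    psd: SpectralEstimate | np.ndarray,
    frequencies: np.ndarray | None = None,
    edge: float = 0.95,
) -> np.ndarray | float:
    """Smallest grid frequency at which cumulative power reaches ``edge``.

    Computed on the discrete grid without interpolation. Zero-power spectra
    return NaN (suppressed sentinel, excluded from summaries).
    """
    if isinstance(psd, SpectralEstimate):
        power, freqs = psd.power, psd.frequencies
    else:
        power, freqs = np.asarray(psd, dtype=float), np.asarray(frequencies, dtype=float)
    scalar = power.ndim == 1
    power = np.atleast_2d(power)
    total = power.sum(axis=-1)
    cum = np.cumsum(power, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        reached = cum >= edge * total[..., None] - 1e-12 * total[..., None]
    idx = np.argmax(reached, axis=-1)
    out = freqs[idx].astype(float)
    out[total <= 0] = np.nan
    return float(out[0]) if scalar else out


def instantaneous_spectral_entropy(
    psd: SpectralEstimate | np.ndarray, frequencies: np.ndarray | None = None
) -> np.ndarray | float:
    """Normalized Shannon entropy of the power distribution across bins.

    ``H = -sum(p_i log p_i) / log N`` with ``p_i`` the bin power fractions
    over the N grid bins: 0 for a point mass, 1 for a flat spectrum.
    Zero-power spectra return NaN.
    """
    power = psd.power if isinstance(psd, SpectralEstimate) else np.asarray(psd, dtype=float)
    scalar = power.ndim == 1
    power = np.atleast_2d(power)
    n_bins = power.shape[-1]
    total = power.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = power / total
        h = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=-1) / np.log(n_bins)
    h = np.where(total[..., 0] > 0, np.clip(h, 0.0, 1.0), np.nan)
    return float(h[0]) if scalar else h


def band_power(psd: SpectralEstimate, lo: float, hi: float, top: float | None = None) -> np.ndarray:
    """Integrated PSD over ``[lo, hi)`` (closed at the global upper edge)."""
    top = top if top is not None else psd.frequencies[-1]
    f = psd.frequencies
    mask = (f >= lo) & ((f < hi) | ((hi >= top) & (f <= hi)))
    df = f[1] - f[0]
    return psd.power[..., mask].sum(axis=-1) * df


def normalize_to_baseline(
    values: np.ndarray, times: np.ndarray, baseline_interval: tuple[float, float]
) -> np.ndarray:
    """Divide a metric series by its mean over the baseline interval.

    The baseline must be nonempty with nonzero mean; the baseline mean maps
    to exactly 1 by construction.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    t0, t1 = baseline_interval
    mask = (times >= t0) & (times < t1)
    if not mask.any():
        raise ValueError(f"no samples fall inside the baseline interval [{t0}, {t1})")
    base = np.nanmean(values[..., mask], axis=-1)
    if np.any(np.isclose(base, 0.0)) or np.any(np.isnan(base)):
        raise ZeroDivisionError("baseline power is zero or undefined; normalization impossible")
    return values / np.expand_dims(base, -1) if values.ndim > 1 else values / base


def qeeg_timecourse(recording: EEGRecording, cfg: QEEGConfig | None = None) -> pd.DataFrame:
    """Per-channel, per-epoch SEF, entropy and band powers as a tidy frame.

    Columns: channel, epoch_start_s (actual), nominal_h (experiment clock),
    rms_uv, suppressed, sef_hz, entropy, power_total and power_<band>.
    Suppressed epochs carry NaN markers.
    """
    cfg = cfg or QEEGConfig()
    starts, epochs = sliding_epoch_matrix(
        recording.signal, recording.sampling_rate, cfg.window_s, cfg.overlap_fraction
    )
    est = compute_psd(epochs, recording.sampling_rate, cfg)  # (ch, n_epochs, n_freq)
    sef = spectral_edge_frequency(est, edge=cfg.edge)
    ent = instantaneous_spectral_entropy(est)
    rms = np.sqrt(np.mean(np.square(epochs), axis=-1))
    suppressed = rms < cfg.suppressed_rms_uv
    sef = np.where(suppressed, np.nan, sef)
    ent = np.where(suppressed, np.nan, ent)

    n_ch, n_ep = rms.shape
    top = max(hi for _, hi in cfg.bands.values())
    frame = {
        "channel": np.repeat([recording.channel_labels[c] for c in range(n_ch)], n_ep),
        "epoch_start_s": np.tile(starts, n_ch),
        "nominal_h": np.tile(
            (recording.start_offset_s + starts * recording.time_compression) / 3600.0, n_ch
        ),
        "rms_uv": rms.ravel(),
        "suppressed": suppressed.ravel(),
        "sef_hz": np.asarray(sef).ravel(),
        "entropy": np.asarray(ent).ravel(),
        "power_total": band_power(est, *cfg.band, top=cfg.band[1]).ravel(),
    }
    for name, (lo, hi) in cfg.bands.items():
        frame[f"power_{name}"] = band_power(est, lo, hi, top=top).ravel()
    return pd.DataFrame(frame)


def animal_qeeg_value(timecourse: pd.DataFrame, metric: str, mode: str = "terminal") -> float:
    """Collapse one animal's timecourse to a scalar marker value.

    ``terminal`` averages the last non-suppressed epoch of each channel
    (the end-of-observation reading); ``mean`` averages all non-suppressed
    epochs. NaN if every epoch is suppressed.
    """
    ok = timecourse[~timecourse["suppressed"]]
    if ok.empty:
        return float("nan")
    if mode == "terminal":
        idx = ok.groupby("channel")["epoch_start_s"].idxmax()
        return float(ok.loc[idx, metric].mean())
    if mode == "mean":
        return float(ok.groupby("channel")[metric].mean().mean())
    raise ValueError(f"unknown aggregation mode {mode!r}")


def cohort_qeeg_summary(
    timecourses: dict[str, tuple[str, pd.DataFrame]],
    metrics: tuple[str, ...] = ("sef_hz", "entropy"),
    mode: str = "terminal",
) -> pd.DataFrame:
    """Group-level marker means from per-animal timecourses.

    ``timecourses`` maps animal_id -> (group, timecourse frame). Returns a
    tidy frame (animal, group, metric, value) ready for group statistics.
    """
    rows = []
    for animal, (group, tc) in timecourses.items():
        for metric in metrics:
            rows.append(
                {"animal": animal, "group": group, "metric": metric,
                 "value": animal_qeeg_value(tc, metric, mode=mode)}
            )
    return pd.DataFrame(rows)
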