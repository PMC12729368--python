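"""Flash visual evoked potentials: trial averaging and P100 extraction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as gstats


@dataclass(frozen=True)
class VEPResult:
    """Grand-average waveform and its P100 reading.

    ``absent`` marks waveforms without a positive deflection in the search
    window (no measurable response); latency/amplitude are NaN then.
    """

    grand_average: np.ndarray
    times_s: np.ndarray
    n_trials: int
    p100_latency_ms: float
    p100_amplitude_uv: float
    channel: str = "O1/O2"
    absent: bool = False


def average_trials(
    trials: np.ndarray,
    times_s: np.ndarray,
    baseline_window_s: tuple[float, float] = (-0.05, 0.0),
) -> np.ndarray:
    """Pointwise mean across baseline-corrected stimulus-locked trials.

    Each trial first has its pre-stimulus baseline mean subtracted, so the
    average is referenced to 0 at baseline; with independent noise the
    residual noise RMS shrinks as 1/sqrt(n_trials).
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    times_s = np.asarray(times_s, dtype=float)
    if trials.shape[1] != times_s.size:
        raise ValueError(
            f"trial length {trials.shape[1]} does not match time axis {times_s.size}"
        )
    if trials.shape[0] < 1:
        raise ValueError("need at least one trial")
    b0, b1 = baseline_window_s
    base = (times_s >= b0) & (times_s < b1)
    if base.any():
        trials = trials - trials[:, base].mean(axis=1, keepdims=True)
    return trials.mean(axis=0)


def extract_p100(
    grand_average: np.ndarray,
    times_s: np.ndarray,
    search_window_s: tuple[float, float] = (0.07, 0.15),
) -> tuple[float, float, bool]:
    """Latency (ms) and amplitude (uV) of the maximal positive deflection.

    Amplitude is relative to the (already-subtracted) pre-stimulus baseline.
    Returns ``(nan, nan, True)`` when nothing positive lies in the window.
    """
    lo, hi = search_window_s
    if lo >= hi or lo < times_s[0] or hi > times_s[-1] + 1e-9:
        raise ValueError(f"search window [{lo}, {hi}] outside epoch")
    mask = (times_s >= lo) & (times_s <= hi)
    seg = np.asarray(grand_average, dtype=float)[mask]
    if seg.size == 0 or np.max(seg) <= 0:
        return float("nan"), float("nan"), True
    k = int(np.argmax(seg))
    return float(times_s[mask][k] * 1000.0), float(seg[k]), False


def analyze_vep(
    trials: np.ndarray,
    times_s: np.ndarray,
    search_window_s: tuple[float, float] = (0.07, 0.15),
    baseline_window_s: tuple[float, float] = (-0.05, 0.0),
    channel: str = "O1/O2",
) -> VEPResult:
    """Average trials and read the P100 in one step."""
    avg = average_trials(trials, times_s, baseline_window_s)
    latency, amplitude, absent = extract_p100(avg, times_s, search_window_s)
    return VEPResult(
        grand_average=avg,
        times_s=times_s,
        n_trials=np.atleast_2d(trials).shape[0],
        p100_latency_ms=latency,
        p100_amplitude_uv=amplitude,
        channel=channel,
        absent=absent,
    )


def group_vep_compare(results: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Group latency/amplitude comparison from per-animal P100 readings.

    ``results`` needs columns animal, group, latency_ms, amplitude_uv.
    Returns a summary frame (mean +/- SEM per group) and one-way
    ANOVA + Tukey results per measure.
    """
    if results["group"].nunique() < 2:
        raise ValueError("need at least two groups to compare")
    summary = (
        results.groupby("group", sort=False)
        .agg(
            n=("animal", "count"),
            latency_mean_ms=("latency_ms", "mean"),
            latency_sem_ms=("latency_ms", "sem"),
            amplitude_mean_uv=("amplitude_uv", "mean"),
            amplitude_sem_uv=("amplitude_uv", "sem"),
        )
        .reset_index()
    )
    out = {"summary": summary}
    for measure in ("latency_ms", "amplitude_uv"):
        groups = {g: sub[measure].dropna().to_numpy() for g, sub in results.groupby("group")}
        out[measure] = gstats.anova_oneway(groups, alpha=alpha)
    return out
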