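"""Synthetic cohorts for a piglet asphyxia neuroprotection study.

Emulates the three treatment arms of a 48 h hypoxic-ischemic
encephalopathy protocol: an untreated normothermic arm (A-NT), a molecular
hydrogen arm (A-H2) and a therapeutic hypothermia arm (A-TH). Each animal
gets a multi-channel EEG record (post-asphyxia isoelectric suppression with
exponential amplitude recovery over amplitude-modulated 1/f^alpha noise,
plus spike-and-wave seizure episodes where the arm seizes), flash-VEP trial
matrices, a rectal-temperature protocol schedule and neuropathology
observations (field severities for the neocortex, damaged/total neuron
counts elsewhere).

The generator works on a compressed timeline: one actual second of signal
stands for ``timeline_compression`` nominal seconds, so a full 48 h record
fits desk-scale tests while every downstream algorithm runs unchanged;
burden and onset outputs are reported back in nominal hours. Spectral
content (discharge rate, 1/f shape) is *not* compressed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recording import DEFAULT_MONTAGE, Annotation, EEGRecording

GROUP_NT = "A-NT"
GROUP_H2 = "A-H2"
GROUP_TH = "A-TH"
GROUPS = (GROUP_NT, GROUP_H2, GROUP_TH)

#: Regions scored by damaged/total neuron counts.
COUNT_REGIONS = ("CA1", "CA3", "caudate", "putamen", "thalamus")
#: Neocortical regions scored from 40-field injury-pattern severities.
NEOCORTEX_REGIONS = ("frontal", "parietal", "temporal", "occipital")
SEVERITY_LEVELS = ("none", "scattered", "grouped/laminar", "panlaminar")

NORMOTHERMIA_C = 38.5
HYPOTHERMIA_C = 33.5


@dataclass(frozen=True)
class BackgroundParams:
    """Background EEG model: envelope-modulated band-limited 1/f^alpha noise.

    The RMS envelope sits at ``baseline_amplitude_uv`` before asphyxia,
    collapses to ``floor_uv`` during the insult, stays isoelectric for
    ``isoelectric_duration_h`` and then recovers exponentially with time
    constant ``recovery_tau_h`` toward baseline.
    """

    baseline_amplitude_uv: float = 30.0
    isoelectric_duration_h: float = 2.0
    recovery_tau_h: float = 12.0
    one_over_f_exponent: float = 1.8
    floor_uv: float = 1.5
    asphyxia_suppression_tau_min: float = 2.0
    band: tuple[float, float] = (1.0, 30.0)

    def validate(self) -> None:
        if self.baseline_amplitude_uv <= 0:
            raise ValueError("baseline_amplitude_uv must be positive")
        if self.isoelectric_duration_h < 0 or self.recovery_tau_h < 0:
            raise ValueError("durations and time constants must be nonnegative")


@dataclass(frozen=True)
class SeizureParams:
    """Per-arm electrographic seizure structure (nominal hours).

    ``probability_any`` is the chance an animal seizes at all; seizing
    animals draw a total burden from a gamma distribution with mean
    ``burden_mean_h`` and shape ``burden_shape``, split over
    ``1 + Poisson(episode_count_mean - 1)`` episodes placed after an onset
    drawn uniformly from ``onset_window_h``.
    """

    probability_any: float = 0.0
    onset_window_h: tuple[float, float] = (24.0, 32.0)
    burden_mean_h: float = 0.0
    burden_shape: float = 4.0
    episode_count_mean: float = 2.5
    discharge_hz: float = 10.0
    amplitude_gain: float = 6.0

    def validate(self) -> None:
        if not 0 <= self.probability_any <= 1:
            raise ValueError("probability_any must be in [0, 1]")
        if self.burden_mean_h < 0 or self.burden_shape <= 0:
            raise ValueError("burden distribution parameters must be positive")
        if self.onset_window_h[0] > self.onset_window_h[1]:
            raise ValueError("onset window must be ordered")
        if self.discharge_hz <= 0 or self.amplitude_gain <= 0:
            raise ValueError("discharge_hz and amplitude_gain must be positive")


@dataclass(frozen=True)
class VEPParams:
    """Flash-VEP protocol and response template.

    Ten trains of ten 1 Hz flashes (10 s between trains) give the 100
    trials entering each grand average. The template is a P100-dominated
    waveform: a positive peak at ``p100_latency_ms`` preceded by a small
    N70 trough; trials add white noise of ``noise_sd_uv``.
    """

    p100_latency_ms: float = 105.0
    p100_amplitude_uv: float = 10.0
    noise_sd_uv: float = 5.0
    n_trains: int = 10
    flashes_per_train: int = 10
    flash_interval_s: float = 1.0
    train_gap_s: float = 10.0
    epoch_window_s: tuple[float, float] = (-0.05, 0.35)

    def validate(self) -> None:
        if self.p100_amplitude_uv <= 0 or self.noise_sd_uv < 0:
            raise ValueError("amplitude must be positive, noise nonnegative")
        if min(self.n_trains, self.flashes_per_train) < 1:
            raise ValueError("need at least one train and one flash")


@dataclass(frozen=True)
class PathologyParams:
    """Injury structure for one arm.

    ``injury_probability`` maps each count region to the per-neuron damage
    probability; neocortical severities are Dirichlet-categorical: each
    animal/region draws class probabilities from
    ``Dirichlet(concentration * severity_probs)`` and then 40 field
    severities from them.
    """

    injury_probability: dict[str, float] = field(
        default_factory=lambda: {r: 0.1 for r in COUNT_REGIONS}
    )
    neurons_per_region: int = 200
    severity_probs: tuple[float, float, float, float] = (0.72, 0.22, 0.05, 0.01)
    severity_concentration: float = 60.0
    fields_per_region: int = 40

    def validate(self) -> None:
        for region, p in self.injury_probability.items():
            if not 0 <= p <= 1:
                raise ValueError(f"injury probability for {region} outside [0, 1]: {p}")
        if abs(sum(self.severity_probs) - 1.0) > 1e-6:
            raise ValueError("severity_probs must sum to 1")


@dataclass(frozen=True)
class GroupProfile:
    background: BackgroundParams
    seizure: SeizureParams
    vep: VEPParams
    pathology: PathologyParams

    def validate(self) -> None:
        self.background.validate()
        self.seizure.validate()
        self.vep.validate()
        self.pathology.validate()


def _default_profiles() -> dict[str, GroupProfile]:
    """Arm-specific defaults mirroring the study's group-level structure.

    A-TH seizes never; A-H2 onset is delayed relative to A-NT; burden means
    are 3.4 h (A-NT) and 3.1 h (A-H2) among seizing animals. Recovered-EEG
    spectral shape is flattest (most complex) under H2 and steepest (most
    low-frequency dominated) under hypothermia; TH shortens P100 latency.
    Thalamic injury is near-complete untreated and strongly reduced under
    either treatment; other regions show low-to-moderate injury everywhere.
    """
    shared_pathology = {"CA1": 0.10, "CA3": 0.12, "caudate": 0.12, "putamen": 0.12}
    return {
        GROUP_NT: GroupProfile(
            background=BackgroundParams(one_over_f_exponent=1.8, recovery_tau_h=12.0),
            seizure=SeizureParams(
                probability_any=5.0 / 6.0, onset_window_h=(24.0, 32.0), burden_mean_h=3.4
            ),
            vep=VEPParams(p100_latency_ms=105.0),
            pathology=PathologyParams(
                injury_probability={**shared_pathology, "thalamus": 0.92}
            ),
        ),
        GROUP_H2: GroupProfile(
            background=BackgroundParams(one_over_f_exponent=1.4, recovery_tau_h=10.0),
            seizure=SeizureParams(
                probability_any=1.0, onset_window_h=(30.0, 38.0), burden_mean_h=3.1
            ),
            vep=VEPParams(p100_latency_ms=102.0),
            pathology=PathologyParams(
                injury_probability={
                    "CA1": 0.08, "CA3": 0.09, "caudate": 0.10, "putamen": 0.10,
                    "thalamus": 0.15,
                }
            ),
        ),
        GROUP_TH: GroupProfile(
            background=BackgroundParams(one_over_f_exponent=2.2, recovery_tau_h=16.0),
            seizure=SeizureParams(probability_any=0.0, burden_mean_h=0.0),
            vep=VEPParams(p100_latency_ms=90.0),
            pathology=PathologyParams(
                injury_probability={
                    "CA1": 0.08, "CA3": 0.09, "caudate": 0.10, "putamen": 0.10,
                    "thalamus": 0.15,
                }
            ),
        ),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters for one simulated cohort.

    Defaults reproduce the study conditions: 6/8/8 animals, 256 Hz,
    eight-channel fronto-parieto-centro-occipital montage, 1 h pre-asphyxia
    baseline, 20 min asphyxia, 48 h observation. ``timeline_compression``
    shrinks the waveform (240 nominal seconds per actual second by default,
    i.e. a ~740 s record per animal) without touching spectral content.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {GROUP_NT: 6, GROUP_H2: 8, GROUP_TH: 8}
    )
    seed: int = 0
    timeline_compression: float = 240.0
    sampling_rate: float = 256.0
    channel_labels: tuple[str, ...] = DEFAULT_MONTAGE
    baseline_h: float = 1.0
    asphyxia_duration_min: float = 20.0
    observation_h: float = 48.0
    profiles: dict[str, GroupProfile] = field(default_factory=_default_profiles)

    def validate(self) -> None:
        if self.timeline_compression < 1:
            raise ValueError("timeline_compression must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for group in self.n_per_group:
            if group not in GROUPS:
                raise ValueError(f"unknown group label {group!r}")
            if self.n_per_group[group] < 0:
                raise ValueError("group sizes must be nonnegative")
        for profile in self.profiles.values():
            profile.validate()

    @property
    def n_animals(self) -> int:
        return sum(self.n_per_group.values())

    @property
    def start_offset_s(self) -> float:
        """Nominal start of each record relative to reventilation onset."""
        return -(self.baseline_h * 3600.0 + self.asphyxia_duration_min * 60.0)

    @property
    def record_duration_actual_s(self) -> float:
        nominal = self.observation_h * 3600.0 - self.start_offset_s
        return nominal / self.timeline_compression


# ---------------------------------------------------------------------------
# background EEG


def _rms_envelope(
    t_nominal_s: np.ndarray, params: BackgroundParams, asphyxia_start_s: float
) -> np.ndarray:
    """Target RMS amplitude (uV) along the nominal timeline."""
    iso_end = params.isoelectric_duration_h * 3600.0
    tau = params.recovery_tau_h * 3600.0
    tau_down = params.asphyxia_suppression_tau_min * 60.0
    env = np.full_like(t_nominal_s, params.floor_uv)
    pre = t_nominal_s < asphyxia_start_s
    env[pre] = params.baseline_amplitude_uv
    insult = (t_nominal_s >= asphyxia_start_s) & (t_nominal_s < 0)
    if tau_down > 0:
        drop = np.exp(-(t_nominal_s[insult] - asphyxia_start_s) / tau_down)
        env[insult] = params.floor_uv + (params.baseline_amplitude_uv - params.floor_uv) * drop
    rec = t_nominal_s >= iso_end
    if tau > 0:
        rise = 1.0 - np.exp(-(t_nominal_s[rec] - iso_end) / tau)
    else:
        rise = np.ones(rec.sum())
    env[rec] = params.floor_uv + (params.baseline_amplitude_uv - params.floor_uv) * rise
    return env


def _one_over_f_noise(
    n_channels: int, n_samples: int, sampling_rate: float, alpha: float,
    band: tuple[float, float], rng: np.random.Generator,
) -> np.ndarray:
    """Unit-RMS Gaussian noise with 1/f^alpha PSD inside ``band``."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    shape = np.zeros_like(freqs)
    inband = (freqs >= band[0]) & (freqs <= band[1])
    shape[inband] = freqs[inband] ** (-alpha / 2.0)
    spec = (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    ) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x


def generate_background(
    duration_s: float,
    params: BackgroundParams | None = None,
    seed: int | np.random.Generator = 0,
    *,
    sampling_rate: float = 256.0,
    channel_labels: tuple[str, ...] = DEFAULT_MONTAGE,
    time_compression: float = 1.0,
    start_offset_s: float = 0.0,
    asphyxia_start_s: float = -1200.0,
) -> EEGRecording:
    """Simulate seizure-free background EEG.

    ``duration_s`` is actual signal seconds; the suppression/recovery
    envelope is evaluated on the nominal clock (``start_offset_s`` +
    ``time_compression`` * actual time). Reproducible for a fixed seed.
    """
    params = params or BackgroundParams()
    params.validate()
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_samples = int(round(duration_s * sampling_rate))
    t_nom = start_offset_s + np.arange(n_samples) / sampling_rate * time_compression
    env = _rms_envelope(t_nom, params, asphyxia_start_s)
    noise = _one_over_f_noise(
        len(channel_labels), n_samples, sampling_rate, params.one_over_f_exponent,
        params.band, rng,
    )
    return EEGRecording(
        signal=noise * env[None, :],
        sampling_rate=sampling_rate,
        channel_labels=channel_labels,
        start_offset_s=start_offset_s,
        time_compression=time_compression,
    )


# ---------------------------------------------------------------------------
# seizures


def spike_wave_kernel(discharge_hz: float, sampling_rate: float) -> np.ndarray:
    """One period of a unit-RMS spike-and-wave template.

    A biphasic 20 ms spike followed by a positive slow wave filling the
    remainder of the discharge cycle — the standard electrographic
    morphology; repetition at ``discharge_hz`` puts the spectral mode at
    the discharge frequency.
    """
    if discharge_hz <= 0 or discharge_hz > 40:
        raise ValueError("discharge_hz must be in (0, 40] so the 20 ms spike fits the cycle")
    period = 1.0 / discharge_hz
    n = int(round(period * sampling_rate))
    t = np.arange(n) / sampling_rate
    spike = np.exp(-0.5 * ((t - 0.008) / 0.003) ** 2) - 0.6 * np.exp(
        -0.5 * ((t - 0.016) / 0.004) ** 2
    )
    wave = np.where(t >= 0.02, np.sin(np.pi * (t - 0.02) / max(period - 0.02, 1e-6)), 0.0)
    kernel = 1.4 * spike + wave
    return kernel / np.sqrt(np.mean(kernel**2))


def inject_seizure(
    recording: EEGRecording,
    start_s: float,
    duration_s: float,
    discharge_hz: float = 10.0,
    amplitude_gain: float = 6.0,
) -> EEGRecording:
    """Superimpose a generalized spike-and-wave episode on all channels.

    The inserted discharge train has RMS ``amplitude_gain`` times the local
    background RMS, so the segment RMS is at least that. The interval is
    annotated exactly; samples outside it are bit-identical to the input.
    Zero duration returns an unchanged copy. Overlap with an existing
    seizure annotation or an out-of-range interval raises.
    """
    if duration_s == 0:
        return recording.copy()
    if duration_s < 0:
        raise ValueError("duration_s must be nonnegative")
    end_s = start_s + duration_s
    if start_s < 0 or end_s > recording.duration_s + 1e-9:
        raise ValueError(
            f"seizure interval [{start_s:.3f}, {end_s:.3f}] outside record "
            f"[0, {recording.duration_s:.3f}]"
        )
    for ann in recording.annotations_with_label("seizure"):
        if start_s < ann.end_s and end_s > ann.start_s:
            raise ValueError(f"seizure interval overlaps existing injection {ann}")
    out = recording.copy()
    fs = recording.sampling_rate
    i0, i1 = int(round(start_s * fs)), int(round(end_s * fs))
    local_rms = float(np.sqrt(np.mean(out.signal[:, i0:i1] ** 2)))
    kernel = spike_wave_kernel(discharge_hz, fs)
    train = np.tile(kernel, int(np.ceil((i1 - i0) / kernel.size)))[: i1 - i0]
    out.signal[:, i0:i1] += amplitude_gain * max(local_rms, 1e-3) * train[None, :]
    out.annotations.append(Annotation("seizure", start_s, end_s, "generalized"))
    out.annotations.sort(key=lambda a: a.start_s)
    return out


def plan_seizures(
    params: SeizureParams, rng: np.random.Generator, observation_h: float = 48.0
) -> list[tuple[float, float]]:
    """Draw per-animal episode (start_h, duration_h) pairs on the nominal clock.

    Seizing animals draw a gamma-distributed total burden, split it across
    episodes with a Dirichlet weight vector and space the episodes over the
    window between onset and the end of observation, so episodes never
    overlap. Returns an empty list for seizure-free animals.
    """
    params.validate()
    if rng.random() >= params.probability_any or params.burden_mean_h <= 0:
        return []
    onset = rng.uniform(*params.onset_window_h)
    span_end = observation_h - 0.5
    span = max(span_end - onset, 0.25)
    burden = rng.gamma(params.burden_shape, params.burden_mean_h / params.burden_shape)
    burden = min(burden, 0.8 * span)
    n_ep = 1 + rng.poisson(max(params.episode_count_mean - 1.0, 0.0))
    weights = rng.dirichlet(np.full(n_ep, 4.0))
    durations = burden * weights
    gaps = (span - burden) * rng.dirichlet(np.ones(n_ep))
    episodes, cursor = [], onset
    for k in range(n_ep):
        episodes.append((cursor, durations[k]))
        cursor += durations[k] + gaps[k]
    return episodes


# ---------------------------------------------------------------------------
# VEP


def vep_time_axis(params: VEPParams, sampling_rate: float = 256.0) -> np.ndarray:
    lo, hi = params.epoch_window_s
    n = int(round((hi - lo) * sampling_rate))
    return lo + np.arange(n) / sampling_rate


def vep_template(params: VEPParams, times_s: np.ndarray) -> np.ndarray:
    """Deterministic flash response: N70 trough then P100 peak (uV)."""
    lat = params.p100_latency_ms / 1000.0
    p100 = params.p100_amplitude_uv * np.exp(-0.5 * ((times_s - lat) / 0.012) ** 2)
    n70 = -0.4 * params.p100_amplitude_uv * np.exp(-0.5 * ((times_s - 0.055) / 0.008) ** 2)
    return p100 + n70


def generate_vep_trials(
    params: VEPParams | None = None,
    seed: int | np.random.Generator = 0,
    sampling_rate: float = 256.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate the stimulus-locked flash-VEP trial matrix.

    Returns ``(trials, times_s, stimulus_times_s)``: one epoch per flash
    (template plus independent white noise), the peri-stimulus time axis,
    and the absolute flash instants of the train protocol.
    """
    params = params or VEPParams()
    params.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = vep_time_axis(params, sampling_rate)
    template = vep_template(params, times)
    train_period = params.flashes_per_train * params.flash_interval_s + params.train_gap_s
    stim = np.array(
        [
            tr * train_period + fl * params.flash_interval_s
            for tr in range(params.n_trains)
            for fl in range(params.flashes_per_train)
        ]
    )
    trials = template[None, :] + params.noise_sd_uv * rng.standard_normal(
        (stim.size, times.size)
    )
    return trials, times, stim


# ---------------------------------------------------------------------------
# protocol schedule


@dataclass(frozen=True)
class ProtocolSchedule:
    """Piecewise-linear rectal-temperature target over the observation.

    Breakpoints are (hours post-reventilation, degC); values between
    breakpoints interpolate linearly. ``asphyxia_interval_min`` is
    (start, duration) in minutes on the same clock.
    """

    group: str
    breakpoints_h: tuple[float, ...]
    temperatures_c: tuple[float, ...]
    asphyxia_interval_min: tuple[float, float] = (-20.0, 20.0)

    def temperature_at(self, hours: float | np.ndarray) -> np.ndarray | float:
        return np.interp(hours, self.breakpoints_h, self.temperatures_c)

    def series(self, step_h: float = 0.25) -> pd.DataFrame:
        t = np.arange(0.0, self.breakpoints_h[-1] + 1e-9, step_h)
        return pd.DataFrame({"hours": t, "temperature_c": self.temperature_at(t)})


def generate_protocol_schedule(group: str, observation_h: float = 48.0) -> ProtocolSchedule:
    """Temperature protocol for one arm.

    Normothermic arms hold 38.5 degC throughout. The hypothermia arm cools
    to 33.5 degC within ~47.5 min of reventilation, holds until hour 37,
    rewarms at 0.5 degC/h for 10 h and finishes at the normothermic
    setpoint one hour before the end of observation.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group label {group!r}")
    if group in (GROUP_NT, GROUP_H2):
        return ProtocolSchedule(group, (0.0, observation_h), (NORMOTHERMIA_C, NORMOTHERMIA_C))
    cool_done_h = 47.5 / 60.0
    rewarm_h = (NORMOTHERMIA_C - HYPOTHERMIA_C) / 0.5
    return ProtocolSchedule(
        group,
        (0.0, cool_done_h, 37.0, 37.0 + rewarm_h, observation_h),
        (NORMOTHERMIA_C, HYPOTHERMIA_C, HYPOTHERMIA_C, NORMOTHERMIA_C, NORMOTHERMIA_C),
    )


# ---------------------------------------------------------------------------
# pathology


def generate_pathology(
    spec: CohortSpec, seed: int | np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-animal neuropathology observations for a cohort.

    Returns ``(counts, fields)``: damaged/total neuron counts per count
    region (binomial given the arm's regional injury probability) and
    per-field ordinal severities for each neocortical region
    (Dirichlet-categorical over the four-level scale).
    """
    spec.validate()
    if seed is None:
        seed = spec.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count_rows, field_rows = [], []
    for animal_id, group in iter_animals(spec):
        pp = spec.profiles[group].pathology
        for region in COUNT_REGIONS:
            p = pp.injury_probability.get(region, 0.0)
            total = pp.neurons_per_region
            damaged = int(rng.binomial(total, p))
            count_rows.append(
                {"animal": animal_id, "group": group, "region": region,
                 "damaged": damaged, "total": total}
            )
        for region in NEOCORTEX_REGIONS:
            probs = rng.dirichlet(pp.severity_concentration * np.asarray(pp.severity_probs))
            sev = rng.choice(len(SEVERITY_LEVELS), size=pp.fields_per_region, p=probs)
            for idx, s in enumerate(sev, start=1):
                field_rows.append(
                    {"animal": animal_id, "group": group, "region": region,
                     "field_index": idx, "severity": SEVERITY_LEVELS[s]}
                )
    return pd.DataFrame(count_rows), pd.DataFrame(field_rows)


# ---------------------------------------------------------------------------
# cohort assembly


def iter_animals(spec: CohortSpec) -> list[tuple[str, str]]:
    """Stable (animal_id, group) listing, e.g. NT01..NT06, H201.., TH01..."""
    out = []
    for group in GROUPS:
        n = spec.n_per_group.get(group, 0)
        tag = group.split("-")[1].replace("_", "")
        for i in range(1, n + 1):
            out.append((f"{tag}{i:02d}", group))
    return out


@dataclass
class AnimalData:
    animal_id: str
    group: str
    eeg: EEGRecording
    schedule: ProtocolSchedule
    vep_trials: np.ndarray
    vep_times_s: np.ndarray
    vep_stimulus_times_s: np.ndarray


@dataclass
class Cohort:
    spec: CohortSpec
    animals: list[AnimalData]
    pathology_counts: pd.DataFrame
    pathology_fields: pd.DataFrame

    @property
    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "animal": a.animal_id,
                    "group": a.group,
                    "time_compression": a.eeg.time_compression,
                    "sampling_rate_hz": a.eeg.sampling_rate,
                    "start_offset_s": a.eeg.start_offset_s,
                    "n_injected_seizures": len(a.eeg.annotations_with_label("seizure")),
                }
                for a in self.animals
            ]
        )

    def injected_seizure_table(self) -> pd.DataFrame:
        """Ground-truth annotations, nominal seconds post-reventilation."""
        rows = []
        for a in self.animals:
            c = a.eeg.time_compression
            for ann in a.eeg.annotations_with_label("seizure"):
                rows.append(
                    {
                        "animal": a.animal_id,
                        "start_s": a.eeg.start_offset_s + ann.start_s * c,
                        "end_s": a.eeg.start_offset_s + ann.end_s * c,
                        "channel_scope": ann.channel_scope,
                    }
                )
        return pd.DataFrame(rows, columns=["animal", "start_s", "end_s", "channel_scope"])


def generate_animal_eeg(
    spec: CohortSpec, group: str, rng: np.random.Generator
) -> EEGRecording:
    """One animal's full record: background plus planned seizure episodes."""
    profile = spec.profiles[group]
    rec = generate_background(
        spec.record_duration_actual_s,
        profile.background,
        rng,
        sampling_rate=spec.sampling_rate,
        channel_labels=spec.channel_labels,
        time_compression=spec.timeline_compression,
        start_offset_s=spec.start_offset_s,
        asphyxia_start_s=-spec.asphyxia_duration_min * 60.0,
    )
    for start_h, dur_h in plan_seizures(profile.seizure, rng, spec.observation_h):
        c = spec.timeline_compression
        start_act = (start_h * 3600.0 - spec.start_offset_s) / c
        rec = inject_seizure(
            rec,
            start_act,
            dur_h * 3600.0 / c,
            discharge_hz=profile.seizure.discharge_hz,
            amplitude_gain=profile.seizure.amplitude_gain,
        )
    return rec


def generate_cohort(spec: CohortSpec | None = None) -> Cohort:
    """Simulate a full three-arm cohort, deterministic under (spec, seed)."""
    spec = spec or CohortSpec()
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    animals_list = iter_animals(spec)
    seeds = root.spawn(len(animals_list) + 1)
    animals = []
    for (animal_id, group), seq in zip(animals_list, seeds[:-1]):
        child = seq.spawn(2)
        rng_eeg = np.random.default_rng(child[0])
        rng_vep = np.random.default_rng(child[1])
        eeg = generate_animal_eeg(spec, group, rng_eeg)
        trials, times, stim = generate_vep_trials(
            spec.profiles[group].vep, rng_vep, spec.sampling_rate
        )
        animals.append(
            AnimalData(
                animal_id=animal_id,
                group=group,
                eeg=eeg,
                schedule=generate_protocol_schedule(group, spec.observation_h),
                vep_trials=trials,
                vep_times_s=times,
                vep_stimulus_times_s=stim,
            )
        )
    counts, fields = generate_pathology(spec, np.random.default_rng(seeds[-1]))
    return Cohort(spec=spec, animals=animals, pathology_counts=counts, pathology_fields=fields)


def spec_to_dict(spec: CohortSpec) -> dict:
    return dataclasses.asdict(spec)
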