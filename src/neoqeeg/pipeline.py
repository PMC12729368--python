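"""End-to-end orchestration: simulate -> preprocess -> qEEG -> seizures ->
VEP -> pathology -> group statistics, with CSV/JSON/SVG outputs.

Every artifact embeds the run seed and a hash of the resolved
configuration, and reruns with the same configuration and seed are
byte-identical (figures are written without timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_io, pathology as patho, stats as gstats, vep as vep_mod
from .preprocess import bandpass
from .recording import EEGRecording
from .seizures import (
    DetectionConfig, SeizureSummary, detect_events, events_table, group_onset_profile, summarize,
)
from .spectral import QEEGConfig, animal_qeeg_value, compute_psd, qeeg_timecourse
from .synthetic import Cohort, CohortSpec, COUNT_REGIONS, GROUPS, generate_cohort


class ConfigError(ValueError):
    """Aggregated configuration problems, one per line."""

    def __init__(self, errors: list[str]):
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(errors))
        self.errors = errors


@dataclass(frozen=True)
class RunConfig:
    """Resolved pipeline configuration.

    Either ``simulate`` is true (a cohort is generated from ``cohort``) or
    ``input_dir`` points at a cohort directory written by
    :func:`neoqeeg.cohort_io.write_cohort`. ``detection`` holds
    nominal-timescale settings; they are rescaled to the record's
    compression at run time. ``qeeg_window_s`` is in actual seconds and
    must resolve the 1 Hz spectral grid (>= ~2 s).
    """

    outdir: str = "neoqeeg_run"
    seed: int = 0
    simulate: bool = True
    input_dir: str | None = None
    cohort: CohortSpec = field(default_factory=CohortSpec)
    qeeg_window_s: float = 4.0
    qeeg_overlap: float = 0.5
    qeeg_mode: str = "terminal"
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    alpha: float = 0.05
    filter_low_hz: float = 1.0
    filter_high_hz: float = 30.0
    filter_order: int = 4
    write_figures: bool = True

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)
        blob = json.dumps(_jsonable(payload), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_TOP_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def validate_config(raw: dict | None) -> RunConfig:
    """Resolve a (possibly partial) mapping into a RunConfig.

    Unknown keys are rejected; all violations are reported together.
    """
    raw = dict(raw or {})
    errors: list[str] = []
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        errors.append(f"unknown keys: {', '.join(sorted(unknown))}")
        for k in unknown:
            raw.pop(k)
    if "cohort" in raw and isinstance(raw["cohort"], dict):
        try:
            raw["cohort"] = cohort_io.spec_from_dict(raw["cohort"])
        except (ValueError, TypeError, KeyError) as exc:
            errors.append(f"cohort: {exc}")
            raw.pop("cohort")
    if "detection" in raw and isinstance(raw["detection"], dict):
        try:
            raw["detection"] = DetectionConfig(**raw["detection"])
        except TypeError as exc:
            errors.append(f"detection: {exc}")
            raw.pop("detection")
    try:
        cfg = RunConfig(**raw)
    except (TypeError, ValueError) as exc:
        errors.append(str(exc))
        raise ConfigError(errors) from None
    if not cfg.simulate and not cfg.input_dir:
        errors.append("either simulate: true or an input_dir is required")
    if not 0 < cfg.filter_low_hz < cfg.filter_high_hz:
        errors.append(
            f"filter band edges must increase from above 0, got "
            f"({cfg.filter_low_hz}, {cfg.filter_high_hz})"
        )
    if cfg.qeeg_window_s < 1.0:
        errors.append(f"qeeg_window_s {cfg.qeeg_window_s} cannot resolve the 1 Hz grid")
    if not 0 <= cfg.qeeg_overlap < 1:
        errors.append(f"qeeg_overlap {cfg.qeeg_overlap} outside [0, 1)")
    if cfg.qeeg_mode not in ("terminal", "mean"):
        errors.append(f"qeeg_mode must be 'terminal' or 'mean', got {cfg.qeeg_mode!r}")
    try:
        cfg.cohort.validate()
    except ValueError as exc:
        errors.append(f"cohort: {exc}")
    try:
        cfg.detection.scaled(1.0)
    except ValueError as exc:
        errors.append(f"detection: {exc}")
    if errors:
        raise ConfigError(errors)
    if cfg.cohort.seed != cfg.seed:
        cfg = dataclasses.replace(cfg, cohort=dataclasses.replace(cfg.cohort, seed=cfg.seed))
    return cfg


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _write_csv(df: pd.DataFrame, path: Path, provenance: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {provenance}\n")
        df.to_csv(fh, index=False)


def _test_result_dict(res: gstats.TestResult) -> dict:
    out = {
        "test": res.name,
        "statistic": res.statistic,
        "df": res.df,
        "p_value": res.p_value,
    }
    if res.pairwise is not None:
        out["pairwise"] = res.pairwise.to_dict(orient="records")
    return _jsonable(out)


def analyze_recording(
    eeg: EEGRecording, config: RunConfig
) -> tuple[pd.DataFrame, list]:
    """Preprocess one record and return (qEEG timecourse, seizure events)."""
    filtered = bandpass(eeg, config.filter_low_hz, config.filter_high_hz, config.filter_order)
    qcfg = QEEGConfig(
        window_s=config.qeeg_window_s,
        overlap_fraction=config.qeeg_overlap,
        segment_s=min(4.0, config.qeeg_window_s),
        band=(config.filter_low_hz, config.filter_high_hz),
    )
    tc = qeeg_timecourse(filtered, qcfg)
    det = config.detection.scaled(eeg.time_compression)
    events = detect_events(filtered, det)
    return tc, events


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle into ``config.outdir``.

    Returns a dict with the output paths and the in-memory summary.
    Deterministic for fixed (config, seed).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = f"neoqeeg seed={config.seed} config={config.config_hash()}"

    if config.simulate:
        cohort = generate_cohort(config.cohort)
    else:
        cohort = cohort_io.read_cohort(config.input_dir)

    qeeg_frames: list[pd.DataFrame] = []
    event_frames: list[pd.DataFrame] = []
    summaries: list[SeizureSummary] = []
    marker_rows: list[dict] = []
    terminal_psds: dict[str, list[np.ndarray]] = {}
    psd_freqs = None
    for animal in cohort.animals:
        try:
            tc, events = analyze_recording(animal.eeg, config)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(
                f"stage=electrophysiology animal={animal.animal_id}: {exc}"
            ) from exc
        tc.insert(0, "animal", animal.animal_id)
        tc.insert(1, "group", animal.group)
        qeeg_frames.append(tc)
        event_frames.append(
            events_table(
                events, animal.animal_id, animal.eeg.time_compression,
                animal.eeg.start_offset_s,
            )
        )
        summaries.append(
            summarize(
                events, animal.animal_id, animal.group,
                animal.eeg.time_compression, animal.eeg.start_offset_s,
            )
        )
        for metric in ("sef_hz", "entropy"):
            marker_rows.append(
                {
                    "animal": animal.animal_id,
                    "group": animal.group,
                    "metric": metric,
                    "value": animal_qeeg_value(tc, metric, config.qeeg_mode),
                }
            )
        est = compute_psd(
            animal.eeg.signal[:, -int(8 * animal.eeg.sampling_rate):],
            animal.eeg.sampling_rate,
            QEEGConfig(segment_s=4.0, band=(config.filter_low_hz, config.filter_high_hz)),
        )
        terminal_psds.setdefault(animal.group, []).append(est.power.mean(axis=0))
        psd_freqs = est.frequencies

    qeeg_df = pd.concat(qeeg_frames, ignore_index=True)
    nonempty = [f for f in event_frames if not f.empty]
    events_df = pd.concat(nonempty, ignore_index=True) if nonempty else event_frames[0]
    summary_df = pd.DataFrame(
        [
            {
                "animal": s.animal_id,
                "group": s.group,
                "total_duration_h": s.total_duration_h,
                "onset_latency_h": s.onset_latency_h,
                "event_count": s.event_count,
                "seizure_free": s.seizure_free,
            }
            for s in summaries
        ]
    )
    onset_df = group_onset_profile(summaries)
    markers_df = pd.DataFrame(marker_rows)

    vep_rows = []
    for animal in cohort.animals:
        res = vep_mod.analyze_vep(animal.vep_trials, animal.vep_times_s)
        vep_rows.append(
            {
                "animal": animal.animal_id,
                "group": animal.group,
                "n_trials": res.n_trials,
                "latency_ms": res.p100_latency_ms,
                "amplitude_uv": res.p100_amplitude_uv,
                "absent": res.absent,
            }
        )
    vep_df = pd.DataFrame(vep_rows)
    if vep_df["group"].nunique() >= 2:
        vep_compare = vep_mod.group_vep_compare(vep_df, alpha=config.alpha)
    else:
        vep_compare = {
            "summary": vep_df.groupby("group", sort=False)
            .agg(
                n=("animal", "count"),
                latency_mean_ms=("latency_ms", "mean"),
                latency_sem_ms=("latency_ms", "sem"),
                amplitude_mean_uv=("amplitude_uv", "mean"),
                amplitude_sem_uv=("amplitude_uv", "sem"),
            )
            .reset_index()
        }

    scores_df = patho.score_cohort(cohort.pathology_fields)
    percent_df = patho.percent_cohort(cohort.pathology_counts)

    stats_summary: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "groups": {g: int((summary_df["group"] == g).sum()) for g in GROUPS},
        "seizures": _jsonable(onset_df.to_dict(orient="records")),
        "qeeg": {},
        "vep": {},
        "pathology": {},
    }
    for metric in ("sef_hz", "entropy"):
        sub = markers_df[markers_df["metric"] == metric].dropna(subset=["value"])
        groups = {g: s["value"].to_numpy() for g, s in sub.groupby("group")}
        if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
            stats_summary["qeeg"][metric] = _test_result_dict(
                gstats.anova_oneway(groups, alpha=config.alpha)
            )
            stats_summary["qeeg"][f"{metric}_group_means"] = _jsonable(
                {g: float(np.mean(v)) for g, v in groups.items()}
            )
    for measure in ("latency_ms", "amplitude_uv"):
        if measure in vep_compare:
            stats_summary["vep"][measure] = _test_result_dict(vep_compare[measure])
    for region in COUNT_REGIONS:
        sub = percent_df[percent_df["region"] == region]
        groups = {g: s["percent_damaged"].to_numpy() for g, s in sub.groupby("group")}
        if len(groups) >= 2:
            stats_summary["pathology"][region] = _test_result_dict(
                gstats.kruskal_wallis_dunn(groups, alpha=config.alpha)
            )
    cortical = {g: s["cortical_sum"].to_numpy() for g, s in scores_df.groupby("group")}
    if len(cortical) >= 2:
        stats_summary["pathology"]["cortical_sum"] = _test_result_dict(
            gstats.kruskal_wallis_dunn(cortical, alpha=config.alpha)
        )

    outputs = {
        "qeeg": outdir / "qeeg_timecourse.csv",
        "markers": outdir / "qeeg_markers.csv",
        "events": outdir / "seizure_events.csv",
        "summaries": outdir / "seizure_summaries.csv",
        "onset": outdir / "group_onset_profile.csv",
        "vep": outdir / "vep_results.csv",
        "vep_groups": outdir / "vep_group_summary.csv",
        "scores": outdir / "pathology_scores.csv",
        "percent": outdir / "pathology_percent.csv",
    }
    _write_csv(qeeg_df, outputs["qeeg"], provenance)
    _write_csv(markers_df, outputs["markers"], provenance)
    _write_csv(events_df, outputs["events"], provenance)
    _write_csv(summary_df, outputs["summaries"], provenance)
    _write_csv(onset_df, outputs["onset"], provenance)
    _write_csv(vep_df, outputs["vep"], provenance)
    _write_csv(vep_compare["summary"], outputs["vep_groups"], provenance)
    _write_csv(scores_df, outputs["scores"], provenance)
    _write_csv(percent_df, outputs["percent"], provenance)

    summary_path = outdir / "stats_summary.json"
    with open(summary_path, "w") as fh:
        json.dump(stats_summary, fh, sort_keys=True, indent=1)
        fh.write("\n")
    outputs["stats"] = summary_path

    if config.write_figures:
        outputs.update(
            _write_figures(outdir, summary_df, events_df, terminal_psds, psd_freqs,
                           markers_df, percent_df, config)
        )
    return {"outputs": {k: str(v) for k, v in outputs.items()}, "summary": stats_summary}


def _write_figures(outdir, summary_df, events_df, terminal_psds, psd_freqs,
                   markers_df, percent_df, config) -> dict:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .spectral import spectral_edge_frequency

    meta = {"Date": None}
    out = {}

    # per-animal seizure raster on the nominal clock
    fig, ax = plt.subplots(figsize=(8, 4))
    order = summary_df.sort_values(["group", "animal"]).reset_index(drop=True)
    for y, row in order.iterrows():
        sub = events_df[events_df["animal"] == row["animal"]]
        for ev in sub.itertuples():
            ax.plot([ev.start_s / 3600, ev.end_s / 3600], [y, y], lw=4, color="crimson")
        ax.text(-1.0, y, f"{row['animal']} ({row['group']})", ha="right", va="center", fontsize=7)
    ax.set_xlim(0, 48)
    ax.set_yticks([])
    ax.set_xlabel("hours post-reventilation")
    ax.set_title("Electrographic seizure raster")
    fig.tight_layout()
    out["fig_raster"] = outdir / "fig_seizure_raster.svg"
    fig.savefig(out["fig_raster"], metadata=meta)
    plt.close(fig)

    # terminal PSD overlays with SEF verticals
    if psd_freqs is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        for group, psds in terminal_psds.items():
            mean_psd = np.mean(psds, axis=0)
            ax.semilogy(psd_freqs, mean_psd, label=group)
            sef = spectral_edge_frequency(mean_psd, psd_freqs)
            ax.axvline(sef, ls="--", lw=1, color=ax.lines[-1].get_color())
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("PSD (uV^2/Hz)")
        ax.set_title("End-of-observation PSD with SEF")
        ax.legend()
        fig.tight_layout()
        out["fig_psd"] = outdir / "fig_psd_sef.svg"
        fig.savefig(out["fig_psd"], metadata=meta)
        plt.close(fig)

    # group marker bars
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
    for ax, metric, label in zip(axes, ("sef_hz", "entropy"), ("SEF (Hz)", "InstSpEnt")):
        sub = markers_df[markers_df["metric"] == metric]
        agg = sub.groupby("group")["value"].agg(["mean", "sem"]).reindex(list(GROUPS))
        ax.bar(agg.index, agg["mean"], yerr=agg["sem"], capsize=4, color="#8899bb")
        ax.set_ylabel(label)
    fig.tight_layout()
    out["fig_markers"] = outdir / "fig_qeeg_markers.svg"
    fig.savefig(out["fig_markers"], metadata=meta)
    plt.close(fig)

    # pathology percent-damaged bars per region
    fig, axes = plt.subplots(1, len(COUNT_REGIONS), figsize=(3 * len(COUNT_REGIONS), 3.2))
    for ax, region in zip(np.atleast_1d(axes), COUNT_REGIONS):
        sub = percent_df[percent_df["region"] == region]
        agg = sub.groupby("group")["percent_damaged"].agg(["mean", "sem"]).reindex(list(GROUPS))
        ax.bar(agg.index, agg["mean"], yerr=agg["sem"], capsize=4, color="#99bb88")
        ax.set_title(region)
        ax.set_ylim(0, 100)
    np.atleast_1d(axes)[0].set_ylabel("% damaged neurons")
    fig.tight_layout()
    out["fig_pathology"] = outdir / "fig_pathology.svg"
    fig.savefig(out["fig_pathology"], metadata=meta)
    plt.close(fig)
    return out
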