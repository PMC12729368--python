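"""On-disk layout for simulated cohorts.

A cohort directory holds one EDF per animal (with its annotation sidecar),
``seizure_annotations.csv`` (ground truth, nominal seconds), per-animal VEP
trial matrices (``vep_<animal>.csv``: first column the peri-stimulus time
axis, then one column per trial), ``vep_stimulus_times.csv``,
``pathology_counts.csv``, ``pathology_fields.csv``, ``metadata.csv`` and the
generating ``cohort_spec.yaml``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .edf import read_edf, write_edf
from .synthetic import AnimalData, Cohort, CohortSpec, generate_protocol_schedule, spec_to_dict


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write a cohort to standard formats; deterministic per (spec, seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for animal in cohort.animals:
        write_edf(animal.eeg, outdir / f"{animal.animal_id}.edf")
        vep = pd.DataFrame(
            animal.vep_trials.T,
            columns=[f"trial_{i + 1:03d}" for i in range(animal.vep_trials.shape[0])],
        )
        vep.insert(0, "time_s", animal.vep_times_s)
        vep.to_csv(outdir / f"vep_{animal.animal_id}.csv", index=False)
    stim_rows = [
        {"animal": a.animal_id, "stimulus_index": i + 1, "time_s": t}
        for a in cohort.animals
        for i, t in enumerate(a.vep_stimulus_times_s)
    ]
    pd.DataFrame(stim_rows).to_csv(outdir / "vep_stimulus_times.csv", index=False)
    cohort.injected_seizure_table().to_csv(outdir / "seizure_annotations.csv", index=False)
    cohort.pathology_counts.to_csv(outdir / "pathology_counts.csv", index=False)
    cohort.pathology_fields.to_csv(outdir / "pathology_fields.csv", index=False)
    cohort.metadata.to_csv(outdir / "metadata.csv", index=False)
    with open(outdir / "cohort_spec.yaml", "w") as fh:
        yaml.safe_dump(spec_to_dict(cohort.spec), fh, sort_keys=True)
    return outdir


def read_cohort(indir: str | Path) -> Cohort:
    """Load a cohort directory written by :func:`write_cohort`."""
    indir = Path(indir)
    with open(indir / "cohort_spec.yaml") as fh:
        raw = yaml.safe_load(fh)
    spec = spec_from_dict(raw)
    meta = pd.read_csv(indir / "metadata.csv")
    stim = pd.read_csv(indir / "vep_stimulus_times.csv")
    animals = []
    for row in meta.itertuples():
        eeg = read_edf(indir / f"{row.animal}.edf")
        vep = pd.read_csv(indir / f"vep_{row.animal}.csv")
        animals.append(
            AnimalData(
                animal_id=row.animal,
                group=row.group,
                eeg=eeg,
                schedule=generate_protocol_schedule(row.group, spec.observation_h),
                vep_trials=vep.drop(columns="time_s").to_numpy().T,
                vep_times_s=vep["time_s"].to_numpy(),
                vep_stimulus_times_s=stim.loc[stim["animal"] == row.animal, "time_s"].to_numpy(),
            )
        )
    return Cohort(
        spec=spec,
        animals=animals,
        pathology_counts=pd.read_csv(indir / "pathology_counts.csv"),
        pathology_fields=pd.read_csv(indir / "pathology_fields.csv"),
    )


def spec_from_dict(raw: dict) -> CohortSpec:
    """Rebuild a CohortSpec from its YAML/dict form."""
    from .synthetic import (
        BackgroundParams, GroupProfile, PathologyParams, SeizureParams, VEPParams,
    )

    def tup(x):
        return tuple(x) if isinstance(x, (list, tuple)) else x

    profiles = {}
    for group, p in raw.get("profiles", {}).items():
        bg = dict(p["background"]); bg["band"] = tup(bg.get("band", (1.0, 30.0)))
        sz = dict(p["seizure"]); sz["onset_window_h"] = tup(sz["onset_window_h"])
        vp = dict(p["vep"]); vp["epoch_window_s"] = tup(vp["epoch_window_s"])
        pa = dict(p["pathology"]); pa["severity_probs"] = tup(pa["severity_probs"])
        profiles[group] = GroupProfile(
            background=BackgroundParams(**bg),
            seizure=SeizureParams(**sz),
            vep=VEPParams(**vp),
            pathology=PathologyParams(**pa),
        )
    kwargs = {k: v for k, v in raw.items() if k != "profiles"}
    if "channel_labels" in kwargs:
        kwargs["channel_labels"] = tuple(kwargs["channel_labels"])
    if profiles:
        kwargs["profiles"] = profiles
    spec = CohortSpec(**kwargs)
    spec.validate()
    return spec


def load_spec(path: str | Path) -> CohortSpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh) or {})


def vep_trials_from_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a trial-matrix CSV -> (trials [n_trials, n_samples], times_s)."""
    df = pd.read_csv(path)
    return df.drop(columns="time_s").to_numpy().T, df["time_s"].to_numpy()
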