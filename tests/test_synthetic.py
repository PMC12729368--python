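"""Synthetic cohort generator: background envelope, seizure injection,
VEP protocol, temperature schedules, pathology draws, determinism."""

import dataclasses

import numpy as np
import pytest
from scipy import signal as sps

import neoqeeg as nq
from neoqeeg import cohort_io
from neoqeeg.synthetic import (
    COUNT_REGIONS, NEOCORTEX_REGIONS, SEVERITY_LEVELS, CohortSpec, GROUP_H2,
    GROUP_NT, GROUP_TH, PathologyParams, SeizureParams, VEPParams, generate_pathology,
    generate_vep_trials, iter_animals, plan_seizures, spike_wave_kernel, vep_template,
    vep_time_axis,
)


def _epoch_rms(signal, fs, window_s=30.0):
    n = int(window_s * fs)
    usable = signal[:, : (signal.shape[1] // n) * n]
    blocks = usable.reshape(signal.shape[0], -1, n)
    return np.sqrt(np.mean(blocks**2, axis=-1))


class TestBackground:
    def test_isoelectric_record_stays_suppressed(self):
        params = nq.BackgroundParams(isoelectric_duration_h=10.0)
        rec = nq.generate_background(300.0, params, seed=0, start_offset_s=0.0)
        assert np.all(_epoch_rms(rec.signal, 256.0) < 5.0)

    def test_instant_recovery_reaches_baseline(self):
        params = nq.BackgroundParams(isoelectric_duration_h=0.0, recovery_tau_h=0.0)
        rec = nq.generate_background(300.0, params, seed=0, start_offset_s=3600.0)
        rms = _epoch_rms(rec.signal, 256.0)
        assert np.allclose(rms, params.baseline_amplitude_uv, rtol=0.15)

    def test_one_over_f_slope_matches_alpha(self):
        params = nq.BackgroundParams(
            isoelectric_duration_h=0.0, recovery_tau_h=0.0, one_over_f_exponent=1.0
        )
        rec = nq.generate_background(300.0, params, seed=1, start_offset_s=3600.0)
        f, p = sps.welch(rec.signal, fs=256.0, nperseg=4096, axis=1)
        m = (f >= 2.0) & (f <= 20.0)
        slope = np.polyfit(np.log(f[m]), np.log(p[:, m].mean(axis=0)), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.2)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            nq.generate_background(-5.0, nq.BackgroundParams(), seed=0)
        with pytest.raises(ValueError):
            nq.generate_background(10.0, nq.BackgroundParams(baseline_amplitude_uv=0.0), seed=0)

    def test_reproducible_for_fixed_seed(self):
        a = nq.generate_background(20.0, seed=42)
        b = nq.generate_background(20.0, seed=42)
        assert np.array_equal(a.signal, b.signal)


class TestInjectSeizure:
    @pytest.fixture()
    def background(self, stationary_background):
        return stationary_background

    def test_spectral_mode_at_discharge_rate(self, background):
        rec = nq.inject_seizure(background, 60.0, 120.0, discharge_hz=10.0)
        f, t, sxx = sps.spectrogram(rec.signal[0], fs=256.0, nperseg=512)
        inside = (t >= 65) & (t <= 175)
        modal = f[np.argmax(sxx[:, inside].mean(axis=1))]
        assert modal == pytest.approx(10.0, abs=0.5)

    def test_zero_duration_returns_unchanged_record(self, background):
        rec = nq.inject_seizure(background, 10.0, 0.0)
        assert np.array_equal(rec.signal, background.signal)
        assert rec.annotations == background.annotations

    def test_amplitude_gain_scales_segment_rms(self, background):
        gain = 5.0
        pre = np.sqrt(np.mean(background.signal[:, 256 * 60 : 256 * 120] ** 2))
        rec = nq.inject_seizure(background, 60.0, 60.0, amplitude_gain=gain)
        post = np.sqrt(np.mean(rec.signal[:, 256 * 60 : 256 * 120] ** 2))
        assert post >= gain * pre

    def test_outside_interval_bit_identical(self, background):
        rec = nq.inject_seizure(background, 60.0, 30.0)
        i0, i1 = 256 * 60, 256 * 90
        assert np.array_equal(rec.signal[:, :i0], background.signal[:, :i0])
        assert np.array_equal(rec.signal[:, i1:], background.signal[:, i1:])

    def test_annotation_matches_interval_exactly(self, background):
        rec = nq.inject_seizure(background, 12.5, 30.0)
        (ann,) = rec.annotations_with_label("seizure")
        assert (ann.start_s, ann.end_s) == (12.5, 42.5)

    def test_out_of_range_rejected(self, background):
        with pytest.raises(ValueError, match="outside record"):
            nq.inject_seizure(background, 290.0, 30.0)

    def test_overlapping_injection_rejected(self, background):
        rec = nq.inject_seizure(background, 60.0, 30.0)
        with pytest.raises(ValueError, match="overlaps"):
            nq.inject_seizure(rec, 80.0, 30.0)

    def test_kernel_is_unit_rms_one_period(self):
        k = spike_wave_kernel(10.0, 256.0)
        assert k.size == 26  # ~100 ms at 256 Hz
        assert np.sqrt(np.mean(k**2)) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            spike_wave_kernel(50.0, 256.0)


class TestVEPTrials:
    def test_default_protocol_yields_100_trials(self):
        trials, _, stim = generate_vep_trials(seed=0)
        assert trials.shape[0] == 100
        assert stim.size == 100
        # 1 Hz flashes within trains, 10 s gaps between trains
        assert np.diff(stim)[:9] == pytest.approx(1.0)
        assert stim[10] - stim[9] == pytest.approx(11.0)

    def test_noiseless_trials_equal_template(self):
        params = VEPParams(noise_sd_uv=0.0)
        trials, times, _ = generate_vep_trials(params, seed=0)
        template = vep_template(params, times)
        assert np.allclose(trials, template[None, :])
        res = nq.analyze_vep(trials, times)
        grid_latency = times[np.argmax(template)] * 1000
        assert res.p100_latency_ms == pytest.approx(grid_latency)

    def test_average_latency_robust_at_unit_snr(self):
        """Monte-Carlo oracle: noise sd equal to the template amplitude still
        localizes the averaged P100 within +/-8 ms."""
        params = VEPParams(noise_sd_uv=10.0, p100_amplitude_uv=10.0)
        times = vep_time_axis(params)
        target = times[np.argmax(vep_template(params, times))] * 1000
        errors = []
        for rep in range(200):
            trials, times, _ = generate_vep_trials(params, seed=rep)
            errors.append(nq.analyze_vep(trials, times).p100_latency_ms - target)
        assert abs(np.mean(errors)) < 8.0
        assert np.percentile(np.abs(errors), 90) < 8.0


class TestProtocolSchedule:
    def test_normothermic_arms_constant(self):
        for group in (GROUP_NT, GROUP_H2):
            sched = nq.generate_protocol_schedule(group)
            t = np.linspace(0, 48, 97)
            assert np.allclose(sched.temperature_at(t), 38.5)

    def test_hypothermia_hold_value_at_hour_36(self):
        sched = nq.generate_protocol_schedule(GROUP_TH)
        assert sched.temperature_at(36.0) == pytest.approx(33.5)
        assert sched.temperature_at(1.0) == pytest.approx(33.5)

    def test_rewarming_terminates_at_normothermia(self):
        sched = nq.generate_protocol_schedule(GROUP_TH)
        assert 33.5 + 10 * 0.5 == pytest.approx(38.5)
        assert sched.temperature_at(48.0) == pytest.approx(38.5)
        # ramp slope is 0.5 degC/h
        assert sched.temperature_at(39.0) - sched.temperature_at(38.0) == pytest.approx(0.5)

    def test_cooling_within_50_minutes(self):
        sched = nq.generate_protocol_schedule(GROUP_TH)
        assert sched.temperature_at(50.0 / 60.0) == pytest.approx(33.5)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            nq.generate_protocol_schedule("A-XX")


class TestPathology:
    def _single_group_spec(self, p, n_animals=50):
        profile = dataclasses.replace(
            CohortSpec().profiles[GROUP_NT],
            pathology=PathologyParams(injury_probability={r: p for r in COUNT_REGIONS}),
        )
        return CohortSpec(
            n_per_group={GROUP_NT: n_animals, GROUP_H2: 0, GROUP_TH: 0},
            profiles={**CohortSpec().profiles, GROUP_NT: profile},
        )

    def test_zero_probability_no_damage(self):
        counts, _ = generate_pathology(self._single_group_spec(0.0), seed=0)
        assert (counts["damaged"] == 0).all()

    def test_unit_probability_full_damage(self):
        counts, _ = generate_pathology(self._single_group_spec(1.0), seed=0)
        assert (counts["damaged"] == counts["total"]).all()

    def test_binomial_mean_percent(self):
        counts, _ = generate_pathology(self._single_group_spec(0.9, n_animals=200), seed=1)
        sub = counts[counts["region"] == "thalamus"]
        assert len(sub) == 200
        assert (100 * sub["damaged"] / sub["total"]).mean() == pytest.approx(90.0, abs=1.0)

    def test_field_table_shape_and_levels(self, tiny_cohort_spec):
        _, fields = generate_pathology(tiny_cohort_spec, seed=0)
        per = fields.groupby(["animal", "region"]).size()
        assert (per == 40).all()
        assert set(fields["region"]) == set(NEOCORTEX_REGIONS)
        assert set(fields["severity"]) <= set(SEVERITY_LEVELS)


class TestSeizurePlanning:
    def test_th_arm_never_seizes(self):
        params = CohortSpec().profiles[GROUP_TH].seizure
        rng = np.random.default_rng(0)
        assert all(plan_seizures(params, rng) == [] for _ in range(50))

    def test_episodes_ordered_and_disjoint(self):
        params = CohortSpec().profiles[GROUP_NT].seizure
        rng = np.random.default_rng(3)
        for _ in range(200):
            eps = plan_seizures(params, rng)
            for (s1, d1), (s2, _) in zip(eps, eps[1:]):
                assert s2 >= s1 + d1
            assert all(s + d <= 48.0 for s, d in eps)

    def test_h2_onsets_stochastically_later_than_nt(self):
        spec = CohortSpec()
        rng = np.random.default_rng(9)
        onsets = {}
        for g in (GROUP_NT, GROUP_H2):
            draws = [plan_seizures(spec.profiles[g].seizure, rng) for _ in range(300)]
            onsets[g] = np.array([e[0][0] for e in draws if e])
        for q in (0.1, 0.25, 0.5, 0.75, 0.9):
            assert np.quantile(onsets[GROUP_H2], q) > np.quantile(onsets[GROUP_NT], q)

    def test_burden_mean_recovers_configured_value(self):
        params = SeizureParams(probability_any=1.0, onset_window_h=(24.0, 32.0), burden_mean_h=3.4)
        rng = np.random.default_rng(7)
        burdens = [sum(d for _, d in plan_seizures(params, rng)) for _ in range(3000)]
        assert np.mean(burdens) == pytest.approx(3.4, rel=0.05)


class TestCohort:
    def test_default_cohort_has_22_animals(self):
        spec = CohortSpec()
        assert spec.n_animals == 22
        assert [g for _, g in iter_animals(spec)].count(GROUP_NT) == 6

    def test_annotation_conservation(self, tiny_cohort_spec):
        cohort = nq.generate_cohort(tiny_cohort_spec)
        for animal in cohort.animals:
            anns = animal.eeg.annotations_with_label("seizure")
            total = sum(a.duration_s for a in anns)
            assert total == pytest.approx(sum(a.end_s - a.start_s for a in anns))
            if animal.group == GROUP_TH:
                assert not anns

    def test_deterministic_and_byte_identical_outputs(self, tiny_cohort_spec, tmp_path):
        c1 = nq.generate_cohort(tiny_cohort_spec)
        c2 = nq.generate_cohort(tiny_cohort_spec)
        for a1, a2 in zip(c1.animals, c2.animals):
            assert np.array_equal(a1.eeg.signal, a2.eeg.signal)
            assert np.array_equal(a1.vep_trials, a2.vep_trials)
        assert c1.pathology_counts.equals(c2.pathology_counts)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        cohort_io.write_cohort(c1, d1)
        cohort_io.write_cohort(c2, d2)
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()

    def test_cohort_roundtrip_through_files(self, tiny_cohort_spec, tmp_path):
        cohort = nq.generate_cohort(tiny_cohort_spec)
        cohort_io.write_cohort(cohort, tmp_path / "c")
        back = cohort_io.read_cohort(tmp_path / "c")
        assert [a.animal_id for a in back.animals] == [a.animal_id for a in cohort.animals]
        a0, b0 = cohort.animals[0], back.animals[0]
        step = np.abs(a0.eeg.signal).max() / 32767
        assert np.abs(b0.eeg.signal - a0.eeg.signal).max() <= step + 1e-9
        assert b0.eeg.time_compression == a0.eeg.time_compression
        assert np.allclose(b0.vep_trials, a0.vep_trials)
        assert back.pathology_counts.equals(cohort.pathology_counts)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            spec = CohortSpec()
            bad = dataclasses.replace(
                spec.profiles[GROUP_NT],
                seizure=SeizureParams(probability_any=1.5),
            )
            dataclasses.replace(spec, profiles={**spec.profiles, GROUP_NT: bad}).validate()
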