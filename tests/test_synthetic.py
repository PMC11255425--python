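import json

import numpy as np
import pytest

from fscv import (
    RecordingConfig,
    StimEvent,
    default_cohort_design,
    fit_pcr,
    generate_cohort,
    generate_recording,
    make_templates,
    make_training_set,
    predict_da,
    quantify_event,
    simulate_kinetics,
    synthesize_scan,
)
from fscv.synthetic import GroundTruth


class TestKineticsSimulator:
    def test_zero_pulses_gives_zero_trace(self):
        t, c = simulate_kinetics(None, 20.0, 1.0)
        assert np.all(c == 0.0)

    def test_single_pulse_is_closed_form_exponential(self):
        stim = StimEvent(onset_time=5.0, frequency=60.0, pulse_count=1)
        t, c = simulate_kinetics(stim, 100.0, 2.0)
        after = t > 5.0
        expected = 100.0 * np.exp(-(t[after] - 5.0) / 2.0)
        np.testing.assert_allclose(c[after], expected, rtol=1e-12)
        assert np.all(c[t <= 5.0] == 0.0)
        res = quantify_event(t, c, stim)
        assert res.tau == pytest.approx(2.0, rel=1e-3)

    def test_more_pulses_release_more(self):
        p30 = StimEvent(5.0, 60.0, 30)
        p60 = StimEvent(5.0, 60.0, 60)
        _, c30 = simulate_kinetics(p30, 20.0, 1.0)
        _, c60 = simulate_kinetics(p60, 20.0, 1.0)
        assert c60.max() >= c30.max()
        assert np.all(c30 >= 0) and np.all(c60 >= 0)

    def test_release_ladder_monotone_in_rate(self):
        stim = StimEvent(5.0, 60.0, 30)
        peaks = [simulate_kinetics(stim, rpp, 1.0)[1].max() for rpp in (5, 10, 20, 40)]
        assert np.all(np.diff(peaks) > 0)


class TestScanSynthesis:
    def test_no_analyte_is_pure_background(self, waveform, templates):
        scan = synthesize_scan(0.0, 0.0, waveform, templates)
        np.testing.assert_array_equal(scan, templates["background"])

    def test_dopamine_component_scales_linearly(self, waveform, templates):
        s1 = synthesize_scan(100.0, 0.0, waveform, templates) - templates["background"]
        s2 = synthesize_scan(200.0, 0.0, waveform, templates) - templates["background"]
        # atol covers cancellation against the ~300 nA background where the
        # dopamine template is vanishingly small
        np.testing.assert_allclose(s2, 2.0 * s1, rtol=1e-9, atol=1e-10)

    def test_template_waveform_mismatch_rejected(self, waveform, templates):
        bad = {k: v[:-1] for k, v in templates.items()}
        with pytest.raises(ValueError):
            synthesize_scan(0.0, 0.0, waveform, bad)

    def test_pcr_built_from_same_templates_recovers_concentration(
        self, waveform, templates
    ):
        """A synthetic scan pushed through fit_pcr/predict_da built from the
        same templates returns the injected dopamine within 1%."""
        sens = 10.0
        # raw (unfiltered) scan here, so train on unfiltered references too
        model = fit_pcr(make_training_set(waveform, templates, sens, lowpass=False))
        for da_nM in (100.0, 250.0, 800.0):
            scan = synthesize_scan(da_nM, 0.01, waveform, templates, sens)
            scan = scan - templates["background"]  # drift stage removes this
            da_nA = predict_da(model, scan).da[0]
            assert da_nA / sens * 1000.0 == pytest.approx(da_nM, rel=0.01)


class TestRecordingGenerator:
    def test_same_seed_writes_byte_identical_files(self, tmp_path):
        cfg = RecordingConfig(n_channels=2, duration_s=16.0)
        generate_recording(cfg, seed=21, out_dir=tmp_path / "a")
        generate_recording(cfg, seed=21, out_dir=tmp_path / "b")
        for rel in ["ch00/seg000.i16", "ch01/seg000.i16", "meta.json"]:
            assert (tmp_path / "a" / rel).read_bytes() == (
                tmp_path / "b" / rel
            ).read_bytes()

    def test_different_seed_differs(self, tmp_path):
        cfg = RecordingConfig(n_channels=1, duration_s=16.0)
        generate_recording(cfg, seed=1, out_dir=tmp_path / "a")
        generate_recording(cfg, seed=2, out_dir=tmp_path / "b")
        assert (tmp_path / "a" / "ch00/seg000.i16").read_bytes() != (
            tmp_path / "b" / "ch00/seg000.i16"
        ).read_bytes()

    def test_ground_truth_round_trips_through_json(self, tmp_path):
        cfg = RecordingConfig(n_channels=3, duration_s=16.0, dead_channels=(1,))
        _, truth = generate_recording(cfg, seed=5, out_dir=tmp_path)
        back = GroundTruth.from_json(tmp_path / "truth.json")
        np.testing.assert_allclose(back.conc_nM, truth.conc_nM)
        np.testing.assert_allclose(
            back.sensitivities_nA_per_uM, truth.sensitivities_nA_per_uM
        )
        assert back.dead_channels == (1,)

    def test_cross_channel_cv_matches_target(self):
        """Log-normal sensitivity dispersion reproduces the target ≈0.27
        cross-fiber coefficient of variation of apparent stimulated release."""
        cfg = RecordingConfig(duration_s=16.0, noise_sd_nA=0.0,
                              drift_rw_frac_per_scan=0.0)
        cvs = []
        for seed in range(50):
            _, truth = generate_recording(cfg, seed=seed)
            vals = truth.per_channel_es_da_nM
            cvs.append(np.std(vals, ddof=1) / np.mean(vals))
        assert np.mean(cvs) == pytest.approx(0.27, abs=0.05)

    def test_dead_channels_have_no_sensitivity(self):
        cfg = RecordingConfig(n_channels=4, duration_s=16.0, dead_channels=(2,))
        _, truth = generate_recording(cfg, seed=3)
        assert truth.sensitivities_nA_per_uM[2] == 0.0
        assert truth.per_channel_es_da_nM[2] == 0.0


class TestCohortGenerator:
    def test_null_slope_gives_constant_true_means(self):
        design = default_cohort_design(sensitization_slope=0.0, n_animals=2)
        _, truth = generate_cohort(design, seed=1)
        means = truth["cell_means_nM"]
        for g in design.groups:
            for p in design.param_multipliers:
                weekly = [means[f"{g}|week{w}|{p}"] for w in range(1, 5)]
                assert len(set(weekly)) == 1

    def test_positive_slope_orders_weeks(self):
        design = default_cohort_design(sensitization_slope=0.25, n_animals=2)
        table, truth = generate_cohort(design, seed=2)
        m = truth["cell_means_nM"]
        assert m["CAST_male|week1|60Hz30p"] < m["CAST_male|week4|60Hz30p"]
        obs = table[table.group == "CAST_male"].groupby("week")["es_da_nM"].mean()
        assert obs[1] < obs[4]

    def test_missingness_rate_approximate(self):
        design = default_cohort_design(n_animals=5, missing_rate=0.2)
        table, _ = generate_cohort(design, seed=3)
        full = 2 * 5 * 16 * 4 * 2  # groups x animals x fibers x weeks x params
        frac = 1.0 - len(table) / full
        assert frac == pytest.approx(0.2, abs=0.03)

    def test_fiber_multiplier_is_stable_across_weeks(self):
        """The repeated-measures structure: a fiber's relative level persists
        over weeks (strong week-to-week correlation within fibers)."""
        design = default_cohort_design(n_animals=3)
        table, _ = generate_cohort(design, seed=4)
        sub = table[(table.group == "CAST_male") & (table.param == "60Hz30p")]
        wide = sub.pivot_table(index="fiber", columns="week", values="es_da_nM")
        corr = np.corrcoef(wide[1], wide[4])[0, 1]
        assert corr > 0.8
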