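import numpy as np
import pandas as pd
import pytest
from scipy.signal import periodogram

import nirsdetect as nd
from nirsdetect.exceptions import ConfigurationError
from nirsdetect.synthgen import (PHYS_GRID_MIN, THC, nback_boxcar,
                                 simulate_physiology_and_raters)


def tiny_config(**kw):
    base = dict(n_participants=10, scan_minutes=1, sample_rate=5,
                scan_missing_rate=0.0, seed=1)
    base.update(kw)
    return nd.CohortConfig(**base)


def _latent(impaired, tolerance=0.0, arm=THC):
    return nd.LatentState(participant="P001", arm=arm,
                          impaired={"postdose1": impaired, "postdose2": False},
                          tolerance=tolerance, dose_mg=35.0)


class TestDeterminismAndStructure:
    def test_same_seed_reproduces_cohort_exactly(self):
        a = nd.generate_cohort(tiny_config())
        b = nd.generate_cohort(tiny_config())
        assert len(a.scans) == len(b.scans)
        for sa, sb in zip(a.scans, b.scans):
            assert np.array_equal(sa.intensity, sb.intensity)
        pd.testing.assert_frame_equal(a.physiology, b.physiology)
        pd.testing.assert_frame_equal(a.raters, b.raters)

    def test_different_seed_changes_cohort(self):
        a = nd.generate_cohort(tiny_config())
        b = nd.generate_cohort(tiny_config(seed=2))
        assert not np.array_equal(a.scans[0].intensity, b.scans[0].intensity)

    def test_placebo_sessions_never_impaired(self):
        cohort = nd.generate_cohort(tiny_config(n_participants=20),
                                    include_signals=False)
        for lat in cohort.latents:
            if lat.arm != THC:
                assert not any(lat.impaired.values())

    def test_scan_schedule_complete_without_attrition(self):
        cfg = tiny_config(n_participants=12)
        cohort = nd.generate_cohort(cfg, include_signals=False)
        per = pd.DataFrame([(s.participant, s.arm, s.timepoint)
                            for s in cohort.scans],
                           columns=["participant", "arm", "timepoint"])
        counts = per.groupby(["participant", "arm"]).size()
        assert (counts == len(cfg.scan_timepoints)).all()

    @pytest.mark.parametrize("field,value", [
        ("impairment_prevalence_target", 1.4),
        ("rater_sensitivity", -0.1),
        ("sample_rate", 0.0),
        ("n_participants", 4),
    ])
    def test_invalid_config_names_field(self, field, value):
        cfg = tiny_config(**{field: value})
        with pytest.raises(ConfigurationError, match=field):
            cfg.validate()

    def test_noninteger_sample_count_rejected(self):
        cfg = tiny_config(sample_rate=0.33, scan_minutes=1)
        with pytest.raises(ConfigurationError, match="sample"):
            cfg.validate()


class TestClassStructure:
    def test_study_scale_class_ratio(self, structural_cohort):
        """At study scale the labeled impaired:nonimpaired scan ratio sits
        within 20% (relative) of 111:782; averaged over seeds to test the
        generator's central class balance rather than one draw."""
        ratios, totals = [], []
        for cohort in (structural_cohort,
                       nd.generate_cohort(nd.CohortConfig(seed=7),
                                          include_signals=False),
                       nd.generate_cohort(nd.CohortConfig(seed=77),
                                          include_signals=False)):
            labels = nd.label_cohort(cohort)
            meta = pd.DataFrame([(s.participant, s.arm, s.timepoint)
                                 for s in cohort.scans],
                                columns=["participant", "arm", "timepoint"])
            meta = nd.training_class_assignment(labels, meta)
            n_imp = int(meta["impaired_class"].sum())
            ratios.append(n_imp / (len(meta) - n_imp))
            totals.append(len(meta))
        target = 111 / 782
        assert abs(np.mean(ratios) - target) / target < 0.20
        # ~893 scheduled-minus-attrition resting scans per cohort
        assert all(750 <= t <= 1030 for t in totals)

    def test_latent_prevalence_tracks_target(self, structural_cohort):
        truth = structural_cohort.truth()
        post_thc = truth[truth["arm"] == THC]
        frac = post_thc["impaired"].mean()
        target = structural_cohort.config.impairment_prevalence_target
        assert abs(frac - target) / target < 0.20

    def test_inconsistent_impairment_subset_exists(self, structural_cohort):
        truth = structural_cohort.truth()
        per = truth[truth["arm"] == THC].groupby("participant")["impaired"].sum()
        assert (per == 1).sum() > 0 and (per == 2).sum() > 0


class TestHemodynamics:
    def test_nback_boxcar_has_12_alternating_blocks(self):
        box = nback_boxcar(3600, 10.0)
        transitions = np.flatnonzero(np.diff(box) != 0)
        assert len(transitions) == 11  # 12 blocks
        assert box[:300].sum() == 0 and box[300:600].sum() == 300  # 0-back first

    def test_effect_size_zero_removes_impairment_signature(self):
        cfg = tiny_config(effect_size=0.0)
        for scan_type in ("resting", "nback"):
            a = nd.simulate_hemodynamics(_latent(True), "postdose1", scan_type,
                                         cfg, np.random.default_rng(3))
            b = nd.simulate_hemodynamics(_latent(False), "postdose1", scan_type,
                                         cfg, np.random.default_rng(3))
            assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_impaired_resting_band_variance_elevated(self):
        """Monte-Carlo: the 0.02-0.08 Hz HbO band carries more power when
        impaired (effect_size=2), measured by direct periodogram."""
        cfg = tiny_config(scan_minutes=3, sample_rate=5, effect_size=2.0,
                          n_channels=4)
        powers = {True: [], False: []}
        for seed in range(100):
            for imp in (True, False):
                hbo, _ = nd.simulate_hemodynamics(
                    _latent(imp), "postdose1", "resting", cfg,
                    np.random.default_rng(seed))
                f, p = periodogram(hbo, fs=cfg.sample_rate, axis=0)
                band = (f >= 0.02) & (f <= 0.08)
                powers[imp].append(p[band].mean())
        assert np.mean(powers[True]) > 1.3 * np.mean(powers[False])

    def test_nback_amplitude_scales_with_impairment(self):
        cfg = tiny_config(scan_minutes=2, effect_size=2.0, n_channels=4)
        a, _ = nd.simulate_hemodynamics(_latent(True, tolerance=0.0),
                                        "postdose1", "nback", cfg,
                                        np.random.default_rng(5))
        b, _ = nd.simulate_hemodynamics(_latent(False), "postdose1", "nback",
                                        cfg, np.random.default_rng(5))
        # identical noise realization, tripled task amplitude when impaired
        assert np.abs(a - b).max() > cfg.task_amplitude_um


class TestForwardModel:
    def test_zero_concentration_gives_constant_baseline(self):
        cfg = tiny_config()
        n = cfg.n_samples
        zeros = np.zeros((n, cfg.n_channels))
        baseline = np.full(2 * cfg.n_channels, 500.0)
        intensity, meta = nd.hb_to_intensity(zeros, zeros, cfg,
                                             np.random.default_rng(0),
                                             artifacts=False, noise=False,
                                             baseline=baseline)
        assert np.allclose(intensity, 500.0)

    def test_round_trip_recovers_concentrations(self):
        """Forward MBLL + exponentiation, inverted by the preprocessing
        module with a known baseline, reproduces the input to 1e-9 µM."""
        cfg = tiny_config()
        rng = np.random.default_rng(7)
        hbo, hbr = nd.simulate_hemodynamics(_latent(True), "postdose1",
                                            "resting", cfg, rng)
        baseline = np.full(2 * cfg.n_channels, 1000.0)
        intensity, _ = nd.hb_to_intensity(hbo, hbr, cfg, rng, artifacts=False,
                                          noise=False, baseline=baseline)
        od = nd.to_optical_density(intensity, cfg.sample_rate,
                                   nd.synthgen.intensity_columns(
                                       cfg.n_channels, cfg.wavelengths),
                                   nd.default_montage(cfg.n_channels),
                                   reference=baseline)
        hemo = nd.convert_to_hemoglobin(od, extinction=cfg.extinction,
                                        dpf=cfg.dpf)
        assert np.abs(hemo.hbo - hbo).max() < 1e-9
        assert np.abs(hemo.hbr - hbr).max() < 1e-9

    def test_artifact_probability_one_injects_spikes(self):
        cfg = tiny_config(artifact_spike_prob=1.0)
        cohort = nd.generate_cohort(cfg)
        assert all(len(s.meta["spikes"]) >= 1 for s in cohort.scans)


class TestPhysiologyAndRaters:
    def test_fst_operating_point_matches_configuration(self):
        """Over 2000 THC sessions the empirical FST recall and false-positive
        rate land on the configured 0.84 / 0.34 within binomial error."""
        cfg = tiny_config()
        rng = np.random.default_rng(9)
        outcomes = []
        for i in range(2000):
            state = _latent(i % 2 == 0)
            _, _, fst = simulate_physiology_and_raters(state, cfg, rng)
            outcomes.append(fst)
        df = pd.DataFrame(outcomes)
        recall = df[df.session_impaired].fst_positive.mean()
        fpr = df[~df.session_impaired].fst_positive.mean()
        assert abs(recall - 0.84) < 0.04
        assert abs(fpr - 0.34) < 0.05
        # ordinal score consistent with the binary call
        assert ((df.fst_score >= 2) == df.fst_positive).all()

    def test_perfect_raters_reproduce_latent_state(self):
        cfg = tiny_config(rater_sensitivity=1.0, rater_specificity=1.0,
                          n_participants=20)
        cohort = nd.generate_cohort(cfg, include_signals=False)
        truth = cohort.truth().set_index(["participant", "arm", "timepoint"])
        for _, r in cohort.raters.iterrows():
            t = bool(truth.loc[(r.participant, r.arm, r.timepoint), "impaired"])
            assert r.rater_a == t and r.rater_b == t

    def test_placebo_heart_rate_change_is_null(self):
        cfg = tiny_config()
        rng = np.random.default_rng(1)
        deltas = []
        for _ in range(300):
            state = _latent(False, arm="placebo")
            phys, _, _ = simulate_physiology_and_raters(state, cfg, rng)
            hr = phys["hr_bpm"].to_numpy()
            base = hr[PHYS_GRID_MIN <= 0].mean()
            deltas.append(hr[PHYS_GRID_MIN > 0].mean() - base)
        assert abs(np.mean(deltas)) < 0.5

    def test_impaired_sessions_show_elevated_hr_and_deq(self):
        cfg = tiny_config()
        rng = np.random.default_rng(2)
        imp_hr, non_hr = [], []
        for i in range(200):
            state = _latent(i % 2 == 0)
            phys, _, _ = simulate_physiology_and_raters(state, cfg, rng)
            hr = phys["hr_bpm"].to_numpy()
            win = np.abs(PHYS_GRID_MIN - 100) <= 20
            d = hr[win].mean() - hr[PHYS_GRID_MIN <= 0].mean()
            (imp_hr if state.impaired["postdose1"] else non_hr).append(d)
        assert np.mean(imp_hr) > np.mean(non_hr) + 8.0
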