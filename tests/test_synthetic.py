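"""Synthetic cohort generator: determinism, prevalence control, POMS logic,
waveform round-trips through the signal-processing oracles."""

import numpy as np
import pytest

from mosr.cpet import detect_at_vslope, vo2_peak
from mosr.synthetic import (Cohort, GeneratorConfig, POMSAssessment,
                            generate_cohort, generate_cpet_waveforms,
                            generate_poms, poms_class_probability)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"prevalence_target": 0.0}, {"prevalence_target": 1.0},
        {"ts_fraction": 1.5}, {"n_patients": 0},
        {"crf_effect": float("nan")}, {"noise_sd": 0.0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GeneratorConfig(**kwargs)


class TestDeterminism:
    def test_identical_seed_bitwise_identical_tables(self):
        cfg = GeneratorConfig(n_patients=150, seed=7)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        assert a.table.to_csv() == b.table.to_csv()
        assert a.latent.to_csv() == b.latent.to_csv()

    def test_waveforms_deterministic(self):
        cfg = GeneratorConfig(n_patients=40, seed=3, ts_fraction=0.5,
                              waveform_noise_sd=0.05)
        a = generate_cohort(cfg).waveforms()
        b = generate_cohort(cfg).waveforms()
        pid = next(iter(a))
        assert np.array_equal(a[pid].channels["vo2"], b[pid].channels["vo2"])


class TestPrevalenceControl:
    def test_null_model_prevalence_and_independence(self):
        cfg = GeneratorConfig(n_patients=2000, seed=1, crf_effect=0.0,
                              clinical_effect=0.0)
        cohort = generate_cohort(cfg)
        prev = cohort.outcome.mean()
        se = np.sqrt(cfg.prevalence_target * (1 - cfg.prevalence_target) / 2000)
        assert abs(prev - cfg.prevalence_target) <= 3 * se
        r = np.corrcoef(cohort.table["vo2_kg_at"], cohort.outcome)[0, 1]
        assert abs(r) < 0.1

    def test_mean_prevalence_over_seeds(self):
        # over many seeds the empirical prevalence is tightly controlled
        prevs = [generate_cohort(
            GeneratorConfig(n_patients=2000, seed=s)).outcome.mean()
            for s in range(20)]
        assert abs(np.mean(prevs) - 633 / 1190) <= 0.02


class TestCorrelationEmulation:
    def test_at_feature_tracks_poms_count(self):
        cfg = GeneratorConfig(seed=0)  # n=1190, corr target 0.69
        cohort = generate_cohort(cfg)
        r = np.corrcoef(cohort.table["vo2_kg_at"],
                        cohort.table["poms_count_d3"])[0, 1]
        assert 0.59 <= abs(r) <= 0.79
        assert r < 0  # fitter patients accumulate fewer morbidity domains

    def test_late_day_counts_track_day3(self):
        cohort = generate_cohort(GeneratorConfig(n_patients=1000, seed=2))
        r35 = np.corrcoef(cohort.table["poms_count_d3"],
                          cohort.table["poms_count_d5"])[0, 1]
        r37 = np.corrcoef(cohort.table["poms_count_d3"],
                          cohort.table["poms_count_d7"])[0, 1]
        assert r35 > 0.3 and r37 > 0.3


class TestMonotoneRisk:
    def test_class_probability_increases_with_latent_risk(self):
        etas = np.linspace(-6, 6, 200)
        probs = poms_class_probability(etas, intercept=-1.0)
        assert (np.diff(probs) > 0).all()

    def test_higher_fitness_never_raises_risk(self):
        # under the generator's model, risk is monotone decreasing in the
        # fitness latent that drives the AT feature
        cfg = GeneratorConfig()
        z = np.linspace(-3, 3, 100)
        eta = -cfg.crf_effect * z
        probs = poms_class_probability(eta, intercept=-1.0)
        assert (np.diff(probs) <= 0).all()
        interior = probs[(probs > 1e-9) & (probs < 1 - 1e-9)]
        assert (np.diff(interior) < 0).all()


class TestPOMS:
    def test_extreme_negative_risk_gives_class_zero(self, rng):
        poms = generate_poms(-50.0, 3, rng)
        assert poms.positive_count == 0 and poms.morbidity_class == 0

    def test_two_positive_domains_is_morbid(self):
        flags = [True, True] + [False] * 7
        poms = POMSAssessment(day=3, domain_positive=tuple(flags))
        assert poms.positive_count == 2 and poms.morbidity_class == 1

    def test_single_positive_domain_is_not_morbid(self):
        flags = [True] + [False] * 8
        poms = POMSAssessment(day=3, domain_positive=tuple(flags))
        assert poms.morbidity_class == 0

    def test_excluded_routine_care_domain_not_counted(self):
        flags = [True] + [False] * 8
        poms = POMSAssessment(day=3, domain_positive=tuple(flags),
                              excluded_domains=(0,))
        assert poms.positive_count == 0 and poms.morbidity_class == 0

    def test_class_threshold_is_deterministic_in_count(self, rng):
        for _ in range(50):
            flags = tuple(bool(b) for b in rng.integers(0, 2, size=9))
            poms = POMSAssessment(day=5, domain_positive=flags)
            assert poms.morbidity_class == int(sum(flags) >= 2)

    def test_invalid_day_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_poms(0.0, 4, rng)

    def test_domain_probabilities_monotone_in_risk(self, rng):
        low = np.mean([generate_poms(-2.0, 3, rng).positive_count
                       for _ in range(300)])
        high = np.mean([generate_poms(2.0, 3, rng).positive_count
                        for _ in range(300)])
        assert high > low


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(GeneratorConfig(n_patients=60, seed=5,
                                           ts_fraction=0.5))


class TestWaveforms:
    def test_channel_count_is_fifteen(self, cohort):
        series = cohort.waveforms([cohort.ts_patients[0]]).popitem()[1]
        assert len(series.channels) == 15

    def test_noiseless_at_round_trip(self, cohort):
        for pid in cohort.ts_patients[:10]:
            s = cohort.waveforms([pid])[pid]
            marks = s.phase_marks
            res = detect_at_vslope(s.channels["vo2"], s.channels["vco2"],
                                   (marks["ramp_start"], marks["peak"]))
            assert res is not None and res.index == marks["at"]

    def test_noiseless_peak_round_trip(self, cohort):
        for pid in cohort.ts_patients[:10]:
            s = cohort.waveforms([pid])[pid]
            planted = cohort.latent.loc[pid, "vo2_kg_peak"]
            got = vo2_peak(s.channels["vo2_kg"], s.phase_marks["peak"])
            assert got == pytest.approx(planted, rel=1e-9)

    def test_planted_reference_peak_value(self):
        # a patient planted at the population-median peak of 16.9 ml/kg/min
        import pandas as pd
        row = pd.Series({"vo2_kg_at": 10.6, "vo2_kg_peak": 16.9,
                         "vo2_kg_rest": 3.8, "body_mass_kg": 75.0},
                        name="P0000")
        s = generate_cpet_waveforms(row, np.random.default_rng(0))
        assert vo2_peak(s.channels["vo2_kg"], s.phase_marks["peak"]) == \
            pytest.approx(16.9, abs=1e-9)

    def test_nonpositive_targets_rejected(self, rng):
        import pandas as pd
        row = pd.Series({"vo2_kg_at": -1.0, "vo2_kg_peak": 16.9})
        with pytest.raises(ValueError):
            generate_cpet_waveforms(row, rng)

    def test_vslope_geometry(self, cohort):
        # the V̇CO₂-vs-V̇O₂ slope steepens after the planted threshold
        pid = cohort.ts_patients[0]
        s = cohort.waveforms([pid])[pid]
        k = s.phase_marks["at"]
        lo = s.phase_marks["ramp_start"]
        hi = s.phase_marks["peak"]
        vo2, vco2 = s.channels["vo2"], s.channels["vco2"]
        below = np.polyfit(vo2[lo:k], vco2[lo:k], 1)[0]
        above = np.polyfit(vo2[k:hi], vco2[k:hi], 1)[0]
        assert above > below


class TestMarkFreeExtraction:
    def test_crf_features_recovered_without_phase_annotations(self, cohort):
        # writing + re-reading the long CSV drops the phase marks; ramp
        # bounds must then be inferred from the ergometer load channel
        from mosr.cpet import (extract_crf_features, read_long_waveforms,
                               write_long_waveforms)
        pid = cohort.ts_patients[0]
        waves = cohort.waveforms([pid])
        import io
        buf = io.StringIO()
        write_long_waveforms(waves, buf)
        buf.seek(0)
        back = read_long_waveforms(buf)[pid]
        feats = extract_crf_features(back)
        annotated = extract_crf_features(waves[pid])
        assert feats.values["vo2_kg_peak"] == pytest.approx(
            annotated.values["vo2_kg_peak"], rel=0.02)
        assert feats.values["vo2_kg_at"] <= feats.values["vo2_kg_peak"]


class TestCohortStructure:
    def test_feature_counts_follow_config(self, small_cohort):
        groups = small_cohort.feature_groups
        assert sum(g == "clinical" for g in groups.values()) == 39
        assert sum(g == "crf" for g in groups.values()) == 46
        assert len(small_cohort.table) == 300

    def test_outcome_defined_and_binary(self, small_cohort):
        y = small_cohort.outcome
        assert set(np.unique(y)) <= {0, 1}
        assert len(y) == len(small_cohort.table)

    def test_no_duplicate_feature_names(self, small_cohort):
        names = small_cohort.feature_names
        assert len(names) == len(set(names))

    def test_write_round_trip(self, small_cohort, tmp_path):
        import json
        import pandas as pd
        small_cohort.write(tmp_path)
        back = pd.read_csv(tmp_path / "cohort.csv", index_col=0)
        assert back.shape == small_cohort.table.shape
        sidecar = json.loads((tmp_path / "feature_groups.json").read_text())
        assert sidecar["outcome_column"] == "poms_class_d3"
        assert sidecar["feature_groups"]["vo2_kg_at"] == "crf"
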