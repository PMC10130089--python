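import numpy as np
import pytest
from scipy import stats

from sibamod import SimConfig, generate_cohort, simulate_severity
from sibamod.cohort_io import DEFAULT_GROUP_SIZES
from sibamod.synthetic_data import emit_features, emit_visits, write_synthetic_cohort


def noise_free_config(**over):
    base = dict(
        n_patients=1,
        severity_noise_sd=0.0,
        relapse_prob=0.0,
        missing_rate=0.0,
        visit_noise=0,
        baseline_madrs_range=(30.0, 30.0),
    )
    base.update(over)
    return SimConfig(**base)


class TestSeverity:
    def test_pure_decay_matches_repeated_multiplication(self):
        s, relapse = simulate_severity(noise_free_config(), patient_seed=1)
        assert relapse is None
        expected = 30.0
        for _ in range(30):
            expected *= 0.984
        assert s[0] == 30.0
        assert s[30] == pytest.approx(expected, abs=1e-9)

    def test_zero_rate_gives_constant_severity(self):
        s, _ = simulate_severity(noise_free_config(lam_true=0.0), patient_seed=1)
        np.testing.assert_allclose(s, 30.0)

    def test_same_seed_reproduces_trajectory(self):
        cfg = SimConfig(n_patients=1, seed=5)
        a, _ = simulate_severity(cfg, patient_seed=9)
        b, _ = simulate_severity(cfg, patient_seed=9)
        np.testing.assert_array_equal(a, b)

    def test_relapse_raises_severity_after_onset(self):
        cfg = noise_free_config()
        s, day = simulate_severity(cfg, patient_seed=3, relapse=True, sustained=False, relapse_day=80)
        base, _ = simulate_severity(cfg, patient_seed=3, relapse=False)
        assert day == 80
        assert s[95] > base[95] + 10

    def test_values_stay_in_madrs_range(self):
        cfg = SimConfig(n_patients=1, severity_noise_sd=8.0)
        s, _ = simulate_severity(cfg, patient_seed=2)
        assert (s >= 0).all() and (s <= 60).all()


class TestFeatures:
    def test_complete_matrix_without_missingness(self):
        cfg = noise_free_config()
        s, _ = simulate_severity(cfg, 1)
        feats, links = emit_features(s, cfg, 1, ["hrv_00", "sleep_02"])
        assert feats.shape == (cfg.n_days, 101)
        assert not feats.isna().any().any()
        assert set(links) == {"hrv_00", "sleep_02"}

    def test_missing_gaps_blank_whole_days(self):
        cfg = noise_free_config(missing_rate=0.3)
        s, _ = simulate_severity(cfg, 1)
        feats, _ = emit_features(s, cfg, 1, ["hrv_00"])
        gap_days = feats.isna().all(axis=1)
        assert gap_days.any()
        # a day is either fully present or fully absent
        assert (feats.isna().any(axis=1) == gap_days).all()

    def test_noiseless_level_feature_tracks_severity_monotonically(self):
        cfg = noise_free_config(feature_noise_sd=0.0, severity_noise_sd=0.5, trend_fraction=0.0)
        s, _ = simulate_severity(cfg, 1)
        feats, links = emit_features(s, cfg, 1, ["hrv_00", "hrv_01"])
        for name, link in links.items():
            kind = link.split(":")[1]
            if kind in ("identity", "negation"):
                rho = stats.spearmanr(feats[name], s).statistic
                assert abs(rho) == pytest.approx(1.0, abs=1e-12)


class TestVisits:
    def test_noise_free_visits_round_severity(self):
        cfg = noise_free_config()
        s, _ = simulate_severity(cfg, 1)
        visits, adjusted = emit_visits(s, cfg, 1)
        assert len(visits) == 7
        assert not adjusted
        for v in visits:
            assert v.madrs == int(round(s[v.day]))

    def test_final_visit_clipped_into_study(self):
        cfg = noise_free_config()
        s, _ = simulate_severity(cfg, 1)
        visits, _ = emit_visits(s, cfg, 1)
        assert visits[-1].day == cfg.n_days - 1

    def test_baseline_forced_to_inclusion_threshold(self):
        cfg = noise_free_config(baseline_madrs_range=(18.0, 18.0), lam_true=0.0)
        s, _ = simulate_severity(cfg, 1)
        visits, adjusted = emit_visits(s, cfg, 1)
        assert visits[0].madrs == 20 and adjusted


class TestCohort:
    def test_record_and_truth_counts(self):
        cfg = SimConfig(n_patients=5, seed=0)
        recs, truths = generate_cohort(cfg)
        assert len(recs) == 5 and len(truths) == 5
        for r, t in zip(recs, truths):
            assert len(t.planted_ids) == cfg.signature_size_true
            assert set(t.planted_ids) <= set(r.feature_names)
            assert sum(DEFAULT_GROUP_SIZES.values()) == r.features.shape[1] == 101

    def test_same_seed_reproduces_cohort_files_byte_for_byte(self, tmp_path):
        cfg = SimConfig(n_patients=2, seed=7)
        write_synthetic_cohort(cfg, tmp_path / "a")
        write_synthetic_cohort(cfg, tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_shared_core_yields_intermediate_apparition_counts(self):
        cfg = SimConfig(n_patients=12, seed=1, shared_core_fraction=0.5)
        _, truths = generate_cohort(cfg)
        counts = {}
        for t in truths:
            for f in t.planted_ids:
                counts[f] = counts.get(f, 0) + 1
        assert max(counts.values()) > 1  # core features shared
        assert max(counts.values()) < 12  # but not universal

    def test_planted_features_dominate_decoys_in_population_dependence(self):
        from sibamod.signature import hsic

        margin_ok = 0
        for seed in range(5):
            cfg = SimConfig(n_patients=1, seed=200 + seed)
            recs, truths = generate_cohort(cfg)
            r, t = recs[0], truths[0]
            feats = r.features.ffill().bfill()
            s = t.severity
            planted = [hsic(feats[f].to_numpy(), s) for f in t.planted_ids[:4]]
            decoys = [f for f in r.feature_names if f not in t.planted_ids][:20]
            decoy_scores = [hsic(feats[f].to_numpy(), s) for f in decoys]
            if np.median(planted) > np.quantile(decoy_scores, 0.95):
                margin_ok += 1
        assert margin_ok >= 4
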