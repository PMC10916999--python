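"""Synthetic cohort generator: determinism, degenerate limits, and moment calibration."""

import math
from dataclasses import replace

import numpy as np
import pytest

from tapcog.cohort_filter import apply_exclusions
from tapcog.keystroke_io import Hand, TestType, segment_protocol
from tapcog.motor_features import build_feature_table
from tapcog.synthetic_cohort import (
    ExclusionInjection,
    SimConfig,
    OutcomeModel,
    _default_outcomes,
    _participant_rng,
    simulate_cohort,
    simulate_demographics,
)

NO_FLAGS = ExclusionInjection(0, 0, 0, 0)


class TestDeterminism:
    def test_same_seed_same_cohort(self, small_synthetic_cohort):
        cfg, cohort = small_synthetic_cohort
        again = simulate_cohort(cfg)
        f1, f2 = build_feature_table(cohort), build_feature_table(again)
        assert f1.equals(f2)
        for p1, p2 in zip(cohort.participants, again.participants):
            assert (p1.paltea6, p1.swmbe6, p1.swms) == (p2.paltea6, p2.swmbe6, p2.swms)
            assert p1.memory_change == p2.memory_change

    def test_different_seed_differs(self):
        c1 = simulate_cohort(SimConfig(n_participants=10, seed=1, exclusions=NO_FLAGS))
        c2 = simulate_cohort(SimConfig(n_participants=10, seed=2, exclusions=NO_FLAGS))
        f1, f2 = build_feature_table(c1), build_feature_table(c2)
        assert not f1.equals(f2)

    def test_growing_n_preserves_earlier_participants(self):
        small = simulate_cohort(SimConfig(n_participants=25, seed=9, exclusions=NO_FLAGS))
        large = simulate_cohort(SimConfig(n_participants=50, seed=9, exclusions=NO_FLAGS))
        f_small = build_feature_table(small)
        f_large = build_feature_table(large)
        assert f_large.iloc[:25].equals(f_small)


class TestProtocolValidity:
    def test_generated_blocks_form_complete_protocols(self, small_synthetic_cohort):
        cfg, cohort = small_synthetic_cohort
        n_incomplete = sum(
            not segment_protocol(p.blocks).complete for p in cohort.participants
        )
        assert n_incomplete == cfg.exclusions.n_incomplete

    def test_events_respect_block_bounds_and_order(self, small_synthetic_cohort):
        _, cohort = small_synthetic_cohort
        for p in cohort.participants[:10]:
            for b in p.blocks:
                downs = [e.down_ms for e in b.events]
                assert downs == sorted(downs)
                assert all(e.up_ms > e.down_ms for e in b.events)
                assert all(e.up_ms <= b.duration_s * 1000 for e in b.events)


class TestDegenerateLimits:
    def test_zero_log_interval_sd_gives_exactly_zero_variability(self):
        cfg = SimConfig(
            n_participants=5,
            seed=3,
            exclusions=NO_FLAGS,
            tapping=replace(
                SimConfig().tapping,
                log_interval_sd_single=0.0,
                log_interval_sd_alternate=0.0,
                rhythm_sd_log=0.0,
            ),
        )
        table = build_feature_table(simulate_cohort(cfg))
        var_cols = [c for c in table.columns if "_var_" in c]
        assert (table[var_cols] == 0.0).all().all()

    def test_zero_wrong_key_probability_gives_exact_perfect_accuracy(self):
        cfg = SimConfig(
            n_participants=5,
            seed=3,
            exclusions=NO_FLAGS,
            tapping=replace(
                SimConfig().tapping,
                p_adjacent_single=0.0,
                p_other_single=0.0,
                p_adjacent_alternate=0.0,
                p_other_alternate=0.0,
            ),
        )
        table = build_feature_table(simulate_cohort(cfg))
        acc_cols = [c for c in table.columns if "_acc_" in c]
        assert (table[acc_cols] == 1.0).all().all()


class TestDemographics:
    def test_moments_match_targets(self):
        cfg = SimConfig(n_participants=85)
        n = 3000
        rows = [
            simulate_demographics(cfg, _participant_rng(123, i)) for i in range(n)
        ]
        ages = np.array([r["age_years"] for r in rows])
        d = cfg.demographics
        assert abs(ages.mean() - d.age_mean) < 3 * ages.std() / math.sqrt(n)
        assert ages.min() >= d.age_min and ages.max() <= d.age_max
        p_f = np.mean([r["sex"] == "female" for r in rows])
        se = math.sqrt(d.p_female * (1 - d.p_female) / n)
        assert abs(p_f - d.p_female) < 3 * se
        anx = np.array([r["hads_anxiety"] for r in rows])
        assert 0 <= anx.min() and anx.max() <= 21
        assert abs(anx.mean() - d.hads_anxiety_mean) < 0.35

    def test_education_levels_all_represented(self):
        rows = [
            simulate_demographics(SimConfig(n_participants=85), _participant_rng(5, i))
            for i in range(800)
        ]
        levels = {r["education_level"] for r in rows}
        assert len(levels) == 6


class TestOutcomeLink:
    def test_negative_frequency_coefficient_lowers_error_counts(self):
        """Injected IRR < 1 on tapping frequency: faster tappers make fewer errors."""
        cohort = simulate_cohort(
            SimConfig(n_participants=400, seed=8, exclusions=NO_FLAGS)
        )
        table = build_feature_table(cohort, columns=["ak_freq_d"])
        pal = np.array([p.paltea6 for p in cohort.participants], dtype=float)
        freq = table["ak_freq_d"].to_numpy()
        fast = pal[freq > np.median(freq)].mean()
        slow = pal[freq <= np.median(freq)].mean()
        assert fast < slow

    def test_zero_slopes_break_the_link(self):
        outcomes = _default_outcomes()
        pal = outcomes["paltea6"]
        outcomes["paltea6"] = OutcomeModel(
            family=pal.family, mean_count=pal.mean_count, theta=pal.theta, cap=pal.cap,
            coef={},
        )
        cohort = simulate_cohort(
            SimConfig(n_participants=600, seed=8, exclusions=NO_FLAGS, outcomes=outcomes)
        )
        table = build_feature_table(cohort, columns=["ak_freq_d"])
        pal_counts = np.array([p.paltea6 for p in cohort.participants], dtype=float)
        freq = table["ak_freq_d"].to_numpy()
        r = np.corrcoef(freq, pal_counts)[0, 1]
        assert abs(r) < 3 / math.sqrt(len(freq))

    def test_counts_respect_caps(self, small_synthetic_cohort):
        cfg, cohort = small_synthetic_cohort
        for p in cohort.participants:
            assert 0 <= p.paltea6 <= cfg.outcomes["paltea6"].cap
            assert 0 <= p.swmbe6 <= cfg.outcomes["swmbe6"].cap
            assert 0 <= p.swms <= cfg.outcomes["swms"].cap


class TestExclusionInjection:
    def test_injected_flag_counts(self, small_synthetic_cohort):
        cfg, cohort = small_synthetic_cohort
        _, ledger = apply_exclusions(cohort)
        assert ledger.counts["cognitive_symptoms"] == 4
        assert ledger.counts["pd_dx"] == 1
        assert ledger.counts["ms_dx"] == 2
        assert ledger.counts["incomplete_tapping"] == 3

    def test_too_many_flags_rejected(self):
        with pytest.raises(ValueError, match="more exclusion flags"):
            SimConfig(n_participants=10, exclusions=ExclusionInjection(20, 0, 0, 0))


class TestTappingCalibration:
    def test_block_frequency_means_track_targets_at_moderate_n(self):
        cohort = simulate_cohort(
            SimConfig(n_participants=600, seed=14, exclusions=NO_FLAGS)
        )
        cols = ["sk_freq_b1", "sk_freq_b2", "sk_freq_b3", "sk_freq_b4"]
        table = build_feature_table(cohort, columns=cols)
        targets = SimConfig().tapping.single_freq_targets
        for col, target in zip(cols, targets):
            se = table[col].std() / math.sqrt(len(table))
            assert abs(table[col].mean() - target) < 3.5 * se

    def test_warmup_trend_rises_across_blocks(self):
        cohort = simulate_cohort(
            SimConfig(n_participants=600, seed=14, exclusions=NO_FLAGS)
        )
        cols = ["sk_freq_b1", "sk_freq_b2", "sk_freq_b3", "sk_freq_b4"]
        means = build_feature_table(cohort, columns=cols).mean()
        assert means["sk_freq_b1"] < means["sk_freq_b4"]

    def test_variability_feature_recovers_generator_sigma(self):
        cfg = SimConfig(
            n_participants=300,
            seed=21,
            exclusions=NO_FLAGS,
            tapping=replace(SimConfig().tapping, rhythm_sd_log=0.0),
        )
        table = build_feature_table(simulate_cohort(cfg), columns=["ak_var_d"])
        # sample SD of ~65 log intervals is nearly unbiased for sigma
        assert table["ak_var_d"].mean() == pytest.approx(
            cfg.tapping.log_interval_sd_alternate, rel=0.05
        )


def test_config_dict_round_trip():
    cfg = SimConfig(n_participants=420, seed=7)
    back = SimConfig.from_dict(cfg.to_dict())
    assert back == cfg
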