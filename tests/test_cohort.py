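"""Generator contracts: preset statistics, determinism, trace structure,
the fitness -> heart-rate-response link, and the longitudinal model."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from wearfit.cohort import (
    CohortConfig,
    DeltaModel,
    generate_followup,
    generate_participants,
    generate_trace,
    recover_vo2max,
    simulate_study,
)
from wearfit.pipeline import oracle_r2, simulate_bundle
from wearfit.processing import detect_nonwear


def _frame(records):
    return pd.DataFrame(
        {
            "sex": [r.sex for r in records],
            "vo2max": [r.vo2max_measured for r in records],
            "vo2max_true": [r.vo2max_true for r in records],
            "rhr": [r.rhr for r in records],
            "age": [r.age for r in records],
        }
    )


class TestParticipants:
    def test_fenland_like_preset_statistics(self):
        df = _frame(generate_participants(CohortConfig.fenland_like(5000, seed=3)))
        assert 39.0 <= df["vo2max"].mean() <= 40.0
        assert 4.5 <= df["vo2max"].std() <= 5.5
        women = df.loc[df["sex"] == "female", "vo2max"]
        assert 36.9 <= women.mean() <= 37.9

    def test_bbvs_like_preset_is_less_fit(self):
        df = _frame(generate_participants(CohortConfig.bbvs_like(5000, seed=3)))
        assert 32.2 <= df["vo2max"].mean() <= 33.6

    def test_rhr_inversely_related_to_fitness(self):
        df = _frame(generate_participants(CohortConfig.fenland_like(2000, seed=4)))
        assert np.corrcoef(df["rhr"], df["vo2max_true"])[0, 1] < -0.3

    def test_determinism_and_extensibility(self):
        cfg = CohortConfig.fenland_like(100, seed=5)
        a = generate_participants(cfg)
        b = generate_participants(cfg)
        assert a == b
        # a smaller cohort is a strict prefix: adding participants never
        # reshuffles existing ones
        prefix = generate_participants(dataclasses.replace(cfg, n_participants=40))
        assert a[:40] == prefix

    def test_record_invariants(self):
        for r in generate_participants(CohortConfig.fenland_like(500, seed=6)):
            assert abs(r.bmi - r.weight / r.height**2) < 1e-9
            assert 35.0 <= r.rhr <= 110.0
            assert r.vo2max_measured > 0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="n_participants"):
            CohortConfig.fenland_like(0)
        with pytest.raises(ValueError, match="days"):
            CohortConfig.fenland_like(10, days=0)
        with pytest.raises(ValueError):
            CohortConfig.fenland_like(10, rhr_sd=-1.0)


class TestTraces:
    def test_minute_grid_and_length(self):
        cfg = CohortConfig.fenland_like(1, seed=8)
        rec = generate_participants(cfg)[0]
        trace = generate_trace(rec, cfg)
        assert trace.n_minutes == 6 * 1440
        assert list(trace.data.index) == list(range(6 * 1440))
        deltas = np.diff(trace.timestamps.view("int64"))
        assert (deltas == 60 * 1_000_000_000).all()

    def test_diurnal_structure(self):
        cfg = CohortConfig.fenland_like(1, seed=8, gap_rate_per_day=0.0)
        rec = generate_participants(cfg)[0]
        trace = generate_trace(rec, cfg)
        mod = trace.minute_of_day
        night = (mod >= 1410) | (mod < 390)
        intensity = trace.data["intensity"].to_numpy()
        assert intensity[night].mean() < intensity[~night].mean()

    def test_less_fit_participant_has_higher_exercise_hr(self):
        """Same activity schedule, fitness 30 vs 50: the less fit heart
        works harder at >= 3 METs."""
        cfg = CohortConfig.fenland_like(1, seed=9, hr_noise_sd=0.0,
                                        hr_response_sd=0.0, gap_rate_per_day=0.0)
        base = generate_participants(cfg)[0]
        unfit = dataclasses.replace(base, vo2max_true=30.0)
        fit = dataclasses.replace(base, vo2max_true=50.0)
        tr_unfit = generate_trace(unfit, cfg)
        tr_fit = generate_trace(fit, cfg)
        # identical activity schedules by construction
        assert np.array_equal(tr_unfit.data["intensity"], tr_fit.data["intensity"])
        active = tr_unfit.data["intensity"].to_numpy() / 71.0 >= 3.0
        assert tr_unfit.data["hr"].to_numpy()[active].mean() > \
            tr_fit.data["hr"].to_numpy()[active].mean()

    def test_zero_gap_rate_gives_full_wear(self):
        cfg = CohortConfig.fenland_like(3, seed=10, gap_rate_per_day=0.0)
        for rec in generate_participants(cfg):
            trace = generate_trace(rec, cfg)
            summary = detect_nonwear(trace)
            assert summary.nonwear_runs == []
            assert trace.data["wear"].all()

    def test_gap_durations_straddle_detection_threshold(self):
        cfg = CohortConfig.fenland_like(40, seed=11)
        lengths = []
        for rec in generate_participants(cfg):
            trace = generate_trace(rec, cfg)
            mask = np.concatenate(([0], trace.nonwear_true.astype(np.int8), [0]))
            edges = np.flatnonzero(np.diff(mask))
            lengths += [int(b - a) for a, b in zip(edges[::2], edges[1::2])]
        lengths = np.asarray(lengths)
        assert (lengths <= 90).any() and (lengths > 90).any()

    def test_noiseless_oracle_recovers_fitness_exactly(self):
        cfg = CohortConfig.fenland_like(20, seed=12).noiseless()
        for rec in generate_participants(cfg):
            est = recover_vo2max(generate_trace(rec, cfg), rec, cfg)
            assert est == pytest.approx(rec.vo2max_true, abs=1e-9)

    def test_days_below_one_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig.fenland_like(1, days=0)


class TestFollowup:
    def test_elapsed_years_distribution(self):
        cfg = CohortConfig.fenland_like(4000, seed=13)
        baseline = generate_participants(cfg)
        followup = generate_followup(baseline, DeltaModel(), cfg)
        elapsed = np.array([f.age - b.age for b, f in zip(baseline, followup)])
        assert 6.5 <= np.median(elapsed) <= 7.5
        q25, q75 = np.percentile(elapsed, [25, 75])
        assert 4.5 <= q25 <= 6.0
        assert 7.5 <= q75 <= 8.5

    def test_deltas_respect_clip_range(self):
        cfg = CohortConfig.fenland_like(4000, seed=13)
        baseline = generate_participants(cfg)
        followup = generate_followup(baseline, DeltaModel(), cfg)
        deltas = np.array([f.vo2max_true - b.vo2max_true
                           for b, f in zip(baseline, followup)])
        assert deltas.min() >= -10.0 and deltas.max() <= 10.0

    def test_degenerate_delta_model_keeps_fitness_constant(self):
        cfg = CohortConfig.fenland_like(50, seed=14)
        baseline = generate_participants(cfg)
        frozen = DeltaModel(location=0.0, scale=0.0, skewness=0.0,
                            age_effect=0.0, fitness_reversion=0.0)
        followup = generate_followup(baseline, frozen, cfg)
        for b, f in zip(baseline, followup):
            assert f.vo2max_true == pytest.approx(b.vo2max_true)
            assert f.participant_id == b.participant_id
            assert f.phase == "followup"

    def test_invalid_delta_model_rejected(self):
        with pytest.raises(ValueError):
            DeltaModel(scale=-1.0)
        with pytest.raises(ValueError):
            generate_followup([], DeltaModel(), CohortConfig.fenland_like(1))

    def test_followup_pairs_with_exactly_one_baseline(self):
        study = simulate_study(CohortConfig.fenland_like(60, seed=15),
                               longitudinal_fraction=0.4)
        base_ids = [r.participant_id for r in study.baseline]
        assert len(set(base_ids)) == len(base_ids)
        for rec in study.followup:
            assert base_ids.count(rec.participant_id) == 1


def test_observation_noise_monotonically_degrades_oracle():
    """More heart-rate-response heterogeneity -> weakly lower best-achievable
    test R^2, checked at three noise levels."""
    r2s = []
    for sd in (0.0, 0.033, 0.2):
        cfg = CohortConfig.fenland_like(250, seed=16, hr_response_sd=sd)
        bundle = simulate_bundle(cfg, longitudinal_fraction=0.5,
                                 followup_traces=False)
        r2s.append(oracle_r2(bundle))
    assert r2s[0] >= r2s[1] >= r2s[2]
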