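import numpy as np
import pytest

from fertkin import (
    Fate,
    KineticParams,
    LandmarkSet,
    ObservationSchedule,
    censor,
    chronogram_from_observation_log,
    generate_truth,
    recovery_experiment,
    recovery_summary,
    write_chronogram,
    read_chronogram,
)

LM = LandmarkSet()


class TestGenerateTruth:
    def test_zero_rate_empty_truth(self):
        truth = generate_truth(KineticParams(lambda0=0.0, n_oocytes=5), seed=0)
        assert all(not o.sperm for o in truth)

    def test_same_seed_identical(self):
        p = KineticParams(n_oocytes=30)
        a, b = generate_truth(p, seed=4), generate_truth(p, seed=4)
        for x, y in zip(a, b):
            assert [(s.pen_time, s.fusion_time) for s in x.sperm] == [
                (s.pen_time, s.fusion_time) for s in y.sperm
            ]

    def test_landmarks_ordered_and_within_one_sd(self):
        truth = generate_truth(KineticParams(n_oocytes=100), seed=8)
        checked = 0
        for o in truth:
            for s in o.sperm:
                if s.fusion_time is None:
                    continue
                checked += 1
                seq = [
                    s.fusion_time,
                    s.head_disappearance,
                    s.pb2_onset,
                    s.pb2_angle_crossover,
                    s.pb2_complete,
                ]
                assert all(b > a for a, b in zip(seq, seq[1:]))
                assert 21 <= s.head_disappearance - s.fusion_time <= 27
                assert 26 <= s.pb2_onset - s.fusion_time <= 30
                assert 43 <= s.pb2_angle_crossover - s.fusion_time <= 55
                assert 63 <= s.pb2_complete - s.fusion_time <= 83
        assert checked > 20


class TestSchedule:
    def test_rounds_increasing_nonoverlapping(self):
        sched = ObservationSchedule()
        rng = np.random.default_rng(0)
        for _ in range(50):
            rounds = sched.draw(240, rng)
            for (a1, b1), (a2, b2) in zip(rounds, rounds[1:]):
                assert a1 < b1 <= a2 < b2 <= 240 + 1e-9

    def test_range_validation(self):
        with pytest.raises(ValueError):
            ObservationSchedule(gap_range=(10, 5))


class TestCensor:
    def test_windows_contain_truth(self):
        """Round-trip containment: every censored window contains its true
        event time (default schedule, 200 oocytes)."""
        truth = generate_truth(KineticParams(n_oocytes=200), seed=21)
        chron, _ = censor(truth, seed=22)
        tmap = {(o.oocyte_id, s.sperm_id): s for o in truth for s in o.sperm}
        n_pen = n_fus = 0
        for o in chron.oocytes:
            for s in o.sperm:
                t = tmap[(o.oocyte_id, s.sperm_id)]
                n_pen += 1
                assert s.penetration.contains(t.pen_time)
                if s.fused:
                    n_fus += 1
                    assert s.fusion.contains(t.fusion_time)
        assert n_pen > 100 and n_fus > 50

    def test_single_round_before_any_event(self):
        truth = generate_truth(KineticParams(n_oocytes=20), seed=3)

        # one short round right after insemination, nothing after
        class OneRound(ObservationSchedule):
            def draw(self, horizon, rng):
                return [(0.5, 0.6)]

        chron, _ = censor(truth, OneRound(), seed=4)
        assert all(o.fate is Fate.UNPENETRATED for o in chron.oocytes)

    def test_continuous_observation_gives_exact_events(self):
        """One uninterrupted round: penetrations dated exactly, fusions to
        within the +/-1 min live-arrest rule."""
        truth = generate_truth(KineticParams(n_oocytes=40), seed=6)

        class Continuous(ObservationSchedule):
            def draw(self, horizon, rng):
                return [(0.0, horizon)]

        chron, _ = censor(truth, Continuous(), seed=7)
        tmap = {(o.oocyte_id, s.sperm_id): s for o in truth for s in o.sperm}
        for o in chron.oocytes:
            for s in o.sperm:
                t = tmap[(o.oocyte_id, s.sperm_id)]
                assert s.penetration.width == 0
                assert s.penetration.lower == t.pen_time
                if s.fused:
                    assert s.fusion.width <= 2.0
                    assert s.fusion.contains(t.fusion_time)

    def test_chronogram_validates_and_round_trips(self, tmp_path):
        truth = generate_truth(KineticParams(n_oocytes=60), seed=31)
        chron, obs_log = censor(truth, seed=32)
        path = tmp_path / "c.csv"
        write_chronogram(chron, path)
        back = read_chronogram(path)
        assert back.n_oocytes == chron.n_oocytes

    def test_observation_log_rebuilds_same_chronogram(self, tmp_path):
        """The observation log is a faithful serialization: refining it
        reproduces the censored chronogram exactly."""
        truth = generate_truth(KineticParams(n_oocytes=40), seed=41)
        chron, obs_log = censor(truth, seed=42)
        log_path = tmp_path / "log.csv"
        obs_log.to_csv(log_path, index=False, float_format="%.17g")
        import pandas as pd

        from fertkin.cli import _read_obs_log

        back = chronogram_from_observation_log(
            _read_obs_log(log_path), LM, condition=chron.condition_label
        )
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        write_chronogram(chron, a)
        write_chronogram(back, b)
        assert a.read_bytes() == b.read_bytes()


class TestRecovery:
    def test_single_replicate_row(self):
        p = KineticParams(n_oocytes=30)
        rep = recovery_experiment(
            p, n_replicates=1, seed=0, n_realizations=50, n_bootstrap=20
        )
        assert len(rep) == 1
        assert "tau_pb_hat" in rep.columns
        summary = recovery_summary(rep, p)
        assert "tau_pb_hat" in summary

    def test_wider_gaps_do_not_shrink_tau_spread(self):
        """Sparser observation cannot carry more information: the tau_PB
        estimate spread under long gaps is at least that under continuous
        observation (same truth seeds; non-strict with slack for MC noise)."""

        class Continuous(ObservationSchedule):
            def draw(self, horizon, rng):
                return [(0.0, horizon)]

        p = KineticParams(n_oocytes=57)
        kw = dict(n_replicates=5, seed=100, n_realizations=100, n_bootstrap=0)
        wide = recovery_experiment(p, ObservationSchedule(gap_range=(40.0, 70.0)), LM, **kw)
        cont = recovery_experiment(p, Continuous(), LM, **kw)
        s_wide = wide["tau_pb_hat"].std(ddof=1)
        s_cont = cont["tau_pb_hat"].std(ddof=1)
        assert s_wide >= 0.5 * s_cont
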