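import numpy as np
import pytest

from ethofly import sleep as sl

from .oracles import sleep_bouts_rle


def zt_bin(hours: float, minutes: float = 0.0) -> int:
    """Bin index at 30-s resolution for a ZT clock position."""
    return int(round((hours * 60 + minutes) * 2))


def active_day(rng, n_days=1):
    """A fully active recording (no zero bins) to carve bouts into."""
    return rng.integers(1, 4, n_days * 2880)


class TestDetectSleep:
    def test_subthreshold_run_is_not_sleep(self, rng):
        c = active_day(rng)
        c[100:109] = 0  # 9 bins = 4.5 min
        sleep, bouts = sl.detect_sleep(sl.ActivitySeries("f", "g", c))
        assert not sleep.any() and bouts == []

    def test_threshold_boundary_run(self, rng):
        c = active_day(rng)
        c[100:110] = 0  # exactly 10 bins = 5 min
        sleep, bouts = sl.detect_sleep(sl.ActivitySeries("f", "g", c))
        assert sleep.sum() == 10
        assert len(bouts) == 1 and bouts[0].duration_min == 5.0

    def test_oracle_equivalence_random(self, rng):
        for p_zero in (0.5, 0.8, 0.95):
            counts = (rng.random((2000, 120)) > p_zero) * rng.integers(1, 5, (2000, 120))
            for row in counts:
                s = sl.ActivitySeries("f", "g", row)
                sleep, bouts = sl.detect_sleep(s)
                o_sleep, o_bouts = sleep_bouts_rle(row)
                assert sleep.tolist() == o_sleep
                assert [(b.start_min, b.duration_min) for b in bouts] == [
                    (s0 * 0.5, ln * 0.5) for s0, ln in o_bouts
                ]

    def test_idempotent_and_flank_invariant(self, rng):
        c = active_day(rng)
        c[500:560] = 0
        s = sl.ActivitySeries("f", "g", c)
        sleep1, bouts1 = sl.detect_sleep(s)
        sleep2, _ = sl.detect_sleep(s)
        assert (sleep1 == sleep2).all()
        # appending active bins cannot change existing bouts
        ext = sl.ActivitySeries("f", "g", np.concatenate([c, rng.integers(1, 3, 50)]))
        _, bouts_ext = sl.detect_sleep(ext)
        assert [(b.start_min, b.duration_min) for b in bouts_ext] == [
            (b.start_min, b.duration_min) for b in bouts1
        ]

    def test_missing_bins_break_runs(self, rng):
        c = active_day(rng)
        c[200:230] = 0
        miss = np.zeros(c.size, dtype=bool)
        miss[215] = True  # gap marker in the middle of the zero run
        c[215] = 0
        s = sl.ActivitySeries("f", "g", c, missing=miss)
        _, bouts = sl.detect_sleep(s)
        assert [b.duration_min for b in bouts] == [7.5, 7.0]
        _, bridged = sl.detect_sleep(s, missing_breaks_runs=False)
        assert [b.duration_min for b in bridged] == [15.0]


class TestPhaseMetrics:
    def test_hand_computed_night_bouts(self, rng):
        c = active_day(rng)
        c[zt_bin(13) : zt_bin(13, 20)] = 0  # 20-min bout, latency 60 min
        c[zt_bin(18) : zt_bin(18, 7)] = 0  # 7-min bout
        m = sl.phase_metrics(sl.ActivitySeries("f", "g", c))
        assert m.night.total_sleep_min == 27.0
        assert m.night.sleep_latency_min == 60.0
        assert m.night.bout_count == 2
        assert m.night.mean_bout_duration_min == 13.5

    def test_all_zero_day(self):
        m = sl.phase_metrics(sl.ActivitySeries("f", "g", np.zeros(2880, dtype=int)))
        for phase in (m.day, m.night):
            assert phase.total_sleep_min == 720.0
            assert phase.sleep_latency_min == 0.0
            assert phase.activity_while_awake == 0.0
        # the single 1440-min bout starts in the day phase
        assert m.day.bout_count == 1 and m.day.mean_bout_duration_min == 720.0
        assert m.night.bout_count == 0

    def test_no_sleep_day(self, rng):
        m = sl.phase_metrics(sl.ActivitySeries("f", "g", active_day(rng)))
        for phase in (m.day, m.night):
            assert phase.total_sleep_min == 0.0
            assert phase.sleep_latency_min == 720.0
            assert phase.bout_count == 0

    def test_conservation_and_boundary_bout(self, rng):
        c = active_day(rng, n_days=2)
        c[zt_bin(11, 50) : zt_bin(12, 30)] = 0  # 40-min bout spanning ZT12
        s = sl.ActivitySeries("f", "g", c)
        sleep, bouts = sl.detect_sleep(s)
        m = sl.phase_metrics(s, sleep, bouts)
        # minutes split by overlap, bout attributed to its (day) onset phase
        assert m.day.total_sleep_min == pytest.approx(10.0 / 2)  # averaged over 2 days
        assert m.night.total_sleep_min == pytest.approx(30.0 / 2)
        assert m.day.bout_count == 0.5 and m.night.bout_count == 0.0
        # ongoing bout at night start: latency 0 that day, 720 the other
        assert m.night.sleep_latency_min == pytest.approx((0 + 720) / 2)
        # whole-recording conservation: bout minutes sum to total sleep
        assert sum(b.duration_min for b in bouts) == sleep.sum() * 0.5

    def test_incomplete_final_day_warns(self, rng):
        c = np.concatenate([active_day(rng), rng.integers(1, 3, 100)])
        with pytest.warns(UserWarning, match="incomplete"):
            m = sl.phase_metrics(sl.ActivitySeries("f", "g", c))
        assert m.n_days == 1


class TestProfileCurve:
    def test_constant_activity(self):
        s = sl.ActivitySeries("f", "g", np.ones(2880, dtype=int))
        prof = sl.profile_curve([s])
        assert len(prof) == 48
        np.testing.assert_allclose(prof["activity"], 60.0)
        np.testing.assert_allclose(prof["sleep_min"], 0.0)

    def test_all_asleep_group(self):
        group = [sl.ActivitySeries(f"f{i}", "g", np.zeros(2880, dtype=int)) for i in range(3)]
        prof = sl.profile_curve(group)
        np.testing.assert_allclose(prof["sleep_min"], 30.0)
        np.testing.assert_allclose(prof["activity"], 0.0)

    def test_matches_bruteforce_group_mean(self, rng):
        group = []
        raw = []
        for i in range(5):
            c = (rng.random(2 * 2880) > 0.7) * rng.integers(1, 5, 2 * 2880)
            group.append(sl.ActivitySeries(f"f{i}", "g", c))
            raw.append(c)
        prof = sl.profile_curve(group)
        acc = np.zeros(48)
        slp = np.zeros(48)
        for s, c in zip(group, raw):
            sleep, _ = sl.detect_sleep(s)
            for d in range(2):
                for w in range(48):
                    b0 = d * 2880 + w * 60
                    acc[w] += c[b0 : b0 + 60].sum()
                    slp[w] += sleep[b0 : b0 + 60].sum() * 0.5
        np.testing.assert_allclose(prof["activity"], acc / 10)
        np.testing.assert_allclose(prof["sleep_min"], slp / 10)


def test_exclude_dead(rng):
    alive = sl.ActivitySeries("a", "g", active_day(rng, 2))
    dead_counts = active_day(rng, 2)
    dead_counts[2880:] = 0
    dead = sl.ActivitySeries("d", "g", dead_counts)
    kept = sl.exclude_dead([alive, dead])
    assert [s.fly_id for s in kept] == ["a"]
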