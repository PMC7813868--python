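import numpy as np
import pytest

from ethofly import habituation as hb
from ethofly import simulate as sim
from ethofly import sleep as sl


class TestHabituationSim:
    def test_reproducible(self):
        p = sim.HabituationSimParams(n_flies=20, seed=7)
        s1, t1 = sim.simulate_habituation(p)
        s2, t2 = sim.simulate_habituation(p)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.jumps, b.jumps)
        np.testing.assert_array_equal(t1["lambda_i"], t2["lambda_i"])

    def test_immediate_habituation_limit(self):
        p = sim.HabituationSimParams(n_flies=30, p0=1.0, lam=50.0,
                                     heterogeneity_sd=0.0, seed=1)
        series, _ = sim.simulate_habituation(p)
        for s in series:
            r = hb.compute_ttc(s.jumps)
            assert (r.ttc, r.censored) == (1, False)
            assert s.jumps[0] == 1 and s.jumps[1:].sum() == 0

    def test_no_habituation_limit(self):
        p = sim.HabituationSimParams(n_flies=30, p0=1.0, lam=0.0, seed=1)
        series, _ = sim.simulate_habituation(p)
        for s in series:
            assert s.jumps.all()
            r = hb.compute_ttc(s.jumps)
            assert (r.ttc, r.censored) == (100, True)

    def test_mean_curve_matches_lognormal_integral(self):
        p = sim.HabituationSimParams(n_flies=500, p0=0.9, lam=0.05,
                                     heterogeneity_sd=0.3, seed=42)
        series, _ = sim.simulate_habituation(p)
        emp = hb.mean_jump_curve(series)
        expect = sim.expected_jump_curve(p)
        # 3 Monte-Carlo sds per trial, Bernoulli
        mc_sd = np.sqrt(expect * (1 - expect) / p.n_flies)
        assert (np.abs(emp - expect) <= 3 * mc_sd + 1e-12).mean() > 0.99

    def test_median_ttc_monotone_in_effect(self):
        medians = []
        for i, eff in enumerate((0.25, 0.5, 1.0, 2.0)):
            p = sim.HabituationSimParams(n_flies=500, genotype_effect=eff, seed=100 + i)
            series, _ = sim.simulate_habituation(p)
            t, _, j = hb.ttc_matrix(np.stack([s.jumps for s in series]))
            medians.append(np.median(t[j]))
        assert medians == sorted(medians, reverse=True)
        assert medians[0] > medians[-1]  # strictly slower at weakest effect

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            sim.HabituationSimParams(p0=0.0)
        with pytest.raises(ValueError):
            sim.HabituationSimParams(lam=-1)
        with pytest.raises(ValueError):
            sim.HabituationSimParams(genotype_effect=0.0)
        with pytest.raises(ValueError):
            sim.HabituationSimParams(n_trials=4)


class TestDamSim:
    def test_reproducible(self):
        p = sim.DamSimParams(n_flies=4, n_days=1, seed=3)
        a, _ = sim.simulate_dam(p)
        b, _ = sim.simulate_dam(p)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.counts, y.counts)

    def test_all_sleep_limit(self):
        p = sim.DamSimParams(
            n_flies=3, n_days=1,
            p_fall_asleep={"day": 1.0, "night": 1.0},
            p_wake={"day": 0.0, "night": 0.0}, seed=2,
        )
        series, _ = sim.simulate_dam(p)
        for s in series:
            assert (s.counts == 0).all()
            m = sl.phase_metrics(s)
            assert m.day.total_sleep_min == 720.0
            assert m.night.total_sleep_min == 720.0

    def test_no_sleep_limit(self):
        p = sim.DamSimParams(
            n_flies=3, n_days=1,
            p_fall_asleep={"day": 0.0, "night": 0.0},
            p_wake={"day": 1.0, "night": 1.0},
            activity_rate=2.0, seed=2,
        )
        series, _ = sim.simulate_dam(p)
        for s in series:
            assert (s.counts > 0).all()
            m = sl.phase_metrics(s)
            assert m.day.total_sleep_min == 0.0
            # zero-truncated Poisson(2) mean = 2/(1-e^-2) ~ 2.313 per bin
            mu = 2.0 / (1 - np.exp(-2.0))
            assert s.counts.mean() == pytest.approx(mu, rel=0.05)

    def test_stationary_rest_fraction(self):
        p = sim.DamSimParams(n_flies=200, n_days=1, seed=9)
        series, truth = sim.simulate_dam(p)
        counts = np.stack([s.counts for s in series])
        for phase, sel in (("day", slice(0, 1440)), ("night", slice(1440, 2880))):
            # counts are zero exactly in rest bins, so rest = zero count
            emp = (counts[:, sel] == 0).mean()
            theory = sim.stationary_rest_fraction(p, phase)
            se = np.sqrt(theory * (1 - theory) / counts[:, sel].size) * 10
            assert abs(emp - theory) < max(se, 0.01), (phase, emp, theory)

    def test_sleep_pressure_shifts_rest(self):
        lo = sim.stationary_rest_fraction(sim.DamSimParams(sleep_pressure=0.5), "day")
        hi = sim.stationary_rest_fraction(sim.DamSimParams(sleep_pressure=2.0), "day")
        assert lo < hi

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            sim.DamSimParams(activity_rate=0.0)
        with pytest.raises(ValueError):
            sim.DamSimParams(p_wake={"day": 1.5, "night": 0.1})
        with pytest.raises(ValueError):
            sim.DamSimParams(bin_seconds=45)


class TestQpcrSim:
    def test_reproducible_and_schema(self):
        p = sim.QpcrSimParams(seed=4)
        a = sim.simulate_qpcr(p)
        b = sim.simulate_qpcr(p)
        assert a.equals(b)
        assert set(a.columns) == {"gene", "tissue", "stage", "replicate", "ct"}
        # 7 stages x 2 tissues x 3 reps x 3 genes
        assert len(a) == 7 * 2 * 3 * 3

    def test_reference_ct_independent_of_stage(self):
        p = sim.QpcrSimParams(noise_sd=0.0, seed=4)
        df = sim.simulate_qpcr(p)
        refs = df[df["gene"] == "eIF-1A"]
        assert refs["ct"].nunique() == 1

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            sim.QpcrSimParams(noise_sd=-0.1)
        with pytest.raises(ValueError):
            sim.QpcrSimParams(body_expression=(1.0,))


def test_ground_truth_sidecar_roundtrips(tmp_path):
    import json

    p = sim.DamSimParams(n_flies=2, seed=5)
    sim.write_ground_truth(p, tmp_path / "gt.json")
    d = json.loads((tmp_path / "gt.json").read_text())
    assert d["n_flies"] == 2 and d["seed"] == 5
    assert d["p_fall_asleep"]["day"] == 0.04
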