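"""Survival machinery: KM, log-rank, Cox, C-statistic and DeLong tests."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from _oracles import cox_loglik_two_group, logrank_oracle
from octcfa.outcomes import (
    SurvivalRecord,
    binary_cstat,
    binary_outcome_at_2y,
    cox_univariable,
    delong_paired_test,
    kaplan_meier,
    logrank,
)


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        km = kaplan_meier([100, 200, 300], [False, False, False])
        assert np.all(km["survival"].to_numpy() == 1.0)

    def test_all_events_distinct_times_closed_form(self):
        n = 6
        km = kaplan_meier(np.arange(1, n + 1), [True] * n)
        post_event = km[km["time_days"] > 0]["survival"].to_numpy()
        expected = (n - np.arange(1, n + 1)) / n
        assert np.allclose(post_event, expected)

    def test_uncensored_equals_empirical_survival(self, rng):
        times = rng.exponential(300, size=80)
        km = kaplan_meier(times, [True] * 80)
        for t in (50.0, 150.0, 400.0):
            s_km = km[km["time_days"] <= t]["survival"].iloc[-1]
            assert s_km == pytest.approx((times > t).mean())

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            kaplan_meier([], [])


class TestLogrank:
    def test_six_patient_example_matches_arithmetic_oracle(self):
        times = [1, 2, 3, 4, 5, 6]
        events = [True] * 6
        group = [True, False, True, False, True, False]
        stat, p = logrank(times, events, group)
        assert stat == pytest.approx(logrank_oracle(times, events, group), rel=1e-9)

    def test_null_p_is_roughly_uniform(self, rng):
        ps = []
        for _ in range(200):
            times = rng.exponential(500, size=60)
            events = times < 700
            times = np.minimum(times, 700)
            group = rng.uniform(size=60) < 0.5
            if events[group].sum() and events[~group].sum():
                ps.append(logrank(times, events, group)[1])
        ps = np.asarray(ps)
        assert 0.01 < (ps < 0.05).mean() < 0.12  # nominal 5% within MC noise

    def test_one_empty_group_errors(self):
        with pytest.raises(ValueError):
            logrank([1, 2], [True, True], [True, True])


class TestCox:
    def test_four_record_example_matches_bruteforce_likelihood(self):
        # interleaved exposure: the partial likelihood has a finite maximiser
        # (an exposure perfectly ranking the death order would be monotone)
        times = [1.0, 2.0, 3.0, 4.0]
        events = [True] * 4
        expo = [True, False, True, False]
        res = cox_univariable(times, events, expo)
        grid = minimize_scalar(
            lambda b: -cox_loglik_two_group(b, times, events, expo),
            bounds=(-5, 5),
            method="bounded",
            options={"xatol": 1e-10},
        )
        # tolerance bounded by the fitter's own Newton stopping rule
        assert res.log_hr == pytest.approx(grid.x, abs=1e-5)

    def test_null_exposure_centred_on_one(self, rng):
        hrs = []
        for _ in range(40):
            times = rng.exponential(2000, size=300)
            events = times < 760
            times = np.minimum(times, 760)
            expo = rng.uniform(size=300) < 0.4
            res = cox_univariable(times, events, expo)
            if res.converged:
                hrs.append(res.log_hr)
        assert abs(np.mean(hrs)) < 0.12

    def test_time_rescaling_invariance(self, rng):
        times = rng.exponential(500, size=120)
        events = times < 700
        times = np.minimum(times, 700)
        expo = rng.uniform(size=120) < 0.5
        r1 = cox_univariable(times, events, expo)
        r2 = cox_univariable(times * 3.7, events, expo)
        assert r1.hr == pytest.approx(r2.hr, rel=1e-6)

    def test_exposure_relabel_inverts_hr(self, rng):
        times = rng.exponential(500, size=120)
        events = times < 700
        times = np.minimum(times, 700)
        expo = rng.uniform(size=120) < 0.5
        r1 = cox_univariable(times, events, expo)
        r2 = cox_univariable(times, events, ~expo)
        assert r1.hr == pytest.approx(1 / r2.hr, rel=1e-6)

    def test_monotone_likelihood_reported_not_raised(self):
        times = [10.0, 20.0, 30.0, 40.0]
        events = [True, True, False, False]
        expo = [True, True, False, False]
        res = cox_univariable(times, events, expo)
        assert not res.converged and "monotone" in res.message


class TestBinaryCstat:
    def test_patient_count_reconstruction(self):
        # 17 events among 143 exposed vs 17 among 271 unexposed -> C = 0.58
        expo = np.r_[np.ones(143), np.zeros(271)].astype(bool)
        out = np.r_[
            np.ones(17), np.zeros(126), np.ones(17), np.zeros(254)
        ].astype(bool)
        c, ci = binary_cstat(expo, out)
        assert round(c, 2) == 0.58
        assert ci[0] < c < ci[1]

    def test_equals_mean_of_sensitivity_and_specificity(self, rng):
        for _ in range(25):
            expo = rng.uniform(size=150) < rng.uniform(0.2, 0.8)
            out = rng.uniform(size=150) < rng.uniform(0.1, 0.5)
            if out.all() or not out.any():
                continue
            c, _ = binary_cstat(expo, out)
            se = expo[out].mean()
            sp = (~expo[~out]).mean()
            assert c == pytest.approx((se + sp) / 2, abs=1e-12)

    def test_perfect_and_null_markers(self, rng):
        out = np.r_[np.ones(20), np.zeros(80)].astype(bool)
        assert binary_cstat(out, out)[0] == 1.0
        cs = [
            binary_cstat(rng.uniform(size=2000) < 0.5, out.repeat(20))[0]
            for _ in range(10)
        ]
        assert abs(np.mean(cs) - 0.5) < 0.03

    def test_degenerate_outcome_errors(self):
        with pytest.raises(ValueError):
            binary_cstat([True, False], [True, True])


class TestDeLong:
    def test_marker_against_itself(self):
        out = np.r_[np.ones(15), np.zeros(45)].astype(bool)
        expo = np.r_[np.ones(10), np.zeros(50)].astype(bool)
        diff, z, p = delong_paired_test(expo, expo, out)
        assert diff == 0.0 and p == 1.0

    def test_null_p_roughly_uniform(self, rng):
        ps = []
        for _ in range(300):
            out = rng.uniform(size=200) < 0.2
            if not out.any() or out.all():
                continue
            a = rng.uniform(size=200) < 0.4
            b = rng.uniform(size=200) < 0.4
            ps.append(delong_paired_test(a, b, out)[2])
        ps = np.asarray(ps)
        assert 0.02 < (ps < 0.05).mean() < 0.10
        assert 0.35 < (ps < 0.5).mean() < 0.65

    def test_matches_paired_bootstrap_oracle(self, rng):
        n = 250
        out = rng.uniform(size=n) < 0.25
        latent = out.astype(float) + rng.normal(0, 1.5, n)
        a = latent > 0.8
        b = rng.uniform(size=n) < 0.3
        diff, _, p = delong_paired_test(a, b, out)

        def auc(marker, o):
            se = marker[o].mean()
            sp = (~marker[~o]).mean()
            return (se + sp) / 2

        boots = []
        for _ in range(4000):
            idx = rng.integers(0, n, n)
            o = out[idx]
            if not o.any() or o.all():
                continue
            boots.append(auc(a[idx], o) - auc(b[idx], o))
        boots = np.asarray(boots)
        # two-sided bootstrap p for H0: diff = 0
        p_boot = 2 * min((boots <= 0).mean(), (boots >= 0).mean())
        assert p == pytest.approx(p_boot, abs=0.05)

    def test_mismatched_sets_error(self):
        with pytest.raises(ValueError):
            delong_paired_test([1.0, 0.0], [1.0], [True, False])


class TestBinaryOutcomeWindow:
    def test_short_followup_censored_patients_excluded(self):
        recs = [
            SurvivalRecord("a", 720, False),
            SurvivalRecord("b", 300, False),
            SurvivalRecord("c", 100, True, "death"),
        ]
        kept, outcome, dropped = binary_outcome_at_2y(recs)
        assert [r.patient_id for r in kept] == ["a", "c"]
        assert dropped == ["b"]
        assert list(outcome) == [False, True]
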