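"""Analysis metrics: intake arithmetic, circadian bins, ITIs, bouts,
efficiency, entrainment, decay fit, breakpoints, group tests."""

import numpy as np
import pandas as pd
import pytest

import homecage as hc
from homecage import metrics
from homecage.errors import InsufficientDataError, MetricError
from homecage.events import MouseIdentity, Trial, TrialLedger


def _mouse(tag="TAGA", group="control"):
    return MouseIdentity(tag, tag.lower(), group, "cageX")


def _trial(t0, pokes=1, fent=0, water=0, tag="TAGA", group="control",
           port="left", vol=10.0):
    """A compact synthetic visit: pokes at 1-s spacing, rewards at the end."""
    poke_times = tuple((t0 + 0.5 + i, port) for i in range(pokes))
    rewards = tuple((t0 + 0.5 + pokes - 1, "fentanyl", vol)
                    for _ in range(fent))
    rewards += tuple((t0 + 0.5 + pokes - 1, "water", vol)
                     for _ in range(water))
    t_end = t0 + 0.5 + max(pokes - 1, 0) + 3.0
    return Trial(mouse=_mouse(tag, group), t_start=t0, t_end=t_end,
                 pokes=poke_times, rewards=rewards,
                 termination="gap_timeout")


class TestDailyIntake:
    @pytest.mark.parametrize("n_rewards,conc,expected_mg", [
        (12, 0.1, 0.012), (20, 0.15, 0.030)])
    def test_mass_arithmetic(self, n_rewards, conc, expected_mg):
        # day chosen so the default staging carries the right concentration
        day = 5 if conc == 0.1 else 13
        t0 = (day - 1) * 86400.0
        trials = tuple(_trial(t0 + 100 * i, pokes=1, fent=n_rewards // 4)
                       for i in range(4))
        ledger = TrialLedger(trials=trials)
        daily = metrics.daily_intake(ledger, hc.default_protocol(), n_days=day)
        row = daily[(daily["day"] == day)].iloc[0]
        assert row["fentanyl_mg"] == pytest.approx(expected_mg)
        assert row["fentanyl_ul"] == pytest.approx(n_rewards * 10.0)

    def test_empty_days_get_zero_rows(self):
        ledger = TrialLedger(trials=(_trial(10.0, water=1),))
        daily = metrics.daily_intake(ledger, hc.default_protocol(), n_days=3)
        assert len(daily) == 3
        assert (daily.loc[daily["day"] > 1, "visit_count"] == 0).all()
        assert (daily.loc[daily["day"] > 1, "fentanyl_mg"] == 0).all()

    def test_conservation_against_ledger(self):
        cage = hc.default_cohort(n_cages=1, mice_per_cage=3)[0]
        proto = hc.default_protocol()
        events = hc.simulate(cage, proto, 6, seed=2)
        res = hc.replay_protocol(events, proto, cage.roster)
        daily = metrics.daily_intake(res.ledger, proto)
        for liquid in ("fentanyl", "water"):
            assert daily[f"{liquid}_ul"].sum() == pytest.approx(
                metrics.total_reward_volume(res.ledger, liquid))
            assert metrics.total_reward_volume(res.ledger, liquid) == \
                pytest.approx(metrics.reward_event_volume(events, liquid))


class TestEscalationSlope:
    def _daily(self, mgs):
        return pd.DataFrame({"rfid_tag": "TAGA",
                             "day": range(1, len(mgs) + 1),
                             "fentanyl_mg": mgs})

    def test_exact_linear_series_recovered(self):
        mgs = [0.002 * d + 0.01 for d in range(1, 8)]
        res = metrics.escalation_slope(self._daily(mgs), "TAGA")
        assert res.slope == pytest.approx(0.002)

    def test_constant_series_zero_slope(self):
        res = metrics.escalation_slope(self._daily([0.05] * 6), "TAGA")
        assert res.slope == 0.0

    def test_too_few_days_raise(self):
        with pytest.raises(InsufficientDataError):
            metrics.escalation_slope(self._daily([0.1, 0.2]), "TAGA")

    def test_noisy_recovery_unbiased(self):
        rng = np.random.default_rng(0)
        slopes = []
        for _ in range(200):
            days = np.arange(1, 15, dtype=float)
            y = 0.003 * days + rng.normal(0, 0.01, days.size)
            df = pd.DataFrame({"rfid_tag": "TAGA", "day": days,
                               "fentanyl_mg": y})
            slopes.append(metrics.escalation_slope(df, "TAGA").slope)
        assert np.mean(slopes) == pytest.approx(0.003, abs=3e-4)


class TestHourlyProfile:
    def test_all_mass_in_one_bin(self):
        t0 = 13 * 3600.0
        ledger = TrialLedger(trials=tuple(
            _trial(t0 + 60 * i, water=1) for i in range(5)))
        prof, summary = metrics.hourly_profile(ledger, lights_on_hour=7)
        busy = prof[prof["visits"] > 0]
        assert list(busy["hour_rel"]) == [13]
        assert list(busy["hour"]) == [(13 + 7) % 24]
        assert busy["visits"].iloc[0] == 5
        assert summary["dark_visit_share"] == 1.0  # hour 13 is dark phase

    def test_bin_totals_conserve_visit_count(self):
        cage = hc.default_cohort(n_cages=1, mice_per_cage=3)[0]
        proto = hc.default_protocol()
        events = hc.simulate(cage, proto, 4, seed=6)
        ledger = hc.replay_protocol(events, proto, cage.roster).ledger
        prof, summary = metrics.hourly_profile(ledger, proto.lights_on_hour)
        assert prof["visits"].sum() == len(ledger)
        assert summary["light_visits"] + summary["dark_visits"] == len(ledger)


class TestITI:
    def test_simple_interval_and_median(self):
        trials = (_trial(0.0), _trial(100.0), _trial(200.0))
        # t_end = t0 + 3.5 with one poke; check a single explicit gap
        ledger = TrialLedger(trials=trials)
        res = metrics.iti_distribution(ledger, "TAGA")
        assert res.itis[0] == pytest.approx(100.0 - 3.5)

    def test_median_of_known_set(self):
        trials = (_trial(0.0), _trial(3.5 + 5.0), _trial(17.0),
                  _trial(120.5))
        ledger = TrialLedger(trials=trials)
        res = metrics.iti_distribution(ledger, "TAGA")
        assert res.itis.size == 3
        assert res.median == pytest.approx(sorted(res.itis)[1])

    def test_fewer_than_two_trials_empty(self):
        ledger = TrialLedger(trials=(_trial(0.0),))
        res = metrics.iti_distribution(ledger, "TAGA")
        assert res.itis.size == 0 and np.isnan(res.median)


class TestBoutCDF:
    def test_fraction_by_definition(self):
        # bouts {1,1,3,5}: rewards in bouts <=1 are 2 of 10 total
        trials = (_trial(0.0, fent=1), _trial(50.0, fent=1),
                  _trial(100.0, fent=3), _trial(150.0, fent=5))
        xs, cdf = metrics.bout_size_cdf(TrialLedger(trials=trials), "fentanyl")
        assert list(xs) == [1, 3, 5]
        assert cdf[0] == pytest.approx(0.2)
        assert cdf[-1] == pytest.approx(1.0)
        assert (np.diff(cdf) >= 0).all()

    def test_all_singleton_bouts(self):
        trials = tuple(_trial(60.0 * i, fent=1) for i in range(4))
        xs, cdf = metrics.bout_size_cdf(TrialLedger(trials=trials), "fentanyl")
        assert list(xs) == [1] and cdf[0] == pytest.approx(1.0)

    def test_absent_liquid_empty(self):
        trials = (_trial(0.0, fent=2),)
        xs, cdf = metrics.bout_size_cdf(TrialLedger(trials=trials), "water")
        assert xs.size == 0 and cdf.size == 0


class TestRewardEfficiency:
    def test_seven_of_ten(self):
        trials = tuple(_trial(40.0 * i, fent=1 if i < 7 else 0)
                       for i in range(10))
        ledger = TrialLedger(trials=trials)
        assert metrics.reward_efficiency(ledger, "TAGA", 1) == pytest.approx(0.7)

    def test_all_rewarded_is_one(self):
        trials = tuple(_trial(40.0 * i, water=2) for i in range(5))
        ledger = TrialLedger(trials=trials)
        assert metrics.reward_efficiency(ledger, "TAGA", 1) == 1.0

    def test_no_visits_flagged_nan(self):
        ledger = TrialLedger(trials=(_trial(0.0),))
        assert np.isnan(metrics.reward_efficiency(ledger, "TAGA", 2))


class TestPokesPerTrial:
    def _ledger_at_fr3(self, counts):
        # day 9 of the default staging runs FR3; fentanyl port that day
        proto = hc.default_protocol()
        t0 = 8 * 86400.0
        pm, _ = proto.resolve(9, "TAGA")
        port = next(p for p, liq in pm.items() if liq == "fentanyl")
        trials = tuple(_trial(t0 + 100 * i, pokes=c, port=port)
                       for i, c in enumerate(counts))
        return TrialLedger(trials=trials), proto

    def test_entrainment_score_by_definition(self):
        ledger, proto = self._ledger_at_fr3([3, 3, 6, 4])
        prob, score = metrics.pokes_per_trial_distribution(
            ledger, "fentanyl", 3, proto)
        assert score == pytest.approx(0.75)
        assert prob.sum() == pytest.approx(1.0)
        assert prob.loc[3] == pytest.approx(0.5)

    def test_fr1_score_always_one(self):
        proto = hc.choice_protocol(ratio=1)
        pm, _ = proto.resolve(1, "TAGA")
        port = next(p for p, liq in pm.items() if liq == "fentanyl")
        trials = tuple(_trial(100.0 * i, pokes=c, port=port)
                       for i, c in enumerate([1, 2, 5, 7]))
        _prob, score = metrics.pokes_per_trial_distribution(
            TrialLedger(trials=trials), "fentanyl", 1, proto)
        assert score == 1.0

    @pytest.mark.parametrize("fidelity,lo,hi", [(1.0, 0.999, 1.0),
                                                (0.0, 0.0, 0.35)])
    def test_simulated_fidelity_maps_to_entrainment_score(self, fidelity,
                                                          lo, hi):
        from homecage.simulate import AgentProfile, CageConfig
        profile = AgentProfile(entrainment_fidelity=fidelity,
                               entrainment_fidelity_water=fidelity)
        members = tuple(
            (hc.MouseIdentity(f"FID{j}", f"f{j}", "control", "cageF"), profile)
            for j in range(3))
        cage = CageConfig(cage_id="cageF", members=members)
        proto = hc.choice_protocol(ratio=5)
        events = hc.simulate(cage, proto, 2, seed=31)
        ledger = hc.replay_protocol(events, proto, cage.roster).ledger
        _prob, score = metrics.pokes_per_trial_distribution(
            ledger, "fentanyl", 5, proto)
        assert lo <= score <= hi


class TestDecayFit:
    def _points(self, x, y):
        return pd.DataFrame({"visit_count": x, "mean_trial_length_s": y})

    def test_noiseless_parameters_recovered(self):
        x = np.linspace(1, 60, 12)
        y = 60.0 * np.exp(-0.05 * x)
        fit = metrics.visit_profile_fit(self._points(x, y))
        assert fit.a == pytest.approx(60.0, rel=1e-4)
        assert fit.b == pytest.approx(0.05, rel=1e-4)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-8)

    def test_constant_data_degenerates_to_zero_r2(self):
        x = np.linspace(1, 30, 8)
        fit = metrics.visit_profile_fit(self._points(x, np.full(8, 12.0)))
        assert fit.b == pytest.approx(0.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-9)

    def test_r2_decreases_with_noise(self):
        rng = np.random.default_rng(3)
        x = np.linspace(1, 60, 40)
        clean = 60.0 * np.exp(-0.05 * x)
        r2s = []
        for noise in (0.5, 4.0, 20.0):
            vals = []
            for _ in range(10):
                y = np.clip(clean + rng.normal(0, noise, x.size), 0.01, None)
                vals.append(metrics.visit_profile_fit(
                    self._points(x, y)).r_squared)
            r2s.append(np.mean(vals))
        assert r2s[0] > r2s[1] > r2s[2]

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            metrics.visit_profile_fit(self._points([1, 2, 3], [3, 2, 1]))


class TestBreakpoints:
    def _pr_ledger(self, fent, water, tag="TAGA"):
        trials = []
        t = 0.0
        for k in range(1, fent + 1):
            trials.append(_trial(t, pokes=k, fent=1, tag=tag))
            t += 100.0
        for k in range(1, water + 1):
            trials.append(_trial(t, pokes=k, water=1, tag=tag, port="right"))
            t += 100.0
        return trials

    def test_final_completed_ratio(self):
        ledger = TrialLedger(trials=tuple(self._pr_ledger(3, 0)))
        bp = metrics.pr_breakpoint(ledger)
        row = bp.table.iloc[0]
        assert row["breakpoint_fentanyl"] == 3
        assert row["breakpoint_water"] == 0

    def test_state_crosscheck_rejects_non_pr_ledger(self, roster):
        from homecage.engine import PRState
        ledger = TrialLedger(trials=tuple(self._pr_ledger(3, 1)))
        good = PRState({("TAGA", "fentanyl"): 4, ("TAGA", "water"): 2})
        metrics.pr_breakpoint(ledger, pr_state=good)  # consistent: no raise
        bad = PRState({("TAGA", "fentanyl"): 2, ("TAGA", "water"): 2})
        with pytest.raises(MetricError):
            metrics.pr_breakpoint(ledger, pr_state=bad)

    def test_paired_statistic_direction(self):
        trials = tuple(self._pr_ledger(5, 2, "TAGA"))
        t2 = tuple(Trial(mouse=_mouse("TAGB"), t_start=tr.t_start + 5000,
                         t_end=tr.t_end + 5000,
                         pokes=tuple((t + 5000, p) for t, p in tr.pokes),
                         rewards=tuple((t + 5000, l, v)
                                       for t, l, v in tr.rewards),
                         termination=tr.termination)
                   for tr in self._pr_ledger(4, 1, "TAGA"))
        bp = metrics.pr_breakpoint(TrialLedger(trials=trials + t2))
        assert bp.t_statistic > 0
        assert bp.p_value < 0.05


class TestGroupCompare:
    def test_identical_distributions_ks_zero(self):
        x = [1, 2, 3, 4, 5]
        stat, _p = metrics.group_compare(x, x)
        assert stat == 0.0

    def test_disjoint_support_ks_one(self):
        stat, p = metrics.group_compare([1, 2, 3], [10, 11, 12])
        assert stat == 1.0
        assert p < 0.2

    def test_small_group_rejected(self):
        with pytest.raises(MetricError):
            metrics.group_compare([1.0], [1, 2, 3])

    def test_poke_distributions_differ_between_phenotypes(self):
        proto = hc.choice_protocol(ratio=5)
        rejections = 0
        for seed in range(5):
            cages = hc.default_cohort(n_cages=2, mice_per_cage=4,
                                      inhibited_per_cage=2,
                                      heterogeneous=False)
            events = hc.simulate_cohort(cages, proto, 2, seed=100 + seed)
            ledger = hc.replay_protocol(
                events, proto, hc.cohort_roster(cages)).ledger
            df = metrics.compare_poke_distributions(ledger, proto,
                                                    fr_values=(5,))
            rejections += (df["p_bonferroni"] < 0.01).iloc[0]
        assert rejections >= 4
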