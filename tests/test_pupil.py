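"""Pupil preprocessing, peri-event dynamics, matched controls, phase analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special

from pupilexplore import behavior, pupil, synth


class TestPreprocess:
    def test_injected_outlier_is_excluded(self, rng):
        x = rng.normal(0, 1, 500)
        x[100] = x.mean() + 7 * x.std()
        res = pupil.preprocess_pupil(x)
        assert not res.valid[100]
        assert res.valid.sum() == 499

    def test_zscore_contract(self, rng):
        x = rng.normal(5, 3, 400)
        res = pupil.preprocess_pupil(x)
        v = res.values[res.valid]
        assert abs(v.mean()) < 1e-9
        assert abs(v.std() - 1) < 1e-9

    def test_change_criterion_also_excludes(self, rng):
        x = rng.normal(0, 1, 300)
        d = rng.normal(0, 1, 300)
        d[42] = d.mean() + 8 * d.std()
        res = pupil.preprocess_pupil(x, change=d)
        assert not res.valid[42]

    def test_small_session_flagged_unusable(self, rng):
        x = rng.normal(0, 1, 30)
        s = np.r_[np.zeros(25, int), np.ones(5, int)]
        with pytest.warns(UserWarning):
            res = pupil.preprocess_pupil(x, session=s)
        assert res.usable_sessions[1] is False
        assert not res.valid[25:].any()

    def test_benchmark_exclusion_fraction(self, rng):
        # 28-session corpus with 0.8% injected blink-like artifacts
        level = []
        sess = []
        for sid in range(28):
            x = rng.normal(0, 1, 778)
            x, _ = synth.inject_pupil_artifacts(x, fraction=0.008, magnitude_sd=20, rng=rng)
            level.append(x)
            sess.append(np.full(778, sid))
        res = pupil.preprocess_pupil(np.concatenate(level), session=np.concatenate(sess))
        frac = (~res.valid).mean()
        assert 0.006 < frac < 0.010


class TestPeriEvent:
    def test_full_window_has_31_lags(self, rng):
        x = rng.normal(0, 1, 100)
        res = pupil.peri_event_matrix(x, [20], window=15)
        assert np.sum(~np.isnan(res.matrix[0])) == 31

    def test_session_edges_masked(self, rng):
        x = rng.normal(0, 1, 40)
        sessions = np.r_[np.zeros(20, int), np.ones(20, int)]
        res = pupil.peri_event_matrix(x, [18], window=15, sessions=sessions)
        # lags reaching into session 1 or before trial 0 are masked
        assert np.isnan(res.matrix[0, -15:]).sum() == 14  # lags +2..+15

    def test_ramp_recovered_in_lag_means(self):
        states = np.ones(600, dtype=int)
        comp = synth.simulate_pupil(
            states, np.ones(600, int),
            synth.PupilGenConfig(ramp_per_trial=0.01, osc_amplitude=0, omission_gain=0,
                                 onset_reset=0, noise_sd=0),
            rng=0,
        )
        events = np.arange(50, 550, 25)
        res = pupil.peri_event_matrix(comp.total, events, window=15)
        slope = np.polyfit(res.lags, res.mean, 1)[0]
        assert slope == pytest.approx(0.01, abs=1e-10)

    def test_exploit_run_requirement_masks_explore_crossings(self):
        states = np.ones(50, dtype=int)
        states[24] = behavior.EXPLORE
        states[30] = behavior.EXPLORE
        x = np.arange(50.0)
        res = pupil.peri_event_matrix(x, [24], window=10, states=states)
        row = res.matrix[0]
        # lags beyond the explore trial at 30 (lag +6) are masked
        assert np.isnan(row[res.lags >= 6]).all()
        assert not np.isnan(row[(res.lags >= -10) & (res.lags < 6)]).any()

    def test_post_onset_dip_below_pre_onset_baseline(self, default_session):
        gt = default_session.ground_truth
        states = gt["states"]
        comp = gt["pupil_components"]
        events = np.flatnonzero(gt["onsets"])
        res = pupil.peri_event_matrix(comp.total, events, window=10, states=states)
        pre = res.mean[(res.lags >= -5) & (res.lags < 0)]
        post = res.mean[(res.lags > 0) & (res.lags <= 5)]
        assert np.nanmean(post) < np.nanmean(pre)


class TestLaggedChange:
    def test_pure_ramp_closed_form(self):
        s = 0.02
        x = s * np.arange(100)
        states = np.ones(100, dtype=int)
        df = pupil.lagged_pupil_change(x, states)
        assert np.allclose(df["delta"], s * df["lag"])
        assert not df["crossed"].any()

    def test_ols_slope_on_noncrossing_pairs_matches_ramp(self, default_session):
        cfg = synth.PupilGenConfig(ramp_per_trial=0.004, osc_amplitude=0,
                                   omission_gain=0, onset_reset=0, noise_sd=0)
        gt = default_session.ground_truth
        comp = synth.simulate_pupil(gt["states"], default_session.trials["reward"], cfg, rng=0)
        df = pupil.lagged_pupil_change(comp.total, gt["states"])
        keep = df[~df["crossed"]]
        slope = np.polyfit(keep["lag"], keep["delta"], 1)[0]
        assert slope == pytest.approx(0.004, abs=1e-6)

    def test_reset_makes_crossing_pairs_smaller(self, default_session):
        gt = default_session.ground_truth
        comp = gt["pupil_components"]
        df = pupil.lagged_pupil_change(comp.ramp + comp.reset, gt["states"])
        # compare at matched lag: the ramp contribution cancels and only the
        # onset reset separates crossing from non-crossing pairs
        g = df.groupby(["lag", "crossed"])["delta"].mean().unstack().dropna()
        assert len(g) > 5
        assert (g[True] - g[False]).mean() < 0

    def test_segments_with_two_bouts_skipped(self):
        states = np.ones(25, dtype=int)
        states[[5, 15]] = behavior.EXPLORE  # two separate bouts
        df = pupil.lagged_pupil_change(np.zeros(25), states)
        assert len(df) == 0


class TestMatchedRewards:
    def test_hand_enumerated_toy(self):
        # one onset at trial 12 (preceded by >= 3 exploit trials), k=3;
        # exactly one other exploit window shares the reward vector (1,0,1)
        states = np.array([1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 1, 1, 1, 1, 1, 1])
        rewards = np.array([1, 0, 1, 1, 1, 1, 0, 1, 0, 1, 0, 1, 0, 1, 1, 1, 0, 0, 1, 1])
        ms = pupil.match_reward_sequences(states, rewards, k=3, min_matches=1)
        assert list(ms.onset_indices) == [12]
        assert np.array_equal(ms.onset_windows[0], [9, 10, 11])
        # candidate windows with rewards (1,0,1): starts 0, 5, 7; start 7
        # overlaps the onset window [9,11] so only 0 and 5 survive
        assert set(ms.controls[0].tolist()) == {0, 5}

    def test_no_controls_flags_session(self):
        states = np.array([1] * 6 + [0, 1, 1])
        rewards = np.array([1, 1, 1, 1, 1, 1, 0, 1, 1])
        ms = pupil.match_reward_sequences(states, rewards, k=6, min_matches=1)
        assert ms.flagged

    def test_reward_match_is_exact_on_default_fixture(self, default_session):
        gt = default_session.ground_truth
        tr = default_session.trials
        rewards = tr["reward"].to_numpy()
        ms = pupil.match_reward_sequences(gt["states"], rewards, k=6, min_matches=1)
        n = sum(len(c) for c in ms.controls)
        assert n > 0
        for o, ctrls in zip(ms.onset_indices, ms.controls):
            for w in ctrls:
                assert np.array_equal(rewards[w : w + 6], rewards[o - 6 : o])

    def test_shuffling_rewards_destroys_matches(self, default_session, rng):
        # balanced Bernoulli(0.5) rewards: a 6-bit history collides with a
        # fixed target by chance with probability 1/64, so a shuffle should
        # destroy >= 95% of matches (an exploit-heavy session with ~80%
        # reward rate would not satisfy this, by simple counting)
        gt = default_session.ground_truth
        rewards = rng.integers(0, 2, len(gt["states"]))
        ms = pupil.match_reward_sequences(gt["states"], rewards, k=6, min_matches=1)
        n_before = sum(len(c) for c in ms.controls)
        if n_before < 20:
            pytest.skip("too few matches for a rate estimate")
        shuf = rng.permutation(rewards)
        kept = sum(
            np.array_equal(shuf[w : w + 6], rewards[o - 6 : o])
            for o, ctrls in zip(ms.onset_indices, ms.controls)
            for w in ctrls
        )
        assert kept <= 0.05 * n_before + 1


class TestMorletPhase:
    def test_pure_tone_phase_advances_by_two_pi_over_period(self):
        t = np.arange(300)
        ps = pupil.morlet_phase(np.cos(2 * np.pi * t / 5), 5, 5)
        ph = ps.phase[ps.edge_mask]
        step = np.angle(np.exp(1j * np.diff(ph)))
        assert np.max(np.abs(step - 2 * np.pi / 5)) < 1e-6

    def test_phase_zero_at_local_maximum(self):
        t = np.arange(200)
        ps = pupil.morlet_phase(np.cos(2 * np.pi * t / 5), 5, 5)
        assert abs(ps.phase[50]) < 1e-8  # t=50 is a cosine maximum

    def test_shift_equivariance(self):
        t = np.arange(240)
        x = np.cos(2 * np.pi * t / 5 + 0.3)
        ps0 = pupil.morlet_phase(x, 5, 5)
        ps1 = pupil.morlet_phase(np.r_[0.0, x[:-1]], 5, 5)  # delayed by one trial
        ok = ps0.edge_mask.copy()
        ok[:30] = ok[-30:] = False
        rot = np.angle(np.exp(1j * (ps1.phase[ok] - ps0.phase[ok])))
        assert np.allclose(rot, -2 * np.pi / 5, atol=1e-3)

    def test_short_session_fully_masked(self):
        with pytest.warns(UserWarning):
            ps = pupil.morlet_phase(np.zeros(10), 5, 5)
        assert not ps.edge_mask.any()

    def test_five_trial_cycle_is_in_mayer_band(self):
        # three-second trials put the 5-trial cycle at ~0.067 Hz
        assert pupil.mayer_band_frequency(5, 3.0) == pytest.approx(1 / 15, abs=1e-12)
        assert 0.06 <= pupil.mayer_band_frequency(5, 3.2)
        assert pupil.mayer_band_frequency(5, 2.2) <= 0.1


def exact_hodges_ajne(phases):
    """Independent oracle: brute-force minimum half-circle count + the exact
    combinatorial formula."""
    phases = np.asarray(phases) % (2 * np.pi)
    n = len(phases)
    m = n
    for a in phases:
        inside = ((phases - a) % (2 * np.pi) < np.pi).sum()
        m = min(m, inside, n - inside)
    return float((n - 2 * m) * special.comb(n, m) * 2.0 ** (1 - n))


class TestCircularStats:
    def test_identical_phases_fully_locked(self):
        res = pupil.phase_locking_stats(np.full(50, 1.2), n_boot=200, seed=0)
        assert res.resultant_length == pytest.approx(1.0)
        assert res.p_hodges_ajne < 0.001

    def test_uniform_grid_has_zero_resultant(self):
        grid = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        r, _ = pupil.resultant_vector(grid)
        assert r < 1e-12

    def test_hodges_ajne_matches_exact_oracle_n20(self, rng):
        for _ in range(5):
            ph = rng.uniform(0, 2 * np.pi, 20)
            assert pupil.hodges_ajne_p(ph) == pytest.approx(
                exact_hodges_ajne(ph), rel=1e-9
            )

    @pytest.mark.parametrize("n", [50, 300, 1135])
    def test_bootstrap_null_mean_matches_closed_form(self, n):
        res = pupil.phase_locking_stats(
            np.random.default_rng(n).uniform(0, 2 * np.pi, n), n_boot=1000, seed=1
        )
        expected = np.sqrt(np.pi / (4 * n))          # E[R] under uniformity
        sd = np.sqrt((4 - np.pi) / 2) * np.sqrt(1 / (2 * n))
        se = sd / np.sqrt(1000)
        assert abs(res.null_mean - expected) < 3 * se

    def test_resultant_length_in_unit_interval(self, rng):
        for _ in range(20):
            r, _ = pupil.resultant_vector(rng.uniform(-np.pi, np.pi, 17))
            assert 0.0 <= r <= 1.0


def watson_u2_oracle(a, b):
    """Direct cumulative-step implementation of the two-sample statistic."""
    a = np.sort(np.asarray(a) % (2 * np.pi))
    b = np.sort(np.asarray(b) % (2 * np.pi))
    n1, n2 = len(a), len(b)
    n = n1 + n2
    vals = np.concatenate([a, b])
    labels = np.concatenate([np.zeros(n1), np.ones(n2)])
    order = np.argsort(vals, kind="mergesort")
    d = []
    i = j = 0
    for lab in labels[order]:
        if lab == 0:
            i += 1
        else:
            j += 1
        d.append(i / n1 - j / n2)
    d = np.asarray(d)
    return n1 * n2 / n**2 * np.sum((d - d.mean()) ** 2)


class TestWatsonU2:
    def test_identical_samples_not_different(self, rng):
        x = rng.uniform(0, 2 * np.pi, 40)
        u2, p = pupil.compare_phase_distributions(x, x, n_perm=199, seed=0)
        assert p > 0.5

    def test_matches_rank_formula_oracle(self, rng):
        for _ in range(5):
            a = rng.uniform(0, 2 * np.pi, 20)
            b = rng.uniform(0, 2 * np.pi, 20)
            assert pupil.watson_u2(a, b) == pytest.approx(
                watson_u2_oracle(a, b), abs=1e-12
            )

    def test_opposite_von_mises_detected(self):
        hits = 0
        for s in range(100):
            r = np.random.default_rng(s)
            a = r.vonmises(0.0, 2.0, 100)
            b = r.vonmises(np.pi, 2.0, 100)
            _, p = pupil.compare_phase_distributions(a, b, n_perm=199, seed=s)
            hits += p < 0.01
        assert hits >= 95


class TestQuantileCurve:
    def test_linear_ground_truth_prefers_linear_model(self, rng):
        x = rng.normal(0, 1, 2000)
        y = x + rng.normal(0, 0.5, 2000)  # exact y = x makes the AIC degenerate
        res = pupil.quantile_response_curve(x, y, n_quantiles=10)
        assert res.linear.params["x1"] > 0
        assert abs(res.quadratic.params["x1_sq"]) < 0.05
        assert res.aic_weights[0] > 0.5

    def test_known_curvature_prefers_quadratic_model(self, rng):
        x = rng.normal(0, 1, 5000)
        y = 0.2 + 0.5 * (x - 0.3) ** 2 + rng.normal(0, 0.3, 5000)
        res = pupil.quantile_response_curve(x, y, n_quantiles=10)
        assert res.aic_weights[1] > 0.95

    def test_too_few_quantiles_raises(self, rng):
        with pytest.raises(ValueError):
            pupil.quantile_response_curve(rng.normal(size=100), np.zeros(100), n_quantiles=2)


@settings(max_examples=25, deadline=None)
@given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=6), st.floats(-50, 50))
def test_aic_weights_shift_invariant_and_normalized(aics, shift):
    from pupilexplore import stats

    w1 = stats.aic_weights(aics)
    w2 = stats.aic_weights(np.asarray(aics) + shift)
    assert abs(w1.sum() - 1) < 1e-12
    assert np.allclose(w1, w2, atol=1e-9)
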