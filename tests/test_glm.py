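import numpy as np
import pandas as pd
import pytest

from pebga.glm import (
    Cluster,
    RegressionTimecourse,
    SiteStats,
    _prune_short_runs,
    cluster_permutation,
    condition_contrast_timecourse,
    outcome_contrast_by_phase,
    parcel_fixed_effect,
    pointwise_regression,
    site_fdr_significance,
)
from pebga.preprocessing import EpochedPower, epoch_grid


def make_epochs(data, times=None):
    if times is None:
        times = epoch_grid()
    return EpochedPower(
        data=data, times=times, trial_index=np.arange(len(data)),
        baseline_mode="outcome-centered-6s",
    )


class TestPointwiseRegression:
    def test_exact_noise_free_beta(self):
        rng = np.random.default_rng(0)
        pe = rng.standard_normal(60)
        pe = (pe - pe.mean()) / pe.std()
        Y = 0.5 * pe[:, None] * np.ones((1, 289))
        tc = pointwise_regression(make_epochs(Y), pe)
        assert np.allclose(tc.betas[0], 0.5, atol=1e-12)

    def test_matches_statsmodels_ols(self):
        """Betas, t and p agree with an independent OLS implementation."""
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        n, T = 80, 30
        x1, x2 = rng.standard_normal(n), rng.standard_normal(n)
        Y = 0.4 * x1[:, None] - 0.2 * x2[:, None] + rng.standard_normal((n, T))
        tc = pointwise_regression(make_epochs(Y, times=np.arange(T) / 64.0), {"a": x1, "b": x2})
        for j in rng.integers(0, T, size=5):
            fit = sm.OLS(Y[:, j], sm.add_constant(np.column_stack([x1, x2]))).fit()
            assert np.allclose(tc.betas[:, j], fit.params[1:], atol=1e-8)
            assert np.allclose(tc.t[:, j], fit.tvalues[1:], atol=1e-8)
            assert np.allclose(tc.p[:, j], fit.pvalues[1:], atol=1e-8)

    def test_closed_form_single_regressor(self):
        rng = np.random.default_rng(2)
        n = 50
        x = rng.standard_normal(n)
        Y = rng.standard_normal((n, 10))
        tc = pointwise_regression(make_epochs(Y, times=np.arange(10) / 64.0), x)
        expected = [np.cov(Y[:, j], x, ddof=0)[0, 1] / x.var() for j in range(10)]
        assert np.allclose(tc.betas[0], expected, atol=1e-10)

    def test_sign_recovery_two_regressors(self):
        rng = np.random.default_rng(3)
        n = 200
        R = rng.standard_normal(n)
        Q = rng.standard_normal(n)
        Y = 0.4 * R[:, None] - 0.3 * Q[:, None] + 0.8 * rng.standard_normal((n, 20))
        tc = pointwise_regression(make_epochs(Y, times=np.arange(20) / 64.0), {"R": R, "Q": Q})
        assert (tc.betas[0] > 0).all() and (tc.betas[1] < 0).all()

    def test_zero_variance_regressor_rejected(self):
        Y = np.random.default_rng(4).normal(size=(20, 5))
        with pytest.raises(ValueError, match="zero variance"):
            pointwise_regression(make_epochs(Y, times=np.arange(5) / 64.0), np.ones(20))

    def test_too_few_trials_rejected(self):
        Y = np.random.default_rng(5).normal(size=(3, 5))
        with pytest.raises(ValueError, match="too few"):
            pointwise_regression(
                make_epochs(Y, times=np.arange(5) / 64.0),
                {"a": np.arange(3.0), "b": np.array([0.0, 1.0, 0.5])},
            )


def make_tc(pvals, betas=None, times=None):
    pvals = np.atleast_2d(pvals)
    if times is None:
        times = epoch_grid()
    if betas is None:
        betas = np.zeros_like(pvals)
    return RegressionTimecourse(
        betas=betas, t=np.zeros_like(pvals), p=pvals, times=times,
        n_trials=100, regressor_names=["pe"],
    )


class TestSiteFDR:
    def test_97_comparisons_in_window(self):
        tc = make_tc(np.full((1, 289), 0.5))
        st = site_fdr_significance(tc)
        assert st.n_comparisons == 97

    def test_short_run_pruned(self):
        """A 3-sample (~47 ms) significant run is discarded (<100 ms rule)."""
        p = np.full((1, 289), 0.9)
        i0 = np.argmin(np.abs(epoch_grid() - 0.5))
        p[0, i0 : i0 + 3] = 1e-12
        st = site_fdr_significance(make_tc(p))
        assert not st.any_significant
        # a 10-sample (156 ms) run survives
        p[0, i0 : i0 + 10] = 1e-12
        st = site_fdr_significance(make_tc(p))
        assert st.any_significant
        assert st.significant_mask.sum() == 10

    def test_null_uniform_false_positive_rate(self):
        """Under the global null the site-level any-significant rate stays <= q."""
        rng = np.random.default_rng(6)
        hits = 0
        n_draws = 400
        for _ in range(n_draws):
            st = site_fdr_significance(make_tc(rng.uniform(size=(1, 289))))
            hits += st.any_significant
        assert hits / n_draws <= 0.05 + 2.6 * np.sqrt(0.05 * 0.95 / n_draws)

    def test_prune_short_runs_helper(self):
        m = np.array([1, 1, 0, 1, 1, 1, 1, 1, 1, 1, 0, 1], dtype=bool)
        out = _prune_short_runs(m, 7)
        assert out.sum() == 7
        assert out[3:10].all()


def make_site_stats(beta, sig, site_id):
    return SiteStats(
        site_id=site_id, significant_mask=np.zeros(1, bool), any_significant=sig,
        window_beta=beta, n_comparisons=97,
    )


class TestParcelScreening:
    def test_planted_parcels_selected(self):
        rng = np.random.default_rng(7)
        stats, pmap = [], {}
        for p in range(8):
            planted = p < 4
            for s in range(6):
                sid = f"p{p}s{s}"
                beta = rng.normal(0.3 if planted else 0.0, 0.05)
                stats.append(make_site_stats(beta, planted, sid))
                pmap[sid] = f"parcel{p}"
        out = parcel_fixed_effect(stats, pmap)
        selected = {o.parcel for o in out if o.selected}
        assert selected == {f"parcel{p}" for p in range(4)}

    def test_proportion_threshold_is_strict(self):
        """Exactly 20% significant sites does not pass the 'superior to 20%' rule."""
        rng = np.random.default_rng(8)
        stats, pmap = [], {}
        for s in range(10):
            sid = f"s{s}"
            stats.append(make_site_stats(rng.normal(0.3, 0.01), s < 2, sid))
            pmap[sid] = "P"
        out = parcel_fixed_effect(stats, pmap, n_parcels=1)
        assert out[0].proportion_significant == pytest.approx(0.2)
        assert not out[0].selected

    def test_single_site_parcel_excluded_with_warning(self):
        stats = [make_site_stats(0.5, True, "a"), make_site_stats(0.5, True, "b"),
                 make_site_stats(0.4, True, "lone")]
        pmap = {"a": "P1", "b": "P1", "lone": "P2"}
        with pytest.warns(UserWarning, match="single site"):
            out = parcel_fixed_effect(stats, pmap)
        assert {o.parcel for o in out} == {"P1"}

    def test_bonferroni_null_calibration(self):
        """All-null parcels: family-wise selection rate <= alpha over draws."""
        rng = np.random.default_rng(9)
        n_draws, any_selected = 200, 0
        for _ in range(n_draws):
            stats, pmap = [], {}
            for p in range(6):
                for s in range(5):
                    sid = f"p{p}s{s}"
                    stats.append(make_site_stats(rng.normal(0, 0.1), rng.random() < 0.5, sid))
                    pmap[sid] = f"parcel{p}"
            out = parcel_fixed_effect(stats, pmap)
            any_selected += any(o.selected for o in out)
        assert any_selected / n_draws <= 0.05 + 2.6 * np.sqrt(0.05 * 0.95 / n_draws)


class TestClusterPermutation:
    def test_planted_effect_found_at_floor(self):
        rng = np.random.default_rng(10)
        times = np.arange(-32, 97) / 64.0
        n_sites, n_trials = 10, 120
        Y_by_site, x_by_site = [], []
        win = (times >= 0.25) & (times <= 1.0)
        for _ in range(n_sites):
            x = rng.standard_normal(n_trials)
            Y = rng.standard_normal((n_trials, len(times)))
            Y[:, win] += 0.4 * x[:, None]
            Y_by_site.append(Y)
            x_by_site.append(x)
        res = cluster_permutation(Y_by_site, x_by_site, times, n_perm=199, rng=0)
        sig = res.significant()
        assert sig, "expected a significant cluster"
        best = max(sig, key=lambda c: abs(c.mass))
        assert best.p_corrected == pytest.approx(1.0 / 200.0)
        assert best.start_time < 1.0 and best.end_time > 0.25

    def test_pc_floor_respects_estimator(self):
        rng = np.random.default_rng(11)
        times = np.arange(30) / 64.0
        Y = [rng.standard_normal((40, 30)) for _ in range(4)]
        x = [rng.standard_normal(40) for _ in range(4)]
        with pytest.warns(UserWarning, match="coarse"):
            res = cluster_permutation(Y, x, times, n_perm=50, rng=1)
        for c in res.clusters:
            assert c.p_corrected >= 1.0 / 51.0

    def test_null_family_wise_rate(self):
        """No planted association: corrected-significant clusters are rare."""
        rng = np.random.default_rng(12)
        times = np.arange(-16, 65) / 64.0
        hits, n_datasets = 0, 60
        for _ in range(n_datasets):
            Y = [rng.standard_normal((60, len(times))) for _ in range(8)]
            x = [rng.standard_normal(60) for _ in range(8)]
            res = cluster_permutation(Y, x, times, n_perm=99, rng=rng)
            hits += bool(res.significant())
        assert hits / n_datasets <= 0.05 + 2.6 * np.sqrt(0.05 * 0.95 / n_datasets)


class TestConditionContrast:
    @staticmethod
    def _dataset(rng, asym):
        times = np.arange(-16, 80) / 64.0
        win = (times >= 0.25) & (times <= 0.7)
        Y_by_site, x_by, m_by = [], [], []
        for _ in range(8):
            n = 120
            m = np.zeros(n, bool)
            m[: n // 2] = True
            rng.shuffle(m)
            x = rng.standard_normal(n)
            Y = rng.standard_normal((n, len(times)))
            gain = np.where(m, 0.3, 0.3 + asym)
            Y[:, win] += (gain * x)[:, None]
            Y_by_site.append(Y)
            x_by.append(x)
            m_by.append(m)
        return Y_by_site, x_by, m_by, times

    def test_symmetric_gains_no_cluster(self):
        rng = np.random.default_rng(13)
        Y, x, m, times = self._dataset(rng, 0.0)
        _, _, res = condition_contrast_timecourse(Y, x, x, m, times, n_perm=99, rng=0)
        assert not res.significant(alpha=0.01)

    def test_punishment_dominant_gains_yield_negative_cluster(self):
        rng = np.random.default_rng(14)
        Y, x, m, times = self._dataset(rng, 0.5)  # punishment gain larger
        br, bp, res = condition_contrast_timecourse(Y, x, x, m, times, n_perm=199, rng=0)
        sig = res.significant()
        assert sig and min(c.mass for c in sig) < 0

    def test_label_swap_flips_sign_exactly(self):
        rng = np.random.default_rng(15)
        Y, x, m, times = self._dataset(rng, 0.4)
        br, bp, _ = condition_contrast_timecourse(Y, x, x, m, times, n_perm=1, rng=0)
        br2, bp2, _ = condition_contrast_timecourse(
            Y, x, x, [~mm for mm in m], times, n_perm=1, rng=0
        )
        assert np.allclose(br - bp, -(br2 - bp2), atol=1e-12)

    def test_few_trials_per_condition_rejected(self):
        times = np.arange(10) / 64.0
        Y = [np.zeros((20, 10)), np.zeros((20, 10))]
        x = [np.arange(20.0)] * 2
        m = [np.array([True] * 15 + [False] * 5)] * 2
        with pytest.raises(ValueError, match="at least 10 trials"):
            condition_contrast_timecourse(Y, x, x, m, times)


class TestOutcomePhaseContrast:
    @staticmethod
    def _dataset(rng, ramp=0.0, gain=0.5):
        times = np.arange(-16, 80) / 64.0
        win = (times >= 0.25) & (times <= 1.0)
        Y_by, nz_by, ph_by = [], [], []
        for _ in range(10):
            n = 120
            nz = rng.random(n) < 0.5
            phase = np.arange(n) >= n // 2
            g = gain + ramp * np.linspace(0, 1, n)
            Y = rng.standard_normal((n, len(times)))
            Y[:, win] += (g * nz)[:, None]
            Y_by.append(Y)
            nz_by.append(nz)
            ph_by.append(phase)
        return Y_by, nz_by, ph_by, times

    def test_stationary_gain_no_interaction(self):
        rng = np.random.default_rng(16)
        Y, nz, ph, times = self._dataset(rng)
        out = outcome_contrast_by_phase(Y, nz, ph, times)
        assert out["early_p"] < 0.01 and out["late_p"] < 0.01
        assert out["interaction_p"] > 0.05

    def test_ramping_gain_detected(self):
        rng = np.random.default_rng(17)
        Y, nz, ph, times = self._dataset(rng, ramp=1.5)
        out = outcome_contrast_by_phase(Y, nz, ph, times)
        assert out["interaction_p"] < 0.05

    def test_zero_gain_both_null(self):
        rng = np.random.default_rng(18)
        Y, nz, ph, times = self._dataset(rng, gain=0.0)
        out = outcome_contrast_by_phase(Y, nz, ph, times)
        assert abs(out["early_contrast_mean"]) < 0.1
        assert abs(out["late_contrast_mean"]) < 0.1


class TestPreOutcomeExpectation:
    def test_planted_pre_outcome_sign_recovered(self):
        """A positive pre-outcome expectation modulation yields positive betas
        in the -1.2 to -0.2 s window through the full synthetic path."""
        import pandas as pd

        from pebga import TABLE1_QLR, TaskConfig, derive_regressors, simulate_patient
        from pebga.glm import WINDOW_PRE_OUTCOME
        from pebga.preprocessing import GAMMA, epoch_and_baseline, session_envelope
        from pebga.synth import SiteSpec, generate_session_recording

        sessions = simulate_patient(TABLE1_QLR, TaskConfig(n_sessions=1), 21)
        fit = type("F", (), {"params": TABLE1_QLR})
        reg = derive_regressors(fit, sessions).reset_index(drop=True)
        spec = SiteSpec(site_id="A1-A2", parcel="aINS", pre_outcome_gain=0.5)
        rec, ev = generate_session_recording([spec], sessions[0], reg, 22)
        envs, _ = session_envelope(rec.data, rec.ch_names, rec.sfreq, GAMMA)
        ep = epoch_and_baseline(envs[0], ev)
        tc = pointwise_regression(ep, reg.loc[ep.trial_index, "expectation_z"].to_numpy())
        win = (tc.times >= WINDOW_PRE_OUTCOME[0]) & (tc.times <= WINDOW_PRE_OUTCOME[1])
        assert tc.betas[0, win].mean() > 0
        assert tc.t[0, win].mean() > 2.0
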