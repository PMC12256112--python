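import numpy as np
import pytest

from proteofret import (RateEstimate, StatePath, extract_dwells,
                        fit_exponential, fit_titration, percent_change,
                        simulate_state_path)
from proteofret.dwells import (DegenerateFitError, DwellSet, TooFewDwellsError,
                               correct_frame_discretization,
                               exponential_loglik)
from proteofret.kinetics import KineticParams, forward_rate_at_conc

DT = 0.0517


def _uncensored(durations, dt=0.0, quantized=False):
    n = len(durations)
    return DwellSet(state="s1", durations=np.asarray(durations, float),
                    flags=["interior"] * n, trace_ids=["t"] * n,
                    frame_interval=dt, quantized=quantized)


class TestExtractDwells:
    def test_interior_dwell_arithmetic(self):
        path = StatePath(["s1", "ns1", "s1"],
                         np.array([0.0, 10 * DT, 14 * DT]),
                         np.array([10 * DT, 14 * DT, 20 * DT]),
                         frame_interval=DT, quantized=True, trace_id="a")
        ns1 = extract_dwells([path], "ns1")
        assert ns1.n == 1
        assert ns1.durations[0] == pytest.approx(4 * DT)  # 0.2068 s
        assert ns1.flags == ["interior"]
        s1 = extract_dwells([path], "s1")
        assert list(s1.boundary) == [True, True]
        assert s1.flags == ["first-dwell", "last-dwell"]

    def test_single_state_path_is_censored(self):
        path = StatePath(["s1"], np.array([0.0]), np.array([5.0]))
        d = extract_dwells([path], "s1")
        assert d.n == 1 and d.censored[0]

    def test_pooled_transition_count_at_experimental_scale(self):
        rng = np.random.default_rng(12)
        paths = [simulate_state_path(1.45, 5.8, 50.0, seed=rng)
                 for _ in range(200)]
        assert sum(p.n_transitions() for p in paths) > 2900


class TestFitExponential:
    def test_uncensored_mle_is_reciprocal_mean(self):
        est = fit_exponential(_uncensored([1.0, 2.0, 3.0] * 5))
        assert est.estimate == pytest.approx(0.5, rel=1e-12)

    def test_censored_mle_matches_grid_search(self, rng):
        durations = rng.exponential(0.7, 200)
        flags = ["interior"] * 150 + ["last-dwell"] * 50
        # censored dwells are truncated observations of longer dwells
        durations[150:] *= rng.uniform(0.2, 1.0, 50)
        d = DwellSet(state="s1", durations=durations, flags=flags,
                     trace_ids=["t"] * 200, frame_interval=DT, quantized=True)
        est = fit_exponential(d)
        grid = np.arange(0.05, 10.0, 1e-3)
        ll = [exponential_loglik(k, d) for k in grid]
        assert est.estimate == pytest.approx(grid[int(np.argmax(ll))], abs=1e-3)

    def test_recovery_at_printed_rate_and_scale(self, rng):
        """~2,900 dwells at the wild-type apo forward rate recover it within 5%."""
        paths = [simulate_state_path(1.45, 5.8, 35.0, seed=rng)
                 for _ in range(120)]
        d = extract_dwells(paths, "s1")
        assert d.n_uncensored > 2000
        est = fit_exponential(d)
        assert abs(est.estimate - 1.45) / 1.45 < 0.05

    def test_too_few_dwells_error_carries_count(self):
        with pytest.raises(TooFewDwellsError) as err:
            fit_exponential(_uncensored([1.0, 2.0]))
        assert err.value.n_uncensored == 2

    def test_censoring_aware_fit_beats_naive_on_short_records(self):
        """Bleach-truncated dwells bias the naive fit; the censored MLE stays
        within a few percent (median over replicates)."""
        rng = np.random.default_rng(55)
        bias_cens, bias_naive = [], []
        for _ in range(100):
            paths = [simulate_state_path(1.45, 5.8, 4.0, seed=rng)
                     for _ in range(40)]
            d = extract_dwells(paths, "s1")
            bias_cens.append(fit_exponential(d, "censored").estimate / 1.45 - 1)
            bias_naive.append(fit_exponential(d, "naive").estimate / 1.45 - 1)
        med_c = abs(np.median(bias_cens))
        med_n = abs(np.median(bias_naive))
        assert med_c < 0.03
        assert med_n > med_c


class TestPercentChange:
    def test_printed_rate_pairs(self):
        mk = lambda x: RateEstimate(x, 0.0, 100, "m")
        assert percent_change(mk(1.45), mk(0.45)).estimate == pytest.approx(69.0, abs=0.5)
        assert percent_change(mk(1.0), mk(1.0)).estimate == 0.0
        assert percent_change(mk(1.45), mk(0.87)).estimate == pytest.approx(40.0, abs=0.1)

    def test_se_propagation(self):
        a = RateEstimate(2.0, 0.2, 100, "m")
        b = RateEstimate(1.0, 0.1, 100, "m")
        out = percent_change(a, b)
        expected = 100 * np.hypot(1.0 * 0.2 / 4.0, 0.1 / 2.0)
        assert out.se == pytest.approx(expected)


class TestFrameDiscretizationInversion:
    @pytest.mark.parametrize("k_f,k_b", [(1.45, 5.8), (0.45, 5.8), (0.87, 6.2)])
    def test_exact_on_point_sampled_chain(self, k_f, k_b):
        """Round trip: analytic apparent rates of the sampled chain invert
        exactly to the continuous-time rates."""
        lam = k_f + k_b
        decay = 1.0 - np.exp(-lam * DT)
        q_f = (k_f / lam) * decay * (k_b / k_f)  # pi_ns1... see below
        # per-frame switch probabilities of P = exp(Q dt)
        q_f = (k_f / lam) * decay
        q_b = (k_b / lam) * decay
        k_app_f = q_f / (DT * (1 - q_f))
        k_app_b = q_b / (DT * (1 - q_b))
        mk = lambda x: RateEstimate(x, 0.0, 100, "m")
        out_f, out_b = correct_frame_discretization(mk(k_app_f), mk(k_app_b), DT)
        assert out_f.estimate == pytest.approx(k_f, rel=1e-10)
        assert out_b.estimate == pytest.approx(k_b, rel=1e-10)


class TestTitration:
    CONCS = [0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0]

    def test_noiseless_inversion_is_exact(self):
        p = KineticParams(k_f_apo=1.45, k_f_sat=0.30, k_b=5.8, K_D_app=3.1)
        rates = [RateEstimate(forward_rate_at_conc(p, c), 0.0, 100, "m")
                 for c in self.CONCS]
        fit = fit_titration(self.CONCS, rates)
        assert fit.K_D_app.estimate == pytest.approx(3.1, rel=1e-6)
        assert fit.k_apo.estimate == pytest.approx(1.45, rel=1e-6)
        assert fit.k_sat.estimate == pytest.approx(0.30, rel=1e-6)

    def test_noisy_recovery_coverage(self):
        """K_D within 2 SE of the generating value in >=90% of replicates."""
        p = KineticParams(k_f_apo=1.45, k_f_sat=0.30, k_b=5.8, K_D_app=3.1)
        rng = np.random.default_rng(99)
        hits = 0
        n_rep = 50
        for _ in range(n_rep):
            rates = []
            for c in self.CONCS:
                mu = forward_rate_at_conc(p, c)
                se = 0.03
                rates.append(RateEstimate(mu + rng.normal(0, se), se, 100, "m"))
            fit = fit_titration(self.CONCS, rates)
            if abs(fit.K_D_app.estimate - 3.1) < 2 * fit.K_D_app.se:
                hits += 1
        assert hits / n_rep >= 0.90

    def test_flat_response_is_degenerate(self):
        rates = [RateEstimate(1.0, 0.05, 100, "m") for _ in self.CONCS]
        with pytest.raises(DegenerateFitError):
            fit_titration(self.CONCS, rates)

    def test_requires_zero_and_four_concentrations(self):
        rates = [RateEstimate(1.0, 0.01, 10, "m")] * 3
        with pytest.raises(ValueError):
            fit_titration([1.0, 2.0, 3.0], rates)
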