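import numpy as np
import pytest

from proteofret import (AcquisitionParams, EventBands, IntensityTrace,
                        ProcessingParams, capture_success, classify_event,
                        detect_events, extract_events, gehan_breslow_wilcoxon,
                        simulate_processing_cohort, simulate_processing_trace,
                        survival_curve, tail_insertion_time)
from proteofret.events import ProcessingEvent, SUCCESSFUL, UNSUCCESSFUL, REJECTED

ACQ = AcquisitionParams()


def _blank(n=2000, seed=0):
    rng = np.random.default_rng(seed)
    return IntensityTrace(
        donor=ACQ.background + rng.normal(0, ACQ.noise_sd, n),
        acceptor=ACQ.background + rng.normal(0, ACQ.noise_sd, n),
        acq=ACQ)


def _constructed(E_segments, seed=0, noise=None):
    """Build a trace from (n_frames, E_or_None) segments; None = donor-only."""
    rng = np.random.default_rng(seed)
    noise = ACQ.noise_sd if noise is None else noise
    E, fret_on, donor_on = [], [], []
    for n, e in E_segments:
        if e == "off":
            E += [0.0] * n; fret_on += [False] * n; donor_on += [False] * n
        elif e is None:
            E += [0.0] * n; fret_on += [False] * n; donor_on += [True] * n
        else:
            E += [e] * n; fret_on += [True] * n; donor_on += [True] * n
    E = np.array(E); fret_on = np.array(fret_on); donor_on = np.array(donor_on)
    T = ACQ.total_intensity
    acceptor = np.where(fret_on, T * E, 0.0) + ACQ.background
    donor = np.where(donor_on, T * (1 - np.where(fret_on, E, 0.0)), 0.0) + ACQ.background
    n = E.size
    acq = AcquisitionParams(n_frames=n)
    return IntensityTrace(donor=donor + rng.normal(0, noise, n),
                          acceptor=acceptor + rng.normal(0, noise, n), acq=acq)


class TestDetectEvents:
    def test_planted_arrivals_found(self):
        pp = ProcessingParams(p_success=0.5, encounter_rate=0.05)
        tr = simulate_processing_trace(pp, seed=3)
        assert tr.true_events
        windows = detect_events(tr)
        assert len(windows) == len(tr.true_events)
        for w, ev in zip(windows, tr.true_events):
            assert abs(w[0] - ev["arrival_frame"]) <= 1

    def test_blank_trace_has_no_candidates(self):
        assert detect_events(_blank()) == []

    def test_single_frame_flicker_ignored(self):
        tr = _blank(seed=1)
        tr.donor[500] += 900.0
        tr.acceptor[500] += 900.0
        assert detect_events(tr) == []


class TestClassifyEvent:
    def test_canonical_successful_pattern(self):
        seg = [(50, "off"), (20, 0.45), (3, 0.65), (10, 0.85), (20, 0.5),
               (40, None), (50, "off")]
        tr = _constructed(seg, seed=2)
        (window,) = detect_events(tr)
        ev = classify_event(tr, window)
        assert ev.event_class == SUCCESSFUL
        assert ev.donor_recovery and ev.tau_ins > 0

    def test_canonical_unsuccessful_pattern(self):
        seg = [(50, "off"), (15, 0.45), (60, "off")]
        tr = _constructed(seg, seed=3)
        (window,) = detect_events(tr)
        ev = classify_event(tr, window)
        assert ev.event_class == UNSUCCESSFUL

    def test_out_of_band_binding_rejected(self):
        seg = [(50, "off"), (30, 0.1), (60, "off")]
        tr = _constructed(seg, seed=4)
        (window,) = detect_events(tr)
        assert classify_event(tr, window).event_class == REJECTED

    def test_agreement_with_simulator_ground_truth(self):
        """>=95% of ~500 simulated events are classified as generated."""
        pp = ProcessingParams(p_success=0.078)
        traces = simulate_processing_cohort(pp, n_events=500, seed=77)
        agree = total = 0
        for tr in traces:
            events = [classify_event(tr, w) for w in detect_events(tr)]
            for truth in tr.true_events:
                total += 1
                match = [e for e in events
                         if abs(e.arrival_frame - truth["arrival_frame"]) <= 2]
                if match and match[0].event_class == truth["type"]:
                    agree += 1
        assert agree / total >= 0.95


class TestCaptureSuccess:
    def _events(self, n_succ, n_fail, n_rej=0):
        out = []
        for i in range(n_succ):
            out.append(ProcessingEvent("t", 0, 10, SUCCESSFUL, tau_ins=1.0))
        for i in range(n_fail):
            out.append(ProcessingEvent("t", 0, 10, UNSUCCESSFUL))
        for i in range(n_rej):
            out.append(ProcessingEvent("t", 0, 10, REJECTED))
        return out

    def test_printed_percentages(self):
        pct, se = capture_success(self._events(78, 922))
        assert pct == pytest.approx(7.8)
        pct, _ = capture_success(self._events(37, 963))
        assert pct == pytest.approx(3.7)

    def test_zero_successes(self):
        pct, se = capture_success(self._events(0, 50))
        assert pct == 0.0 and se == 0.0

    def test_rejected_events_excluded(self):
        pct, _ = capture_success(self._events(10, 90, n_rej=100))
        assert pct == pytest.approx(10.0)

    def test_all_rejected_is_error(self):
        with pytest.raises(ValueError):
            capture_success(self._events(0, 0, n_rej=5))


class TestTailInsertionTime:
    def test_arrival_to_first_peak_arithmetic(self):
        # peak 31 frames after arrival at the default frame interval
        seg = [(100, "off"), (28, 0.45), (3, 0.7), (10, 0.85), (15, 0.5),
               (40, None), (50, "off")]
        tr = _constructed(seg, seed=5, noise=0.0)
        (window,) = detect_events(tr)
        tau = tail_insertion_time(tr, window)
        assert tau == pytest.approx(31 * 0.0517, abs=2 * 0.0517)

    def test_minimum_is_one_frame(self):
        seg = [(100, "off"), (1, 0.45), (10, 0.85), (20, 0.5), (40, None),
               (50, "off")]
        tr = _constructed(seg, seed=6, noise=0.0)
        (window,) = detect_events(tr)
        assert tail_insertion_time(tr, window) >= 0.0517

    def test_rejects_non_successful_event(self):
        ev = ProcessingEvent("t", 0, 10, UNSUCCESSFUL)
        with pytest.raises(ValueError):
            tail_insertion_time(_blank(), (0, 10), event=ev)

    def test_recovery_of_insertion_time_constant(self):
        """300 successful events at tau = 1.64 s refit within 10%."""
        pp = ProcessingParams(p_success=1.0, tau_ins_mean=1.64,
                              encounter_rate=0.05)
        traces = simulate_processing_cohort(pp, n_events=320, seed=42)
        events = [e for e in extract_events(traces)
                  if e.event_class == SUCCESSFUL]
        assert len(events) >= 300
        taus = np.array([e.tau_ins for e in events[:300]])
        assert abs(taus.mean() - 1.64) / 1.64 < 0.10


class TestSurvivalCurve:
    def test_empirical_steps(self):
        c = survival_curve([1.0, 2.0, 3.0])
        np.testing.assert_allclose(c.evaluate([0.0, 1.0, 2.0, 3.0]).ravel(),
                                   [1.0, 2 / 3, 1 / 3, 0.0])

    def test_tied_times_single_step(self):
        c = survival_curve([2.0, 2.0, 2.0])
        np.testing.assert_allclose(c.evaluate([1.9, 2.0]).ravel(), [1.0, 0.0])

    def test_glivenko_cantelli_for_exponential_sample(self, rng):
        tau = 1.5
        t = rng.exponential(tau, 5000)
        c = survival_curve(t)
        grid = np.linspace(0, 10, 200)
        sup = np.max(np.abs(c.evaluate(grid).ravel() - np.exp(-grid / tau)))
        assert sup < 0.05

    def test_monotone_non_increasing_on_random_input(self, rng):
        for _ in range(20):
            c = survival_curve(rng.exponential(1.0, rng.integers(1, 50)))
            assert np.all(np.diff(c.survival) <= 1e-12)
            assert 0.0 <= c.survival[-1] <= 1.0


def _gehan_stat(x, y):
    return np.sum(np.sign(y[None, :] - x[:, None]))


class TestGehanBreslowWilcoxon:
    def test_identical_samples_are_null(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        stat, p = gehan_breslow_wilcoxon(x, x)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_symmetric_under_group_exchange(self, rng):
        a = rng.exponential(1.0, 20)
        b = rng.exponential(2.0, 25)
        assert gehan_breslow_wilcoxon(a, b)[0] == pytest.approx(
            gehan_breslow_wilcoxon(b, a)[0], rel=1e-9)

    def test_empty_or_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            gehan_breslow_wilcoxon([], [1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError):
            gehan_breslow_wilcoxon([1.0, 2.0], [1.0, 2.0, 3.0, 4.0, 5.0])

    @pytest.mark.parametrize("n,tol", [(10, 0.05), (50, 0.02)])
    def test_p_value_against_permutation_oracle(self, n, tol):
        """Chi-squared p agrees with the permutation law of the Gehan
        statistic; at n=10 per group the asymptotic approximation is a few
        percent off, converging by n=50."""
        rng = np.random.default_rng(n)
        x = rng.exponential(1.5, n)
        y = rng.exponential(2.5, n)
        _, p = gehan_breslow_wilcoxon(x, y)
        pooled = np.concatenate([x, y])
        obs = abs(_gehan_stat(x, y))
        exceed = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if abs(_gehan_stat(perm[:n], perm[n:])) >= obs:
                exceed += 1
        assert abs(p - exceed / n_perm) <= tol
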