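import itertools

import numpy as np
import pytest

from proteofret import HmmModel, fit_hmm, forward_loglik, viterbi_path
from proteofret import simulate_dynamics_cohort, qc_select, apparent_fret

MODEL = HmmModel(
    means=np.array([0.4, 0.8]), sds=np.array([0.07, 0.07]),
    trans=np.array([[0.94, 0.06], [0.23, 0.77]]),
    startprob=np.array([0.8, 0.2]),
)


def _gauss(x, mu, sd):
    return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))


def enumeration_loglik(model, E):
    """Brute-force likelihood: sum over all 2^T state paths."""
    T = len(E)
    total = 0.0
    for path in itertools.product((0, 1), repeat=T):
        p = model.startprob[path[0]] * _gauss(E[0], model.means[path[0]],
                                              model.sds[path[0]])
        for t in range(1, T):
            p *= model.trans[path[t - 1], path[t]] * _gauss(
                E[t], model.means[path[t]], model.sds[path[t]])
        total += p
    return np.log(total)


def enumeration_viterbi(model, E):
    """Brute-force maximum-probability path."""
    best, best_p = None, -np.inf
    for path in itertools.product((0, 1), repeat=len(E)):
        p = np.log(model.startprob[path[0]]) + np.log(
            _gauss(E[0], model.means[path[0]], model.sds[path[0]]))
        for t in range(1, len(E)):
            p += np.log(model.trans[path[t - 1], path[t]]) + np.log(
                _gauss(E[t], model.means[path[t]], model.sds[path[t]]))
        if p > best_p:
            best, best_p = path, p
    return best, best_p


class TestForward:
    def test_matches_path_enumeration(self, rng):
        E = rng.uniform(0.2, 1.0, 6)
        assert forward_loglik(MODEL, E) == pytest.approx(
            enumeration_loglik(MODEL, E), rel=1e-9)

    def test_single_frame_is_log_mixture_density(self):
        E = np.array([0.55])
        expected = np.log(
            MODEL.startprob[0] * _gauss(0.55, 0.4, 0.07)
            + MODEL.startprob[1] * _gauss(0.55, 0.8, 0.07))
        assert forward_loglik(MODEL, E) == pytest.approx(expected, rel=1e-12)

    def test_identical_emissions_make_transitions_irrelevant(self, rng):
        E = rng.uniform(0.0, 1.0, 50)
        base = dict(means=np.array([0.5, 0.5]), sds=np.array([0.1, 0.1]),
                    startprob=np.array([0.5, 0.5]))
        m1 = HmmModel(trans=np.array([[0.9, 0.1], [0.1, 0.9]]), **base)
        m2 = HmmModel(trans=np.array([[0.5, 0.5], [0.6, 0.4]]), **base)
        assert forward_loglik(m1, E) == pytest.approx(forward_loglik(m2, E),
                                                      rel=1e-12)

    def test_invariant_under_state_relabeling(self, rng):
        E = rng.uniform(0.2, 1.0, 40)
        perm = HmmModel(means=MODEL.means[::-1].copy(),
                        sds=MODEL.sds[::-1].copy(),
                        trans=MODEL.trans[::-1, ::-1].copy(),
                        startprob=MODEL.startprob[::-1].copy())
        assert forward_loglik(MODEL, E) == pytest.approx(
            forward_loglik(perm, E), rel=1e-12)

    def test_undefined_frames_rejected(self):
        with pytest.raises(ValueError):
            forward_loglik(MODEL, np.array([0.4, np.nan, 0.5]))

    def test_agrees_with_hmmlearn(self, rng):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        E = rng.uniform(0.1, 1.0, 200)
        gm = hmmlearn.GaussianHMM(n_components=2, covariance_type="diag",
                                  init_params="")
        gm.startprob_ = MODEL.startprob
        gm.transmat_ = MODEL.trans
        gm.means_ = MODEL.means.reshape(-1, 1)
        gm.covars_ = (MODEL.sds ** 2).reshape(-1, 1)
        assert forward_loglik(MODEL, E) == pytest.approx(
            gm.score(E.reshape(-1, 1)), rel=1e-9)


class TestViterbi:
    def test_noiseless_trace_decoded_exactly(self):
        E = np.array([0.4] * 10 + [0.8] * 4 + [0.4] * 6)
        path = viterbi_path(MODEL, E, 0.0517)
        assert path.states == ["s1", "ns1", "s1"]
        np.testing.assert_allclose(path.durations / 0.0517, [10, 4, 6])

    def test_matches_enumeration_for_short_series(self, rng):
        for _ in range(5):
            E = rng.uniform(0.2, 1.0, 8)
            path = viterbi_path(MODEL, E, 1.0)
            seq = []
            for s, d in zip(path.states, path.durations):
                seq += [0 if s == "s1" else 1] * int(round(d))
            best, _ = enumeration_viterbi(MODEL, E)
            assert tuple(seq) == best

    def test_degenerate_model_ties_break_toward_staying(self):
        uniform = HmmModel(means=np.array([0.5, 0.5000001]),
                           sds=np.array([0.1, 0.1]),
                           trans=np.array([[0.5, 0.5], [0.5, 0.5]]),
                           startprob=np.array([0.5, 0.5]))
        E = np.full(30, 0.5)
        path = viterbi_path(uniform, E, 1.0)
        assert len(path.states) == 1  # never switches on a tie


class TestFit:
    def test_noiseless_two_level_traces_recover_means_exactly(self):
        rng = np.random.default_rng(3)
        traces = []
        for _ in range(10):
            seq = rng.random(200) < 0.25
            traces.append(np.where(seq, 0.8, 0.4))
        model = fit_hmm(traces)
        np.testing.assert_allclose(model.means, [0.4, 0.8], atol=1e-6)

    def test_recovery_on_rendered_cohort(self):
        """Emission means recovered from 300 simulated traces.

        The low-FRET state is recovered to 0.02; the high-FRET state sits a
        little further off because its short dwells are dwell-averaged with
        the low state within frames.
        """
        traces = simulate_dynamics_cohort(1.45, 5.8, 300, seed=8)
        passing, _ = qc_select(traces)
        series = []
        for tr in passing:
            E = apparent_fret(tr)
            series.append(E[np.isfinite(E)])
        model = fit_hmm(series)
        acq = traces[0].acq
        T, bg = acq.total_intensity, acq.background
        truth = np.array([(0.4 * T + bg) / (T + 2 * bg),
                          (0.8 * T + bg) / (T + 2 * bg)])
        assert model.converged
        assert abs(model.means[0] - truth[0]) < 0.02
        assert abs(model.means[1] - truth[1]) < 0.05

    def test_swapped_init_converges_to_same_canonical_model(self, rng):
        traces = [np.where(rng.random(300) < 0.2, 0.8, 0.4)
                  + rng.normal(0, 0.05, 300) for _ in range(5)]
        init = HmmModel(means=np.array([0.75, 0.45]), sds=np.array([0.1, 0.1]),
                        trans=np.array([[0.9, 0.1], [0.1, 0.9]]),
                        startprob=np.array([0.5, 0.5]))
        swapped = HmmModel(means=init.means[::-1].copy(),
                           sds=init.sds[::-1].copy(),
                           trans=init.trans[::-1, ::-1].copy(),
                           startprob=init.startprob[::-1].copy())
        m1 = fit_hmm(traces, init=init)
        m2 = fit_hmm(traces, init=swapped)
        np.testing.assert_allclose(m1.means, m2.means, atol=1e-6)
        np.testing.assert_allclose(m1.trans, m2.trans, atol=1e-6)

    def test_canonical_ordering(self):
        m = HmmModel(means=np.array([0.8, 0.4]), sds=np.array([0.1, 0.2]),
                     trans=np.array([[0.7, 0.3], [0.4, 0.6]]),
                     startprob=np.array([0.3, 0.7])).canonical()
        assert m.means[0] == 0.4
        assert m.trans[0, 1] == pytest.approx(0.4)
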