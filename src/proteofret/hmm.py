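"""Two-state Gaussian hidden Markov model for apparent-FRET idealization.

Maximum-likelihood Baum-Welch over pooled traces (shared emission and
transition parameters, per-trace forward-backward) followed by Viterbi
decoding.  State 0 is always the lower-emission state (the engagement-
competent s1 conformation); models are canonicalized to that ordering.

Numerical conventions: per-frame scaling in the forward/backward passes;
deterministic initialization (emission means at the 25th/75th percentiles of
the pooled data, 0.95 self-transition probability); EM is asserted to be
monotone in log-likelihood at every iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .simulate import StatePath

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class HmmModel:
    """Two-state Gaussian HMM parameterization.

    ``means``/``sds``: per-state emission parameters in apparent-FRET units;
    ``trans``: 2x2 per-frame transition probability matrix (rows sum to 1);
    ``startprob``: initial state distribution.
    """

    means: np.ndarray
    sds: np.ndarray
    trans: np.ndarray
    startprob: np.ndarray
    loglik: float = np.nan
    n_iter: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "sds", np.asarray(self.sds, dtype=float))
        object.__setattr__(self, "trans", np.asarray(self.trans, dtype=float))
        object.__setattr__(self, "startprob", np.asarray(self.startprob, dtype=float))
        if self.means.shape != (2,) or self.sds.shape != (2,):
            raise ValueError("exactly two states required")
        if np.any(self.sds <= 0):
            raise ValueError("emission SDs must be > 0")
        if self.trans.shape != (2, 2) or not np.allclose(self.trans.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must sum to 1")
        if not np.isclose(self.startprob.sum(), 1.0):
            raise ValueError("startprob must sum to 1")

    def canonical(self) -> "HmmModel":
        """Relabel so that state 0 has the lower emission mean (= s1)."""
        if self.means[0] <= self.means[1]:
            return self
        perm = np.array([1, 0])
        return replace(
            self,
            means=self.means[perm], sds=self.sds[perm],
            trans=self.trans[np.ix_(perm, perm)], startprob=self.startprob[perm],
        )


def _check_series(E: np.ndarray) -> np.ndarray:
    E = np.asarray(E, dtype=float)
    if E.ndim != 1 or E.size == 0:
        raise ValueError("E series must be a nonempty 1-D array")
    if not np.all(np.isfinite(E)):
        raise ValueError("E series contains undefined frames; truncate in QC first")
    return E


def _emission_probs(model: HmmModel, E: np.ndarray) -> np.ndarray:
    """(T, 2) Gaussian densities of each frame under each state."""
    z = (E[:, None] - model.means[None, :]) / model.sds[None, :]
    return np.exp(-0.5 * z * z) / (model.sds[None, :] * _SQRT2PI)


def forward_loglik(model: HmmModel, E: np.ndarray) -> float:
    """Scaled forward-algorithm log-likelihood of one E series."""
    E = _check_series(E)
    B = _emission_probs(model, E)
    alpha = model.startprob * B[0]
    c = alpha.sum()
    if c <= 0:
        return -np.inf
    ll = np.log(c)
    alpha /= c
    for t in range(1, E.size):
        alpha = (alpha @ model.trans) * B[t]
        c = alpha.sum()
        if c <= 0:
            return -np.inf
        ll += np.log(c)
        alpha /= c
    return float(ll)


def default_init(traces_E: list[np.ndarray]) -> HmmModel:
    pooled = np.concatenate([np.asarray(e, dtype=float) for e in traces_E])
    lo, hi = np.percentile(pooled, [25.0, 75.0])
    if hi - lo < 1e-6:
        hi = lo + 1e-3
    sd = max(float(pooled.std() / 2.0), 1e-3)
    return HmmModel(
        means=np.array([lo, hi]), sds=np.array([sd, sd]),
        trans=np.array([[0.95, 0.05], [0.05, 0.95]]),
        startprob=np.array([0.5, 0.5]),
    )


def _pad(traces_E: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.array([e.size for e in traces_E])
    Tmax = int(lengths.max())
    obs = np.zeros((len(traces_E), Tmax))
    valid = np.zeros((len(traces_E), Tmax), dtype=bool)
    for i, e in enumerate(traces_E):
        obs[i, : e.size] = e
        valid[i, : e.size] = True
    return obs, valid


def robust_noise_sd(traces_E: list[np.ndarray]) -> float:
    """Frame-to-frame noise estimate: median MAD of first differences.

    Within a dwell, successive apparent-FRET frames differ only by camera
    noise; the median absolute first difference (scaled by sqrt(2) * 0.6745)
    is therefore a state-transition-insensitive noise estimate.
    """
    mads = [np.median(np.abs(np.diff(e))) / (np.sqrt(2.0) * 0.6745)
            for e in traces_E if e.size > 1]
    return float(np.median(mads))


def fit_hmm(
    traces_E: list[np.ndarray],
    init: HmmModel | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    sd_cap_mult: float | None = 2.0,
) -> HmmModel:
    """Baum-Welch maximum-likelihood fit over pooled traces.

    All traces share one emission/transition parameter set; the E-step runs
    forward-backward per trace (vectorized across traces).  Iterates until
    the relative log-likelihood improvement falls below ``tol``; warns and
    flags the model if ``max_iter`` is reached first.

    Emission SDs are bounded above by ``sd_cap_mult`` times the robust
    frame-to-frame noise estimate (clipping the M-step, which is the exact
    constrained maximizer).  Frames that straddle a conformational
    transition carry dwell-averaged intermediate FRET values; without the
    bound the high-FRET state occasionally widens to absorb them, which
    corrupts the dwell statistics.  ``sd_cap_mult=None`` disables the bound.
    """
    if not traces_E:
        raise ValueError("need at least one trace")
    traces_E = [_check_series(e) for e in traces_E]
    if min(e.size for e in traces_E) < 10:
        raise ValueError("each trace must have >= 10 usable frames")
    model = (init or default_init(traces_E)).canonical()
    sd_cap = np.inf
    if sd_cap_mult is not None:
        sigma = robust_noise_sd(traces_E)
        if sigma > 1e-6:  # effectively noiseless data needs no guardrail
            sd_cap = sd_cap_mult * sigma
    obs, valid = _pad(traces_E)
    N, T = obs.shape

    prev_ll = -np.inf
    ll = -np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        ll, gamma0, gamma_sum, gamma_obs, gamma_obs2, xi_sum = _em_step(
            model, obs, valid)
        # EM must not decrease the log-likelihood (small numerical slack)
        assert ll >= prev_ll - 1e-8 * max(1.0, abs(prev_ll)), (
            f"EM log-likelihood decreased: {prev_ll} -> {ll}")
        means = gamma_obs / gamma_sum
        var = gamma_obs2 / gamma_sum - means**2
        sds = np.minimum(np.sqrt(np.clip(var, 1e-10, None)), sd_cap)
        trans = xi_sum / xi_sum.sum(axis=1, keepdims=True)
        startprob = gamma0 / gamma0.sum()
        model = HmmModel(means=means, sds=sds, trans=trans, startprob=startprob,
                         loglik=ll, n_iter=n_iter)
        if np.isfinite(prev_ll) and (ll - prev_ll) <= tol * abs(prev_ll):
            converged = True
            break
        prev_ll = ll

    if not converged:
        warnings.warn(f"Baum-Welch did not converge in {max_iter} iterations",
                      RuntimeWarning)
    return replace(model.canonical(), loglik=ll, n_iter=n_iter, converged=converged)


def _em_step(model: HmmModel, obs: np.ndarray, valid: np.ndarray):
    """One scaled forward-backward pass over all traces; returns sufficient stats."""
    N, T = obs.shape
    A = model.trans
    # emission probs; padded frames get 1.0 so they are likelihood-neutral
    z = (obs[..., None] - model.means) / model.sds
    B = np.exp(-0.5 * z * z) / (model.sds * _SQRT2PI)
    B[~valid] = 1.0

    alpha = np.empty((N, T, 2))
    c = np.empty((N, T))
    a = model.startprob * B[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ A) * B[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]
    ll = float(np.log(c[valid]).sum())

    beta = np.empty((N, T, 2))
    beta[:, T - 1] = 1.0
    xi_sum = np.zeros((2, 2))
    for t in range(T - 2, -1, -1):
        bb = B[:, t + 1] * beta[:, t + 1]
        # pair (t, t+1) contributes only where both frames are observed
        both = valid[:, t + 1]
        if np.any(both):
            w = (alpha[both, t, :, None] * A[None, :, :]
                 * (bb[both] / c[both, t + 1, None])[:, None, :])
            xi_sum += w.sum(axis=0)
        beta[:, t] = (bb @ A.T) / c[:, t + 1, None]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    gamma[~valid] = 0.0
    gamma0 = gamma[:, 0].sum(axis=0)
    gamma_sum = gamma.sum(axis=(0, 1))
    gamma_obs = (gamma * obs[..., None]).sum(axis=(0, 1))
    gamma_obs2 = (gamma * (obs**2)[..., None]).sum(axis=(0, 1))
    return ll, gamma0, gamma_sum, gamma_obs, gamma_obs2, xi_sum


def viterbi_path(
    model: HmmModel,
    E: np.ndarray,
    frame_interval: float,
    trace_id: str = "",
) -> StatePath:
    """Maximum-a-posteriori state sequence as a frame-quantized StatePath.

    Ties in the dynamic-programming maximization are broken toward staying
    in the current state.
    """
    E = _check_series(E)
    model = model.canonical()
    logB = np.log(np.clip(_emission_probs(model, E), 1e-300, None))
    logA = np.log(np.clip(model.trans, 1e-300, None))
    T = E.size
    delta = np.log(np.clip(model.startprob, 1e-300, None)) + logB[0]
    psi = np.zeros((T, 2), dtype=np.int8)
    for t in range(1, T):
        cand = delta[:, None] + logA  # cand[i, j]: from i into j
        # prefer the self-transition predecessor on ties
        stay = np.array([cand[0, 0], cand[1, 1]])
        switch = np.array([cand[1, 0], cand[0, 1]])
        take_switch = switch > stay
        psi[t] = np.where(take_switch, [1, 0], [0, 1])
        delta = np.where(take_switch, switch, stay) + logB[t]
    # final state: prefer lower index on exact ties (argmax does this)
    state = int(np.argmax(delta))
    seq = np.empty(T, dtype=np.int8)
    seq[-1] = state
    for t in range(T - 1, 0, -1):
        state = psi[t, state]
        seq[t - 1] = state

    return states_to_path(seq, frame_interval, trace_id)


def states_to_path(seq: np.ndarray, frame_interval: float, trace_id: str = "") -> StatePath:
    """Convert a per-frame 0/1 state sequence into dwell segments."""
    seq = np.asarray(seq)
    change = np.nonzero(np.diff(seq) != 0)[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [seq.size]])
    labels = ["s1" if seq[s] == 0 else "ns1" for s in starts]
    return StatePath(
        states=labels,
        entry_times=starts * frame_interval,
        exit_times=ends * frame_interval,
        frame_interval=frame_interval,
        quantized=True,
        trace_id=trace_id,
    )
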