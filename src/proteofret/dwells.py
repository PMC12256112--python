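"""Dwell-time kinetics: censored exponential fits and the K_D titration.

Idealized state paths are reduced to per-state dwell sets.  The first and
last dwell of every trace are flagged as boundary dwells; interior dwells
are complete.  Rates come from the exponential maximum-likelihood estimator:
dwells truncated on the right (photobleach or end of record) contribute
survival terms, first dwells whose exit is observed are complete
observations (the forward-recurrence time of an exponential process is
exponential with the same rate), and frame-quantized dwells are left-
truncated at one frame.  On fully uncensored, untruncated data the MLE
reduces to 1/mean.

Apparent rates from frame-quantized idealizations understate fast dynamics
(excursions shorter than about half a frame are merged away).  An explicit
two-state frame-discretization inversion is provided to map the apparent
per-frame switching probabilities back to continuous-time rates; it is exact
for a two-state chain sampled at the frame interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import optimize

if TYPE_CHECKING:  # structural use only; avoids an import cycle
    from .simulate import StatePath

FIRST_DWELL = "first-dwell"
LAST_DWELL = "last-dwell"
SINGLE_DWELL = "single-dwell"  # spans the whole record: doubly censored
INTERIOR = "interior"


class TooFewDwellsError(ValueError):
    def __init__(self, n_uncensored: int, needed: int = 10) -> None:
        self.n_uncensored = n_uncensored
        super().__init__(f"{n_uncensored} uncensored dwells; need >= {needed}")


class DegenerateFitError(RuntimeError):
    pass


@dataclass
class DwellSet:
    """Dwell durations of one state pooled over traces, with censoring flags."""

    state: str
    durations: np.ndarray
    flags: list[str]
    trace_ids: list[str]
    frame_interval: float
    quantized: bool = False

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        if len(self.flags) != self.durations.size or len(self.trace_ids) != self.durations.size:
            raise ValueError("ragged dwell set")
        bad = set(self.flags) - {FIRST_DWELL, LAST_DWELL, SINGLE_DWELL, INTERIOR}
        if bad:
            raise ValueError(f"unknown censoring flags: {bad}")
        if np.any(self.durations <= 0):
            raise ValueError("dwell durations must be > 0")

    @property
    def boundary(self) -> np.ndarray:
        """Dwells touching a record boundary (first, last or spanning)."""
        return np.array([f != INTERIOR for f in self.flags])

    @property
    def censored(self) -> np.ndarray:
        """Dwells that get survival terms in the likelihood.

        A dwell truncated on the right (photobleach / end of record) is
        right-censored.  A first dwell whose exit IS observed is kept as a
        complete observation: the forward-recurrence time of an exponential
        process is exponential with the same rate, so the residual is fully
        informative.
        """
        return np.array([f in (LAST_DWELL, SINGLE_DWELL) for f in self.flags])

    @property
    def n(self) -> int:
        return self.durations.size

    @property
    def n_uncensored(self) -> int:
        return int((~self.censored).sum())


@dataclass(frozen=True)
class RateEstimate:
    """A fitted kinetic quantity with its uncertainty."""

    estimate: float
    se: float
    n: int
    method: str
    condition: str = "unspecified"
    unit: str = "s^-1"

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("SE must be >= 0")


def extract_dwells(paths: Sequence["StatePath"], state: str) -> DwellSet:
    """Pool the dwells of ``state`` over idealized paths.

    The first and last dwell of each trace are flagged censored; only
    interior dwells have both endpoints observed.
    """
    if not paths:
        raise ValueError("no paths given")
    durations: list[float] = []
    flags: list[str] = []
    ids: list[str] = []
    quantized = all(getattr(p, "quantized", False) for p in paths)
    frame_interval = max(getattr(p, "frame_interval", 0.0) for p in paths)
    for i, p in enumerate(paths):
        tid = getattr(p, "trace_id", str(i))
        durs = p.exit_times - p.entry_times
        for j, (s, d) in enumerate(zip(p.states, durs)):
            if s != state:
                continue
            if j == 0 and j == len(p.states) - 1:
                flag = SINGLE_DWELL
            elif j == 0:
                flag = FIRST_DWELL
            elif j == len(p.states) - 1:
                flag = LAST_DWELL
            else:
                flag = INTERIOR
            durations.append(float(d))
            flags.append(flag)
            ids.append(tid)
    return DwellSet(state=state, durations=np.array(durations), flags=flags,
                    trace_ids=ids, frame_interval=frame_interval,
                    quantized=quantized)


def exponential_loglik(rate: float, d: DwellSet, censoring_mode: str = "censored",
                       t_min: float | None = None) -> float:
    """Log-likelihood of an exponential dwell model (for the grid oracle)."""
    t, cens, t_min = _prepare(d, censoring_mode, t_min)
    excess = np.clip(t - t_min, 0.0, None)
    n_u = int((~cens).sum())
    return n_u * np.log(rate) - rate * float(excess.sum())


def _prepare(d: DwellSet, censoring_mode: str, t_min: float | None):
    if censoring_mode == "censored":
        cens = d.censored
        t = d.durations
    elif censoring_mode == "naive":
        cens = np.zeros(d.n, dtype=bool)
        t = d.durations
    elif censoring_mode == "drop":
        keep = ~d.censored
        t = d.durations[keep]
        cens = np.zeros(t.size, dtype=bool)
    else:
        raise ValueError(f"unknown censoring_mode {censoring_mode!r}")
    if t_min is None:
        t_min = d.frame_interval if d.quantized else 0.0
    return t, cens, t_min


def fit_exponential(d: DwellSet, censoring_mode: str = "censored",
                    t_min: float | None = None) -> RateEstimate:
    """Censoring-aware exponential MLE for the state exit rate.

    Right-censored dwells contribute survival terms; left truncation at
    ``t_min`` (one frame for frame-quantized dwells, else zero) conditions
    on the minimum observable dwell.  Closed form:
    k = n_uncensored / sum(max(t_i - t_min, 0)); SE from the observed Fisher
    information, k / sqrt(n_uncensored).
    """
    t, cens, t_min = _prepare(d, censoring_mode, t_min)
    n_u = int((~cens).sum())
    if n_u < 10:
        raise TooFewDwellsError(n_u)
    total = float(np.clip(t - t_min, 0.0, None).sum())
    if total <= 0:
        raise DegenerateFitError("zero total excess dwell time")
    k = n_u / total
    return RateEstimate(estimate=k, se=k / np.sqrt(n_u), n=d.n,
                        method=f"exp-mle/{censoring_mode}")


def percent_change(a: RateEstimate, b: RateEstimate) -> RateEstimate:
    """Percent decrease from ``a`` to ``b``: 100 (a - b) / a, with SE."""
    if a.estimate <= 0:
        raise ValueError("reference estimate must be > 0")
    value = 100.0 * (a.estimate - b.estimate) / a.estimate
    se = 100.0 * np.hypot(b.estimate * a.se / a.estimate**2, b.se / a.estimate)
    return RateEstimate(estimate=value, se=float(se), n=min(a.n, b.n),
                        method="percent-change", unit="%")


# ---------------------------------------------------------------------------
# frame-discretization inversion
# ---------------------------------------------------------------------------

def correct_frame_discretization(
    k_app_f: RateEstimate, k_app_b: RateEstimate, frame_interval: float
) -> tuple[RateEstimate, RateEstimate]:
    """Map apparent (frame-quantized) rates to continuous-time rates.

    For a two-state chain observed every ``dt``, the per-frame switching
    probabilities are q_f = pi_ns1 (1 - e^(-lam dt)) and
    q_b = pi_s1 (1 - e^(-lam dt)) with lam = k_f + k_b.  The truncated
    exponential MLE applied to geometric dwell counts returns
    k_app = q / (dt (1 - q)), so q = k_app dt / (1 + k_app dt); then
    lam = -ln(1 - q_f - q_b) / dt and k_f = lam q_f / (q_f + q_b).
    SEs are rescaled by the correction factor.
    """
    dt = frame_interval
    qf = k_app_f.estimate * dt / (1.0 + k_app_f.estimate * dt)
    qb = k_app_b.estimate * dt / (1.0 + k_app_b.estimate * dt)
    s = qf + qb
    if not 0.0 < s < 1.0:
        raise DegenerateFitError("apparent switching probabilities saturate")
    lam = -np.log1p(-s) / dt
    k_f, k_b = lam * qf / s, lam * qb / s
    out = []
    for k, app in ((k_f, k_app_f), (k_b, k_app_b)):
        scale = k / app.estimate
        out.append(RateEstimate(estimate=float(k), se=float(app.se * scale),
                                n=app.n, method=app.method + "+frame-corrected",
                                condition=app.condition, unit=app.unit))
    return out[0], out[1]


def ctmc_rates_from_transition_matrix(
    trans: np.ndarray, frame_interval: float,
    se_rel: tuple[float, float] = (0.0, 0.0), n: int = 0,
) -> tuple[RateEstimate, RateEstimate]:
    """Continuous-time rates from a per-frame transition matrix.

    Exact 2x2 matrix logarithm of P = exp(Q dt):
    lam = -ln(1 - P01 - P10) / dt, k_f = lam P01 / (P01 + P10).
    ``se_rel`` carries relative standard errors to attach to the estimates.
    """
    dt = frame_interval
    q1, q2 = float(trans[0, 1]), float(trans[1, 0])
    s = q1 + q2
    if not 0.0 < s < 1.0:
        raise DegenerateFitError("per-frame switching probabilities saturate")
    lam = -np.log1p(-s) / dt
    k_f, k_b = lam * q1 / s, lam * q2 / s
    return (
        RateEstimate(estimate=k_f, se=k_f * se_rel[0], n=n, method="hmm-rate-matrix"),
        RateEstimate(estimate=k_b, se=k_b * se_rel[1], n=n, method="hmm-rate-matrix"),
    )


# ---------------------------------------------------------------------------
# titration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TitrationFit:
    K_D_app: RateEstimate
    k_apo: RateEstimate
    k_sat: RateEstimate
    residuals: np.ndarray
    concs: np.ndarray


def _hyperbola(c: np.ndarray, k_apo: float, k_sat: float, kd: float) -> np.ndarray:
    return k_sat + (k_apo - k_sat) * kd / (kd + c)


def fit_titration(concs: Sequence[float], rates: Sequence[RateEstimate]) -> TitrationFit:
    """Weighted least-squares fit of the rate-vs-concentration hyperbola.

    Requires at least four distinct concentrations including zero.  A flat
    response (rate spread within noise) makes K_D unidentifiable and raises
    ``DegenerateFitError``.
    """
    c = np.asarray(concs, dtype=float)
    y = np.array([r.estimate for r in rates])
    se = np.array([r.se for r in rates])
    if c.size != y.size:
        raise ValueError("concs and rates must align")
    if np.unique(c).size < 4:
        raise ValueError("need >= 4 distinct concentrations")
    if not np.any(c == 0):
        raise ValueError("titration must include zero concentration")
    spread = y.max() - y.min()
    noise = np.median(se)
    if spread < 2.0 * noise or spread == 0.0:
        raise DegenerateFitError("flat titration response; K_D unidentifiable")

    sigma = se if np.all(se > 0) else None
    p0 = (float(y[c == 0].mean()), float(y[np.argmax(c)]), float(np.median(c[c > 0])))
    try:
        popt, pcov = optimize.curve_fit(
            _hyperbola, c, y, p0=p0, sigma=sigma, absolute_sigma=sigma is not None,
            bounds=([1e-9, 1e-9, 1e-9], [np.inf, np.inf, np.inf]), maxfev=10000)
    except RuntimeError as exc:
        raise DegenerateFitError(f"titration fit failed: {exc}") from exc
    perr = np.sqrt(np.diag(pcov))
    if not np.all(np.isfinite(perr)):
        raise DegenerateFitError("unbounded parameter uncertainty")
    resid = y - _hyperbola(c, *popt)
    n = c.size
    mk = lambda est, err, unit: RateEstimate(estimate=float(est), se=float(err),
                                             n=n, method="titration-wls", unit=unit)
    return TitrationFit(K_D_app=mk(popt[2], perr[2], "uM"),
                        k_apo=mk(popt[0], perr[0], "s^-1"),
                        k_sat=mk(popt[1], perr[1], "s^-1"),
                        residuals=resid, concs=c)
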