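"""Bulk fluorescence-polarization kinetics.

Multiple-turnover degradation rates (substrates per enzyme per minute) are
extracted from FP time courses by ordinary least-squares regression of the
initial, approximately linear change in polarization, normalized by the
calibrated dynamic range (intact minus fully degraded substrate) and by the
enzyme:substrate ratio.  The same slope machinery yields initial-rate fold
changes for the deubiquitinase (Ub-TAMRA cleavage) assay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .dwells import RateEstimate


class DegenerateCalibrationError(ValueError):
    pass


@dataclass
class FpTimecourse:
    """A bulk FP recording with its calibration and concentrations.

    time in minutes, polarization in mP; ``enzyme_conc`` in nM and
    ``substrate_conc`` in uM; ``fp_intact``/``fp_degraded`` are the measured
    polarization of undegraded and fully (chymotrypsin-) degraded substrate.
    """

    time: np.ndarray
    polarization: np.ndarray
    condition: str = "unspecified"
    enzyme_conc: float = 50.0
    substrate_conc: float = 10.0
    fp_intact: float = 200.0
    fp_degraded: float = 50.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.polarization = np.asarray(self.polarization, dtype=float)
        if self.time.shape != self.polarization.shape or self.time.ndim != 1:
            raise ValueError("time and polarization must be equal-length 1-D")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not self.fp_intact > self.fp_degraded:
            raise DegenerateCalibrationError("need fp_intact > fp_degraded")

    @property
    def dynamic_range(self) -> float:
        return self.fp_intact - self.fp_degraded


def fit_initial_slope(
    tc: FpTimecourse,
    window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """OLS slope of polarization vs time over ``window``, in mP/min.

    Returns ``(slope, standard_error)``.  When ``window`` is None a
    deterministic self-consistent rule picks it: the longest prefix over
    which the provisional fit predicts at most 10% of the substrate to be
    consumed, capped at half the record.
    """
    if window is None:
        window = _auto_window(tc)
    t0, t1 = window
    if t0 < tc.time[0] - 1e-9 or t1 > tc.time[-1] + 1e-9:
        raise ValueError(f"window {window} outside data range "
                         f"[{tc.time[0]}, {tc.time[-1]}]")
    sel = (tc.time >= t0 - 1e-9) & (tc.time <= t1 + 1e-9)
    if sel.sum() < 5:
        raise ValueError(f"only {int(sel.sum())} points in window; need >= 5")
    res = stats.linregress(tc.time[sel], tc.polarization[sel])
    return float(res.slope), float(res.stderr)


def _auto_window(tc: FpTimecourse) -> tuple[float, float]:
    half = tc.time[0] + (tc.time[-1] - tc.time[0]) / 2.0
    sel = tc.time <= half + 1e-9
    prov = stats.linregress(tc.time[sel], tc.polarization[sel]).slope
    frac_per_min = abs(prov) / tc.dynamic_range
    if frac_per_min <= 0:
        return float(tc.time[0]), float(half)
    t10 = tc.time[0] + 0.1 / frac_per_min
    t1 = min(t10, half)
    # never fewer than 5 points
    if np.sum(tc.time <= t1 + 1e-9) < 5:
        t1 = float(tc.time[min(4, tc.time.size - 1)])
    return float(tc.time[0]), float(t1)


def slope_to_rate(
    slope: float,
    tc: FpTimecourse,
    slope_se: float = 0.0,
) -> RateEstimate:
    """Convert an FP slope into substrates per enzyme per minute.

    rate = |slope| / (fp_intact - fp_degraded) * [S] / [E], with [S] and [E]
    in common molar units.
    """
    if tc.dynamic_range <= 0:
        raise DegenerateCalibrationError("degenerate calibration")
    scale = (tc.substrate_conc * 1000.0 / tc.enzyme_conc) / tc.dynamic_range
    return RateEstimate(
        estimate=abs(slope) * scale,
        se=slope_se * scale,
        n=tc.time.size,
        method="fp-initial-slope",
        condition=tc.condition,
        unit="min^-1",
    )


def recover_degradation_rate(
    timecourses: Sequence[FpTimecourse],
    window: tuple[float, float] | None = None,
) -> RateEstimate:
    """Per-replicate rates, reported as mean +/- SEM across replicates."""
    if not timecourses:
        raise ValueError("no time courses given")
    rates = []
    for tc in timecourses:
        slope, se = fit_initial_slope(tc, window)
        rates.append(slope_to_rate(slope, tc, se).estimate)
    rates = np.asarray(rates)
    sem = float(rates.std(ddof=1) / np.sqrt(rates.size)) if rates.size > 1 else 0.0
    return RateEstimate(
        estimate=float(rates.mean()), se=sem, n=rates.size,
        method="fp-initial-slope", condition=timecourses[0].condition,
        unit="min^-1",
    )


def fold_change(rate_a: RateEstimate, rate_b: RateEstimate) -> RateEstimate:
    """Ratio b/a with first-order error propagation."""
    if rate_a.estimate <= 0:
        raise ValueError("reference rate must be > 0")
    ratio = rate_b.estimate / rate_a.estimate
    rel = 0.0
    if rate_a.estimate > 0 and rate_b.estimate > 0:
        rel = np.sqrt((rate_a.se / rate_a.estimate) ** 2
                      + (rate_b.se / rate_b.estimate) ** 2)
    return RateEstimate(
        estimate=ratio, se=ratio * rel, n=min(rate_a.n, rate_b.n),
        method="fold-change",
        condition=f"{rate_b.condition}/{rate_a.condition}", unit="fold",
    )


def dub_fold_stimulation(
    tc_wt: FpTimecourse | Sequence[FpTimecourse],
    tc_mut: FpTimecourse | Sequence[FpTimecourse],
) -> float:
    """Mutant/wild-type ratio of initial FP slopes (deubiquitinase assay).

    Accepts single time courses or replicate sets (slopes are averaged over
    replicates, as for technical triplicates).
    """
    def mean_slope(tcs):
        if isinstance(tcs, FpTimecourse):
            tcs = [tcs]
        fits = [fit_initial_slope(tc) for tc in tcs]
        return (float(np.mean([s for s, _ in fits])),
                float(np.mean([se for _, se in fits]) / np.sqrt(len(fits))))

    s_wt, se_wt = mean_slope(tc_wt)
    s_mut, _ = mean_slope(tc_mut)
    if abs(s_wt) <= 3.0 * se_wt:
        raise ValueError("wild-type initial slope indistinguishable from zero")
    return abs(s_mut) / abs(s_wt)
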