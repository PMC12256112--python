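"""Trace selection: intensity threshold, photobleach detection, apparent FRET.

Reproduces the trace-selection step of the experimental analysis (total
intensity threshold plus a single photobleaching step) with the manual
inspection replaced by deterministic rules:

* donor bleaching appears as a downward step in the total (donor + acceptor)
  intensity and is found by recursive binary change-point segmentation;
* acceptor bleaching leaves the total unchanged (the donor de-quenches) but
  drops the apparent FRET efficiency persistently to ~0, and is found as the
  onset of a terminal low-FRET run;
* a trace passes when its pre-bleach mean total intensity clears the
  threshold and the total shows at most one step; the usable frame range
  ends at the earliest bleach event.

QC is pure selection plus truncation: retained frame values are never
modified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import median_filter

from .simulate import IntensityTrace

log = logging.getLogger(__name__)

REASON_LOW_INTENSITY = "low-intensity"
REASON_MULTI_STEP = "multi-step"
REASON_NO_BLEACH = "no-bleach"
REASON_OTHER = "other"


@dataclass
class QcVerdict:
    trace_id: str
    passed: bool
    reason: str | None
    bleach_frames: list[int]
    usable_start: int
    usable_end: int  # exclusive


@dataclass
class QcReport:
    verdicts: list[QcVerdict] = field(default_factory=list)

    @property
    def n_pass(self) -> int:
        return sum(v.passed for v in self.verdicts)

    @property
    def n_fail(self) -> int:
        return len(self.verdicts) - self.n_pass

    def to_rows(self) -> list[dict]:
        return [
            {"trace_id": v.trace_id, "passed": int(v.passed),
             "reason": v.reason or "",
             "bleach_frames": ";".join(map(str, v.bleach_frames)),
             "usable_start": v.usable_start, "usable_end": v.usable_end}
            for v in self.verdicts
        ]


def apparent_fret(trace: IntensityTrace, floor: float | None = None) -> np.ndarray:
    """Per-frame apparent FRET efficiency E = acceptor / (acceptor + donor).

    No correction factors are applied.  Frames whose total intensity falls
    below ``floor`` (default: twice the channel background plus three times
    the total-intensity noise SD) are undefined and returned as NaN.
    """
    if trace.n_frames == 0:
        raise ValueError("empty trace")
    if floor is None:
        floor = 2.0 * trace.acq.background + 3.0 * np.sqrt(2.0) * trace.acq.noise_sd
    total = trace.total
    E = np.full(trace.n_frames, np.nan)
    ok = total >= max(floor, 1e-12)
    E[ok] = trace.acceptor[ok] / total[ok]
    return E


def _cusum_split(x: np.ndarray) -> tuple[int, float]:
    """Best single change point of the mean; returns (index, statistic).

    The statistic is |mean_left - mean_right| * sqrt(k (n-k) / n), the CUSUM
    mean-shift statistic; the split index is the first frame of the right
    segment.
    """
    n = x.size
    k = np.arange(1, n)
    cs = np.cumsum(x)
    mean_l = cs[:-1] / k
    mean_r = (cs[-1] - cs[:-1]) / (n - k)
    stat = np.abs(mean_l - mean_r) * np.sqrt(k * (n - k) / n)
    i = int(np.argmax(stat))
    return i + 1, float(stat[i])


def detect_bleach_steps(
    total: np.ndarray,
    min_step: float,
    min_segment: int = 5,
) -> list[int]:
    """Downward level shifts in a total-intensity series.

    Recursive binary segmentation: segments are split at the CUSUM-optimal
    change point while the statistic exceeds ``min_step * sqrt(min_segment)``;
    the resulting level shifts are filtered to downward steps of at least
    ``min_step``.  Returns the sorted first-frame indices of the new levels.
    """
    total = np.asarray(total, dtype=float)
    if total.size < 10:
        raise ValueError("series too short for change-point detection")
    threshold = min_step * np.sqrt(min_segment)
    cps: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        if hi - lo < 2 * min_segment:
            return
        i, stat = _cusum_split(total[lo:hi])
        if stat <= threshold:
            return
        cp = lo + i
        if cp - lo < min_segment or hi - cp < min_segment:
            return
        cps.append(cp)
        recurse(lo, cp)
        recurse(cp, hi)

    recurse(0, total.size)
    cps = sorted(cps)
    # keep only downward level shifts exceeding min_step
    bounds = [0] + cps + [total.size]
    levels = [total[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
    steps = [cp for cp, dl in zip(cps, np.diff(levels)) if dl <= -min_step]
    return steps


def detect_acceptor_bleach(
    trace: IntensityTrace,
    search_end: int | None = None,
    e_low: float = 0.2,
    min_run: int = 20,
    smooth: int = 15,
) -> int | None:
    """Onset frame of a terminal low-FRET run (acceptor photobleaching).

    Looks within [0, search_end) — typically the region before any donor
    bleach step — for the point after which the median-smoothed apparent
    FRET stays below ``e_low`` until the end of the region.  Runs shorter
    than ``min_run`` frames are ignored (they could be state dwells).
    """
    end = trace.n_frames if search_end is None else search_end
    if end < min_run:
        return None
    E = apparent_fret(trace)[:end]
    if np.all(np.isnan(E)):
        return None
    sm = median_filter(np.nan_to_num(E, nan=0.0), size=smooth, mode="nearest")
    # frames within a smoothing window of the region end carry boundary
    # artifacts (e.g. partially integrated donor-bleach frames); exclude them
    guard = max(end - smooth, 1)
    above = np.nonzero(sm[:guard] >= e_low)[0]
    onset = 0 if above.size == 0 else int(above[-1]) + 1
    if guard - onset >= min_run:
        return onset
    return None


def qc_select(
    traces: list[IntensityTrace],
    intensity_threshold: float | None = None,
    require_single_step: bool = True,
    min_step: float | None = None,
    min_usable_frames: int = 10,
) -> tuple[list[IntensityTrace], QcReport]:
    """Select analyzable traces and truncate them at the first bleach event.

    A trace passes when the total intensity shows at most one downward step,
    at least one bleach event (donor step or acceptor low-FRET onset) exists
    within the record (unless ``require_single_step`` is False), and the
    pre-bleach mean total intensity clears ``intensity_threshold``.

    Defaults tie to the simulator photophysics: threshold =
    2*background + 0.4*total_intensity; min_step = 4*noise_sd (floored at 1%
    of the nominal total for noiseless data).
    """
    report = QcReport()
    passing: list[IntensityTrace] = []
    if not traces:
        log.warning("qc_select called with no traces")
        return passing, report

    for tr in traces:
        acq = tr.acq
        thr = intensity_threshold
        if thr is None:
            thr = 2.0 * acq.background + 0.4 * acq.total_intensity
        if thr <= 0:
            raise ValueError("intensity threshold must be > 0")
        step = min_step
        if step is None:
            step = max(4.0 * acq.noise_sd, 0.01 * acq.total_intensity)

        total_steps = detect_bleach_steps(tr.total, step)
        first_total_step = total_steps[0] if total_steps else tr.n_frames
        acc = detect_acceptor_bleach(tr, search_end=first_total_step)
        bleaches = sorted(total_steps + ([acc] if acc is not None else []))

        end = bleaches[0] if bleaches else tr.n_frames
        pre_mean = tr.total[:end].mean() if end > 0 else 0.0
        if len(total_steps) >= 2:
            verdict = QcVerdict(tr.trace_id, False, REASON_MULTI_STEP,
                                bleaches, 0, 0)
        elif pre_mean < thr:
            verdict = QcVerdict(tr.trace_id, False, REASON_LOW_INTENSITY,
                                bleaches, 0, end)
        elif not bleaches and require_single_step:
            verdict = QcVerdict(tr.trace_id, False, REASON_NO_BLEACH,
                                [], 0, 0)
        elif end < min_usable_frames:
            verdict = QcVerdict(tr.trace_id, False, REASON_OTHER,
                                bleaches, 0, end)
        else:
            verdict = QcVerdict(tr.trace_id, True, None, bleaches, 0, end)
            passing.append(_truncate(tr, end))
        report.verdicts.append(verdict)
    return passing, report


def _truncate(tr: IntensityTrace, end: int) -> IntensityTrace:
    t_end = end * tr.acq.frame_interval
    acq = replace(tr.acq, n_frames=max(end, 2))
    return IntensityTrace(
        donor=tr.donor[:end].copy(),
        acceptor=tr.acceptor[:end].copy(),
        acq=acq,
        condition=tr.condition,
        ligand_conc=tr.ligand_conc,
        trace_id=tr.trace_id,
        true_path=tr.true_path.truncated(t_end) if tr.true_path is not None else None,
        donor_bleach_time=tr.donor_bleach_time,
        acceptor_bleach_time=tr.acceptor_bleach_time,
        true_events=tr.true_events,
    )
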