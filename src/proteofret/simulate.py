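"""Synthetic single-molecule and bulk data emulating the TIRF/plate-reader assays.

Generates every input the analysis pipeline consumes:

* conformational-dynamics intensity traces: a continuous-time two-state Markov
  chain rendered through camera frame integration with state-specific apparent
  FRET levels, additive Gaussian camera noise and single-step photobleaching
  of each fluorophore;
* substrate-processing traces: Poisson substrate encounters that are either
  unsuccessful (intermediate-FRET dwell, simultaneous signal loss) or
  successful (intermediate dwell, rise to a high-FRET engaged phase, gradual
  decay during translocation, extended donor-only dwell);
* bulk fluorescence-polarization time courses in the substrate-saturated
  multiple-turnover regime (linear initial decay of the intact-substrate
  fraction).

All generators are deterministic given a seed, and synthetic objects carry
their ground truth (state path, bleach times, event list) for recovery tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
import numpy as np

from .bulk import FpTimecourse

_counter = itertools.count()


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class AcquisitionParams:
    """Camera acquisition and photophysics settings.

    Defaults follow the experimental recordings: 51.7 ms frames, 2000 frames
    per movie.  Intensities are in camera counts per frame; photobleaching
    lifetimes are exponential means in seconds.
    """

    frame_interval: float = 0.0517
    n_frames: int = 2000
    total_intensity: float = 1000.0
    noise_sd: float = 60.0
    background: float = 20.0
    donor_bleach_mean: float = 80.0
    acceptor_bleach_mean: float = 80.0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not self.total_intensity > self.background >= 0:
            raise ValueError("need total_intensity > background >= 0")
        if self.donor_bleach_mean <= 0 or self.acceptor_bleach_mean <= 0:
            raise ValueError("bleach means must be > 0")

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval


@dataclass(frozen=True)
class FretLevels:
    """Apparent FRET efficiency of the two conformational states."""

    E_s1: float = 0.4
    E_ns1: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.E_s1 < self.E_ns1 <= 1.0):
            raise ValueError("need 0 <= E_s1 < E_ns1 <= 1")


@dataclass(frozen=True)
class ProcessingParams:
    """Ground-truth parameters of the substrate-processing assay generator.

    ``tau_ins_mean`` is the exponential mean of the tail-insertion time,
    defined end to end: from substrate arrival (donor appearance) to the first
    high-FRET peak, the quantity the extractor measures.  Dwell means carry
    small floors (``min_bound_dwell``, ``min_post_dwell``) reflecting the
    shortest events a frame-based recording can score.
    """

    encounter_rate: float = 0.05
    p_success: float = 0.037
    E_bind: float = 0.45
    E_high: float = 0.85
    tau_ins_mean: float = 1.64
    high_dwell_mean: float = 0.5
    decay_duration_mean: float = 2.0
    post_dwell_mean: float = 5.0
    unsuccessful_dwell_mean: float = 1.0
    ramp_frames: int = 3
    min_bound_dwell: float = 0.3
    min_post_dwell: float = 1.0
    arrival_window_frac: float = 0.6

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_success <= 1.0):
            raise ValueError("p_success must be in [0, 1]")
        for name in ("encounter_rate", "tau_ins_mean", "high_dwell_mean",
                     "decay_duration_mean", "post_dwell_mean",
                     "unsuccessful_dwell_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.E_bind < self.E_high:
            raise ValueError("E_bind must be < E_high")


@dataclass(frozen=True)
class BulkAssayParams:
    """Parameters of the bulk FP degradation / deubiquitination generator.

    ``rate_per_enzyme`` is in substrates per enzyme per minute; the intact
    fraction declines at ``rate_per_enzyme * enzyme_conc / substrate_conc``
    per minute (zero-order, substrate-saturated regime), floored at zero.
    """

    enzyme_conc: float = 50.0       # nM
    substrate_conc: float = 10.0    # uM
    rate_per_enzyme: float = 0.25   # min^-1
    fp_intact: float = 200.0        # mP
    fp_degraded: float = 50.0       # mP
    fp_noise_sd: float = 1.0        # mP
    sample_interval: float = 0.5    # min
    duration: float = 60.0          # min

    def __post_init__(self) -> None:
        if self.enzyme_conc <= 0 or self.substrate_conc <= 0:
            raise ValueError("concentrations must be > 0")
        if not self.fp_intact > self.fp_degraded:
            raise ValueError("need fp_intact > fp_degraded")
        if self.rate_per_enzyme < 0:
            raise ValueError("rate_per_enzyme must be >= 0")


@dataclass
class StatePath:
    """Idealized alternating state trajectory.

    Simulated paths have exact event times (``quantized=False``); Viterbi
    idealizations carry frame-quantized times (``quantized=True`` with the
    originating ``frame_interval``).
    """

    states: list[str]
    entry_times: np.ndarray
    exit_times: np.ndarray
    frame_interval: float = 0.0
    quantized: bool = False
    trace_id: str = ""

    def __post_init__(self) -> None:
        self.entry_times = np.asarray(self.entry_times, dtype=float)
        self.exit_times = np.asarray(self.exit_times, dtype=float)
        if len(self.states) != len(self.entry_times) or len(self.states) != len(self.exit_times):
            raise ValueError("ragged state path")
        if np.any(self.exit_times <= self.entry_times):
            raise ValueError("dwell durations must be > 0")
        if len(self.states) > 1:
            if not np.allclose(self.exit_times[:-1], self.entry_times[1:]):
                raise ValueError("segments must be contiguous")
            if any(a == b for a, b in zip(self.states[:-1], self.states[1:])):
                raise ValueError("states must alternate")

    @property
    def duration(self) -> float:
        return float(self.exit_times[-1] - self.entry_times[0])

    @property
    def durations(self) -> np.ndarray:
        return self.exit_times - self.entry_times

    def fraction_in(self, state: str) -> float:
        mask = np.array([s == state for s in self.states])
        return float(self.durations[mask].sum() / self.duration)

    def n_transitions(self) -> int:
        return len(self.states) - 1

    def truncated(self, t_end: float) -> "StatePath":
        """Portion of the path on [0, t_end)."""
        keep = self.entry_times < t_end
        states = [s for s, k in zip(self.states, keep) if k]
        entry = self.entry_times[keep]
        exit_ = np.minimum(self.exit_times[keep], t_end)
        return StatePath(states, entry, exit_, frame_interval=self.frame_interval,
                         quantized=self.quantized, trace_id=self.trace_id)


@dataclass
class IntensityTrace:
    """Per-molecule donor/acceptor time series plus acquisition metadata.

    Synthetic traces carry ground-truth annotations (``true_path``, bleach
    times, ``true_events``) that real recordings would not have.
    """

    donor: np.ndarray
    acceptor: np.ndarray
    acq: AcquisitionParams
    condition: str = "unspecified"
    ligand_conc: float = 0.0
    trace_id: str = ""
    true_path: StatePath | None = None
    donor_bleach_time: float | None = None
    acceptor_bleach_time: float | None = None
    true_events: list[dict] | None = None

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape or self.donor.ndim != 1:
            raise ValueError("donor/acceptor series must be equal-length 1-D")
        if not (np.all(np.isfinite(self.donor)) and np.all(np.isfinite(self.acceptor))):
            raise ValueError("counts must be finite")
        if not self.trace_id:
            self.trace_id = f"trace{next(_counter):06d}"

    @property
    def n_frames(self) -> int:
        return self.donor.size

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.n_frames)

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor

    def first_bleach_frame(self) -> int | None:
        """Ground-truth frame of the earliest bleach event, if within record."""
        times = [t for t in (self.donor_bleach_time, self.acceptor_bleach_time)
                 if t is not None]
        if not times:
            return None
        t = min(times)
        if t >= self.acq.duration:
            return None
        return int(t / self.acq.frame_interval)


# ---------------------------------------------------------------------------
# conformational dynamics
# ---------------------------------------------------------------------------

def simulate_state_path(
    k_f: float,
    k_b: float,
    duration: float,
    initial_state: str | None = None,
    seed: int | np.random.Generator | None = None,
) -> StatePath:
    """Continuous-time two-state Markov chain via exponential waiting times.

    ``initial_state`` may be ``"s1"``, ``"ns1"`` or None (drawn from the
    stationary distribution).  Event times are exact, not frame-quantized.
    """
    if k_f <= 0 or k_b <= 0:
        raise ValueError("rates must be > 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = _rng(seed)
    if initial_state is None:
        p_s1 = k_b / (k_f + k_b)
        state = "s1" if rng.random() < p_s1 else "ns1"
    elif initial_state in ("s1", "ns1"):
        state = initial_state
    else:
        raise ValueError("initial_state must be 's1' or 'ns1'")

    states: list[str] = []
    entries: list[float] = []
    exits: list[float] = []
    t = 0.0
    while t < duration:
        rate = k_f if state == "s1" else k_b
        dwell = rng.exponential(1.0 / rate)
        states.append(state)
        entries.append(t)
        exits.append(min(t + dwell, duration))
        t += dwell
        state = "ns1" if state == "s1" else "s1"
    return StatePath(states, np.array(entries), np.array(exits))


def _frame_integral(breaks: np.ndarray, values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Per-frame integral of a piecewise-constant function.

    ``breaks``: boundaries (len n+1), ``values``: value on each piece (len n),
    ``edges``: frame edges.  Returns the integral over each [edge_i, edge_i+1].
    """
    cum = np.concatenate([[0.0], np.cumsum(values * np.diff(breaks))])
    at_edges = np.interp(edges, breaks, cum)
    return np.diff(at_edges)


def render_fret_trace(
    path: StatePath,
    levels: FretLevels = FretLevels(),
    acq: AcquisitionParams = AcquisitionParams(),
    seed: int | np.random.Generator | None = None,
    donor_bleach_time: float | None = None,
    acceptor_bleach_time: float | None = None,
    condition: str = "unspecified",
    ligand_conc: float = 0.0,
) -> IntensityTrace:
    """Render a state path into a camera-integrated donor/acceptor trace.

    Per-frame apparent FRET is the dwell-time-weighted mean of the state
    levels within the frame.  Acceptor bleaching sends the full intensity to
    the donor channel; donor bleaching drops both channels to background.
    Bleach times default to exponential draws from the acquisition params
    (``np.inf`` disables a channel's bleaching).
    """
    if path.duration + 1e-9 < acq.duration:
        raise ValueError("state path shorter than the acquisition window")
    rng = _rng(seed)
    if donor_bleach_time is None:
        donor_bleach_time = float(rng.exponential(acq.donor_bleach_mean))
    if acceptor_bleach_time is None:
        acceptor_bleach_time = float(rng.exponential(acq.acceptor_bleach_mean))

    dt = acq.frame_interval
    edges = np.arange(acq.n_frames + 1) * dt
    breaks = np.concatenate([[path.entry_times[0]], path.exit_times])
    E_vals = np.array([levels.E_s1 if s == "s1" else levels.E_ns1 for s in path.states])

    # time of FRET loss for the acceptor channel, and of total signal loss
    t_fret = min(donor_bleach_time, acceptor_bleach_time)
    t_dark = donor_bleach_time

    # integral of E(t) restricted to t < t_fret, per frame
    e_int = _frame_integral(breaks, E_vals, np.minimum(edges, t_fret))
    # live fractions per frame
    live_fret = np.diff(np.minimum(edges, t_fret))            # FRET pair alive
    live_donor = np.diff(np.minimum(edges, t_dark))           # donor alive
    donor_only = live_donor - live_fret                        # acceptor dark, donor alive

    T = acq.total_intensity
    acceptor = (T * e_int) / dt + acq.background
    donor = (T * (live_fret - e_int) + T * donor_only) / dt + acq.background

    acceptor = acceptor + rng.normal(0.0, acq.noise_sd, acq.n_frames)
    donor = donor + rng.normal(0.0, acq.noise_sd, acq.n_frames)

    return IntensityTrace(
        donor=donor,
        acceptor=acceptor,
        acq=acq,
        condition=condition,
        ligand_conc=ligand_conc,
        true_path=path.truncated(acq.duration),
        donor_bleach_time=donor_bleach_time,
        acceptor_bleach_time=acceptor_bleach_time,
    )


def add_second_emitter(
    trace: IntensityTrace,
    intensity: float,
    bleach_time: float,
    seed: int | np.random.Generator | None = None,
) -> IntensityTrace:
    """Superimpose a second donor fluorophore bleaching at ``bleach_time``.

    Produces the multi-step photobleaching signature of aggregates or
    multiply labeled complexes, for QC rejection tests.
    """
    rng = _rng(seed)
    dt = trace.acq.frame_interval
    edges = np.arange(trace.n_frames + 1) * dt
    live = np.diff(np.minimum(edges, bleach_time)) / dt
    extra = intensity * live + rng.normal(0.0, trace.acq.noise_sd, trace.n_frames)
    out = replace(trace, donor=trace.donor + extra, trace_id="")
    return out


def simulate_dynamics_trace(
    k_f: float,
    k_b: float,
    acq: AcquisitionParams = AcquisitionParams(),
    levels: FretLevels = FretLevels(),
    seed: int | np.random.Generator | None = None,
    condition: str = "unspecified",
    ligand_conc: float = 0.0,
) -> IntensityTrace:
    """Convenience: simulate a state path and render it in one call."""
    rng = _rng(seed)
    path = simulate_state_path(k_f, k_b, acq.duration + acq.frame_interval, seed=rng)
    return render_fret_trace(path, levels, acq, seed=rng,
                             condition=condition, ligand_conc=ligand_conc)


def simulate_dynamics_cohort(
    k_f: float,
    k_b: float,
    n_traces: int,
    acq: AcquisitionParams = AcquisitionParams(),
    levels: FretLevels = FretLevels(),
    seed: int | np.random.Generator | None = None,
    condition: str = "unspecified",
    ligand_conc: float = 0.0,
) -> list[IntensityTrace]:
    rng = _rng(seed)
    return [
        simulate_dynamics_trace(k_f, k_b, acq, levels, rng,
                                condition=condition, ligand_conc=ligand_conc)
        for _ in range(n_traces)
    ]


# ---------------------------------------------------------------------------
# substrate processing
# ---------------------------------------------------------------------------

def _bounded_exp(rng: np.random.Generator, mean: float, floor: float) -> float:
    """Exponential dwell with a hard floor, preserving the requested mean.

    Draws ``floor + Exp(mean - floor)`` when the mean allows, otherwise
    clamps at the floor.
    """
    if mean > floor:
        return floor + float(rng.exponential(mean - floor))
    return floor


def simulate_processing_trace(
    pp: ProcessingParams = ProcessingParams(),
    acq: AcquisitionParams = AcquisitionParams(),
    seed: int | np.random.Generator | None = None,
    condition: str = "unspecified",
) -> IntensityTrace:
    """One substrate-processing movie with Poisson substrate encounters.

    Successful encounters render: intermediate-FRET dwell, linear ramp to the
    high-FRET engaged level (the ramp occupies the final ``ramp_frames`` of
    the insertion interval, so the first high-FRET peak falls at
    arrival + tau_ins), high-FRET dwell, linear FRET decay with donor
    recovery, then an extended donor-only dwell.  Unsuccessful encounters
    render an intermediate-FRET dwell ending in simultaneous loss of both
    signals.  The ground-truth event list is attached to the trace.
    """
    rng = _rng(seed)
    dt = acq.frame_interval
    n = acq.n_frames
    t_mid = (np.arange(n) + 0.5) * dt
    E = np.zeros(n)
    fret_on = np.zeros(n, dtype=bool)
    donor_on = np.zeros(n, dtype=bool)
    events: list[dict] = []

    ramp = pp.ramp_frames * dt
    # Arrivals are confined to the early part of the record so that every
    # scored encounter runs to completion within the movie.  Without this,
    # end-of-record truncation thins long (successful) events preferentially
    # and length-biases the capture-success statistic.
    arrival_cutoff = pp.arrival_window_frac * acq.duration
    t = float(rng.exponential(1.0 / pp.encounter_rate))
    while t < arrival_cutoff:
        success = rng.random() < pp.p_success
        if success:
            tau_ins = max(float(rng.exponential(pp.tau_ins_mean)), ramp + dt)
            t_high = float(rng.exponential(pp.high_dwell_mean))
            t_decay = max(float(rng.exponential(pp.decay_duration_mean)), dt)
            t_post = _bounded_exp(rng, pp.post_dwell_mean, pp.min_post_dwell)
            t_end = t + tau_ins + t_high + t_decay + t_post
        else:
            dwell = _bounded_exp(rng, pp.unsuccessful_dwell_mean, pp.min_bound_dwell)
            t_end = t + dwell
        if t_end >= acq.duration:
            break  # drop encounters truncated by the end of the movie

        sel = (t_mid >= t) & (t_mid < t_end)
        if success:
            rel = t_mid[sel] - t
            e = np.empty(rel.size)
            # intermediate binding dwell, then ramp to the engaged level
            e[:] = pp.E_bind
            in_ramp = (rel >= tau_ins - ramp) & (rel < tau_ins)
            e[in_ramp] = pp.E_bind + (pp.E_high - pp.E_bind) * (
                (rel[in_ramp] - (tau_ins - ramp)) / ramp)
            in_high = (rel >= tau_ins) & (rel < tau_ins + t_high)
            e[in_high] = pp.E_high
            in_decay = (rel >= tau_ins + t_high) & (rel < tau_ins + t_high + t_decay)
            e[in_decay] = pp.E_high * (1.0 - (rel[in_decay] - tau_ins - t_high) / t_decay)
            in_post = rel >= tau_ins + t_high + t_decay
            e[in_post] = 0.0
            E[sel] = e
            fret_on[sel] = ~in_post
            donor_on[sel] = True
        else:
            E[sel] = pp.E_bind
            fret_on[sel] = True
            donor_on[sel] = True

        arrival_frame = int(t / dt)
        end_frame = int(t_end / dt)
        events.append({
            "type": "successful" if success else "unsuccessful",
            "arrival_time": t,
            "arrival_frame": arrival_frame,
            "end_frame": end_frame,
            "tau_ins": tau_ins if success else None,
        })
        t = t_end + float(rng.exponential(1.0 / pp.encounter_rate))

    T = acq.total_intensity
    acceptor = np.where(fret_on, T * E, 0.0) + acq.background
    donor = np.where(donor_on, T * (1.0 - np.where(fret_on, E, 0.0)), 0.0) + acq.background
    acceptor = acceptor + rng.normal(0.0, acq.noise_sd, n)
    donor = donor + rng.normal(0.0, acq.noise_sd, n)

    return IntensityTrace(
        donor=donor, acceptor=acceptor, acq=acq, condition=condition,
        true_events=events,
    )


def simulate_processing_cohort(
    pp: ProcessingParams,
    acq: AcquisitionParams = AcquisitionParams(),
    n_events: int = 1000,
    seed: int | np.random.Generator | None = None,
    condition: str = "unspecified",
) -> list[IntensityTrace]:
    """Simulate processing traces until at least ``n_events`` encounters."""
    rng = _rng(seed)
    traces: list[IntensityTrace] = []
    total = 0
    while total < n_events:
        tr = simulate_processing_trace(pp, acq, rng, condition=condition)
        traces.append(tr)
        total += len(tr.true_events or [])
    return traces


# ---------------------------------------------------------------------------
# bulk fluorescence polarization
# ---------------------------------------------------------------------------

def simulate_fp_timecourse(
    bp: BulkAssayParams = BulkAssayParams(),
    seed: int | np.random.Generator | None = None,
    condition: str = "unspecified",
) -> FpTimecourse:
    """Multiple-turnover FP time course in the zero-order regime.

    The intact-substrate fraction falls linearly at
    ``rate_per_enzyme * enzyme_conc / substrate_conc`` per minute (floored at
    zero); FP interpolates between the intact and fully degraded calibration
    levels, plus Gaussian read noise.
    """
    rng = _rng(seed)
    t = np.arange(0.0, bp.duration + 1e-9, bp.sample_interval)
    consumption = bp.rate_per_enzyme * (bp.enzyme_conc / 1000.0) / bp.substrate_conc
    frac = np.clip(1.0 - consumption * t, 0.0, 1.0)
    fp = bp.fp_degraded + (bp.fp_intact - bp.fp_degraded) * frac
    if bp.fp_noise_sd > 0:
        fp = fp + rng.normal(0.0, bp.fp_noise_sd, t.size)
    return FpTimecourse(
        time=t, polarization=fp, condition=condition,
        enzyme_conc=bp.enzyme_conc, substrate_conc=bp.substrate_conc,
        fp_intact=bp.fp_intact, fp_degraded=bp.fp_degraded,
    )
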