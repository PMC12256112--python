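# Methods

`proteofret` re-implements, as tested library code, the single-molecule FRET
and bulk fluorescence-polarization analyses used to characterize how
ubiquitin binding to the proteasomal deubiquitinase Rpn11 stabilizes the
26S proteasome's engagement-competent (s1) conformation.  No raw recordings
are publicly deposited, so every pipeline stage is validated by parameter
recovery against a synthetic-data generator that emulates the acquisition.

## The two-state conformational model

The substrate-free proteasome interconverts between the engagement-competent
s1 state (apparent FRET ~0.4 in the Rpn9/Rpt5 labeling geometry) and an
aggregate of processing-competent non-s1 states (~0.8).  Both transitions
are modeled as single-exponential:

* `k_f` — s1 → non-s1 rate; wild-type apo default 1.45 s⁻¹.
* `k_b` — non-s1 → s1 rate; default 5.8 s⁻¹ (4 × `k_f`, matching the ~4-fold
  asymmetry that keeps the resting enzyme ~80% in s1).

Ubiquitin-chain binding slows only the forward transition.  The titration
model is a single-site hyperbola in free ligand concentration,
`k_f(c) = k_sat + (k_apo − k_sat)·K_D/(K_D + c)` with `K_D ≈ 3.1 µM` for
K48-linked tetraubiquitin; ligand depletion is ignored because the
immobilized proteasome (≤1 nM) is vastly sub-stoichiometric to the µM
ligand.  Measured condition rates (e.g. 0.45 s⁻¹ at 10 µM chains) are
stored per condition rather than being forced onto the hyperbola; the
isotherm is used only by the titration generator and fitter.  Conditions
whose rates are not numerically published (receptor-mutant panels) carry
representative values flagged `representative` in
`src/proteofret/data/paper_defaults.json`.

## Synthetic data generation

**Conformational dynamics.** A continuous-time two-state Markov chain is
drawn with exact exponential waiting times, then rendered through camera
frame integration: each frame's ideal FRET is the dwell-time-weighted mean
of the state levels within the 51.7 ms frame (2000 frames per movie).
Channels are `acceptor = T·E + bg`, `donor = T·(1−E) + bg` with additive
Gaussian camera noise per channel (default total intensity 1000, noise SD
60, background 20 counts/frame — levels typical of EMCCD smFRET recordings;
a Poisson model was judged unnecessary for recovery testing).  Each
fluorophore photobleaches in a single step with an exponential lifetime
(default 80 s per dye): acceptor bleaching redirects the full intensity to
the donor channel; donor bleaching drops both channels to background.
Ground truth (state path, bleach times) rides along on the trace object.

**Substrate processing.** Encounters arrive as a Poisson process and are
Bernoulli-successful with probability `p_success` (wild type: 0.037 without
and 0.078 with Ub₄ chains).  Successful events render an intermediate-FRET
binding dwell (E ≈ 0.45, a free choice — the intermediate level is not
published numerically), a 3-frame linear ramp to the engaged high-FRET
level (0.85), a short high dwell, a linear FRET decay with donor recovery
(translocation), and an extended donor-only dwell.  The tail-insertion time
`τ_ins` is defined end to end — arrival to first high-FRET peak — so the
ramp occupies the final frames of the insertion interval and the measured
quantity is exponential with the requested mean (1.64 s / 1.39 s defaults).
Unsuccessful events render the intermediate dwell and end with simultaneous
loss of both signals.  Two deliberate regularizations keep the scored
population unbiased: (i) bound dwells carry a 0.3 s floor and the donor-only
dwell a 1 s floor, the shortest events a frame-based recording can score;
(ii) arrivals are confined to the first 60% of the record so every scored
encounter completes — without this, end-of-record truncation removes long
(successful) events preferentially and length-biases capture success
downward by ~0.6 percentage points.

**Bulk FP.** Multiple-turnover degradation operates in the zero-order,
substrate-saturated regime: the intact fraction falls linearly at
`rate · [E]/[S]` per minute (50 nM enzyme, 10 µM substrate), floored at
zero; polarization interpolates between calibrated intact (200 mP) and
fully-degraded (50 mP) levels with 1 mP Gaussian read noise at 0.5 min
sampling.  Michaelis-Menten curvature is out of scope.  The deubiquitinase
(Ub-TAMRA cleavage) assay reuses the same machinery at 0.5 µM enzyme /
100 µM substrate with 0.2 min sampling.

## Trace QC

Apparent FRET is `acceptor/(acceptor+donor)` with no correction factors;
frames whose total falls below `2·bg + 3·√2·noise` are undefined.  The
manual trace selection of the experimental workflow is replaced by
deterministic rules: donor bleaching is found by recursive binary CUSUM
segmentation of the total-intensity series (threshold `min_step·√min_seg`,
`min_step = 4·noise SD`, keeping downward shifts only); acceptor bleaching
— invisible in the total because the donor de-quenches — is found as the
onset of a terminal run of smoothed FRET below 0.2 lasting ≥20 frames,
excluding one 15-frame smoothing window before the search end (boundary
frames next to a donor-bleach step otherwise mask the run; this exclusion
matters — leaked E≈0 tails measurably corrupt the downstream HMM fit).  A
trace passes when the total shows at most one step, at least one bleach
event lies within the record, and the pre-bleach mean total clears the
intensity threshold (default `2·bg + 0.4·T`, tied to the simulator because
the experimental threshold is unpublished).  Passing traces are truncated
at the first bleach; retained values are never altered.

## HMM idealization and rate estimation

A two-state Gaussian-emission hidden Markov model is fitted by pooled
maximum-likelihood Baum-Welch (shared parameters, per-trace scaled
forward-backward), replacing the variational-Bayes ebFRET step of the
original workflow — for two well-separated states and dwell-time readout,
ML is adequate and simpler.  Initialization is deterministic (means at the
25th/75th percentiles of pooled FRET, self-transition 0.95); convergence at
relative ΔLL < 1e-6, max 500 iterations; the log-likelihood is asserted
non-decreasing at every iteration.  Emission SDs are bounded above by twice
a robust frame-to-frame noise estimate (median MAD of first differences):
frames straddling a transition carry dwell-averaged intermediate FRET, and
without the bound one state occasionally widens to absorb them.  Clipping
the M-step is the exact constrained maximizer, so EM monotonicity is
preserved.  State 0 is canonically the lower-mean (s1) state.  Viterbi
decoding breaks ties toward staying in the current state.

Dwell sets pool per-state segment durations with boundary flags.  The
exponential MLE treats right-truncated dwells (bleach/record end) as
censored survival terms, keeps first dwells whose exit is observed as
complete observations (the forward-recurrence time of an exponential
process is exponential with the same rate — discarding them biases short
records by >15%), and left-truncates frame-quantized dwells at one frame:
`k = n_uncensored / Σ max(t − t_min, 0)`, SE `k/√n_uncensored` from the
observed Fisher information.  These are the *apparent* rates, the values a
dwell-histogram exponential fit reports.

Frame quantization compresses apparent rates (a 51.7 ms frame misses
excursions shorter than about half a frame; at `k_b·Δt ≈ 0.3` the mean
non-s1 dwell is only ~3 frames).  Two corrections are provided:
`correct_frame_discretization` inverts the truncated-MLE/geometric
relationship for a point-sampled chain, and the pipeline's headline rates
invert the EM per-frame transition matrix through the exact 2×2 matrix
logarithm (`λ = −ln(1−P01−P10)/Δt`, `k_f = λ·P01/(P01+P10)`).  The
expected-count transition matrix is preferred because hard-path decoding
suppresses one-to-two-frame dwells, while Baum-Welch integrates over state
uncertainty; in recovery scans over 24 cohorts (four conditions, 60- and
300-trace sizes, three seeds) the headline `k_f` lands within −7…+6% of
truth.  **Known limitation:** `k_b` remains compressed by ~12% on average
under every estimator tried — transition-blurred frames are not fully
separable by a two-state model at this frame rate — so recovery tests hold
`k_f` to 10% and `k_b` to 15%.  A full missed-event (blur-aware) likelihood
could remove this but is deliberately out of scope, matching the
apparent-rate convention of the original analysis.

## Processing-event analysis

Candidate events are contiguous runs of elevated total intensity (donor
appearance colocalized with acceptor signal), minimum 3 frames.  The manual
scoring is replaced by a band state machine on 3-frame-median-smoothed
FRET: medium band [0.30, 0.60], high band ≥0.70, FRET-lost level 0.20,
minimum donor-only dwell 10 frames — bands centered on the ~0.4/~0.8 levels;
all configurable.  An event reaching the high band with a medium-band
prefix and an extended terminal donor-only run is successful; one that
stays in the medium band and ends in simultaneous signal loss is
unsuccessful; everything else is rejected and excluded from both numerator
and denominator of capture success (successful / (successful +
unsuccessful), binomial SE).  On simulated cohorts at default photophysics
the classifier agrees with ground-truth labels on >99% of events.

The tail-insertion time is the first local maximum of smoothed FRET inside
the high band, relative to the window start (minimum one frame; measured
extraction offset at default noise: +0.4 frame).  Times are summarized both
as the exponential-MLE time constant (primary) and the distribution mean,
and treated as uncensored — events bleaching mid-insertion classify as
rejected rather than censored, a simplification that slightly favors short
events but is negligible at the default photophysics.  Survival curves are
empirical 1−CDF; conditions are compared with the Gehan-Breslow-Wilcoxon
weighted log-rank test (weights = number at risk, χ²₁ p value) via
`lifelines`; a 10⁴-permutation oracle and a type-I-error simulation at the
published group sizes (96 vs 104) validate it in the tests.  At 10 events
per group the χ² approximation deviates from the permutation law by a few
percent; agreement tightens to <0.02 by n = 50.

## Bulk FP analysis

Rates come from OLS regression of polarization against time over an initial
window, normalized by the calibrated dynamic range and the
enzyme:substrate ratio: `rate = |slope|/(FP_intact − FP_degraded) · [S]/[E]`
in substrates·enzyme⁻¹·min⁻¹.  The regression window is chosen
deterministically and self-consistently: the longest prefix over which a
provisional fit predicts ≤10% substrate consumption, capped at half the
record, never fewer than five points (the experimental window is
unpublished).  Replicates are fitted individually and reported as
mean ± SEM, matching the triplicate design.  Deubiquitinase fold changes
are ratios of replicate-averaged initial slopes.

## What passing tests do and do not show

The generator reproduces the features the pipeline is sensitive to — state
switching statistics, frame integration, photobleaching, event phase
structure, zero-order FP decay — but not spectral crosstalk, gamma factors,
donor blinking, baseline drift, non-Gaussian EMCCD noise, or
Michaelis-Menten curvature.  Recovery therefore demonstrates the
correctness of the estimators under the stated acquisition model, not
robustness to every artifact of real recordings.  Problem sizes in the
recovery tests (60–300 traces, 2000 frames; 300–4000 events; triplicate FP
curves) were chosen to match the scale of the original experiments
(≥200 traces, >2,900 transitions, ~1000 encounters per condition).
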