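# Methods

`ribofret` reconstructs, as testable code, the analysis chain used in
single-molecule FRET studies of EF-G-catalysed tRNA translocation on the
bacterial ribosome, together with a trace simulator that provides ground
truth for every stage. This note records the models, the parameter
choices, the numerical decisions, and the places where the design was
genuinely open.

## The physical picture

A donor dye (Cy3) on ribosomal protein L11 and an acceptor (Cy5) on the
A-site peptidyl-tRNA (or, for the tt-FRET pair, on the two tRNAs) report
the tRNA's position through the FRET efficiency E = I_A / (I_D + I_A).
Four canonical Lt-FRET states appear across conditions: 0.8 (classical
PRE), 0.6 (hybrid PRE), 0.4 (a chimeric translocation intermediate
stalled by EF-G variants) and 0.2 (POST). Conditions differ in which
states are populated, what fraction of complexes is static, and the
transition rates (all in the 1-8 /s range).

## Synthetic traces

Conformational dynamics are a continuous-time Markov chain over the
condition's states, simulated by the Gillespie algorithm. Static
complexes are frozen in a state drawn from the scheme's initial
distribution; the PRE condition uses a static fraction of 0.5. The
factor-free PRE exchange rates are not tabulated anywhere; 3 /s in each
direction reproduces the observed roughly equal classical/hybrid
occupancy and sits inside the measured 1-8 /s range. Translocation with
wild-type EF-G is modelled as a 30 /s decay to the 0.2 state (complete
within about one 33 ms frame).

Rendering integrates the state path over camera frames (mid-frame
transitions produce occupancy-weighted FRET), then emits

    donor    = B * (1 - E_t) + N(0, sigma)
    acceptor = B * E_t + beta * donor_signal + N(0, sigma)

with brightness B = 1000 counts/frame, detector noise sigma = 60 counts
and bleed-through beta = 0.13. Channel noise alone yields a FRET spread
of only ~0.05, far below the published state SDs (0.08-0.12), so the
dominant spread is modelled explicitly: a per-frame Gaussian FRET jitter
with the occupied state's SD, applied anticorrelated between the
channels (as dye-environment fluctuations are). This same jitter is what
makes static traces pass the anti-correlation screen, as in experiment.
Photobleaching is a single exponential step per dye (0.05 /s each, so
0.1 /s combined and a ~10 s mean analyzable trace within the 33 s
window); donor bleach darkens both channels, acceptor bleach de-quenches
the donor. Blinking is off by default. What the simulator does *not*
emulate: baseline drift, multi-step partial bleaching of real
multi-fluorophore spots (available only as constructed fixtures),
non-exponential dye photophysics, and the apparatus-specific trace
selection of a real TIRF field. Passing tests therefore validate the
analysis logic under idealized photophysics, not instrument robustness.

## Quality control

Order of operations: bleed-through correction, bleach detection and
truncation, lifetime/step selection, anti-correlation screen, 3-point
smoothing, FRET calculation. Truncation precedes smoothing so a bleach
step is never smeared into the analyzed window (the difference is
confined to one frame at the cut).

Bleach detection compares 5-frame window means; a candidate step must
drop by more than 4 standard errors of the windowed mean at the detector
noise floor (estimated as the minimum windowed difference-based SD,
which finds the post-bleach background when one exists) and must then
either sit at background for 5 frames (a photobleach) or exceed 80% of
the remaining total intensity (a partial step of a multi-fluorophore
spot — no single FRET transition can produce one). A channel stops being
scanned after its first background step. Limits: a donor level within
~2.5 noise SDs of background (E above roughly 0.85 at default
brightness) makes donor-bleach detection unreliable; affected traces are
truncated early or rejected by the invalid-frame rule, never passed
through with dead frames.

Selection follows the published rules: both dyes alive for at least 10
frames, at most one bleach step per channel, anti-correlated channels
(Pearson r <= -0.3 over the pre-bleach window; the original selection
was semi-automated without a printed threshold, and -0.3 cleanly
separates simulated signal from unstructured noise at the default SNR).
E is not clipped; histograms span [-0.1, 1.1].

## Idealization

Per-trace Gaussian-emission HMMs are fitted by Baum-Welch EM (scaled
forward-backward, numba kernels) for K = 1..K_max, five restarts with
quantile-initialized means, convergence at relative log-likelihood
change < 1e-6 or 500 iterations, SD floor 1e-3. Decoding is Viterbi.
K is selected by BIC.

One addition proved necessary: 3-point smoothing correlates neighboring
frames, and EM exploits that correlation to split one broad state (e.g.
0.76 +/- 0.12) into alternating sub-levels that mimic dynamics. A
winning multi-state model is therefore re-scored on every 3rd frame
(with the 3-step transition matrix); if it fails to beat the one-state
model by at least 2 nats there, the one-state fit is kept. Measured on
synthetic PRE data this reduces falsely-dynamic static traces to ~1% at
the cost of missing ~19% of genuinely dynamic traces (short records
carry too little decimated evidence), i.e. ~90% static/dynamic
agreement. That is the honest discrimination limit at 30 fps for states
separated by 0.2 with SDs of 0.08-0.12.

Fit quality flags: any state holding fewer than 2 Viterbi frames, more
than 1% of frames beyond 3 fitted SDs, or systematic within-state
residual drift (first-half vs second-half mean differing by more than 6
standard errors — the factor allows for smoothing-correlated noise).
Flagged traces are excluded downstream, mirroring the ~3% exclusion in
the original analysis.

Fitted levels map to the nearest canonical center (0.8/0.6/0.4/0.2 for
Lt-FRET, 0.9/0.7/0.5/0.0 for tt-FRET) within +/-0.1; an unassignable
level flags the trace.

## Transition filtering

Beyond the two published filters (changes < 0.05 are not transitions;
one-frame dwells are not counted), three rules handle what idealization
of smoothed 30 fps data actually produces:

1. Sub-resolution merging. Adjacent dwell levels closer than 1.5 pooled
   raw-equivalent emission SDs (fitted SD x sqrt(3) to undo smoothing)
   merge, keeping the longer dwell's level — the published rationale
   ("changes smaller than the s.d. ... not distinguished from the
   noise") applied at the fitted scale. Keeping the dominant level
   prevents merge cascades across genuine state boundaries.
2. Transit-blur removal. A dwell of at most 2 frames whose neighbors
   straddle it monotonically is the smoothed image of a direct
   transition (a sharp edge spends up to smooth_window - 1 frames at
   intermediate values); its frames are split between the flanking
   dwells. This restores direct 0.6 -> 0.2 events that would otherwise
   always appear as 0.6 -> 0.4 -> 0.2 staircases.
3. Class fusion. Consecutive dwells carrying the same canonical class
   are one sojourn, not a transition.

Post-synchronization aligns each trace at the first transition into a
class with center <= 0.5, judged on the filtered dwell classes (robust
to noise) rather than raw E. Traces that never make such a transition
are excluded from synchronized analyses but kept for unsynchronized
distributions. Equilibrium conditions are analyzed without
synchronization; the pipeline switches automatically when fewer than
half the accepted traces synchronize.

## Populations and energetics

Populations P are frame-occupancy fractions of the canonical classes
over the first 45 frames (1.5 s) after the sync point (whole records
for equilibrium data), attributing frames by the filtered dwells. At
the fast tabulated rates nearly half of all frames carry camera- and
smoothing-mixed values, which biases any occupancy count toward the
mid-range state; when the emission model is known,
`unmix_populations` instead decomposes the pooled histogram by
nonnegative least squares over per-state Gaussians plus "bridge" bases
(the erf-shaped density of uniformly mixed transition frames, split
evenly between the endpoint states). Unmixing recovers populations to
about +/-0.01 on two-state and sequential three-state conditions;
conditions with direct long-jump transitions retain a +/-0.1 confound
on the middle state (transit mass and genuine occupancy overlap).
Histograms use 0.025-wide bins over [-0.1, 1.1] (at least 3 bins per
published SD); Gaussian sums are fitted to binned counts by unweighted
least squares with means initialized at the canonical centers, SDs at
0.1, a 0.02 SD collapse floor, and the component count fixed by the
condition's expected states. K_eq = P_S2/P_S1 and dG = -ln K_eq in
k_B*T.

## Dwell-time kinetics

Dwells come from the filtered segments; the last dwell of each trace is
censored (bleach or record end) and excluded from fits but counted in
the bleach-rate estimate, which is the censoring-aware maximum
likelihood rate: bleach events divided by total pre-bleach observation
time. Complete dwells per state (destinations pooled) are binned at the
frame interval from the 2-frame floor and fitted with
y = y0 + A exp(-t/tau); the observed exit rate 1/tau is apportioned
over destinations by transition counts. Per-destination dwell fits are
deliberately not the rate estimator: dwell durations are memoryless and
thus identically distributed for every destination, so per-destination
1/tau would return the total exit rate for each branch.

Two corrections are available.

*Analytic* (`correct_rates`): subtract the bleach rate per state
(competing risks), optionally divide each branch by the destination's
dead-time survival probability exp(-(k_exit + k_bleach) * t_d), solved
self-consistently, with t_d = 1.5 frames (the scale of the two-frame
dwell floor), and optionally down-weight by the static-trace term
N_dyn / (N_dyn + N_static (1 - exp(-k T_eff))). The static adjustment is
off by default because simulated static complexes are a structurally
distinct (frozen) sub-population. The analytic route is accurate when
mean dwells span many frames.

*Simulation calibration* (`calibrate_rates`): at 30 fps several
tabulated states have mean dwells of only 2-4 frames; there, even an
ideal detector reading the true state sequence frame-by-frame under the
same filters mis-estimates rates by tens of percent, and no closed-form
correction is adequate. When the observation model is known (simulated
studies; or an instrument with calibrated brightness, noise, bleaching
and emission parameters), candidate rate matrices are iterated until
full re-simulation through the identical pipeline reproduces the
measured observables. Two observables are matched per branch: the
empirical exit rate n_SD / T_S (events per second spent in the source
class — monotone in the true rate even when visible dwells are
blur-dominated) and the dwell-fit branch rate (which separates direct
transitions from blurred staircase paths, breaking the degeneracy
between 0.6 <-> 0.2 cycling and adjacent exchange). Updates are damped
log-space steps (alpha = 0.6); because events cluster within traces,
per-iterate simulation noise is several percent, so the returned
estimate averages the last iterates (Polyak tail) instead of trusting a
single stopping point. Accuracy on tabulated three-state conditions is
limited by this noise and by residual identifiability; two-state
conditions recover within ~15%. On real data the estimate inherits the
observation model's assumptions wholesale — that is the method's main
caveat and the reason the analytic correction remains the default in
the command-line pipeline.

## Degenerate inputs and numerics

Absorbing CTMC states yield single-sojourn paths, not errors. Constant
channels make the anti-correlation statistic undefined (trace rejected).
Frames with non-positive total intensity are invalid; >5% invalid
rejects the trace. Mixture components collapsing below SD 0.02 are
refloored and flagged. Dwell sets below 20 events refuse a fit (table
entries rendered absent). Exponential-fit histograms start at the
two-frame floor so the truncation artifact never enters. All randomness
flows from explicit seeds through numpy SeedSequence spawning; per-trace
idealization seeds derive from a CRC of the trace id, so results do not
depend on trace order.

## Known limitations

- In three-state schemes the partition of flux between direct
  0.6 <-> 0.2 transitions and smoothing-blurred 0.6 -> 0.4 -> 0.2
  staircases is weakly identifiable at 33 ms frames: a truth-rate
  simulation reproduces the measured observables essentially exactly,
  but so, nearly, does a direct-heavy degenerate solution, and the
  calibration iteration can settle on either. Rates for such schemes
  should be treated as order-of-magnitude unless the acquisition
  includes longer integration times (the original work measured the
  direct rates at >= 100 ms); two-state schemes calibrate to ~15%.
- Static/dynamic classification has a ~10% error floor under the
  published emission overlap, dominated by short dynamic traces judged
  static.
- tt-FRET 0.85-state donor signals sit near the detection floor at the
  default brightness; their bleach steps are unreliable.
- The variational-Bayes model selector used by the original software is
  approximated by BIC plus the decimated validation; equivalence was
  established by recovery on synthetic data, not by matching that
  software's output.
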