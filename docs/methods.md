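# Model and methods

## The circuit

Each cortical area is a local population of 500 spiking neurons: 400
regular-spiking (RS) pyramidal cells, 75 fast-spiking (FS) and 25
low-threshold-spiking (LTS) interneurons.  Membrane dynamics follow the
two-variable quadratic model

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I,      du/dt = a (b v - u),

with a reset `v <- c`, `u <- u + d` whenever `v` crosses +30 mV.  The
per-type parameters are (a, b, c, d) = RS (0.02, 0.2, -65, 8),
FS (0.1, 0.2, -65, 2), LTS (0.02, 0.25, -65, 2).  Synapses are
current-based and instantaneous-rise: a presynaptic spike adds a fixed
per-pair amplitude to the target's synaptic current, which decays with
tau_E = 2.5 ms (AMPA-like) or tau_I = 6 ms (GABA-like).  Within an area
connectivity is all-to-all (no self-connections); each directed pair's
amplitude is drawn uniformly between 0 and a signed per-type-pair bound
(RS->RS 0.0375, RS->FS 0.125, RS->LTS 0.125, FS->RS -0.25, FS->FS -0.15,
FS->LTS -0.1, LTS->RS -0.3, LTS->FS -0.1, LTS->LTS 0).  Every neuron
receives an independent Gaussian noise current per integration substep,
N(mu, sigma) with RS (4, 6), FS (5, 4), LTS (4, 4).

With these settings one area settles into a pyramidal-interneuron gamma
(PING) regime: RS cells fire at 5-10 Hz, interneurons at ~25-35 Hz, and
the excitatory population spike-time histogram (STH, 1 ms bins — the
package's LFP proxy) carries a 30-50 Hz spectral peak.  Raising the tonic
drive to E cells raises gamma power; raising it to I cells lowers it;
both raise the gamma frequency.

Two areas are coupled by a feedforward projection from the sending area's
RS cells onto the receiving area's RS and FS cells, mirroring the local
wiring convention (all-to-all, same uniform bounds).  No reference values
exist for this projection; it is the model's largest free choice and is
fully exposed (`FeedforwardSpec`: connection probability, overall
strength scale, and a separate scale for the RS->FS component).  The
RS->FS component is what lets the sender's gamma bursts phase-lock the
receiver; removing it collapses the coherence modulation described below.

## The alpha drive

A higher-order thalamic (pulvinar-style) alpha rhythm is not modeled as
spikes but as a modulatory current delivered to each area's inhibitory
neurons: I(t) = A sin^2(phi(t)/2), non-negative, effective frequency
10 Hz, default amplitude A = 23 pA.  The two areas' phases are coupled
noisy oscillators:

    dphi1/dt = w0 + eta1 + J sin((phi2 + d) - phi1)
    dphi2/dt = w0 + eta2 + J sin((phi1 - d) - phi2)

with w0 = 2*pi*10 Hz, coupling J = 0.2 rad/ms, and white frequency noise
eta of standard deviation 0.05 rad/sqrt(ms) (our choice; it yields a
narrow ~10 Hz spectral line with visible cycle-to-cycle fluctuation).
The lock target `d` holds an arbitrary phase difference against the
noise; with J = 0.2 rad/ms the offset relaxes in a few milliseconds, so
the configured difference is maintained throughout a trial.  J
interpreted per millisecond is the only reading under which the offset is
"well maintained" on the 2 s trial timescale.

Two conventions deserve explicit statement because the literature leaves
them ambiguous:

* **Sign of the phase difference.**  We label offsets so that *negative*
  delta-phi means the *sending* area's excitable window (alpha-current
  trough) precedes the receiving area's in time.  The optimum for
  communication then sits at about -90 deg, i.e. the sender leads by
  ~25 ms, one gamma cycle.
* **Current units.**  The neuron model's currents are dimensionless.
  Quantities quoted in pA at the interfaces (alpha amplitude, stimulus
  amplitude) are converted by a single factor, 0.13 model units per pA,
  calibrated once so that the plausible 0-45 pA alpha range spans the
  intended regimes: at 23 pA the excitatory population is rhythmically
  gated but retains activity near the inhibition peak; only near 45 pA is
  the low-activity phase almost completely silenced.  The noise table
  above is in native model units (as pA it could not drive the network).

## Numerical scheme

Each 1 ms simulation step is two sequential forward-Euler substeps of
0.5 ms; spikes are detected and reset after every substep, and the spike
time is the substep at which the peak was reached.  Noise is drawn per
substep and deliberately not rescaled by sqrt(dt): the noise level is
defined at the 0.5 ms substep, which makes it part of the model
specification rather than an approximation of a continuous process.
Initial conditions are the per-type analytic resting state plus ~1 mV
seeded jitter.  At this step size the single-neuron tonic firing rate
deviates from a dt = 0.01 ms reference integration by at most ~5% over
the relevant drive range.  The simulator aborts with a diagnostic if any
membrane potential becomes non-finite.  Everything is reproducible
bit-for-bit from (configuration, seed).

## Analysis stack

* **Spectra and coherence.**  Multitaper estimates with Slepian tapers,
  NW = 5 (9 tapers), on 2000 ms STH segments sampled at 1 kHz; coherence
  is |S_xy|^2 / (S_xx S_yy) averaged over tapers and trials.  Coherence
  is decomposed into a *phase component* (squared resultant of
  unit-magnitude per-trial cross-spectra; tapers averaged within a trial
  first, since single tapers have spectral nulls with undefined phase)
  and an *amplitude component* (across-trial Pearson correlation of
  taper-averaged amplitudes, floored at 0).  The estimation bias of any
  of these is measured by re-pairing trials with random derangements.
* **Wavelets.**  Complex Morlet transform with envelope width
  sigma_t = 1/f0 (one period), L1-normalized; the cycle origin for
  spike-phase reporting is the ascending zero-crossing, putting the
  signal peak at +90 deg.  Coefficients within 2 sigma_t of an edge are
  flagged invalid and excluded from phase-coupling statistics.
* **Granger causality.**  VAR models fitted by pooled least squares
  (AIC order selection up to 20 at 1 kHz, or a fixed order); the spectral
  measure uses the transfer-function factorization with the residual
  rotation that zeroes the source/target covariance.  The conditional
  variant (used to discount the shared alpha drive) expresses the full
  (x, y, z) model in the frame where the reduced (x, z) model's
  x-innovations are white.  Frequency averages agree with the
  time-domain nested-regression value (Geweke consistency) within a few
  percent on fixtures.
* **Spike transmission.**  For each sender spike, the binary outcome is
  whether any of its actual feedforward targets fires within (t+1, t+4]
  ms (half-open; the model has no axonal delays, so this window is the
  synaptic delay range).  Spikes are binned by gamma phase (16 bins by
  default) and bins are equalized to the minimum positive count by
  seeded subsampling before the per-bin probability is computed.
* **Decoding.**  A linear maximum-margin classifier (large-C SVM,
  C = 1e4 with an iteration cap so heavily overlapping classes cannot
  stall the solver) on the receiving area's spike counts in the 30 ms
  post-onset window; stratified 5-fold cross-validation; mutual
  information from the pooled held-out confusion table, log base 2
  (capped at 1 bit for two stimuli).

## Experiment scenarios and their scales

The `scenarios` module packages the experiments; the CLI (`alphagate run
<scenario>`) writes their tables as CSV.  Desk-scale defaults: 10 trials
of 2000 ms for single-area statistics; 5-10 trials per offset for the
12-point (30 deg) phase-difference sweeps; 40 presentations per stimulus
for decoding (batched as one stimulus identity per 2 s trial with ~4
phase-aligned presentations each).  These sizes keep any single scenario
within a few minutes on one CPU while leaving the headline effects well
clear of their trial-to-trial variability.

Stimulus experiments run the sending area at a reduced tonic E drive
(mu_RS = 2, below the rheobase of 4) so its pre-stimulus state carries
only low-amplitude interneuron-driven gamma and the stimulus (default
30 pA, 50 ms) lifts it into the full PING regime.  The decoding scenario
uses a stronger 90 pA stimulus: discrimination needs a transient strong
enough to propagate; both amplitudes are exposed in the scenario
signatures.

## What the generator does and does not emulate

The synthetic alpha drive captures phase diffusion, frequency
fluctuation, and a controllable inter-areal offset, but not stimulus
phase resets, amplitude envelopes, or an explicit spiking pulvinar.  The
network has no axonal delays, no laminar structure, no plasticity, and
no topography.  Passing tests therefore establish the internal
consistency of the mechanism — alpha-phase-difference control of
gamma-band communication — not its quantitative fidelity to any
particular cortical recording.

## Known limitations

With the prescribed noise table the RS population sits exactly at its
rheobase and is fluctuation-driven.  A consequence is that the alpha
gating in this implementation is *harsher* than the published account of
the same circuit: the E population is fully silenced during the
inhibited half of each alpha cycle even at moderate amplitudes.  Three
measurable consequences, all robust to the exposed knobs and therefore
reported as-is rather than tuned away:

1. the alpha-band phase offset between E and I population activity is
   ~148-150 deg rather than ~180 (the E burst lags the release from
   inhibition, and the I centroid is pulled toward the E burst through
   the E->I projection);
2. the receiving area's stimulus-response modulation with the phase
   difference is much deeper than a factor of two, and the pooled
   response can even turn negative through feedforward inhibition;
3. two-stimulus decoding from 200-neuron subpopulation means reaches its
   ceiling only near the optimal phase difference; at the least
   favorable offset the channel is gated nearly shut and accuracy stays
   well below 100%.

The coherence-versus-offset structure itself (single maximum with the
sender leading by ~a quarter alpha cycle, minimum near the opposite
offset, depth growing with alpha amplitude, phase component modulated
more than the amplitude component, causality direction following the
sign of the offset) is stable across seeds at the default calibration.
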