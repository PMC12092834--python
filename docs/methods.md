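# Methods

## The model

`mea_sbi` simulates a cultured network of excitatory neurons on a
multi-electrode array (MEA) and infers the biophysical parameters of that
model from the recorded activity, using amortized simulation-based
inference on summary features.

### Network simulator (`simulate`, `simcore`, `topology`)

The network consists of N point neurons (default 100) with Hodgkin-Huxley
dynamics.  The membrane equation per neuron is

    C dV/dt = -g_l (V - E_l) - g_Na m^3 h (V - E_Na) - g_K n^4 (V - E_K)
              - g_AHP c (V - E_K) - g_AMPA (V - E_AMPA)
              - g_NMDA s B(V) (V - E_NMDA) + I_ext + noise

with conductance densities converted to absolute conductances through the
membrane area (300 um^2, so 1 mS/cm^2 = 3 nS and C = 3 pF).  The published
constants of the model (Nernst potentials, time constants, V_T, area) are
the `FixedParams` defaults; ten parameters are free and inferred:
membrane-noise sd, g_K, g_Na, g_AHP, g_AMPA, g_NMDA, connection
probability, and the short-term-plasticity parameters tau_D, U (STD),
U (asynchronous).

Pieces the published constants do not pin down are explicit,
config-exposed reimplementation choices:

- **HH rate functions.** Traub-Miles-style kinetics in which every
  alpha/beta depends on V - V_T (m^3 h sodium, n^4 potassium).  This is
  the canonical conductance-based formulation that is parameterized by a
  threshold-shift V_T, which is the form the fixed constant V_T = -30.4 mV
  implies.  The exact alpha/beta expressions are in
  `simcore.build_gating_tables`.
- **sAHP.** A per-neuron activation c increments by alpha_Ca = 3.5e-4 at
  each spike and decays with tau_AHP = 6 s; the current is
  g_AHP * c * (V - E_K).  This produces slow spike-frequency adaptation
  and burst termination over seconds.
- **Membrane noise.** An Ornstein-Uhlenbeck voltage perturbation with
  stationary sd equal to the `noise_sd` parameter (mV) and a 5 ms
  correlation time (`FixedParams.noise_tau`); its increments are added to
  V at every step (Euler-Maruyama).
- **Heterogeneous excitability.** Each neuron receives a constant input
  current drawn once per topology from Normal(9 pA, 3 pA).  The isolated
  rheobase of the neuron model is ~12.5 pA, so the median neuron sits just
  below threshold and roughly one neuron in eight is an intrinsic
  pacemaker; the rest are recruited by noise and recurrent excitation.
  These values were chosen (once, by inspection of the regime diversity
  across the prior) so prior draws produce the spectrum seen in real
  cultures: silent wells, irregular spiking, and networks bursting at
  1-50 bursts/min.
- **Synapses.** A spike releases the fraction U*x of the presynaptic
  resource x (Tsodyks-Markram; recovery dx/dt = (1-x)/tau_D).  The
  released fraction is converted into conductance with the transmitter
  gain x_0 = 5 ("transmitter per vesicle"): the AMPA conductance of each
  target increments by g_AMPA * w * x_0 * U * x, and the same weighted
  amount drives the NMDA rise variable.  NMDA gating is a
  rise/decay pair (2 ms / 100 ms) with activation rate alpha_NMDA =
  0.5 kHz and the Jahr-Stevens magnesium block
  B(V) = 1/(1 + [Mg]/3.57 * exp(-0.062 V)) at [Mg] = 1 mM.
- **Asynchronous release.** A presynaptic residual rate u increments by
  U_asyn per spike, saturates at U_max = 0.5 /ms, and decays with
  tau_asyn = 700 ms.  Each outgoing synapse releases asynchronously as a
  Poisson process with rate u; an asynchronous event is a spike-triggered
  release scaled down by x_0 (it releases U*x/x_0 of the resource and
  delivers 1/x_0 of the synchronous conductance increment) — one vesicle's
  worth of the multi-vesicular synchronous release.
- **Topology.** Neurons on a square grid; every ordered pair connected
  independently with probability conn_p; lognormal weights with mean 1 and
  CV = 0.7; conduction delays proportional to grid distance, scaled so the
  grid diagonal maps to 25 ms.  Twelve virtual electrodes form a 4 x 3
  interior grid (the 12-site MEA well layout) and each neuron reports its
  spikes to the nearest electrode, so electrode spike counts partition
  neuron spike counts.

### Numerics

Integration is fixed-step: Rush-Larsen exponential updates for the gating
variables (via voltage-indexed lookup tables, 0.02 mV resolution) and an
exponential-Euler membrane update in which the conductances are frozen
over the step.  The membrane update makes the integrator unconditionally
stable despite the stiffness of the Na conductance during the spike
upstroke (membrane time constant ~0.01 ms at full activation), which a
forward-Euler scheme cannot handle at any practical dt.  Default dt is
0.05 ms; 0.1 ms is used throughout the tests and acceptance runs and gives
spike counts within ~1% of dt = 0.05 ms at mid-prior parameters.  Spikes
are extracted as upward crossings of 0 mV with a 2 ms dead time.  A
voltage-blow-up guard (|V| > 200 mV) raises `SimulationError` naming the
offending step; with the exponential-Euler update it should never fire.

Randomness is split into named substreams (topology + input currents,
initial conditions, dynamics) derived from one seed, so the topology can
be held fixed while noise varies.  The dynamics noise and the
asynchronous-release draws share the kernel's single stream; runs are
bit-reproducible for fixed (parameters, seed, dt, duration) on one thread.

### Signal path (`signalproc`)

Raw traces are band-passed 100-3500 Hz with a fifth-order Butterworth
filter, applied forward-backward (zero phase) so detected spike times are
not biased by group delay.  Detection thresholds |signal| at 4x the RMS of
the whole trace, per electrode, both polarities; suprathreshold runs
within a 2 ms dead time collapse to one event at the absolute extremum.
RMS over the whole trace (not a sliding window) and both-polarity
thresholding are documented choices where the 4xRMS rule alone is
underdetermined.  A synthetic-trace generator (templates + white noise)
makes the whole path testable; at a 4-sigma threshold, expect ~0.5 false
events per second of pure noise — precision statements only make sense at
realistic spike densities.

### Features (`features`)

The 13 summary statistics (standard MEA abbreviations): MFR, NBR, NBD, PSIB,
#FBs, CV_IBI, mean/sd ISI CC, ISI distance, mean ISI, sd ISI (temporal),
sd ISI (electrode), MAC, plus the two optional binarized-correlation
features.  Conventions where the definitions leave freedom:

- Network rate = spikes of all electrodes in 25 ms bins; `max_rate` is the
  maximum of the *raw* binned rate.
- Burst detection: open at >= max_rate/4 sustained for 50 ms (2 bins),
  close below max_rate/50 by the same rule, keep only bursts in which
  >= 50% of active electrodes (mean rate > 0.02 Hz) fire at least one
  spike ("firing during the NB" read as >= 1 spike).
- Fragments: peaks of the Gaussian-smoothed rate (sigma = 50 ms, a width
  that suppresses single-bin jitter but preserves ~100 ms sub-burst
  structure) with height >= max/16 and prominence >= max/20; every
  detected burst counts at least one fragment.
- No-burst conventions: NBD = PSIB = #FBs = 0 without bursts; CV_IBI = 0
  with fewer than 3 bursts; inter-burst interval is onset-to-onset.  These
  imputations keep silent prior draws in the training set instead of
  truncating the prior predictive.
- ISI series are sampled on the 25 ms grid between each electrode's first
  and last spike; pairwise statistics use the overlap of defined ranges;
  constant-series or <2-spike electrodes are excluded.
- MAC: maximum of the mean-removed, (n - lag)-normalized autocorrelation
  of the network rate over lags in [0.1 s, duration/2], clamped to [0, 1];
  0 by convention for zero variance.  The lag window is a documented
  choice.

One code path serves simulated and measured rasters.

### Inference (`nde`, `inference`)

The density estimator is a conditional Gaussian mixture: a full-covariance
Gaussian mixture is fitted by EM to the joint z-scored (theta, x) space
(component count selected by BIC, up to 12), and conditioning on an
observed feature vector is done in closed form, yielding an explicit
mixture posterior with exact log-density, analytic gradients, and cheap
sampling.  This satisfies the amortization contract — one fit, then any
number of observations evaluated in milliseconds — with a deterministic,
reproducible training procedure.  Its main limitation against a
normalizing flow is a less flexible response of the posterior shape to x
between mixture components; on the linear-Gaussian oracle it is calibrated
(simulation-based-calibration ranks uniform) and accurate to a few percent
in posterior mean and sd, and on the reduced network model it recovers the
identifiable parameters (see below).  Posterior samples are truncated to
the prior box by rejection; observations further than 10 training-sd from
the training mean trigger a misspecification warning, not a failure.

Posterior analysis:

- **Mode**: best of 10^4 posterior samples refined by L-BFGS-B inside the
  prior box (the joint mode, not per-marginal modes).
- **Conditionals**: density on a grid over the free parameter(s)' prior
  ranges with the others clamped (default 100 points/axis), normalized on
  the grid; sampling by inverse-CDF/categorical cells.
- **Conditional correlation matrix**: 50 clamping points drawn from the
  posterior, 50 samples from each 2-D conditional, Pearson r each; mean
  matrix plus a one-sample t-test of the 50 r values against zero.
- **Sensitivity**: active-subspace scores — eigen-decomposition of the
  covariance of the log-density gradient over posterior samples, gradients
  taken w.r.t. prior-range-normalized parameters, scores normalized to a
  max of 1; finite-difference fallback if the analytic gradient fails.
- **PPC**: simulate at a known theta*, condition, and require the Scott-
  rule KDE (1000 samples) of every univariate and pairwise marginal to
  give theta* at least 50% of the marginal's maximum density.  The
  criterion depends on the KDE bandwidth; Scott's rule is the documented
  choice.
- **PRE**: mean absolute deviation of marginal samples from theta*,
  normalized by the prior range — 0.25 for a uniform marginal with the
  truth at the midpoint, 0.5 at an edge.  (The original reference for this
  statistic is not reproduced here; any monotone alternative could sit
  behind the same contract.)

### Comparison layer (`stats`)

Marginal comparison: 50 samples per side, two-sample KS test per
parameter, raw p-values (a Holm flag exists but is off by default, to
match the per-network/per-batch raw-p reporting convention), shift
direction = sign of the median difference.  Each side's sample stream is
seeded by a digest of that posterior's content, which makes the comparison
exactly symmetric under argument swap (the sample sets swap rather than
re-draw); two *identical* posteriors fall back to independent side
streams.  With n = 50 per side the KS statistic lives on a lattice of
multiples of 1/50.  Posteriors whose metadata name different MEA batches
refuse comparison without an explicit override — batch effects dominate
posterior shape, so cross-batch parameter comparisons are not meaningful.
Feature-group comparisons use two-sided Mann-Whitney tests; conditional
correlations are tested against zero with a one-sample t-test behind a
logged Shapiro-Wilk gate.

## Synthetic data and what passing tests show

The generator family in `fixtures` defines the test conditions:

- *Crafted rasters* have exactly known burst structure (onsets, durations,
  participation) so burst-detector decisions can be hand-verified.
- *Synthetic traces* are template + white Gaussian noise; real recordings
  have colored noise, electrode drift, and overlapping units, so passing
  detection tests bounds performance only for the idealized noise model.
- *The linear-Gaussian toy* (x = theta + eps, uniform prior) has an
  analytic truncated-Gaussian posterior and exercises every inference
  operation against closed forms.
- *The reduced network model* frees 5 parameters (noise_sd, g_AMPA,
  conn_p, tau_D, U_std) with the rest clamped at prior midpoints, 50
  neurons, 60 s (45 s in the acceptance run) — small enough for desk-scale
  end-to-end recovery.  It shares every code path with the full model;
  what it cannot show is the 10-parameter degeneracy structure at the
  full training scale (hundreds of thousands of 3-minute simulations),
  which is out of desk-scale reach by design.

Problem sizes used by the acceptance script (chosen once as desk-scale
stand-ins for the full-scale study): 100 full-prior 45 s simulations (50
neurons) for the feature-redundancy correlation, 250 reduced-model
training simulations + 10 held-out ground truths for the recovery loop,
and n = 5000 for the toy oracle suite; roughly 12 minutes on one CPU in
total.

## Known limitations

- No inhibitory neurons or astrocytes (the in vitro system the model
  mimics lacks them); no compartmental morphology; no GPU path.
- The conditional-GMM estimator can under-resolve sharply curved
  parameter-feature manifolds that a masked autoregressive flow would
  capture; the module boundary (`train_nde` / `Posterior`) is
  estimator-agnostic so a flow can be swapped in.
- Feature extraction assumes 12 electrodes and 25 ms bins by default;
  other layouts are configurable but untested against hardware.
- The asynchronous-release vesicle accounting (role of x_0) is a
  documented interpretation; alternative readings rescale U_asyn's
  effective strength without changing its qualitative role.
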