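# Methods

## Model and dynamics

The network is a firing-rate model: `M` input channels `x` (log-spaced
frequencies, like points along the cochlea) drive `N` output neurons `s`
through feed-forward weights `W` (N×M), recurrent weights `K` (N×N) and
thresholds `T`:

    tau ds_i/dt = -s_i + g(sum_j W_ij x_j + sum_k K_ik s_k - T_i)

with the logistic activation `g(h) = 1/(1+e^-h)`.  Stimuli are assumed slow
compared to `tau`, so the network's response to a stimulus is the steady
state `s = g(Wx + Ks - T)`.  Steady states are found by Newton-Raphson on
the fixed-point equation (tolerance 1e-10 in the infinity norm, at most 200
iterations, initialized from the recurrence-free response `g(Wx - T)`);
failures and — where stability is checked — unstable fixed points fall back
to explicit Euler integration (`dt = 0.1 tau`, convergence when the
per-step change drops below 1e-6, budget 1e6 steps).  The Euler fallback
start is perturbed by uniform noise of magnitude 1e-3 so the dynamics can
leave an unstable homogeneous state and settle into a symmetry-broken
attractor; the perturbation is seeded (fixed default seed), keeping results
reproducible.

A fixed point is linearly stable iff all eigenvalues of `I - GK`
(`G = diag(g'(h))`) have positive real parts.  Since `g' <= 1/4`, spectral
radius `rho(K) < 4` guarantees stability, and `rho(K) = 4` is used
throughout as the operational critical point.

## Learning

Training minimizes

    eps = -1/2 < log det(chi^T chi) >_x + lambda_W |W|_1 + lambda_K/2 |K|_2^2

where `chi = dS/dx = phi W` and `phi = (I-GK)^{-1} G` is the susceptibility
of the steady state.  Maximizing the log-determinant of the Jacobian's Gram
matrix maximizes output entropy for the overcomplete case N > M.  The exact
gradient-descent updates are

    dW = eta ( phi^T ((chi+)^T + y x^T) - lambda_W sign(W) )
    dK = eta ( phi^T (chi chi+ + y s^T) - lambda_K K )
    dT = eta ( -phi^T y )

with `chi+ = (chi^T chi)^{-1} chi^T`, `y_l = (chi chi+ phi)_ll g''(h_l) /
g'(h_l)^3` and `sign(0) = 0`.  These follow from differentiating `eps`
through the implicit dependence of the steady state on the parameters; the
test suite checks them against central finite differences of the objective
(relative error below 1e-5 is required; observed ~1e-10).  Swapping a
regularization norm to its l1/l2 counterpart swaps the corresponding
`sign(A)` / `A` term.  The expectation over stimuli is approximated by
single-sample online updates.

Training runs in three phases (clean feed-forward, clean recurrent,
deprived recurrent).  During phase 1 the recurrence is clamped to zero and
`W`, `T` learn with `eta = 0.1`; phases 2-3 train only `K` with
`eta = 0.001`.  Autapses (diagonal of K) are truncated to zero after every
update.  Samples whose steady-state solve fails are skipped and counted; a
phase aborts (carrying its partial state) if more than 1% of solves fail
within a 10,000-sample window, which in practice signals that the
recurrence has escaped into the supercritical regime.  The full-size
iteration counts (50k / 1M / 1M) are available through the configuration;
the defaults use 100k for phases 2-3, which the training traces show is
already well past convergence at these sizes.

## Stimuli

Each sample is a mixture of 1-5 tones on the M-channel log-frequency axis:
tone centers uniform on [1, M], Gaussian response curves whose widths are
folded-normal with scale M/2 (floored at 0.25 channels to avoid
sub-channel spikes), amplitudes uniform in [7, 10] (arbitrary units,
standing for log-amplitudes of natural sounds after cochlear gain control),
plus per-channel uniform [0, 1] background noise.  A global divisor — twice
the maximum activation over a 10,000-sample calibration batch — maps all
samples into [0, 0.5]; the divisor is fixed once before training (online
generation cannot know the global maximum) and later samples are clipped at
0.5 in the rare case they exceed it.

Deprivation multiplies stimuli by an attenuation envelope: a sigmoid edge
`a(k) = 1/(1+exp(-beta (k0-k)))` (beta > 0 attenuates high frequencies,
beta < 0 the lows) or a band profile combining two opposing edges.  Channel
indices are 1-based in these formulas.

What the generator does *not* emulate: cochlear mechanics, temporal
waveforms, realistic loudness distributions, correlations between
successive stimuli.  Passing tests therefore show that the *model's*
mechanism (entropy maximization + weight regularization + attenuation)
produces the reported phenomenology under these idealized statistics, not
that it does so for natural sound ensembles.

## Measurements

* **Scaling sweeps.**  Training mostly rescales the recurrent profile, so
  distance from criticality is probed by replacing `K` with `sigma K` and
  tracking: the entropy term of the objective on a fixed evaluation set
  (1,000 stimuli at full size, 200 at desk scale, drawn once from the
  pre-deprivation distribution and reused across sigma and across pre/post
  comparisons); the Euler step count to convergence on the silent stimulus
  (critical slowing down); the population-vector modulus
  `|1/N sum_k s_k e^{2 pi i k/N}|` of the silent attractor (spontaneous
  symmetry breaking; output neurons are given equally spaced angles, ring
  boundary conditions being a good approximation for N >> 1); and the mean
  squared Pearson correlation over output pairs (zero-variance neurons
  excluded).  The critical scale is `sigma_c = 4/rho(K)`; the operating
  point is `sigma = 1`.

* **Zones and profiles.**  A neuron's preferred frequency is the argmax of
  its feed-forward row (ties to the lower channel; all-zero rows flagged).
  Neurons are *deprived* iff the attenuation at their preferred frequency is
  below 0.5.  Aligned connectivity profiles re-index each row by the
  presynaptic-minus-postsynaptic preferred-frequency offset and average.

* **Hallucination scoring.**  The spontaneous baseline is the
  pre-deprivation network's deterministic silent response, per neuron.  The
  hallucination score is the maximal elevation of the (noise-seeded) silent
  attractor above that baseline; detection uses an absolute threshold of
  0.1 — a tenth of the (0,1) activity range, orders of magnitude above
  solver tolerance.  A relative threshold tied to the across-neuron spread
  of the baseline was rejected: trained thresholds make the baseline
  heterogeneous, so its 5-sigma spread can exceed the largest elevation
  physically available to many neurons.  Peak structure is assessed on the
  elevation profile smoothed by a circular moving average of width ~N/8
  (the recurrent bump width); contiguous regions above half the smoothed
  maximum are counted, so per-neuron baseline ripple does not masquerade as
  extra peaks.

* **Audiograms.**  Per channel, bisection (interval [0, 100], tolerance
  1e-6) finds the probe amplitude at which the steady-state response
  differs from the silent response by 0.01 in the infinity norm.  Probes
  into a deprived system pass through the attenuation envelope first — the
  hearing loss lives in the periphery — which is what elevates in-band
  thresholds.  The single-frequency probe is a one-channel delta by
  default; a narrow Gaussian tone is available via `probe_width`.

* **lambda_K sweeps.**  All grid points share one phase-1 checkpoint.  The
  *hallucination interval* is the lambda range between the points where the
  pre- and post-deprivation `rho(K)` curves cross the midpoint (3.0) of
  their sharp drop from ~4 to well below.

## Desk-scale configuration

The reduced preset (`small_config()`) uses M=10, N=40, phase iterations
20k/30k/30k, a 2,000-sample calibration batch, 200 evaluation stimuli and a
25-point sigma grid; it runs in about half a minute and is the
configuration exercised by the end-to-end tests.  Because the useful range
of `lambda_K` depends mainly on N, it was re-located for this size with the
same lambda-grid procedure used for the full model: the interval is roughly
(0.12, 0.20), and the preset fixes `lambda_K = 0.19` near its upper bound,
where the hallucination profile is single-peaked.  At this size the
deprived zone spans ~19 of 40 ring positions and per-neuron heterogeneity
is strong; the correlation measure's maximum-versus-minimum structure
around the operating point is only partially reproduced (the post curve
peaks below sigma = 1), while all other signatures — Mexican hat, the
critical-scale shift, deprived-zone single-peak hallucination, in-band
audiogram elevation — carry over cleanly from the full-size setting.

## Numerical notes and limitations

* Eigenvalues use LAPACK's general nonsymmetric solver; `rho(K)` is the
  maximal modulus.
* `chi+` is computed by solving the M×M Gram system, never by forming an
  explicit pseudo-inverse of the tall matrix.
* Newton steps are clipped into (0, 1) elementwise, which only binds for
  saturated units.
* Gradient checks require a Newton tolerance (1e-13) well below the
  finite-difference step (1e-5); with the default 1e-10 tolerance the
  solver residual would contaminate the quotient.
* The model is stationary by construction: no spiking, delays, adaptation
  or non-stationary inputs, and no claim is made about avalanche-style
  criticality hallmarks.
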