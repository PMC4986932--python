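# Methods

## The model

A hyperpolarization-activated cation (Ih) current component is described by
a two-state Hodgkin–Huxley gate with three ingredients:

* **Steady-state activation** — a Boltzmann sigmoid
  `r_inf(V) = 1 / (1 + exp(-(V - Vh)/k))` with half-activation voltage `Vh`
  (mV) and slope factor `k` (mV, negative: the channel opens on
  hyperpolarization).
* **Activation time constant** — a Gaussian bump
  `tau_r(V) = B + A * exp(-(M - V)^2 / S^2)` peaking at `A + B` ms at
  voltage `M`, width `S`, riding on a base constant `B`.
* **Maximal conductance** `G` (nS), with reversal potential `Eh = -36 mV`.

Under a voltage-clamp step from `Vps` to `Vs` the gate relaxes
exponentially, giving the closed-form current (pA, with nS·mV = pA)

    Ih(t) = G [ r_inf(Vs) + (r_inf(Vps) - r_inf(Vs)) e^{-t/tau_r(Vs)} ] (Vs - Eh).

The measured current is modelled as the sum of two such components, a slow
high-voltage-activated one and a fast low-voltage-activated one.
Deactivation (the return to `Vps`) uses the same `tau_r` curve evaluated at
the post-step voltage — a symmetric kinetic model; no separate deactivation
protocol is modelled.

## Identification methods

**Single-trace (baseline).** Each trace is fitted independently with the
step-response form, the initial activation pinned at `r_inf(Vps) ≈ 0`.
Per component and step this yields `(G, r_inf, tau_r)`; the conductances
are then averaged across steps, the `r_inf(Vs)` points fitted with the
Boltzmann and the `tau_r(Vs)` points with the Gaussian (bounded multi-start
least squares, 5 restarts). Two deliberate properties of this baseline are
preserved because they are what the comparison is about: (i) a single trace
constrains only the product `G·r_inf(Vs)`, so the per-trace split between
conductance and activation is degenerate; (ii) at steps where a component
carries no measurable current its fitted time constant is meaningless, and
with long noisy traces the least-squares estimate drifts toward the
search-region boundary (it fits the low-frequency noise path). Steps with
no signal at all (`Vs = Vps`) are flagged and excluded from the curve fits.

**Full-trace.** All characteristic-curve parameters of all components
(7 per component) are identified simultaneously from every trace at once by
minimizing the summed squared difference between the modelled and observed
currents at all sampled time points. The minimization runs in
region-normalized coordinates (the search box mapped to [-1, 1] per
parameter).

**Multi-start and retention.** Both methods run many independent trials
with uniform random initialization inside a search region of fractional
size `tol` (default 0.8) around a centre vector (the generating parameters
for synthetic benchmarks). The lowest-residual 28% of trials — the first
mode of the residual distribution, which coincides with the global-minimum
basin — is retained and the retained parameter vectors averaged after
relabelling components slow-first by peak time constant `A + B`.

### Numerical choices

* **Optimizer.** The default minimizer is bounded trust-region least
  squares (`scipy.optimize.least_squares`, TRF) in normalized coordinates
  with an analytic Jacobian of the closed-form model (validated against
  finite differences); it reaches the noise-floor residual from a large
  fraction of random starts, which is what produces the expected
  first-mode structure of the residual distribution, and an iteration cap
  of 100 keeps trials that wander in degenerate valleys cheap (they simply
  rank as high-residual trials). A direction-set (Powell) option is
  retained (`optimizer="powell"`); in our measurements scipy's bounded
  Powell stalls well above the residual floor on this 14-parameter problem
  and is not recommended.
* **Fitted segment.** The error functional includes both the activation
  segment and the post-step (tail) segment by default
  (`include_deactivation=True`). The tail substantially tightens the
  kinetic parameters: on the reference benchmark the full-trace grand-mean
  error is ≈ 5% with tails versus ≈ 10% without.
* **Retention.** `keep_fraction` is a fixed 0.28 (14 of 50 trials at
  defaults) rather than a histogram mode detector; ranking uses the
  optimizer residual (full-trace) or the residual of the assembled
  reconstruction against the data (single-trace).
* **Degenerate inputs.** A trace at the holding potential is flagged
  (tau unidentifiable); `tol` must stay below 1 so bounds preserve each
  parameter's sign; component label ties (identical `A + B`) break by
  conductance.
* **Reproducibility.** One master seed spawns per-trial sub-seeds through
  `numpy.random.SeedSequence`; all results are deterministic given
  (data, seed).

## The synthetic benchmark

No recordings are distributed with this package, so method evaluation uses
synthetic trace sets. The reference benchmark sums a slow component
(Vh -100 mV, k -6, M -80 mV, S 80, A 1000 ms, B 60 ms, G 3 nS) and a fast
one (Vh -130 mV, k -9, M -80 mV, S 40, A 250 ms, B 40 ms, G 4 nS) under the
standard protocol — hold -60 mV, steps -60 → -150 mV in -10 mV decrements,
then back to -60 mV — with additive i.i.d. Gaussian white noise of 10 pA
standard deviation ("10-pA amplitude" noise is read as SD; configurable).
Step timing and sampling are choices of this package: 4000 ms steps
(≥ 3.7 × the slowest time constant, so steady state is approached), 1000 ms
post-step, 1-ms sampling.

What the generator does *not* emulate: series-resistance and capacitive
artefacts, imperfect Ba²⁺ subtraction, correlated (non-white) noise, and
cell-to-cell parameter variability. Passing benchmarks therefore shows the
estimators work under the stated noise model, not that every recording
artefact is survivable.

A second parameter fixture carries the values identified from recorded
vestibular ganglion cells (slow Vh -108.6 mV, k -9.6, peak tau 0.995 s;
fast Vh -130.6 mV, k -5.1, peak tau 0.244 s). Its Gaussian widths are
shipped in both published assignments ("text": Sf 59.8 / Ss 31.2;
"figure": Ss 59.8 / Sf 31.2) because the source is internally
inconsistent; its maximal conductances and kinetic-peak voltage M were
never published, so the fixture uses the benchmark's stand-ins (3 / 4 nS,
-80 mV) and says so.

## What the benchmark studies compute

* **Error metric.** Per parameter, epsilon = |p - p_i| / |p| × 100, averaged
  over retained trials; the grand mean averages over all 14 parameters.
  On the reference benchmark the full-trace method lands near 4–5% and the
  single-trace baseline several-fold higher, with the baseline's slope and
  kinetic-amplitude errors pinned at the search bounds by the weak-step
  pathology described above.
* **Goodness of fit.** The coefficient-of-determination form
  `GoF = 1 - Σ(y - ŷ)² / Σ(y - ȳ)²` (≤ 1), computed against noiseless
  reference traces for synthetic data — for the combined current and for
  each component in isolation. The full-trace method reconstructs both
  isolated components at GoF ≈ 0.99; the single-trace baseline reconstructs
  the combined current equally well but the isolated components worse —
  the central diagnostic for why the simultaneous fit is needed.
* **Sensitivity sweeps.** Grids over the search-zone size `tol`, the
  activation separation (slow Vh from -130 to -90 mV) and the kinetic
  separation (slow A from 250 to 1250 ms), recording the Vhs/Vhf/As/Af
  errors and their per-method average m. Default grids are 5 evenly spaced
  points (the test suite uses 3-point grids at 16 trials, best 4 retained,
  with 2-ms sampling to stay within a desk-scale budget).
* **Model-order comparison.** Multi-start fits at 1/2/3 components with
  per-retained-trial GoF distributions compared pairwise by two-sample,
  two-sided Student t-tests at alpha = 0.05 (Welch variant by flag).
* **Problem sizes.** The acceptance script runs the full protocol
  (50 trials, keep 14, 1-ms sampling). The test suite replicates the
  benchmark five times at 20 trials / keep 6 — the same retention fraction
  at a smaller trial count — and this reduction does not change the
  methods' ordering.

## The neuron model

A single-compartment conductance model of a vestibular ganglion neuron:

    C dV/dt = -[ G_Na m³h (V-E_Na) + G_KH (0.85 n² + 0.15 p)(V-E_K)
                 + G_KL w⁴z (V-E_K) + G_l (V-E_l) + I_hs + I_hf ] + I_t

with fast sodium, high- and low-threshold potassium kinetics transcribed
from the cochlear-nucleus model family, a leak, and the two identified Ih
components as first-order gates. Defaults: C 12 pF, G_Na 1000 nS,
G_KH 140 nS, G_KL 0 nS (sustained phenotype) or 50 nS (transient),
G_l 2 nS; E_Na 50, E_K -77, E_h -36, E_l -67 mV. C, G_l and G_Na are the
cited family's standard values, not published for these cells; all are
overridable.

**Temperature.** The transcribed kinetics are 22 °C tables. At the default
37 °C all gating time constants are divided by `3^((37-22)/10) ≈ 5.2`
(Q10 = 3) and the transcribed Na/K conductances multiplied by
`2^((37-22)/10) ≈ 2.8` (Q10 = 2), following the source family's convention.
Without the conductance scaling the accelerated gating abolishes tonic
firing; with it the sustained model fires repetitively at 20–40 pA steps
and the transient model fires a single onset spike, as required. The Ih
kinetics are Q10-scaled like the other gates; the Ih conductances are
calibrated quantities (below) and are not temperature-scaled.

**cAMP modulation** multiplies both Ih conductances by 1.91, shifts both
half-activations by +12 mV (slope unchanged), and divides the time-constant
curves by 2.87 (fast) and 5.31 (slow). Both A and B are divided — a uniform
kinetic speed-up — switchable via `ModulationSpec.divide_base`.

**Integration** is fixed-step exponential Euler for all gates with an
exponential-integrator membrane update (unconditionally stable), dt 0.01 ms
by default; spikes are upward crossings of -10 mV grouped within a 1-ms
refractory window and reported at the local voltage peak. Halving dt moves
spike times by < 0.05 ms on the tested protocols.

**Conditioning** at a commanded potential is implemented as a
voltage-clamp-like hold (gates evolve, V forced) followed by current-free
release; 500 ms conditioning and a 5-ms gap before the test EPSC (a
double-exponential current, rise 0.05 ms, decay 5 ms, amplitude 10% above
the bisection-determined spike threshold unless given).

### Calibration of the Ih conductances

The maximal conductances of the two identified components were never
published, so the neuron model's G_hs/G_hf are calibrated against the
qualitative rebound-firing behaviours the model must reproduce:

* `G_hf = 4 nS` (default): the fast-only sustained model fires **exactly
  one** rebound spike after -250/-300 pA steps of any tested duration,
  in control and under cAMP. (At much weaker stimuli it fires none, and
  beyond ≈ -350 pA a second spike appears; single-spike behaviour across an
  arbitrarily wide amplitude range is not attainable with this activation
  curve.)
* `G_hs = 1.3 nS` (default): the slow-only sustained model fires
  duration-graded rebound bursts in control, and under cAMP the burst
  becomes duration-independent — 2 spikes at -250 pA, 3 at -300 pA — i.e.
  the neuron switches from coding stimulus duration to coding amplitude.
* `G_hs = 0.9 nS` (`G_HS_CONTROL_TRIPLE`): the alternative calibration at
  which the control burst at -250 pA grades exactly through 1/2/3 spikes
  as duration grows. No single G_hs reproduces simultaneously the 1/2/3
  triple at -250 pA, the steeper -300 pA profile and the cAMP pair, so the
  two calibrations are documented separately and the default favours the
  cAMP contrast.

The transient phenotype never fires more than one rebound spike under any
of these settings — its low-threshold potassium conductance suppresses
rebound bursting regardless of which Ih component is present.

The neuron simulations default to the recorded-cell fixture with the
"figure" width assignment (slow component wide, S 59.8), which keeps the
slow component slow across the voltages visited during rebound
(time-constant of a few hundred ms at -120 mV at 37 °C); the "text"
assignment would make the slow kinetic curve so narrow that the component
deactivates almost instantly there, erasing the slow/fast distinction the
simulations probe.

## Known limitations

* The single-trace baseline's printed-table error pattern depends on the
  optimizer's behaviour in unidentifiable directions (see the per-trace
  degeneracies above); a competent least-squares implementation polarizes
  those parameters toward the search bounds instead of leaving them near
  their random initial values. The qualitative conclusion — the
  simultaneous fit is several-fold more accurate and separates the
  components where the baseline cannot — is robust to this; the baseline's
  exact per-parameter error magnitudes are not.
* Markov-state HCN models, cyclic-nucleotide binding kinetics and
  asymmetric activation/deactivation kinetics are out of scope.
* The neuron model is single-compartment; synaptic release, calyx
  morphology and stochastic channel gating are not modelled, and the
  quantitative EPSP/latency ranges depend on the unpublished conductances
  discussed above.
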