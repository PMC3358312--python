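# Methods

## Scope and model

`stochan` simulates populations of stochastic ion channels, either
exactly (Markov-chain number tracking) or through the coupled-particle
diffusion approximation (DA), inside single-compartment membrane
models.  A kinetic scheme is a connected graph of aggregated channel
states; each edge ("transition pair") carries a forward and a backward
voltage-dependent rate.  Package-wide units are mV and ms (rates in
ms⁻¹); each membrane model declares its own consistent
conductance/current/capacitance units.

### Diffusion approximation

For `N` channels with state-fraction vector `x`, the channel-count
jump process is approximated by the Langevin equation
`dx/dt = Aᵀx + S(x,V) ξ`, where `A` is the rate matrix and
`S Sᵀ = D`, the diffusion matrix
`D_ij = −(α_ij x_i + α_ji x_j)/N` (i≠j, connected), diagonal minus the
row sums.  `S` is built in closed form with one column per transition
pair: column `k = (i,j)` holds `±c_k`, `c_k = sqrt((α_ij x_i +
α_ji x_j)/N)`, positive sign at the lower-indexed state (an arbitrary
but fixed convention; `S Sᵀ` is invariant under per-column sign
flips).  `D` is the weighted graph Laplacian of the scheme and `S` the
corresponding weighted incidence matrix, which is why the identity
holds for any topology.  The derivation treats each per-pair net
channel flux over `dt` as the difference of two binomial counts and
applies the Gaussian limit; the property suite checks
`‖S Sᵀ − D‖∞ < 1e−12` over randomized schemes.

Integration is Euler–Maruyama: per population and step, `T` (= number
of pairs) standard normals are drawn; drift always uses the
instantaneous fractions.  The highest-index state of every population
is stored implicitly as `1 − Σ(others)`, so Σx = 1 holds to machine
precision over arbitrarily long runs (the noise columns sum to zero,
making the reduction exact rather than a projection).  Fractions are
*not* clipped to [0,1] and not rounded to integers; transient
excursions below 0 are part of the method and the square roots are
taken of absolute values so coefficients remain real.  An optional
`clip01` flag exists for experimenting with large time steps, where
unclipped Euler–Maruyama is known to blow up (the engines flag and
truncate trajectories whose voltage becomes non-finite rather than
propagating NaNs); it defaults off, and with it enabled conservation
holds only approximately.

Variants:

* `exact` — the method of record, as above.
* `steady_state` — noise coefficients evaluated at the equilibrium
  fractions x∞(V) of the *instantaneous* voltage, recomputed every
  step (under current clamp through a precomputed table on a 0.05 mV
  grid over [−150, 250] mV with linear interpolation, which preserves
  the unit sum exactly; under voltage clamp the single exact vector is
  used).  This reproduces the approximation made by several published
  DA implementations.  An alternative reading — freezing x∞ at the
  resting voltage — was rejected as a strictly cruder approximation of
  those implementations.
* `uncoupled` — every gating-particle type becomes an independent
  two-state SDE with particle count = multiplicity × N, and the open
  fraction is the product of per-type fraction powers.  This is the
  diffusion limit of simulating each particle as its own Markov chain;
  with the alternative per-channel scaling (count = N) the uncoupled
  MC and DA would not coincide.  It exists as a comparison baseline
  and is only defined for schemes built from particle combinatorics.

### Markov-chain engine

Number tracking: within each membrane step of length `dt`, the rates
are frozen at the current voltage; the total event rate
λ = Σ_states N_i ζ_i (ζ_i = total escape rate of state i) generates
exponential lifetimes; each event picks a directed transition with
probability `N_i α_j / λ` by inverting the cumulative distribution with
one uniform draw, updates the counts, and redraws the lifetime.  The
residual next-transition time is carried across steps (the lifetime is
redrawn only after an event), so a pending event scheduled under the
previous voltage's rates is honoured — for large `dt` this is exactly
the accuracy degradation the benchmarks probe, and it is intentionally
not corrected.  Initial counts come from target fractions by
largest-remainder rounding (deterministic, reproducible); multinomial
sampling is available behind a flag.

Both engines run inside numba-compiled kernels; rate functions are
evaluated exactly in-kernel through a four-family encoding (constant,
linear-over-expm1, exponential, sigmoid, each with a multiplicity
factor).  Rates with removable singularities (the 0/0 point of the
linear-over-expm1 family) switch to the analytic series limit within
a relative distance 1e−7 of the singular voltage.  Arbitrary Python
callables are supported by the pure-NumPy reference backend
(`backend="python"`), which implements the identical update rules and
is cross-checked against the kernels in the test suite.

## Built-in models

* **HH potassium** (5 states / 4 pairs) and **HH sodium** (8 states /
  10 pairs) from four `n`, respectively three `m` plus one `h`,
  independent two-state particles, with the classical squid-axon rate
  functions in the frame where rest is −65 mV.  Membrane: C_m = 1 µF,
  ḡ_Na = 120 mS, ḡ_K = 36 mS, g_l = 0.3 mS, E_Na = 50 mV,
  E_K = −77 mV, E_l = −54.4 mV; currents in µA.  The benchmark channel
  ratio is N_K = 0.3 N_Na.
* **Node-of-Ranvier sodium** — same 8-state topology with the fast
  mammalian-node rates (αm = 1.872(V−25.41)/(1−e^((25.41−V)/6.06)) and
  companions), leak reversal defining 0 mV.  Membrane: R = 7.372 MΩ,
  ḡ_Na = 6.808 µS, E_Na = 144 mV, stimulus in nA, and **C_m
  = 18.9 pF**.  Published descriptions of this model are not
  unit-consistent (the capacitance is sometimes printed in nF and the
  stimulus range in pA); only the pF/nA pairing yields a working
  excitable membrane — R·C = 139 µs and ~31 mV of depolarisation per
  threshold-level 100 µs pulse — whereas an 18.9 nF membrane with
  µS-scale sodium conductance could never reach the 80 mV spike
  criterion.  The constants table keeps the printed numerals with the
  consistent units.

Gating-particle aggregation (`particle_scheme`) accepts any list of
particle types; the state space is the product of active-particle
counts with rates `(multiplicity − c)·α` up and `c·β` down, which makes
the stationary distribution the product of binomials — verified against
the nullspace of `Aᵀ` in the tests.

Current-clamp runs start, unless told otherwise, from the
deterministic resting state: V from root-finding on the steady-state
I–V curve (the root nearest the leak reversal), fractions at x∞(V).

## Analysis procedures

**Nonstationary noise analysis.**  Ensembles of voltage-clamp sweeps
(default protocol: equilibrate at the holding voltage, step to the
command voltage) yield per-time-point mean Ī and unbiased variance σ²
of the open-channel count; fitting σ² = i·Ī − Ī²/N recovers the
single-channel amplitude and channel count.  The fit is performed on
(mean, variance) pairs averaged in 100 equal-width bins along the mean
axis — the classical weighting, which gives the informative rising
phase its place rather than letting the millions of stationary samples
dominate; a raw per-time-point fit (`bins=None`) is available and
yields the same parameters with a much less interpretable R².  Two
kinds of standard errors are reported: the curve-fit errors (optimistic,
because binned residuals are strongly time-correlated) and batch-means
errors from refitting 10 disjoint sweep groups, which are the honest
ensemble-level uncertainty; consistency assertions in the tests use the
latter.  Variance estimators are unbiased (n−1) throughout.

**Spike detection and firing efficiency.**  Spikes are upward
threshold crossings (re-arming requires falling back below; a trace
starting at/above threshold counts one initial event).  Firing
efficiency at a stimulus amplitude is the fraction of independent
pulse trials with ≥1 crossing; firing-time statistics use spiking
trials only, non-spiking trials count in the denominator.  FE(a) is
fitted with the cumulative Gaussian ½(1 + erf((a − Th)/(σ√2))),
initialised from the interpolated 0.5 crossing and the 0.16/0.84
quantile spread.

**ISI analysis.**  Interspike intervals from free runs are histogrammed
(default bin width 10 ms — unstated in the original protocol,
configurable) and the normalised density fitted with an exponential
decay beyond a refractory dead time, `f(t) = r·e^(−r(t−t₀))`; a
free-amplitude parameterisation `A·e^(−rt)` is available (the tied form
is the default because the dead-time form makes the density integrate
to one).  The first two histogram bins are always excluded from the
fit regardless of bin width (they sit above the exponential trend for
membrane-resonance reasons unrelated to the simulation algorithm);
the exclusion count is configurable and recorded.

## Numerical choices and problem sizes

Default time steps: 5 µs for voltage-clamp ensembles, 1 µs for the
node-of-Ranvier pulse benchmark, 10 µs for HH free runs — small enough
that both engines sit in their converged regime (the frozen-rate MC
and Euler–Maruyama DA degrade together as dt grows).  Reproducibility:
every public entry point takes a master seed; sweep/trial k of
experiment seeded s uses the independent stream SeedSequence((s, k))
(plus an amplitude index for FE batches), so ensembles are reproducible
under any execution order.  The validation suite runs desk-scaled
versions of the three benchmark experiments — 200-sweep noise-analysis
ensembles, 200 trials × 16 amplitudes for the firing-efficiency
comparison, and 50 s / 20 s free runs at N_Na = 3000 / 1000 — sizes
chosen so the whole suite completes in minutes on one CPU while every
comparison retains enough statistical power for its assertion; the
same entry points accept the full-size parameters (1000 trials, 500 s).

## What the tests do and do not show

The benchmarks exercise the three regimes where coupled channel noise
matters: stationary and step-response conductance fluctuations under
voltage clamp, threshold-crossing variability under brief current
pulses, and noise-driven spontaneous spiking.  Passing them shows the
DA reproduces exact Markov statistics for these HH-type schemes at
physiological channel counts (hundreds to thousands).  They do not
probe very small N (tens), where the Gaussian approximation itself
breaks down; schemes with genuinely cooperative (non-particle-factorisable)
topologies are supported by construction but validated only through the
structural identities, not against an MC benchmark; and the fixed
initial composition of an ensemble means the early transient variance
lies slightly below the iid-channel parabola — an effect shared by both
engines and visible only at high ensemble precision.

## Known limitations

Euler–Maruyama only (stability findings are tied to it; no Milstein or
implicit schemes).  Rates enter kernels through the four named
families; exotic rate laws need the slow python backend or a new
family.  Single compartments only; no temperature (Q10) scaling.  The
MC engine requires one-population-per-conductance models (no product
conductances).  R² of the noise-analysis fit depends on the binning
convention; parameter estimates are insensitive to it but the
goodness-of-fit number should be compared only between fits using the
same convention.
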