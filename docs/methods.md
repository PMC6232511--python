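# Methods

## Generative model

Population activity is modelled as a driven branching process on a
discrete time grid of width Δt (default 4 ms, a typical mono-synaptic
propagation lag; it is configurable everywhere). Conditional on the
population count a_t,

    a_{t+1} | a_t  ~  Poisson(m·a_t + h).

The microscopic noise model is a genuine choice: any offspring/input
distribution with conditional mean m·a_t + h yields the same first-order
behaviour. We use Poisson because it makes two identities *exact* rather
than asymptotic — the stationary mean h/(1−m) and the lag-k
autocorrelation m^k — and the test suite leans on both. The stationary
variance is h/(1−m)/(1−m²), i.e. the Fano factor 1/(1−m²) grows near
criticality.

Initial condition: the first bin is drawn from Poisson(h/(1−m)) when the
initial efficacy is subcritical (the process starts at stationarity), or
Poisson(h) otherwise. Stationary statistics nevertheless discard a
burn-in of max(1000, 10·τ/Δt) bins, since relaxation happens on the
intrinsic timescale τ.

Supercritical efficacies (m ≥ 1) are legal inputs but have finite
expected blow-up time; a hard cap (default 10⁶ spikes/bin) raises a
divergence error naming the offending bin rather than overflowing
silently.

Time-varying efficacy m(t) is piecewise-constant between schedule
breakpoints — the simplest reading of m as a state variable, with no
interpolation assumed.

Rasters assign each bin's a_t spikes to n_neurons by uniform multinomial
allocation, the simplest exchangeable scheme for a homogeneous network.
The population stream and the assignment stream are independent
sub-streams of the one user seed (`SeedSequence(seed, spawn_key=(i,))`),
so the per-bin totals are identical for any neuron count.

Subsampling is provided in two modes: a fixed random neuron subset
(what an electrode array sees) and binomial thinning of spikes. Both
attenuate covariances more than variances and hence bias the naive lag-1
estimator; both leave the multistep estimator invariant, and the tests
require that of each.

## What the simulator does and does not emulate

The generator reproduces the statistical skeleton that the estimator
consumes: stationary rates, geometric autocorrelation decay, realistic
subsampling. It does not emulate refractoriness, oscillations,
excitatory/inhibitory structure (m already nets both contributions),
spatial topology, or non-Poissonian count dispersion. Passing tests
therefore demonstrate estimator correctness under the model's
assumptions, not robustness to every feature of real recordings.

## Multistep-regression estimation

For a (possibly subsampled) trace, the lag-k slope r_k is the OLS slope
of a_{t+k} on a_t over all valid t. Under the model, E[r_k] = b·m^k with
b = 1 under full sampling and 0 < b < 1 under subsampling (for binomial
thinning with keep-probability p, b = pV/(pV + (1−p)μ) with stationary
mean μ and variance V). The published description of the
subsampling-invariant method fixes the slope/exponential structure but
not the fitting protocol; our reconstruction is:

* **Lag range.** k_max = min(40, ⌈5·τ_guess/Δt⌉), τ_guess from the
  lag-1/lag-2 slope ratio — enough lags to span several timescales
  without descending into the noise floor. Always ≥ 3 (the fit needs
  three points).
* **Fit.** Unweighted nonlinear least squares of r_k = b·m^k with
  moment-matching start values b₀ = r₁, m₀ = r₂/r₁ clipped to (0, 1),
  avoiding local minima. Non-convergence, m̂ ≤ 0 or m̂ ≥ 1 are *flagged*
  (converged=False), never clamped: supercritical data is a legitimate
  outcome.
* **Noise floor.** If the lag-1 slope is not significantly positive
  (r₁ < 3·SE), the trace carries no detectable reverberation and the fit
  would latch onto noise; we report m̂ = 0, flagged. This makes the
  estimator exact on independent-count traces instead of erratic.
* **Timescale.** τ̂ = −Δt/log(m̂), defined (and reported) only for
  0 < m̂ < 1; exp(−Δt/τ̂) = m̂ holds to machine precision whenever the
  fit converged.

### Confidence intervals

The 95% CI uses a segment bootstrap. Lag slopes are computed once within
contiguous non-overlapping segments of max(5·k_max, 50, 3·τ̂/Δt) bins;
bootstrap replicates resample segments with replacement, average their
slope tables and refit the exponential. Resampling *within-segment
statistics* (rather than concatenating resampled blocks) matters: block
concatenation breaks temporal correlations at every join, which at lags
comparable to the block length biases the refitted m far low — we
measured 0% coverage for a naive block scheme. Per-segment slopes carry
a small finite-length bias that shifts the whole bootstrap distribution,
so the percentile deviations are centred on the full-trace point
estimate; empirical coverage is then ≈ 95% at m = 0.9 and 10⁴ bins.
Defaults: 250 replicates; `n_boot=0` skips the bootstrap.

### Time-resolved estimation

In trial-based designs, the slope at time t and lag k is estimated
across trials: each bin is centred by its own across-trial mean (which
removes the trial-averaged response, so rate transients do not
masquerade as correlation), covariances are pooled over a window of bins
around t, and the pooled slopes are fitted exactly as above. Defaults:
window 1 (pure across-trial regression; pooling exposed as a parameter),
k_max 5. Five trials are the hard minimum; below 30 a warning notes that
estimates will be noisy. Near an efficacy step the look-ahead lags mix
regimes, so estimates within ~k_max + window bins before and a few τ
after a transition should be discarded.

## Analytic regime properties

sensitivity(m) = 1/(1−m); stationary_rate(m, h) = h/(1−m);
τ(m, Δt) = −Δt/log(m) with the near-critical approximation Δt/(1−m)
also reported (relative difference < 1.1% at m ≥ 0.98, ~39% at m = 0.5);
implied_m(T, Δt) = exp(−Δt/T) inverts τ. Amplification is named but not
given a formula in the linear-response picture, so this package defines
it as the cumulative impulse response Σ_{k≥1} m^k = m/(1−m) — the unique
linear-response-consistent choice (the total response including the
injected spike, 1/(1−m), differs by one). Every divergent quantity
raises a flagged error at m ≥ 1 rather than returning infinity.

Regime labels partition m ≥ 0: asynchronous-irregular [0, 0.5),
subcritical-intermediate [0.5, 0.9), reverberating [0.9, 0.995),
near-critical [0.995, 1), critical {1}, unstable (1, ∞). The 0.9/0.995
cuts are the in-vivo band; the 0.5 cut is this package's convention and
all boundaries are configurable.

Properties that diverge with unknown exponents (active information
storage, trial-to-trial variability) are deliberately not computed:
assigning them exponents would be invention.

## Safety margin and goal function

The single-neuron efficacy m_i sums k synaptic weights; with weight CV
cv_w and fluctuations uncorrelated across synapses, σ_mi = cv_w·m/√k
(an optional correlation ρ inflates the variance by 1 + ρ(k−1),
default 0). The safety margin is n_σ·σ_mi below criticality, and the
stability probability is the one-sided Gaussian tail Φ(n_σ) — the
Gaussian model is implied by quoting "three standard deviations →
99.9%". Defaults cv_w = 0.5, k = 10,000, n_σ = 3 give a 1.5% margin and
operating point 0.985, inside the reverberating band. A Monte-Carlo
helper (`simulate_efficacy_fluctuations`) verifies that the *network
mean* over ≥ 100 neurons stays subcritical in > 99.9% of draws —
stability is governed by the average efficacy, not individual neurons.

The goal function is read with negative exponents,
Φ_α(m) = (1−m)^(−β₊) − α′(1−m)^(−β₋), because the traded-off properties
are defined as diverging at criticality like (1−m)^(−β); this is also
the only reading whose stationarity condition reproduces the closed-form
optimum m* = 1 − (α′β₋/β₊)^(−1/(β₊−β₋)). First- and second-order
conditions give the validity region β₋ > β₊, 0 < α′ < β₊/β₋, derived
here and enforced through flags: an m* outside (0, 1) or a non-maximum
stationary point is returned with `valid=False`, never clipped. α′ = 0
returns m* = 1 exactly. `optimal_m_numeric` is an independent dense
grid-search oracle over (ε, 1−ε); the suite checks closed-form/oracle
agreement on 100 random valid specs to within one grid step. The
unnormalized weight α and the normalization constants of the two
properties are absorbed into α′; no real-task exponents are shipped —
all worked values are illustrative.

## Problem sizes and numerical choices

Stationary tests use 10⁵-bin traces (10²–10⁴ intrinsic timescales
depending on m); parameter-recovery checks use 50 independent
simulations at m = 0.98 thinned to 5%; the time-resolved check uses 200
trials of 1000 bins; CI calibration uses 100 runs of 10⁴ bins — sizes at
which every targeted tolerance is comfortably inside the estimator's
sampling error. Statistical tests compare means through the effective
sample size n(1−m)/(1+m) implied by the m^k autocorrelation. Fixture
traces (10⁴ bins) hold the *analytic* stationary rate fixed across
regimes via h = r₀(1−m); their empirical means agree within sampling
error, which near criticality is necessarily wider than a few percent.

## Known limitations

* The estimator assumes stationarity within the fitted window (or within
  a trial ensemble, stationarity across trials at each bin).
* b̂ is only interpretable as a subsampling fraction proxy under
  thinning-like observation; for neuron subsets it also absorbs
  neuron-identity correlations.
* The branching description collapses all biophysics into (m, h, Δt);
  inferred τ inherits any mismatch in Δt linearly.
* Near-critical traces (m ≳ 0.995) need many multiples of τ to estimate
  m tightly; at 10⁴ bins expect m̂ scatter of ~0.01.
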