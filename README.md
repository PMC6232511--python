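# reverbkit

Cortical networks in vivo appear to operate in a *reverberating regime*:
collective spiking is neither asynchronous-irregular nor critical, but in
between, with a neural efficacy of roughly 0.9 < m < 0.995 (median
m ≈ 0.98). In this regime small changes of effective synaptic strength
retune sensitivity, amplification and the intrinsic integration timescale
over a wide range — a mechanism for rapidly adapting a circuit's
computation to task demands.

`reverbkit` is a toolkit for working with this picture quantitatively.
It is aimed at computational neuroscientists who want to simulate
population activity at a given distance from criticality, recover that
distance from (heavily subsampled) recordings, and evaluate the analytic
consequences.

## The model and the estimator

Population spike counts follow a driven branching process,

    a_{t+1} ~ Poisson(m · a_t + h),

where **m** is the neural efficacy — the mean number of additional
spikes one spike triggers in its postsynaptic targets one propagation
lag Δt later — and **h** is the external input per bin. For m < 1 the
process is stationary with rate r = h/(1−m), lag-k autocorrelation m^k,
sensitivity ∂r/∂h = 1/(1−m), and intrinsic timescale

    τ = −Δt / log(m) ≈ Δt / (1−m).

Estimating m from experiments is hard because only a tiny fraction of
neurons can be recorded: spatial subsampling attenuates the lag-1
regression slope (the conventional estimator) far below m. The
**multistep-regression (MR) estimator** implemented here is
subsampling-invariant: the lag-k slopes of a subsampled trace obey
r_k = b·m^k, so fitting that exponential across lags k = 1..k_max
recovers m while the unknown attenuation b is absorbed into the
amplitude. A trial-based variant estimates a time-resolved m(t) by
regressing across trials at each time bin.

Two analytic results close the loop:

* **Safety margin.** Single-synapse strengths fluctuate with CV ≈ 0.5,
  so a neuron with k outgoing synapses has efficacy SD
  σ_mi ≈ 0.5·m/√k. With k ≈ 10,000 a 3σ margin below criticality is
  only 1.5% (operating point m ≈ 0.985, stable 99.9% of the time) —
  right inside the band observed in vivo.
* **Task-optimal efficacy.** Properties diverge at criticality as
  (1−m)^(−β); weighing a desirable against a detrimental one,
  Φ_α(m) = (1−m)^(−β₊) − α′(1−m)^(−β₋), is maximized at
  m* = 1 − (α′β₋/β₊)^(−1/(β₊−β₋)), strictly subcritical whenever
  α′ > 0.

## Worked example

Simulate a reverberating network (m = 0.98, h = 2, 10⁵ bins of 4 ms),
observe only 5% of its spikes, and estimate m back:

```python
import reverbkit as rk

params = rk.ProcessParams(m=0.98, h=2.0, n_bins=100_000, seed=1)
trace  = rk.simulate_branching(params)
thin   = rk.subsample(trace, rk.SubsampleSpec(mode="binomial_thinning",
                                              fraction=0.05, seed=2))
res = rk.MultistepRegression(thin, k_max=40).fit(n_boot=250, seed=3)
print(res.summary())
print("naive lag-1:", round(rk.estimate_m_naive(thin), 4))
```

```
Multistep Regression Results
========================================
neural efficacy m_hat              0.977685
amplitude b_hat                    0.562068
intrinsic timescale tau (ms)       177.2418
lags used k_max                          40
bin width dt (ms)                    4.0000
converged                              True
95% CI (bootstrap, n=250)      [0.973224, 0.981562]
========================================
naive lag-1: 0.5465
```

Despite seeing one spike in twenty, the multistep fit lands on
m̂ = 0.978 with the truth (0.98) inside the CI, while the conventional
lag-1 estimator collapses to 0.55 — the subsampling attenuation b ≈ 0.56
that the MR fit absorbed into its amplitude. `rk.regime_properties(res.m_hat,
h=2.0, dt=4.0)` then reports the implied computational properties
(sensitivity ≈ 45, amplification ≈ 44, τ ≈ 177 ms, regime
"reverberating").

The same machinery is available from the shell:

```sh
reverbkit simulate --m 0.98 --h 2 --bins 100000 --seed 1 --out trace.txt
reverbkit estimate --input trace.txt --format kv --out report.txt
reverbkit classify --input report.txt
reverbkit properties --m 0.98 --h 0.2 --dt 4
reverbkit margin --k 10000 --cv 0.5 --nsigma 3
reverbkit optimize --alpha-prime 0.05 --beta-plus 1 --beta-minus 2
```

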