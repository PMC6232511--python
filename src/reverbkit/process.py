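"""Driven branching-process simulation of population spiking activity.

The generative model is a discrete-time branching process with external
drive: given the population spike count ``a_t`` in bin ``t``, the next
count is drawn as

    a_{t+1} ~ Poisson(m * a_t + h)

where ``m`` is the neural efficacy (mean number of additional spikes one
spike triggers in its postsynaptic targets in the next bin) and ``h`` is
the mean external input per bin.  For ``m < 1`` the process is stationary
with mean ``h / (1 - m)``; the lag-k autocorrelation is exactly ``m**k``.
The Poisson offspring/input choice makes both identities exact, which the
test suite exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "ProcessParams",
    "ActivityTrace",
    "SpikeRaster",
    "SubsampleSpec",
    "DivergenceError",
    "simulate_branching",
    "simulate_raster",
    "subsample",
    "default_burn_in",
]

#: hard cap on spikes per bin; crossing it raises :class:`DivergenceError`
DEFAULT_ACTIVITY_CAP = 1_000_000

# spawn keys for deriving independent sub-streams from one user seed;
# stream 0 drives the population counts, stream 1 the neuron assignment.
_STREAM_COUNTS = 0
_STREAM_ASSIGN = 1


class DivergenceError(RuntimeError):
    """Raised when activity crosses the cap (supercritical blow-up).

    Attributes
    ----------
    bin_index : int
        First bin whose count exceeded the cap.
    """

    def __init__(self, bin_index: int, cap: int):
        self.bin_index = int(bin_index)
        self.cap = int(cap)
        super().__init__(
            f"activity exceeded cap of {cap} spikes/bin at bin {bin_index}: "
            "supercritical divergence"
        )


def _substream(seed: int, stream: int) -> np.random.Generator:
    """One seeded generator per simulation stage (documented scheme)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(stream,)))


@dataclass
class ProcessParams:
    """Generative parameters of a driven branching process.

    Parameters
    ----------
    m : float
        Neural efficacy (dimensionless, >= 0).  Overridden bin-by-bin if
        ``m_schedule`` is given.
    h : float
        Mean external input per bin (spikes/bin, >= 0).
    n_bins : int
        Number of time bins (> 1).
    dt : float
        Bin width in milliseconds (> 0); default 4 ms, a typical lag of
        spike propagation between connected neurons.
    n_neurons : int, optional
        Neuron count, required only for raster generation.
    seed : int
        Random seed.
    m_schedule : sequence of (start_bin, m) pairs, optional
        Piecewise-constant efficacy schedule.  Breakpoints must be
        strictly increasing and start at bin 0; overrides ``m``.
    cap : int
        Activity cap in spikes/bin; exceeding it raises
        :class:`DivergenceError`.
    """

    m: float = 0.98
    h: float = 1.0
    n_bins: int = 10_000
    dt: float = 4.0
    n_neurons: Optional[int] = None
    seed: int = 0
    m_schedule: Optional[Sequence[tuple]] = None
    cap: int = DEFAULT_ACTIVITY_CAP

    def __post_init__(self):
        for name in ("m", "h", "dt"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.m < 0:
            raise ValueError(f"m must be >= 0, got {self.m}")
        if self.h < 0:
            raise ValueError(f"h must be >= 0, got {self.h}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if int(self.n_bins) <= 1:
            raise ValueError(f"n_bins must be > 1, got {self.n_bins}")
        self.n_bins = int(self.n_bins)
        if self.n_neurons is not None and int(self.n_neurons) < 1:
            raise ValueError(f"n_neurons must be >= 1, got {self.n_neurons}")
        if self.cap <= 0:
            raise ValueError("cap must be positive")
        if self.m_schedule is not None:
            sched = [(int(b), float(mm)) for b, mm in self.m_schedule]
            if not sched or sched[0][0] != 0:
                raise ValueError("m_schedule must start at bin 0")
            starts = [b for b, _ in sched]
            if any(b2 <= b1 for b1, b2 in zip(starts, starts[1:])):
                raise ValueError("m_schedule breakpoints must be strictly increasing")
            if any(mm < 0 or not np.isfinite(mm) for _, mm in sched):
                raise ValueError("scheduled m values must be finite and >= 0")
            self.m_schedule = sched

    def efficacy_per_bin(self) -> np.ndarray:
        """Efficacy m applied when stepping *from* each bin t to t+1."""
        if self.m_schedule is None:
            return np.full(self.n_bins, float(self.m))
        m_t = np.empty(self.n_bins)
        sched = list(self.m_schedule) + [(self.n_bins, None)]
        for (b0, mm), (b1, _) in zip(sched[:-1], sched[1:]):
            m_t[b0:min(b1, self.n_bins)] = mm
        return m_t


@dataclass
class ActivityTrace:
    """A binned population spike-count time series.

    ``counts`` are non-negative integers, one per bin; ``dt`` is the bin
    width in ms; ``meta`` records provenance (generating parameters or
    source file).
    """

    counts: np.ndarray
    dt: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 1 or c.size < 2:
            raise ValueError("counts must be a 1-d sequence with length >= 2")
        if not np.issubdtype(c.dtype, np.integer):
            if not np.all(np.equal(np.mod(c, 1), 0)):
                raise ValueError("counts must be integers")
            c = c.astype(np.int64)
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        self.counts = c.astype(np.int64)
        self.dt = float(self.dt)

    @property
    def n_bins(self) -> int:
        return self.counts.size

    def mean_rate(self, burn_in: int = 0) -> float:
        """Mean spikes/bin after discarding the first ``burn_in`` bins."""
        return float(self.counts[burn_in:].mean())


@dataclass
class SpikeRaster:
    """Per-neuron spike events on a discrete time grid.

    ``neuron_ids`` and ``bin_indices`` are parallel arrays, one entry per
    spike; summing events per bin reproduces the generating
    :class:`ActivityTrace` exactly.
    """

    n_neurons: int
    neuron_ids: np.ndarray
    bin_indices: np.ndarray
    n_bins: int
    dt: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int64)
        self.bin_indices = np.asarray(self.bin_indices, dtype=np.int64)
        if self.neuron_ids.shape != self.bin_indices.shape:
            raise ValueError("neuron_ids and bin_indices must be parallel arrays")
        if self.n_neurons < 1 or self.n_bins < 2 or self.dt <= 0:
            raise ValueError("invalid raster dimensions")
        if self.neuron_ids.size:
            if self.neuron_ids.min() < 0 or self.neuron_ids.max() >= self.n_neurons:
                raise ValueError("neuron_id out of range")
            if self.bin_indices.min() < 0 or self.bin_indices.max() >= self.n_bins:
                raise ValueError("bin_index out of range")

    @property
    def events(self) -> np.ndarray:
        """(n_events, 2) array of (neuron_id, bin_index) pairs."""
        return np.column_stack([self.neuron_ids, self.bin_indices])

    def to_trace(self) -> ActivityTrace:
        counts = np.bincount(self.bin_indices, minlength=self.n_bins)
        return ActivityTrace(counts, self.dt, meta=dict(self.meta, source="raster"))


@dataclass
class SubsampleSpec:
    """How to subsample a recording.

    ``neuron_subset`` keeps a fixed random subset of ``round(fraction *
    n_neurons)`` neurons (requires a raster); ``binomial_thinning`` keeps
    each spike independently with probability ``fraction``.
    """

    mode: str = "binomial_thinning"
    fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("neuron_subset", "binomial_thinning"):
            raise ValueError(f"unknown subsample mode {self.mode!r}")
        if not (0 < self.fraction <= 1):
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")


def default_burn_in(m: float, dt: float) -> int:
    """Bins to discard before computing stationary statistics.

    Relaxation to stationarity happens on the intrinsic timescale
    tau = -dt/log(m), so we discard max(1000, 10*tau/dt) bins.
    """
    if 0 < m < 1:
        tau_bins = -1.0 / np.log(m)
    else:
        tau_bins = 0.0
    return int(max(1000, np.ceil(10 * tau_bins)))


def simulate_branching(params: ProcessParams) -> ActivityTrace:
    """Simulate population counts of the driven branching process.

    The first bin is drawn from the stationary Poisson mean ``h/(1-m)``
    when the initial efficacy is subcritical, else from ``Poisson(h)``.
    Raises :class:`DivergenceError` (identifying the bin) if any count
    exceeds ``params.cap``.
    """
    rng = _substream(params.seed, _STREAM_COUNTS)
    m_t = params.efficacy_per_bin()
    n = params.n_bins
    counts = np.empty(n, dtype=np.int64)
    m0 = m_t[0]
    lam0 = params.h / (1.0 - m0) if m0 < 1 else params.h
    a = np.int64(rng.poisson(max(lam0, 0.0)))
    counts[0] = a
    cap = params.cap
    h = params.h
    poisson = rng.poisson
    for t in range(1, n):
        a = poisson(m_t[t - 1] * a + h)
        if a > cap:
            raise DivergenceError(t, cap)
        counts[t] = a
    meta = {
        "m": params.m, "h": params.h, "dt": params.dt,
        "seed": params.seed, "n_bins": n,
    }
    if params.m_schedule is not None:
        meta["m_schedule"] = list(params.m_schedule)
    return ActivityTrace(counts, params.dt, meta=meta)


def simulate_raster(params: ProcessParams) -> SpikeRaster:
    """Simulate a neuron-resolved raster.

    Population totals are generated by :func:`simulate_branching` with the
    identical random stream (same seed gives the same per-bin totals
    regardless of ``n_neurons``); each bin's spikes are then assigned to
    neurons by uniform multinomial allocation using an independent
    sub-stream of the same seed.
    """
    if params.n_neurons is None:
        raise ValueError("n_neurons must be set for raster simulation")
    trace = simulate_branching(params)
    rng = _substream(params.seed, _STREAM_ASSIGN)
    n_neurons = int(params.n_neurons)
    pvals = np.full(n_neurons, 1.0 / n_neurons)
    # per-bin multinomial allocation of each bin's total count
    alloc = rng.multinomial(trace.counts, pvals)  # (n_bins, n_neurons)
    bins, neurons = np.nonzero(alloc)
    reps = alloc[bins, neurons]
    return SpikeRaster(
        n_neurons=n_neurons,
        neuron_ids=np.repeat(neurons, reps),
        bin_indices=np.repeat(bins, reps),
        n_bins=trace.n_bins,
        dt=params.dt,
        meta=dict(trace.meta, n_neurons=n_neurons),
    )


def subsample(data: Union[SpikeRaster, ActivityTrace], spec: SubsampleSpec) -> ActivityTrace:
    """Subsample a recording, returning the observed population counts.

    ``neuron_subset`` requires a :class:`SpikeRaster`; ``binomial_thinning``
    accepts either input.  Expected subsampled mean is ``fraction`` times
    the full mean.  With ``fraction == 1`` the counts are returned
    unchanged.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "neuron_subset":
        if not isinstance(data, SpikeRaster):
            raise TypeError("neuron_subset subsampling requires a SpikeRaster")
        n_keep = int(round(spec.fraction * data.n_neurons))
        if n_keep < 1:
            raise ValueError("fraction * n_neurons must be >= 1")
        keep = rng.choice(data.n_neurons, size=n_keep, replace=False)
        mask = np.isin(data.neuron_ids, keep)
        counts = np.bincount(data.bin_indices[mask], minlength=data.n_bins)
        meta = dict(data.meta, subsample="neuron_subset", fraction=spec.fraction,
                    subsample_seed=spec.seed, n_kept_neurons=n_keep)
        return ActivityTrace(counts, data.dt, meta=meta)
    # binomial thinning
    trace = data.to_trace() if isinstance(data, SpikeRaster) else data
    if spec.fraction == 1.0:
        counts = trace.counts.copy()
    else:
        counts = rng.binomial(trace.counts, spec.fraction)
    meta = dict(trace.meta, subsample="binomial_thinning", fraction=spec.fraction,
                subsample_seed=spec.seed)
    return ActivityTrace(counts, trace.dt, meta=meta)
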