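"""Stability safety margin and task-optimal efficacy.

Two pieces of theory for networks operating near the critical point
m = 1:

1. **Safety margin.** Single synaptic weights w fluctuate with a
   coefficient of variation of about 0.5 over hours and days.  If these
   fluctuations are not strongly correlated across the k outgoing
   synapses of a neuron, the single-neuron efficacy m_i (a sum over k
   synapses) fluctuates with standard deviation

       sigma_mi ~ cv_w * m_i / sqrt(k),

   so with cv_w = 0.5 and k = 10,000 synapses, keeping the operating
   point n_sigma = 3 standard deviations below m = 1 — a margin of
   3 * 0.5/100 = 1.5% — leaves the network stable 99.9% of the time
   (one-sided Gaussian tail at 3 sigma).

2. **Task-optimal efficacy.** Network properties diverge at criticality
   as (1-m)^(-beta); some are desirable for a task, some detrimental.
   The trade-off goal function

       Phi_alpha(m) = (1-m)^(-beta_plus) - alpha' * (1-m)^(-beta_minus)

   is maximized at

       m* = 1 - (alpha' * beta_minus / beta_plus)^(-1/(beta_plus - beta_minus)),

   which lies strictly below 1 whenever the detrimental weight alpha' is
   positive.  The exponents here are *negative* powers of (1-m): the
   properties traded off are precisely those that diverge at the critical
   point, and this reading is the one whose stationarity condition
   reproduces the closed form above (verified against a grid-search
   oracle, :func:`optimal_m_numeric`).

The unnormalized task weight alpha and the normalization constants of
the two divergent properties are absorbed into the single rescaled
weight alpha'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "StabilitySpec",
    "GoalSpec",
    "single_neuron_efficacy_sd",
    "safety_margin",
    "stability_probability",
    "simulate_efficacy_fluctuations",
    "goal_function",
    "optimal_m",
    "optimal_m_numeric",
]


@dataclass
class StabilitySpec:
    """Parameters of the synaptic-fluctuation safety margin.

    k_synapses : outgoing synapses per neuron (cortex: order 10,000).
    cv_w : synaptic-weight coefficient of variation sigma_w/w; default
        0.5 (single synapses show ~50% strength variability).
    m : mean neural efficacy the margin is evaluated at.
    n_sigma : margin width in standard deviations (default 3).
    rho : optional pairwise correlation of synaptic fluctuations; scales
        the variance by (1 + rho*(k-1)).  Default 0 (uncorrelated).
    """

    k_synapses: int = 10_000
    cv_w: float = 0.5
    m: float = 1.0
    n_sigma: float = 3.0
    rho: float = 0.0

    def __post_init__(self):
        if int(self.k_synapses) < 1:
            raise ValueError("k_synapses must be >= 1")
        self.k_synapses = int(self.k_synapses)
        if self.cv_w < 0 or self.m < 0 or self.n_sigma < 0:
            raise ValueError("cv_w, m and n_sigma must be non-negative")
        if not (0 <= self.rho <= 1):
            raise ValueError("rho must be in [0, 1]")


def single_neuron_efficacy_sd(spec: StabilitySpec) -> float:
    """Standard deviation of the single-neuron efficacy m_i.

    sigma_mi = cv_w * m / sqrt(k): the efficacy is a sum over k
    synapses, so its variance scales as k * sigma_w^2 while its mean
    scales as k.  With correlated fluctuations (rho > 0) the variance is
    inflated by (1 + rho*(k-1)).
    """
    k = spec.k_synapses
    infl = np.sqrt(1.0 + spec.rho * (k - 1))
    return spec.cv_w * spec.m / np.sqrt(k) * infl


@dataclass
class SafetyMargin:
    """Distance from criticality needed to absorb synaptic fluctuations."""

    margin: float          # n_sigma * sigma_mi, dimensionless
    m_safe: float          # implied operating point 1 - margin
    sigma_mi: float
    spec: StabilitySpec

    @property
    def margin_percent(self) -> float:
        return 100.0 * self.margin


def safety_margin(spec: StabilitySpec) -> SafetyMargin:
    """Safety margin n_sigma * sigma_mi and operating point 1 - margin."""
    sd = single_neuron_efficacy_sd(spec)
    margin = spec.n_sigma * sd
    return SafetyMargin(margin=margin, m_safe=1.0 - margin, sigma_mi=sd, spec=spec)


def stability_probability(n_sigma: float) -> float:
    """P(stable) for a Gaussian-fluctuating efficacy held n_sigma below 1.

    One-sided standard-normal tail: Phi(n_sigma).  At 3 sigma this is
    0.99865 — stable 99.9% of the time.
    """
    if n_sigma < 0:
        raise ValueError("n_sigma must be >= 0")
    return float(stats.norm.cdf(n_sigma))


def simulate_efficacy_fluctuations(spec: StabilitySpec, m_operating: float,
                                   n_neurons: int = 100, n_draws: int = 100_000,
                                   seed: int = 0) -> float:
    """Monte-Carlo check of the margin: fraction of stable network states.

    Draws per-neuron efficacies m_i ~ Normal(m_operating,
    cv_w*m_operating/sqrt(k)) and returns the fraction of draws whose
    *network-mean* efficacy (average over n_neurons) stays below 1 —
    stability is determined by the average efficacy, not the individual
    ones.
    """
    rng = np.random.default_rng(seed)
    sd = spec.cv_w * m_operating / np.sqrt(spec.k_synapses)
    mi = rng.normal(m_operating, sd, size=(n_draws, n_neurons))
    return float(np.mean(mi.mean(axis=1) < 1.0))


@dataclass
class GoalSpec:
    """Parameters of the desirable/detrimental trade-off.

    alpha_prime : rescaled weight of the detrimental property (>= 0).
    beta_plus : scaling exponent of the desirable property (> 0).
    beta_minus : scaling exponent of the detrimental property (> 0).

    The closed-form interior maximum exists when beta_minus > beta_plus
    and 0 < alpha_prime < beta_plus/beta_minus; outside that region the
    result carries a validity flag.
    """

    alpha_prime: float
    beta_plus: float = 1.0
    beta_minus: float = 2.0

    def __post_init__(self):
        if self.alpha_prime < 0:
            raise ValueError("alpha_prime must be >= 0")
        if self.beta_plus <= 0 or self.beta_minus <= 0:
            raise ValueError("exponents must be > 0")


def goal_function(m, spec: GoalSpec):
    """Goal function Phi_alpha(m) = (1-m)^-b+ - alpha'*(1-m)^-b-.

    Accepts a scalar or array of m in (0, 1).
    """
    m_arr = np.asarray(m, dtype=float)
    if np.any((m_arr <= 0) | (m_arr >= 1)):
        raise ValueError("goal function defined for 0 < m < 1")
    x = 1.0 - m_arr
    val = x ** (-spec.beta_plus) - spec.alpha_prime * x ** (-spec.beta_minus)
    return val if val.shape else float(val)


@dataclass
class OptimalEfficacy:
    """Closed-form optimum of the goal function, with validity flags."""

    m_star: float
    valid: bool            # m_star in (0, 1) and an interior maximum
    is_maximum: bool
    spec: GoalSpec


def optimal_m(spec: GoalSpec) -> OptimalEfficacy:
    """Closed-form task-optimal efficacy.

    m* = 1 - (alpha'*b-/b+)^(-1/(b+ - b-)).  alpha' = 0 returns m* = 1
    exactly (detrimental aspects do not matter, the optimum is the
    critical point itself).  Equal exponents are degenerate (no interior
    stationary point) and raise.  An m* outside (0, 1) is returned with
    ``valid=False``, never clipped.
    """
    a, bp, bm = spec.alpha_prime, spec.beta_plus, spec.beta_minus
    if bp == bm:
        raise ValueError("degenerate exponents: beta_plus == beta_minus")
    if a == 0:
        return OptimalEfficacy(m_star=1.0, valid=True, is_maximum=True, spec=spec)
    x_star = (a * bm / bp) ** (-1.0 / (bp - bm))   # x = 1 - m at the stationary point
    m_star = 1.0 - x_star
    valid = bool(0 < m_star < 1)
    # second-order condition at the stationary point:
    # Phi(x) = x^-b+ - a x^-b-, so
    # Phi''(x) = b+(b+ + 1) x^{-b+-2} - a b-(b- + 1) x^{-b--2};
    # x = 1-m is affine, so a maximum in x is a maximum in m.
    d2 = (bp * (bp + 1) * x_star ** (-bp - 2)
          - a * bm * (bm + 1) * x_star ** (-bm - 2))
    is_max = bool(d2 < 0)
    return OptimalEfficacy(m_star=m_star, valid=valid and is_max,
                           is_maximum=is_max, spec=spec)


def optimal_m_numeric(spec: GoalSpec, grid_step: float = 1e-5) -> float:
    """Grid-search argmax of the goal function; oracle for the closed form.

    Evaluates Phi on the grid (grid_step, 1 - grid_step) and returns the
    argmax.  NaN when no interior maximum exists (argmax on the grid
    boundary).
    """
    if not (0 < grid_step <= 0.01):
        raise ValueError("grid_step must be in (0, 0.01]")
    grid = np.arange(grid_step, 1.0, grid_step)
    grid = grid[(grid > 0) & (grid < 1)]
    vals = goal_function(grid, spec)
    i = int(np.argmax(vals))
    if i == 0 or i == grid.size - 1:
        return float("nan")
    return float(grid[i])
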