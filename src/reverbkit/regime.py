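"""Analytic response properties of a network with neural efficacy m.

For a linear-response (branching / AR(1)-type) description of population
activity, the efficacy m fixes a whole family of computational
properties at once: the sensitivity of the stationary rate to input,
the stationary rate itself, the amplification of an injected spike, and
the intrinsic timescale over which input reverberates.  All diverge as
m approaches the critical point m = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "RegimeProperties",
    "DEFAULT_BOUNDARIES",
    "sensitivity",
    "intrinsic_timescale",
    "implied_m",
    "stationary_rate",
    "amplification",
    "classify_regime",
    "regime_properties",
]

#: regime label boundaries on m: [0, b0) AI, [b0, b1) intermediate,
#: [b1, b2) reverberating, [b2, 1) near-critical, {1} critical, >1 unstable.
#: 0.9 and 0.995 bound the band reported for cortex in vivo; 0.5 is this
#: package's convention for the AI/intermediate cut.
DEFAULT_BOUNDARIES = (0.5, 0.9, 0.995)


def _check_m(m: float, upper_open: bool = True) -> float:
    m = float(m)
    if not np.isfinite(m) or m < 0:
        raise ValueError(f"m must be finite and >= 0, got {m}")
    if upper_open and m >= 1:
        raise ValueError(f"m must be < 1, got {m}")
    return m


def sensitivity(m: float) -> float:
    """Sensitivity of the stationary rate to input: dr/dh = 1/(1-m).

    Diverges at criticality; raises for m >= 1.
    """
    m = _check_m(m)
    return 1.0 / (1.0 - m)


def intrinsic_timescale(m: float, dt: float, return_approx: bool = False):
    """Intrinsic network timescale tau = -dt/log(m), in ms.

    This is the decay constant of the activity autocorrelation m**(k):
    input reverberates in the network over tau.  With
    ``return_approx=True`` also returns the near-critical approximation
    dt/(1-m) and the relative difference between the two.
    """
    m = float(m)
    if not (0 < m < 1):
        raise ValueError(f"intrinsic timescale requires 0 < m < 1, got {m}")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    tau = -dt / np.log(m)
    if not return_approx:
        return tau
    approx = dt / (1.0 - m)
    return tau, approx, abs(approx - tau) / tau


def implied_m(response_duration: float, dt: float) -> float:
    """Efficacy whose intrinsic timescale equals a response duration.

    Inverse of :func:`intrinsic_timescale`: m = exp(-dt/duration).  A
    network response lasting at least 50 ms with dt = 4 ms implies
    m >= exp(-4/50) ~ 0.92.
    """
    if response_duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    return float(np.exp(-dt / response_duration))


def stationary_rate(m: float, h: float) -> float:
    """Stationary population rate r = h/(1-m) in spikes/bin."""
    m = _check_m(m)
    if h < 0:
        raise ValueError("h must be >= 0")
    return h / (1.0 - m)


def amplification(m: float) -> float:
    """Total extra spikes eventually triggered per injected spike.

    Defined here as the cumulative impulse response
    sum_{k>=1} m**k = m/(1-m) (the total response including the injected
    spike is 1/(1-m)).  For m >= 1 stimuli can be amplified infinitely,
    so an error is raised rather than returning infinity.
    """
    m = float(m)
    if not np.isfinite(m) or m < 0:
        raise ValueError(f"m must be finite and >= 0, got {m}")
    if m >= 1:
        raise ValueError(f"infinite amplification: m = {m} >= 1")
    return m / (1.0 - m)


def classify_regime(m: float, boundaries=DEFAULT_BOUNDARIES) -> str:
    """Label the dynamical regime of an efficacy m.

    Partition of m >= 0 (default boundaries 0.5, 0.9, 0.995):
    asynchronous-irregular, subcritical-intermediate, reverberating,
    near-critical, critical (m = 1 exactly), unstable (m > 1).
    """
    m = float(m)
    if not np.isfinite(m) or m < 0:
        raise ValueError(f"m must be finite and >= 0, got {m}")
    b0, b1, b2 = boundaries
    if not (0 < b0 < b1 < b2 < 1):
        raise ValueError("boundaries must satisfy 0 < b0 < b1 < b2 < 1")
    if m > 1:
        return "unstable"
    if m == 1:
        return "critical"
    if m >= b2:
        return "near-critical"
    if m >= b1:
        return "reverberating"
    if m >= b0:
        return "subcritical-intermediate"
    return "asynchronous-irregular"


@dataclass
class RegimeProperties:
    """Bundle of analytic properties attached to one efficacy m."""

    m: float
    sensitivity: float
    amplification: float
    regime_label: str
    stationary_rate: Optional[float] = None
    tau: Optional[float] = None
    tau_approx: Optional[float] = None

    def report(self) -> str:
        lines = [
            f"{'neural efficacy m':28s} {self.m:12.6g}",
            f"{'regime':28s} {self.regime_label:>12s}",
            f"{'sensitivity dr/dh':28s} {self.sensitivity:12.6g}",
            f"{'amplification m/(1-m)':28s} {self.amplification:12.6g}",
        ]
        if self.stationary_rate is not None:
            lines.append(f"{'stationary rate (spk/bin)':28s} {self.stationary_rate:12.6g}")
        if self.tau is not None:
            lines.append(f"{'timescale tau (ms)':28s} {self.tau:12.6g}")
            lines.append(f"{'tau approx dt/(1-m) (ms)':28s} {self.tau_approx:12.6g}")
        return "\n".join(lines)


def regime_properties(m: float, h: Optional[float] = None,
                      dt: Optional[float] = None) -> RegimeProperties:
    """All analytic properties of an efficacy m in one record."""
    label = classify_regime(m)
    tau = tau_approx = rate = None
    if dt is not None and 0 < m < 1:
        tau, tau_approx, _ = intrinsic_timescale(m, dt, return_approx=True)
    if h is not None:
        rate = stationary_rate(m, h)
    return RegimeProperties(
        m=float(m),
        sensitivity=sensitivity(m),
        amplification=amplification(m),
        regime_label=label,
        stationary_rate=rate,
        tau=tau,
        tau_approx=tau_approx,
    )
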