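"""Conversions between mutation-scaled and demographic IM parameters.

The inference machinery works with mutation-scaled parameters: per-locus
population mutation rates theta = 4*Ne*mu, a scaled split time T = t*mu,
and migration-to-mutation ratios M_i = m_i/mu.  Demographic readout
(individuals, years) requires a mutation-rate model: under the multilocus
model the relevant mu is the geometric mean of the locus-specific rates.
T converts to years through the per-year rate and theta/M convert through
the per-generation rate (per-year rate x generation time).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

__all__ = [
    "RateModel",
    "geometric_mean_rate",
    "per_generation_rate",
    "to_demographic",
    "from_demographic",
]


def geometric_mean_rate(rates: Sequence[float]) -> float:
    """Geometric mean of per-locus mutation rates: exp(mean(log(rates)))."""
    r = np.asarray(rates, dtype=float)
    if r.size == 0:
        raise ValueError("need at least one rate")
    if np.any(r <= 0):
        raise ValueError("all rates must be positive")
    return float(np.exp(np.mean(np.log(r))))


def per_generation_rate(mu_year: float, generation_time: float) -> float:
    """Per-generation rate from a per-year rate and a generation time in years."""
    if mu_year <= 0 or generation_time <= 0:
        raise ValueError("mu_year and generation_time must be positive")
    return mu_year * generation_time


@dataclasses.dataclass(frozen=True)
class RateModel:
    """Mutation-rate model used for unit conversions.

    ``mu_per_locus_per_year`` are whole-locus rates; the geometric mean is
    the multilocus rate entering every theta/T/M conversion.
    """

    mu_per_locus_per_year: tuple
    generation_time: float = 25.0

    def __post_init__(self):
        object.__setattr__(self, "mu_per_locus_per_year",
                           tuple(float(x) for x in self.mu_per_locus_per_year))
        if any(m <= 0 for m in self.mu_per_locus_per_year):
            raise ValueError("rates must be positive")
        if self.generation_time <= 0:
            raise ValueError("generation_time must be positive")

    @property
    def geometric_mean_per_year(self) -> float:
        return geometric_mean_rate(self.mu_per_locus_per_year)

    @property
    def geometric_mean_per_generation(self) -> float:
        return per_generation_rate(self.geometric_mean_per_year, self.generation_time)

    @classmethod
    def from_design(cls, design) -> "RateModel":
        return cls(design.mu_per_locus, design.generation_time)


def to_demographic(scaled, rate_model: RateModel):
    """Convert mutation-scaled parameters to demographic units.

    Ne = theta / (4 mu_gen);  t_years = T / mu_year;  m = M * mu_gen.
    """
    from .simulate import IMParams  # local import to avoid a cycle

    mu_g = rate_model.geometric_mean_per_generation
    mu_y = rate_model.geometric_mean_per_year
    return IMParams(
        N_A=scaled.theta_A / (4.0 * mu_g),
        N1=scaled.theta1 / (4.0 * mu_g),
        N2=scaled.theta2 / (4.0 * mu_g),
        s=scaled.s,
        t_years=scaled.T / mu_y,
        m1=scaled.M1 * mu_g,
        m2=scaled.M2 * mu_g,
        rho_per_locus=getattr(scaled, "rho_per_locus", 0.0),
    )


def from_demographic(params, rate_model: RateModel):
    """Inverse of :func:`to_demographic` (round-trips to ~1e-12 relative)."""
    from .simulate import ScaledIMParams

    mu_g = rate_model.geometric_mean_per_generation
    mu_y = rate_model.geometric_mean_per_year
    return ScaledIMParams(
        theta_A=4.0 * params.N_A * mu_g,
        theta1=4.0 * params.N1 * mu_g,
        theta2=4.0 * params.N2 * mu_g,
        T=params.t_years * mu_y,
        M1=params.m1 / mu_g,
        M2=params.m2 / mu_g,
        s=params.s,
        rho_per_locus=params.rho_per_locus,
    )
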