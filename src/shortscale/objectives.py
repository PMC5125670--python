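"""Pheromone transforms and cost functions for short-scale optimization.

The ant-colony objective maps four psychometric criteria onto commensurate
(mostly 0-1) "pheromone" levels via logistic transforms centered at the
field's conventional cutoffs, so that differences near a cutoff matter more
than differences in the tails:

* model fit:     phi_CFI   = expit(100*CFI - 95)       (midpoint at CFI = .95)
                 phi_RMSEA = expit(5 - 100*RMSEA)      (midpoint at RMSEA = .05)
                 phi_Fit   = (phi_CFI + phi_RMSEA) / 2
* reliability:   phi_Rel   = expit(10*omega - 9)       (midpoint at omega = .90)
* sensitivity:   phi_Sens  = 1 - 5*(M_item - .625)^2   (peak at mean difficulty
                 .625, the optimum for four-alternative items with a .25
                 guessing floor)
* validity:      phi_Cor   = expit(3 - 100*max|dr|)    (midpoint at max = .03)

The overall objective is the equally weighted sum of the four.  The genetic
algorithm instead minimizes ``cost = I*k + (1 - R^2)``: a fixed per-item cost
I times the number of retained items k, plus the variance of the long-form
total score left unexplained by the retained items.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "PheromoneComponents",
    "GACostInputs",
    "phi_cfi",
    "phi_rmsea",
    "phi_fit",
    "phi_rel",
    "phi_sens",
    "phi_cor",
    "total_objective",
    "ga_cost",
]


def phi_cfi(cfi: float) -> float:
    """Logistic pheromone for the Comparative Fit Index; 0.5 at CFI = .95."""
    if not 0.0 <= cfi <= 1.0:
        raise ValueError(f"CFI must be in [0, 1], got {cfi}")
    return float(expit(100.0 * cfi - 95.0))


def phi_rmsea(rmsea: float) -> float:
    """Logistic pheromone for RMSEA; 0.5 at RMSEA = .05, decreasing."""
    if rmsea < 0:
        raise ValueError(f"RMSEA must be >= 0, got {rmsea}")
    return float(expit(5.0 - 100.0 * rmsea))


def phi_fit(phi_cfi_value: float, phi_rmsea_value: float) -> float:
    """Mean of the two fit pheromones."""
    for v in (phi_cfi_value, phi_rmsea_value):
        if not 0.0 <= v <= 1.0:
            raise ValueError("fit pheromones must be in [0, 1]")
    return 0.5 * (phi_cfi_value + phi_rmsea_value)


def phi_rel(omega: float) -> float:
    """Logistic pheromone for McDonald's omega; 0.5 at omega = .90."""
    if not 0.0 <= omega <= 1.0:
        raise ValueError(f"omega must be in [0, 1], got {omega}")
    return float(expit(10.0 * omega - 9.0))


def phi_sens(mean_difficulty: float, clamp: bool = True) -> float:
    """Quadratic sensitivity pheromone, peaking at mean difficulty .625.

    The raw parabola ``1 - 5*(M - .625)^2`` goes negative for means below
    ~.178 or above ~1.07, out of step with the 0-1 scaling of the logistic
    components; ``clamp=True`` (default) floors it at 0.
    """
    if not 0.0 <= mean_difficulty <= 1.0:
        raise ValueError(f"mean difficulty must be in [0, 1], got {mean_difficulty}")
    value = 1.0 - 5.0 * (mean_difficulty - 0.625) ** 2
    return max(value, 0.0) if clamp else value


def phi_cor(max_abs_diff: float) -> float:
    """Logistic pheromone for the largest covariate-correlation shift; 0.5 at .03."""
    if not 0.0 <= max_abs_diff <= 2.0:
        raise ValueError(f"max |dr| must be in [0, 2], got {max_abs_diff}")
    return float(expit(3.0 - 100.0 * max_abs_diff))


@dataclass(frozen=True)
class PheromoneComponents:
    """The component pheromones of one candidate subset and their sum."""

    phi_cfi: float
    phi_rmsea: float
    phi_fit: float
    phi_rel: float
    phi_sens: float
    phi_cor: float
    total: float
    sens_clamped: bool = True

    @classmethod
    def from_metrics(
        cls,
        cfi: float,
        rmsea: float,
        omega: float,
        mean_difficulty: float,
        max_abs_delta_r: float,
        clamp_sens: bool = True,
    ) -> "PheromoneComponents":
        p_cfi = phi_cfi(cfi)
        p_rmsea = phi_rmsea(rmsea)
        p_fit = phi_fit(p_cfi, p_rmsea)
        p_rel = phi_rel(omega)
        p_sens = phi_sens(mean_difficulty, clamp=clamp_sens)
        p_cor = phi_cor(max_abs_delta_r)
        return cls(
            phi_cfi=p_cfi,
            phi_rmsea=p_rmsea,
            phi_fit=p_fit,
            phi_rel=p_rel,
            phi_sens=p_sens,
            phi_cor=p_cor,
            total=p_fit + p_rel + p_sens + p_cor,
            sens_clamped=clamp_sens,
        )


def total_objective(components: PheromoneComponents) -> float:
    """Equally weighted sum of fit, reliability, sensitivity, and validity."""
    return (
        components.phi_fit
        + components.phi_rel
        + components.phi_sens
        + components.phi_cor
    )


@dataclass(frozen=True)
class GACostInputs:
    """Inputs of the genetic-algorithm cost: item cost I, length k, R^2."""

    item_cost_I: float
    k: int
    r_squared: float

    def __post_init__(self) -> None:
        if self.item_cost_I < 0:
            raise ValueError("item cost must be nonnegative")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("R^2 must be in [0, 1]")


def ga_cost(inputs: GACostInputs) -> float:
    """``cost = I*k + (1 - R^2)``: brevity pressure vs. unexplained variance."""
    return inputs.item_cost_I * inputs.k + (1.0 - inputs.r_squared)
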