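"""Rate kernels of the size-structured isopod population model.

Every demographic and trophic process is a pure function of body length
``l`` (mm) and a small parameter container:

* individual growth ``g(l)`` — von Bertalanffy or (size-dependent)
  logistic, five variants subject to model selection,
* piecewise-constant mortality ``m(l)`` with an optional senile branch,
* reproduction — per-female birth rate ``b(l)`` normally distributed over
  maternal length, offspring entering with normally distributed birth
  lengths,
* three size-selective predation losses: cannibalism (within species),
  intraguild predation (pooled over both species) and terrestrial
  predation (birds taking emerged animals above a critical length).

Internal units are mm and days.  The birth-rate amplitude ``f_max`` is
tabulated per week, as is the net population growth rate; conversion by
a factor of 7 happens exactly once at module boundaries
(:func:`birth_source`, and the week-scale reporting in
:mod:`idopspm.npgr`).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

__all__ = [
    "DAYS_PER_WEEK",
    "GrowthVariant",
    "GrowthParams",
    "MortalityParams",
    "ReproductionParams",
    "PredationParams",
    "SpeciesParams",
    "growth_rate",
    "mortality_rate",
    "fecundity",
    "birth_source",
    "vulnerability",
    "volume_weighted_vulnerability",
    "cannibalism_rate",
    "intraguild_rate",
    "terrestrial_rate",
]

DAYS_PER_WEEK = 7.0


class GrowthVariant(str, Enum):
    """The five individual-growth models subject to AIC selection."""

    G1 = "G1"  #: von Bertalanffy
    G2 = "G2"  #: logistic
    G3 = "G3"  #: logistic, maximal length fixed externally
    G4 = "G4"  #: logistic with size-dependent growth rate
    G5 = "G5"  #: idem, maximal length fixed externally


_SIZE_DEP = (GrowthVariant.G4, GrowthVariant.G5)
_FIXED_LMAX = (GrowthVariant.G3, GrowthVariant.G5)


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of one growth model for one species x sex x treatment.

    ``rho`` is the growth-rate constant of G1-G3; the size-dependent
    variants G4/G5 use a juvenile rate ``rho_j`` saturating to the adult
    rate ``rho_a`` around the critical length ``l_crit`` with steepness
    ``beta``.  ``l_max_fixed`` marks G3/G5 fits where the maximal length
    was taken from a reference fit rather than estimated.
    """

    variant: GrowthVariant
    l_max: float
    rho: float = 0.0
    rho_j: float = 0.0
    rho_a: float = 0.0
    l_crit: float | None = None
    beta: float | None = None
    l_max_fixed: bool = False

    def __post_init__(self) -> None:
        variant = GrowthVariant(self.variant)
        object.__setattr__(self, "variant", variant)
        if self.l_max <= 0:
            raise ValueError("l_max must be positive")
        if min(self.rho, self.rho_j, self.rho_a) < 0:
            raise ValueError("growth rates must be nonnegative")
        if variant in _SIZE_DEP:
            if self.l_crit is None or self.l_crit <= 0:
                raise ValueError(f"{variant.value} requires l_crit > 0")
            if self.beta is None or self.beta <= 0:
                raise ValueError(f"{variant.value} requires beta > 0")
        if variant in _FIXED_LMAX and not self.l_max_fixed:
            object.__setattr__(self, "l_max_fixed", True)


@dataclass(frozen=True)
class MortalityParams:
    """Basic mortality ``mu`` below the senile length l_s = l_max - delta_s,
    senile mortality ``mu_s`` above.  By default the senile branch is off
    (``mu_s = mu``, ``delta_s = 0``)."""

    mu: float
    mu_s: float | None = None
    delta_s: float = 0.0

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be nonnegative")
        if self.delta_s < 0:
            raise ValueError("delta_s must be nonnegative")
        if self.mu_s is None:
            object.__setattr__(self, "mu_s", self.mu)


@dataclass(frozen=True)
class ReproductionParams:
    """Per-female birth rate amplitude ``f_max`` (week^-1), normal over
    maternal length (``l_r``, ``sigma_r``); offspring lengths normal
    (``l_b``, ``sigma_b``).  Birth lengths were not recorded in the
    experiments; 2 and 0.25 mm are the model's deliberate settings."""

    f_max: float
    l_r: float
    sigma_r: float
    l_b: float = 2.0
    sigma_b: float = 0.25

    def __post_init__(self) -> None:
        if self.f_max < 0:
            raise ValueError("f_max must be nonnegative")
        if self.sigma_r <= 0 or self.sigma_b <= 0:
            raise ValueError("sigma_r and sigma_b must be positive")


@dataclass(frozen=True)
class PredationParams:
    """Rates and geometry of the three size-selective predation kernels.

    ``upsilon`` — cannibalism rate, ``upsilon_ig`` — intraguild predation
    rate, ``tau`` — terrestrial predation rate (all d^-1).  The vulnerability
    geometry: a predator must exceed ``lambda_min`` in length and its prey
    by at least ``delta_min``; vulnerability ramps linearly over the
    selective range ``s_range`` and saturates for predators above
    ``lambda_u``.  Terrestrial predators take only prey of length >= ``l_p``.
    """

    upsilon: float = 0.0
    upsilon_ig: float = 0.0
    tau: float = 0.0
    lambda_min: float = 15.0
    delta_min: float = 2.0
    lambda_u: float = 25.0
    s_range: float = 10.0
    l_p: float = 12.0

    def __post_init__(self) -> None:
        if min(self.upsilon, self.upsilon_ig, self.tau) < 0:
            raise ValueError("predation rates must be nonnegative")
        if self.s_range <= 0:
            raise ValueError("s_range must be positive")
        if self.lambda_u < self.lambda_min:
            raise ValueError("lambda_u must be >= lambda_min")
        if self.delta_min < 0:
            raise ValueError("delta_min must be nonnegative")


@dataclass(frozen=True)
class SexParams:
    growth: GrowthParams
    mortality: MortalityParams


@dataclass(frozen=True)
class SpeciesParams:
    """Full demographic parameter set for one species under one treatment."""

    species: str
    female: SexParams
    male: SexParams
    reproduction: ReproductionParams


# ---------------------------------------------------------------------------
# individual-level rates


def growth_rate(l, gp: GrowthParams):
    """Individual growth g(l) in mm/d for the selected variant.

    May be negative for l > l_max (logistic variants); the PDE solver
    clamps it at zero so that no individual shrinks.
    """
    l = np.asarray(l, dtype=float)
    if np.any(l < 0):
        raise ValueError("length must be nonnegative")
    v = gp.variant
    if v is GrowthVariant.G1:
        return gp.rho * (gp.l_max - l)
    if v in (GrowthVariant.G2, GrowthVariant.G3):
        return gp.rho * l * (1.0 - l / gp.l_max)
    if v in _SIZE_DEP:
        rho_l = gp.rho_a - (gp.rho_a - gp.rho_j) * np.exp(
            -((l / gp.l_crit) ** gp.beta)
        )
        return rho_l * l * (1.0 - l / gp.l_max)
    raise ValueError(f"unknown growth variant: {v!r}")


def mortality_rate(l, mp: MortalityParams, l_max: float):
    """Piecewise mortality m(l) in d^-1: mu below l_s = l_max - delta_s,
    mu_s at and above."""
    l = np.asarray(l, dtype=float)
    l_s = l_max - mp.delta_s
    return np.where(l < l_s, mp.mu, mp.mu_s)


def fecundity(l, rp: ReproductionParams):
    """Per-female birth rate b(l) = f_max * N(l; l_r, sigma_r), week^-1 mm^-1."""
    l = np.asarray(l, dtype=float)
    return rp.f_max * stats.norm.pdf(l, rp.l_r, rp.sigma_r)


def birth_source(u_f, rp: ReproductionParams, grid):
    """Newborn source r(t, l) on the grid, in mm^-1 d^-1.

    The total birth rate B = integral of b(l) u_f dl (trapezoidal, per
    week) is converted to d^-1 here — the single week-to-day conversion —
    and distributed over the birth-length distribution N(l; l_b, sigma_b),
    discretized by cell averages so the distributed mass equals B exactly.
    """
    u_f = np.asarray(u_f, dtype=float)
    if np.any(u_f < 0):
        raise ValueError("female density must be nonnegative")
    b = fecundity(grid.centers, rp)
    total_per_week = np.trapezoid(b * u_f, grid.centers)
    total_per_day = total_per_week / DAYS_PER_WEEK
    return total_per_day * grid.cell_averaged_normal(rp.l_b, rp.sigma_b)


# ---------------------------------------------------------------------------
# predation kernels


def vulnerability(lam, Lam, pp: PredationParams):
    """Vulnerability alpha(lambda, Lambda) in [0, 1] of a prey of length
    ``lam`` to a predator of length ``Lam``.

    Zero unless the predator exceeds ``lambda_min`` and the prey by more
    than ``delta_min``; otherwise the linear ramp
    A = min(1, (Lambda - lambda + delta_min) / s_range), evaluated at
    ``lambda_u`` for predators above that threshold.
    """
    lam = np.asarray(lam, dtype=float)
    Lam = np.asarray(Lam, dtype=float)

    def ramp(prey, pred):
        return np.clip((pred - prey + pp.delta_min) / pp.s_range, 0.0, 1.0)

    a = np.where(Lam > pp.lambda_u, ramp(lam, pp.lambda_u), ramp(lam, Lam))
    zero = (Lam <= pp.lambda_min) | (Lam <= lam + pp.delta_min)
    return np.where(zero, 0.0, a)


def volume_weighted_vulnerability(prey_l, predator_density, pp, grid):
    """Fraction of the population's body volume able to prey on each
    prey length: integral of alpha(l, L) L^3 P(L) dL over integral of
    L^3 P(L) dL.  Degree-0 homogeneous in the density; zero when the
    population carries no volume."""
    P = np.asarray(predator_density, dtype=float)
    w = grid.centers**3 * P * grid.dl
    denom = w.sum()
    if denom <= 0.0:
        return np.zeros_like(np.asarray(prey_l, dtype=float))
    alpha = vulnerability(
        np.asarray(prey_l, dtype=float)[:, None], grid.centers[None, :], pp
    )
    return alpha @ w / denom


def cannibalism_rate(l, u_f, u_m, pp: PredationParams, grid):
    """Cannibalistic loss rate (d^-1, nonnegative) at prey lengths ``l``
    given conspecific female and male densities."""
    _check_density(u_f, u_m)
    return pp.upsilon * volume_weighted_vulnerability(l, np.add(u_f, u_m), pp, grid)


def intraguild_rate(l, state_a, state_b, pp: PredationParams, grid, pool: str = "cross"):
    """Intraguild predation loss rate (d^-1, nonnegative) on species A:
    same kernel as cannibalism, rate ``upsilon_ig``.

    ``pool`` selects the predatory mass driving the loss on A.  The
    default ``"cross"`` uses the other species only (mutual predation
    between the two isopods, with cannibalism a separate process), which
    matches the observed asymmetry: only the species reaching predator
    size depresses the other.  ``"both"`` pools both species' volumes,
    which implicitly re-counts conspecific (cannibalistic) predation.
    ``state_a``/``state_b`` are (u_f, u_m) pairs; pass zero arrays for
    an absent species."""
    _check_density(*state_a, *state_b)
    if pool == "cross":
        predators = state_b[0] + state_b[1]
    elif pool == "both":
        predators = state_a[0] + state_a[1] + state_b[0] + state_b[1]
    else:
        raise ValueError(f"unknown predator pool {pool!r}")
    return pp.upsilon_ig * volume_weighted_vulnerability(l, predators, pp, grid)


def terrestrial_rate(l, pp: PredationParams):
    """Terrestrial (bird) predation loss: tau for prey of length >= l_p."""
    l = np.asarray(l, dtype=float)
    return np.where(l >= pp.l_p, pp.tau, 0.0)


def _check_density(*arrays) -> None:
    for u in arrays:
        if np.any(np.asarray(u) < 0):
            raise ValueError("densities must be nonnegative")
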