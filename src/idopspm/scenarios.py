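"""Scenario and gradient analysis: predation-rate sweeps and tipping points.

A *tipping point* is the parameter value at which the two species'
net population growth rates coincide, i.e. where competitive dominance
switches.  Two analyses are provided:

* rate sweeps — NPGR of both species as a function of the cannibalism,
  intraguild or terrestrial predation rate under one treatment's
  parameters, with the crossing rate located by bisection;
* the tidal gradient — every demographic parameter interpolated linearly
  between its reference (theta = 0 h emergence) and tidal (theta = 5 h)
  estimate, NPGR computed along theta, and the critical tidal duration
  located by bisection.  Durations beyond 5 h are linear extrapolations.

In the gradient the intraguild rate is fixed (0.01 d^-1 by default) and
the terrestrial rate grows with emergence duration, tau = 0.01 theta d^-1,
both optionally scaled by +-10 % for sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import load_predation_defaults, load_table3
from .npgr import NpgrFit, npgr
from .process_models import (
    GrowthParams,
    GrowthVariant,
    MortalityParams,
    PredationParams,
    ReproductionParams,
    SexParams,
    SpeciesParams,
)
from .solver import LengthGrid, Scenario, SimulationConfig

__all__ = [
    "DELTA_THETA",
    "RateSweepResult",
    "GradientResult",
    "interpolate_params",
    "interpolate_species_params",
    "npgr_vs_rate",
    "gradient_npgr",
    "sensitivity_table",
]

#: emergence duration of the tidal treatment (h); anchor of the interpolation
DELTA_THETA = 5.0

#: reference intraguild predation rate in the gradient analysis (d^-1)
GRADIENT_UPSILON_IG = 0.01
#: terrestrial rate per hour of emergence in the gradient analysis (d^-1 h^-1)
GRADIENT_TAU_PER_HOUR = 0.01

#: default simulation horizon (d) for NPGR runs; the late half is the fit
#: window, long enough for cohort cycles to damp out (log-linear R^2 > 0.999)
NPGR_T_END = 400.0

_GRADIENT_SCENARIOS = (
    Scenario.NONE,
    Scenario.INTRAGUILD,
    Scenario.TERRESTRIAL,
    Scenario.INTRAGUILD_AND_TERRESTRIAL,
)


@dataclass(frozen=True)
class RateSweepResult:
    scenario: Scenario
    treatment: str
    rates: np.ndarray
    k: dict[str, np.ndarray]  # species -> NPGR (week^-1) per rate
    tipping_rate: float | None  # rate where the two species' k cross


@dataclass(frozen=True)
class GradientResult:
    scenario: Scenario
    p0_scale: float
    thetas: np.ndarray
    k: dict[str, np.ndarray]
    theta_crit: float | None


def interpolate_params(theta: float, p_ref: float, p_tides: float) -> float:
    """Linear interpolation of a scalar parameter along tidal duration
    theta (h): p(theta) = (1 - theta/5) p_ref + (theta/5) p_tides.
    Durations above 5 h extrapolate linearly."""
    if theta < 0:
        raise ValueError("tidal duration must be nonnegative")
    w = theta / DELTA_THETA
    return (1.0 - w) * p_ref + w * p_tides


def _interp_rate(theta: float, p_ref: float, p_tides: float) -> float:
    # extrapolation far beyond 5 h can cross zero; rates are floored there
    return max(0.0, interpolate_params(theta, p_ref, p_tides))


def _promote_to_g4(gp: GrowthParams, template: GrowthParams) -> GrowthParams:
    """Embed a plain logistic fit (G2/G3) in the size-dependent family:
    rho_j = rho_a = rho reduces G4 to G2, with the shape constants
    (l_crit, beta) taken from the size-dependent endpoint."""
    if gp.variant in (GrowthVariant.G4, GrowthVariant.G5):
        return gp
    if gp.variant is GrowthVariant.G1:
        raise ValueError("cannot interpolate between von Bertalanffy and logistic growth")
    return GrowthParams(
        variant=GrowthVariant.G4,
        l_max=gp.l_max,
        rho_j=gp.rho,
        rho_a=gp.rho,
        l_crit=template.l_crit,
        beta=template.beta,
    )


def _interp_growth(theta: float, ref: GrowthParams, tid: GrowthParams) -> GrowthParams:
    size_dep = GrowthVariant.G4 in (ref.variant, tid.variant) or GrowthVariant.G5 in (
        ref.variant,
        tid.variant,
    )
    if size_dep:
        template = tid if tid.variant in (GrowthVariant.G4, GrowthVariant.G5) else ref
        a = _promote_to_g4(ref, template)
        b = _promote_to_g4(tid, template)
        return GrowthParams(
            variant=GrowthVariant.G4,
            l_max=interpolate_params(theta, a.l_max, b.l_max),
            rho_j=_interp_rate(theta, a.rho_j, b.rho_j),
            rho_a=_interp_rate(theta, a.rho_a, b.rho_a),
            l_crit=interpolate_params(theta, a.l_crit, b.l_crit),
            beta=interpolate_params(theta, a.beta, b.beta),
        )
    return GrowthParams(
        variant=GrowthVariant.G2,
        l_max=interpolate_params(theta, ref.l_max, tid.l_max),
        rho=_interp_rate(theta, ref.rho, tid.rho),
    )


def interpolate_species_params(
    theta: float, ref: SpeciesParams, tid: SpeciesParams
) -> SpeciesParams:
    """All demographic parameters interpolated at tidal duration theta."""

    def sex(a: SexParams, b: SexParams) -> SexParams:
        return SexParams(
            growth=_interp_growth(theta, a.growth, b.growth),
            mortality=MortalityParams(
                mu=_interp_rate(theta, a.mortality.mu, b.mortality.mu),
                mu_s=_interp_rate(theta, a.mortality.mu_s, b.mortality.mu_s),
                delta_s=interpolate_params(theta, a.mortality.delta_s, b.mortality.delta_s),
            ),
        )

    rr, rt = ref.reproduction, tid.reproduction
    return SpeciesParams(
        species=ref.species,
        female=sex(ref.female, tid.female),
        male=sex(ref.male, tid.male),
        reproduction=ReproductionParams(
            f_max=_interp_rate(theta, rr.f_max, rt.f_max),
            l_r=interpolate_params(theta, rr.l_r, rt.l_r),
            sigma_r=interpolate_params(theta, rr.sigma_r, rt.sigma_r),
            l_b=interpolate_params(theta, rr.l_b, rt.l_b),
            sigma_b=interpolate_params(theta, rr.sigma_b, rt.sigma_b),
        ),
    )


def _npgr_cfg(scenario: Scenario, ig_pool: str = "pooled") -> SimulationConfig:
    return SimulationConfig(
        t_end=NPGR_T_END, dt_out=1.0, scenario=scenario, ig_pool=ig_pool
    )


def _k_both(
    params: dict[str, SpeciesParams], pp: PredationParams, scenario: Scenario,
    grid: LengthGrid | None = None, coupled: bool = True, ig_pool: str = "pooled",
) -> dict[str, float]:
    cfg = _npgr_cfg(scenario, ig_pool)
    if coupled:
        fits = npgr(params, pp, scenario=scenario, cfg=cfg, grid=grid)
        return {sp: f.k for sp, f in fits.items()}
    out = {}
    for sp, p in params.items():
        fit = npgr({sp: p}, pp, scenario=scenario, cfg=cfg, grid=grid)
        out[sp] = fit[sp].k
    return out


def _bisect(f, lo: float, hi: float, f_lo: float, f_hi: float,
            xtol: float, ftol: float, max_iter: int = 60) -> float:
    """Bisection for the root of a scalar function with known bracket."""
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if abs(f_mid) < ftol or (hi - lo) < xtol:
            return mid
        if np.sign(f_mid) == np.sign(f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    return 0.5 * (lo + hi)


def _crossing(xs, diffs, f, xtol, ftol) -> float | None:
    """First sign change of ``diffs`` along ``xs``, refined by bisection."""
    diffs = np.asarray(diffs)
    sign = np.sign(diffs)
    for i in range(len(xs) - 1):
        if sign[i] != 0 and sign[i + 1] != 0 and sign[i] != sign[i + 1]:
            return float(
                _bisect(f, xs[i], xs[i + 1], diffs[i], diffs[i + 1], xtol, ftol)
            )
        if sign[i + 1] == 0:
            return float(xs[i + 1])
    return None


def npgr_vs_rate(
    scenario: Scenario,
    rates,
    treatment: str,
    pp: PredationParams | None = None,
    grid: LengthGrid | None = None,
    coupled: bool = True,
    ig_pool: str = "pooled",
) -> RateSweepResult:
    """NPGR of both species versus the strength of one biotic interaction
    under one treatment's parameters, plus the tipping rate (if any)
    where the k curves cross, refined by bisection.

    Sweeps default to the coupled two-species system, in which the
    intraguild predator pool reflects the species' relative abundances
    (cannibalism and terrestrial predation are uncoupled processes, so
    coupling only matters for the intraguild sweep).
    """
    scenario = Scenario(scenario)
    if scenario not in (Scenario.CANNIBALISM, Scenario.INTRAGUILD, Scenario.TERRESTRIAL):
        raise ValueError(f"rate sweeps support single-interaction scenarios, not {scenario}")
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0) or np.any(np.diff(rates) < 0):
        raise ValueError("rates must be nonnegative and sorted")
    params = load_table3(treatment)
    base = pp or load_predation_defaults()
    field = {
        Scenario.CANNIBALISM: "upsilon",
        Scenario.INTRAGUILD: "upsilon_ig",
        Scenario.TERRESTRIAL: "tau",
    }[scenario]

    def k_at(rate: float) -> dict[str, float]:
        return _k_both(
            params, replace(base, **{field: rate}), scenario, grid,
            coupled=coupled, ig_pool=ig_pool,
        )

    ks = [k_at(r) for r in rates]
    species = list(params)
    k = {sp: np.array([d[sp] for d in ks]) for sp in species}
    diffs = k[species[0]] - k[species[1]]

    def diff_at(rate: float) -> float:
        d = k_at(rate)
        return d[species[0]] - d[species[1]]

    tipping = _crossing(rates, diffs, diff_at, xtol=0.0, ftol=1e-4)
    return RateSweepResult(scenario, treatment, rates, k, tipping)


def gradient_npgr(
    scenario: Scenario,
    thetas,
    p0_scale: float = 1.0,
    pp: PredationParams | None = None,
    grid: LengthGrid | None = None,
    theta_tol: float = 0.05,
    coupled: bool = False,
    ig_pool: str = "pooled",
) -> GradientResult:
    """NPGR of both species along the tidal-emergence gradient and the
    critical duration theta_crit where they cross (bisection to
    ``theta_tol`` hours; ``None`` when no crossing occurs in range).

    By default each species' NPGR is obtained from its own
    single-species simulation, so the intraguild kernel degenerates to
    predation by the conspecific volume reaching predator size (only
    *I. balthica*); ``coupled=True`` instead simulates both species in
    one system, where the relative abundances set the predator pool.
    """
    scenario = Scenario(scenario)
    if scenario is Scenario.CANNIBALISM:
        raise ValueError("the gradient analysis does not include cannibalism")
    thetas = np.asarray(thetas, dtype=float)
    ref = load_table3("reference")
    tid = load_table3("tides")
    base = pp or load_predation_defaults()
    species = list(ref)

    def k_at(theta: float) -> dict[str, float]:
        params = {sp: interpolate_species_params(theta, ref[sp], tid[sp]) for sp in species}
        upsilon_ig = tau = 0.0
        if scenario in (Scenario.INTRAGUILD, Scenario.INTRAGUILD_AND_TERRESTRIAL):
            upsilon_ig = GRADIENT_UPSILON_IG * p0_scale
        if scenario in (Scenario.TERRESTRIAL, Scenario.INTRAGUILD_AND_TERRESTRIAL):
            tau = GRADIENT_TAU_PER_HOUR * theta * p0_scale
        pp_theta = replace(base, upsilon_ig=upsilon_ig, tau=tau)
        return _k_both(params, pp_theta, scenario, grid, coupled=coupled, ig_pool=ig_pool)

    ks = [k_at(t) for t in thetas]
    k = {sp: np.array([d[sp] for d in ks]) for sp in species}
    diffs = k[species[0]] - k[species[1]]

    def diff_at(theta: float) -> float:
        d = k_at(theta)
        return d[species[0]] - d[species[1]]

    theta_crit = _crossing(thetas, diffs, diff_at, xtol=theta_tol, ftol=0.0)
    return GradientResult(scenario, p0_scale, thetas, k, theta_crit)


def sensitivity_table(
    thetas=None,
    p0_scales=(0.9, 1.0, 1.1),
    grid: LengthGrid | None = None,
) -> pd.DataFrame:
    """Critical tidal duration for the four gradient scenarios at the
    reference predation rates and +-10 %: rows are scenarios, columns
    the p0 scalings.  The predation-free row is computed once (the
    scaling has nothing to act on)."""
    if thetas is None:
        thetas = np.arange(0.0, 12.0 + 1e-9, 1.0)
    rows = {}
    for scenario in _GRADIENT_SCENARIOS:
        row = {}
        for s in p0_scales:
            if scenario is Scenario.NONE and row:
                row[s] = next(iter(row.values()))
                continue
            res = gradient_npgr(scenario, thetas, p0_scale=s, grid=grid)
            row[s] = res.theta_crit
        rows[scenario.value] = row
    df = pd.DataFrame(rows).T
    df.index.name = "scenario"
    df.columns = [f"{s:g}*p0" for s in p0_scales]
    return df
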