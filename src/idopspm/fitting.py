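"""Fitting of the demographic process models to individual rearing data.

The experimental design: individuals reared singly from hatching for 21
weeks, monitored for survival and moulting, body length recorded at each
moult, juveniles counted when gravid females release a brood.  The tidy
table of one row per individual per week (``RearingTable`` schema) is
the input to three fitting stages:

* growth — models G1-G5 fitted directly to per-moult length increments
  dl/dt, with AIC model selection;
* reproduction — weekly brood counts, mapped from time to maternal
  length through the selected growth curve, fitted to the normal
  per-female birth-rate b(l);
* mortality — the exponential decay of the cohort's weekly survivor
  counts matched by the candidate mortality model along the growth
  trajectory.

Nonlinear fits use trust-region least squares with multiple starts;
standard errors come from the Jacobian at the optimum, and the Gaussian
AIC is n ln(RSS/n) + 2 p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from scipy.stats import norm

from .process_models import (
    DAYS_PER_WEEK,
    GrowthParams,
    GrowthVariant,
    MortalityParams,
    ReproductionParams,
    growth_rate,
    mortality_rate,
)

__all__ = [
    "REARING_COLUMNS",
    "FitResult",
    "validate_rearing_table",
    "growth_increments",
    "fit_growth",
    "select_growth_model",
    "time_to_length",
    "fit_reproduction",
    "fit_mortality",
    "fit_all",
]

log = logging.getLogger(__name__)

REARING_COLUMNS = (
    "individual_id",
    "species",
    "treatment",
    "sex",
    "week",
    "length_mm",
    "alive",
    "offspring_count",
)

#: free parameters per growth variant (order used by the optimizer)
_GROWTH_FIELDS = {
    GrowthVariant.G1: ("rho", "l_max"),
    GrowthVariant.G2: ("rho", "l_max"),
    GrowthVariant.G3: ("rho",),
    GrowthVariant.G4: ("rho_j", "rho_a", "l_crit", "beta", "l_max"),
    GrowthVariant.G5: ("rho_j", "rho_a", "l_crit", "beta"),
}


@dataclass
class FitResult:
    """One fitted process model: estimates, Jacobian-based standard
    errors, coefficient of determination and Gaussian AIC."""

    model_tag: str
    params: dict[str, float]
    ses: dict[str, float]
    r2: float
    aic: float
    rss: float
    n: int
    flags: list[str] = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return len(self.params)


def validate_rearing_table(tbl: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REARING_COLUMNS if c not in tbl.columns]
    if missing:
        raise ValueError(f"rearing table is missing columns: {missing}")
    return tbl


# ---------------------------------------------------------------------------
# growth


def growth_increments(tbl: pd.DataFrame) -> pd.DataFrame:
    """Per-moult growth increments pooled within species x treatment x sex.

    For each consecutive pair of recorded lengths of one individual the
    midpoint length and the increment per elapsed day are emitted.
    Individuals with fewer than two recorded lengths are skipped (logged).
    """
    validate_rearing_table(tbl)
    obs = tbl.dropna(subset=["length_mm"]).sort_values("week")
    out = []
    skipped = 0
    for (iid, sp, tr, sex), g in obs.groupby(
        ["individual_id", "species", "treatment", "sex"], sort=False
    ):
        lengths = g["length_mm"].to_numpy(dtype=float)
        weeks = g["week"].to_numpy(dtype=float)
        if len(lengths) < 2:
            skipped += 1
            continue
        dt = np.diff(weeks) * DAYS_PER_WEEK
        out.append(
            pd.DataFrame(
                {
                    "individual_id": iid,
                    "species": sp,
                    "treatment": tr,
                    "sex": sex,
                    "l_mid": 0.5 * (lengths[:-1] + lengths[1:]),
                    "dldt": np.diff(lengths) / dt,
                }
            )
        )
    if skipped:
        log.info("growth_increments: skipped %d individuals with < 2 lengths", skipped)
    if not out:
        return pd.DataFrame(
            columns=["individual_id", "species", "treatment", "sex", "l_mid", "dldt"]
        )
    return pd.concat(out, ignore_index=True)


def _growth_from_vector(variant: GrowthVariant, x, l_max_ref: float | None) -> GrowthParams:
    kw = dict(zip(_GROWTH_FIELDS[variant], x))
    if variant in (GrowthVariant.G3, GrowthVariant.G5):
        kw["l_max"] = l_max_ref
        kw["l_max_fixed"] = True
    if variant in (GrowthVariant.G4, GrowthVariant.G5):
        kw.setdefault("beta", 1.0)
    return GrowthParams(variant=variant, **kw)


def _se_from_jacobian(res, n: int, p: int) -> np.ndarray:
    rss = float(res.cost * 2.0)
    dof = max(n - p, 1)
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj) * rss / dof
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)


def fit_growth(
    pairs: pd.DataFrame,
    variant: GrowthVariant,
    l_max_ref: float | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Trust-region nonlinear least squares of g(l) against dl/dt
    observations, with ``n_starts`` multiplicatively perturbed starting
    points to escape local optima."""
    variant = GrowthVariant(variant)
    l = np.asarray(pairs["l_mid"], dtype=float)
    y = np.asarray(pairs["dldt"], dtype=float)
    if len(l) < 3:
        raise ValueError("need at least 3 increment observations")
    if variant in (GrowthVariant.G3, GrowthVariant.G5) and l_max_ref is None:
        raise ValueError(f"{variant.value} requires l_max_ref")

    fields = _GROWTH_FIELDS[variant]
    l_top = l_max_ref if l_max_ref is not None else 1.05 * l.max()
    slope = max(np.median(y[y > 0]) / max(np.median(l), 1e-6), 1e-4) if np.any(y > 0) else 1e-3
    base = {
        "rho": slope * 4.0,
        "rho_j": slope,
        "rho_a": slope * 8.0,
        "l_crit": 0.3 * l_top,
        "beta": 2.0,
        "l_max": l_top,
    }
    x0 = np.array([base[f] for f in fields])
    lo = np.full(len(fields), 1e-8)
    hi = np.full(len(fields), np.inf)
    if "beta" in fields:
        # beyond ~8 the rate transition is numerically a step function and
        # beta is unidentifiable from increment data
        hi[fields.index("beta")] = 8.0

    def residuals(x):
        gp = _growth_from_vector(variant, x, l_max_ref)
        return growth_rate(l, gp) - y

    rng = np.random.default_rng(seed)
    best = None
    for i in range(max(n_starts, 1)):
        start = x0 if i == 0 else np.clip(
            x0 * rng.uniform(0.4, 2.5, size=len(x0)), lo, hi
        )
        try:
            res = least_squares(residuals, start, bounds=(lo, hi), method="trf")
        except Exception:  # singular model at this start
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError(f"all {variant.value} fits failed")

    n, p = len(y), len(fields)
    rss = float(2.0 * best.cost)
    tss = float(np.sum((y - y.mean()) ** 2))
    ses = _se_from_jacobian(best, n, p)
    flags = []
    if np.any(~np.isfinite(ses)):
        flags.append("non_identifiable")
    params = dict(zip(fields, (float(v) for v in best.x)))
    if variant in (GrowthVariant.G3, GrowthVariant.G5):
        params["l_max"] = float(l_max_ref)
        ses = np.append(ses, 0.0)
    return FitResult(
        model_tag=variant.value,
        params=params,
        ses=dict(zip(list(params), (float(s) for s in ses))),
        r2=1.0 - rss / tss if tss > 0 else 1.0,
        aic=gaussian_aic(rss, n, p),
        rss=rss,
        n=n,
        flags=flags,
    )


def gaussian_aic(rss: float, n: int, p: int) -> float:
    return n * np.log(max(rss, 1e-300) / n) + 2 * p


def select_growth_model(
    pairs: pd.DataFrame,
    l_max_ref: float | None = None,
    variants=None,
    n_starts: int = 5,
    seed: int = 0,
) -> tuple[FitResult, dict[str, FitResult]]:
    """Fit all candidate growth models and return the minimum-AIC fit
    (ties broken toward fewer parameters) plus the full fit table.
    G3/G5 are only attempted when a reference maximal length is given."""
    if variants is None:
        variants = list(GrowthVariant)
    fits: dict[str, FitResult] = {}
    for v in variants:
        v = GrowthVariant(v)
        if v in (GrowthVariant.G3, GrowthVariant.G5) and l_max_ref is None:
            continue
        try:
            fits[v.value] = fit_growth(pairs, v, l_max_ref, n_starts=n_starts, seed=seed)
        except Exception as exc:
            log.warning("growth fit %s failed: %s", v.value, exc)
    if not fits:
        raise RuntimeError("all growth-model fits failed")
    best = min(fits.values(), key=lambda f: (round(f.aic, 9), f.n_params))
    return best, fits


def time_to_length(t_days, growth: GrowthParams | FitResult, l_b: float = 2.0):
    """Length reached after ``t_days`` of growth from birth length l_b:
    closed forms for von Bertalanffy and logistic growth, numeric
    integration for the size-dependent variants."""
    gp = growth if isinstance(growth, GrowthParams) else _fitresult_growth(growth)
    t = np.atleast_1d(np.asarray(t_days, dtype=float))
    if gp.variant is GrowthVariant.G1:
        out = gp.l_max - (gp.l_max - l_b) * np.exp(-gp.rho * t)
    elif gp.variant in (GrowthVariant.G2, GrowthVariant.G3):
        out = gp.l_max / (1.0 + ((gp.l_max - l_b) / l_b) * np.exp(-gp.rho * t))
    else:
        sol = solve_ivp(
            lambda _, l: growth_rate(np.maximum(l, 0.0), gp),
            (0.0, float(t.max()) if t.max() > 0 else 1.0),
            [l_b],
            t_eval=np.unique(np.concatenate(([0.0], t))),
            rtol=1e-8,
            atol=1e-10,
        )
        out = np.interp(t, sol.t, sol.y[0])
    return out if np.ndim(t_days) else float(out[0])


def _fitresult_growth(fit: FitResult) -> GrowthParams:
    return GrowthParams(variant=GrowthVariant(fit.model_tag), **fit.params)


# ---------------------------------------------------------------------------
# reproduction


def fit_reproduction(
    tbl: pd.DataFrame,
    growth: FitResult | GrowthParams,
    l_b: float = 2.0,
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Fit the per-female weekly birth rate b(l) = f_max N(l; l_r, sigma_r).

    Brood observations are time-stamped; the selected growth model maps
    each week to a maternal length, after which (f_max, l_r, sigma_r)
    are fitted by least squares to the weekly counts.
    """
    validate_rearing_table(tbl)
    fem = tbl[(tbl["sex"] == "f") & tbl["alive"].astype(bool)].dropna(
        subset=["offspring_count"]
    )
    if len(fem) < 3:
        raise ValueError("need at least 3 brood observations")
    weeks = fem["week"].to_numpy(dtype=float)
    counts = fem["offspring_count"].to_numpy(dtype=float)
    lengths = np.asarray(time_to_length(weeks * DAYS_PER_WEEK, growth, l_b=l_b))

    if not np.any(counts > 0):
        log.warning("fit_reproduction: no nonzero broods; f_max = 0")
        return FitResult(
            model_tag="reproduction",
            params={"f_max": 0.0, "l_r": float(np.mean(lengths)), "sigma_r": 1.0},
            ses={"f_max": 0.0, "l_r": np.nan, "sigma_r": np.nan},
            r2=1.0, aic=np.nan, rss=0.0, n=len(counts),
            flags=["all_zero_broods"],
        )

    w = counts / counts.sum()
    l_r0 = float(np.sum(w * lengths))
    sigma0 = float(np.sqrt(np.sum(w * (lengths - l_r0) ** 2)))
    sigma0 = max(sigma0, 0.1)
    f0 = float(counts.max() * sigma0 * np.sqrt(2 * np.pi))
    x0 = np.array([f0, l_r0, sigma0])
    lo = np.array([0.0, 0.0, 1e-3])
    hi = np.array([np.inf, np.inf, np.inf])

    def residuals(x, wts):
        return (x[0] * norm.pdf(lengths, x[1], x[2]) - counts) * wts

    ones = np.ones_like(counts)
    rng = np.random.default_rng(seed)
    best = None
    for i in range(max(n_starts, 1)):
        start = x0 if i == 0 else np.clip(
            x0 * rng.uniform(0.5, 2.0, size=3), lo, hi
        )
        res = least_squares(residuals, start, args=(ones,), bounds=(lo, hi), method="trf")
        if best is None or res.cost < best.cost:
            best = res
    # brood counts are counts: one reweighting step with variance
    # proportional to the fitted mean (Poisson-like heteroscedasticity)
    mean = np.maximum(best.x[0] * norm.pdf(lengths, best.x[1], best.x[2]), 0.5)
    wts = 1.0 / np.sqrt(mean)
    best = least_squares(residuals, best.x, args=(wts,), bounds=(lo, hi), method="trf")

    n = len(counts)
    rss = float(np.sum((best.fun / wts) ** 2))
    tss = float(np.sum((counts - counts.mean()) ** 2))
    ses = _se_from_jacobian(best, n, 3)
    # the week -> length mapping inherits the growth fit's uncertainty;
    # propagate it by refitting under parametric draws of the growth
    # parameters and adding the spread in quadrature
    if isinstance(growth, FitResult):
        extra = _growth_uncertainty_spread(
            growth, weeks, counts, best.x, lo, hi, wts, l_b, seed
        )
        ses = np.sqrt(ses**2 + extra**2)
    flags = []
    if best.x[2] <= lo[2] * 1.01:
        flags.append("sigma_r_at_lower_bound")
    names = ("f_max", "l_r", "sigma_r")
    return FitResult(
        model_tag="reproduction",
        params=dict(zip(names, (float(v) for v in best.x))),
        ses=dict(zip(names, (float(s) for s in ses))),
        r2=1.0 - rss / tss if tss > 0 else 1.0,
        aic=gaussian_aic(rss, n, 3),
        rss=rss,
        n=n,
        flags=flags,
    )


def _growth_uncertainty_spread(
    growth: FitResult, weeks, counts, x_best, lo, hi, wts, l_b, seed, n_draws: int = 8
) -> np.ndarray:
    """Spread of the reproduction estimates under parametric draws of the
    growth parameters (independent normal perturbations by one SE)."""
    rng = np.random.default_rng(seed + 1)
    names = list(growth.params)
    draws = []
    for _ in range(n_draws):
        kw = {
            k: max(growth.params[k] + rng.normal(0.0, growth.ses.get(k, 0.0) or 0.0), 1e-8)
            for k in names
        }
        kw.pop("l_max_fixed", None)
        try:
            gp = GrowthParams(variant=GrowthVariant(growth.model_tag), **kw)
            lengths = np.asarray(time_to_length(weeks * DAYS_PER_WEEK, gp, l_b=l_b))
            res = least_squares(
                lambda x: (x[0] * norm.pdf(lengths, x[1], x[2]) - counts) * wts,
                x_best, bounds=(lo, hi), method="trf",
            )
            draws.append(res.x)
        except Exception:
            continue
    if len(draws) < 3:
        return np.zeros(3)
    return np.std(np.asarray(draws), axis=0, ddof=1)


# ---------------------------------------------------------------------------
# mortality


def fit_mortality(
    tbl: pd.DataFrame,
    growth: FitResult | GrowthParams,
    l_b: float = 2.0,
    fit_senile: bool = False,
) -> FitResult:
    """Fit the mortality rate by matching the cohort's weekly survivor
    counts: the cohort advances along the growth curve and dies at the
    candidate rate m(l), so the predicted count at week w is
    n0 exp(-integral of m(l(t)) dt).  With the senile branch disabled
    (default) this is plain exponential survival and mu is fitted alone.
    """
    validate_rearing_table(tbl)
    counts = (
        tbl.groupby("week")["alive"].apply(lambda a: int(a.astype(bool).sum()))
        .sort_index()
    )
    weeks = counts.index.to_numpy(dtype=float)
    n_alive = counts.to_numpy(dtype=float)
    n0 = n_alive[0]
    if n0 <= 0:
        raise ValueError("cohort empty at week 0")
    gp = growth if isinstance(growth, GrowthParams) else _fitresult_growth(growth)

    t_days = weeks * DAYS_PER_WEEK
    t_fine = np.linspace(0.0, float(t_days.max()), 512)
    l_fine = np.asarray(time_to_length(t_fine, gp, l_b=l_b))

    def predicted(x):
        if fit_senile:
            mp = MortalityParams(mu=x[0], mu_s=x[1], delta_s=x[2])
        else:
            mp = MortalityParams(mu=x[0])
        m_fine = mortality_rate(l_fine, mp, gp.l_max)
        cum = np.concatenate(([0.0], np.cumsum(0.5 * (m_fine[1:] + m_fine[:-1]) * np.diff(t_fine))))
        return n0 * np.exp(-np.interp(t_days, t_fine, cum))

    p = 3 if fit_senile else 1
    x0 = np.full(p, 1e-3)
    if fit_senile:
        x0 = np.array([1e-3, 2e-3, 1.0])
    res = least_squares(
        lambda x: predicted(x) - n_alive, x0,
        bounds=(np.zeros(p), np.full(p, np.inf)), method="trf",
    )
    n = len(n_alive)
    rss = float(2.0 * res.cost)
    tss = float(np.sum((n_alive - n_alive.mean()) ** 2))
    names = ("mu", "mu_s", "delta_s")[:p]
    if fit_senile:
        ses = _se_from_jacobian(res, n, p)
    else:
        # survivor counts are a monotone staircase, so count residuals are
        # strongly autocorrelated and a Jacobian SE is dishonest; use the
        # exponential-survival Fisher information instead: se = sqrt(D)/T
        # with D observed deaths and T person-days of exposure
        deaths = float(n0 - n_alive[-1])
        exposure = float(np.sum(n_alive[:-1] * np.diff(t_days)))
        ses = np.array([np.sqrt(max(deaths, 1.0)) / exposure])
    flags = []
    if res.x[0] <= 1e-10:
        flags.append("no_deaths")
    return FitResult(
        model_tag="mortality",
        params=dict(zip(names, (float(v) for v in res.x))),
        ses=dict(zip(names, (float(s) for s in ses))),
        r2=1.0 - rss / tss if tss > 0 else 1.0,
        aic=gaussian_aic(rss, n, p),
        rss=rss,
        n=n,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# orchestration


def fit_all(
    tbl: pd.DataFrame,
    l_max_ref: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit growth (with model selection), mortality and reproduction for
    every species x treatment x sex in the table; returns a tidy frame
    (species, treatment, sex, process, model, param, value, se, r2, aic).

    ``l_max_ref`` optionally maps "species/sex" to a reference maximal
    length enabling the G3/G5 variants.
    """
    validate_rearing_table(tbl)
    rows = []
    increments = growth_increments(tbl)
    for (sp, tr), sub in tbl.groupby(["species", "treatment"]):
        growth_by_sex: dict[str, FitResult] = {}
        for sex, sub_sex in sub.groupby("sex"):
            pairs = increments[
                (increments["species"] == sp)
                & (increments["treatment"] == tr)
                & (increments["sex"] == sex)
            ]
            ref = (l_max_ref or {}).get(f"{sp}/{sex}")
            best, all_fits = select_growth_model(pairs, l_max_ref=ref, seed=seed)
            growth_by_sex[sex] = best
            rows.extend(_fit_rows(sp, tr, sex, "growth", best))
            for tag, f in all_fits.items():
                rows.append(
                    {"species": sp, "treatment": tr, "sex": sex, "process": "growth_aic",
                     "model": tag, "param": "aic", "value": f.aic, "se": np.nan,
                     "r2": f.r2, "aic": f.aic}
                )
            mort = fit_mortality(sub_sex, best)
            rows.extend(_fit_rows(sp, tr, sex, "mortality", mort))
        if "f" in growth_by_sex:
            rep = fit_reproduction(sub, growth_by_sex["f"])
            rows.extend(_fit_rows(sp, tr, "f", "reproduction", rep))
    return pd.DataFrame(rows)


def _fit_rows(sp, tr, sex, process, fit: FitResult):
    return [
        {"species": sp, "treatment": tr, "sex": sex, "process": process,
         "model": fit.model_tag, "param": name, "value": val,
         "se": fit.ses.get(name, np.nan), "r2": fit.r2, "aic": fit.aic}
        for name, val in fit.params.items()
    ]
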