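"""Growth-rate extraction and multiplier parameter estimation.

The lifetime growth rate G of a tree summarises everything its environment
did to it: under the gap-model ODE with constant G the equation is
separable, so G is determined exactly by the planting diameter, the
measured diameter and the stand age,

    G = [ integral_{dbh0}^{dbh_age} du / phi(u) ] / age,

with phi the growth shape factor.  Extracted per-plot G values are then
regressed on the environmental multiplier product G = Gopt * MUL(env; theta)
by bounded multi-start nonlinear least squares, which is how the response
thresholds for salinity, density, elevation and heavy metals are estimated
from a plantation inventory of known age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import least_squares

from .growth import growth_shape, step_dbh_rk4
from .multipliers import combined_multiplier_fields
from .params import (
    MultiplierParams,
    SigmoidMultiplierParams,
    PollutantMultiplierParams,
    SpeciesParams,
)

__all__ = [
    "PlotRecord",
    "FitResult",
    "ValidationResult",
    "extract_G",
    "extract_G_frame",
    "fit_multipliers",
    "fit_pollutant",
    "validate",
    "predict_dbh",
    "stratified_split",
]

#: canonical column schema for plot-inventory frames
PLOT_COLUMNS = [
    "plot_id", "region", "age", "mean_dbh", "mean_height",
    "density", "salinity", "elevation",
]


@dataclass(frozen=True)
class PlotRecord:
    """One inventory plot: growth observations plus local environment."""

    plot_id: str
    region: str
    age: float            # yr
    mean_dbh: float       # cm
    mean_height: float    # cm
    density: float        # trees / 100 m^2
    salinity: float       # ppt
    elevation: float      # m (NaN if not surveyed)
    G_extracted: float | None = None


class InfeasibleError(ValueError):
    """Observation incompatible with the growth model (dbh_age >= Dmax)."""


def extract_G(dbh0: float, dbh_age: float, age: float, sp: SpeciesParams) -> float:
    """Lifetime growth rate G implied by growth from dbh0 to dbh_age in ``age`` yr.

    Computed by quadrature of the separated ODE; this is the exact constant-G
    inversion of the forward integrator (round-trip identity holds to the
    integrator tolerance).  Returns 0 with a warning when no growth is
    observed; raises :class:`InfeasibleError` when dbh_age >= Dmax, which no
    finite G can reach.
    """
    if age <= 0:
        raise ValueError("age must be positive")
    if dbh0 <= 0:
        raise ValueError("dbh0 must be positive")
    if dbh_age <= dbh0:
        warnings.warn(
            f"dbh_age ({dbh_age}) <= dbh0 ({dbh0}): no observable growth, G = 0",
            stacklevel=2,
        )
        return 0.0
    if dbh_age >= sp.Dmax:
        raise InfeasibleError(
            f"dbh_age={dbh_age} >= Dmax={sp.Dmax}: unreachable under the growth model"
        )
    val, _ = quad(lambda u: 1.0 / growth_shape(u, sp), dbh0, dbh_age, limit=200)
    return val / age


def extract_G_frame(plots: pd.DataFrame, sp: SpeciesParams, dbh0: float = 0.5) -> pd.Series:
    """Vectorised :func:`extract_G` over a plot frame; returns a G series."""
    return pd.Series(
        [extract_G(dbh0, row.mean_dbh, row.age, sp) for row in plots.itertuples()],
        index=plots.index, name="G_extracted",
    )


# ---------------------------------------------------------------------------
# Nonlinear regression of G on the multiplier product


@dataclass
class FitResult:
    """Estimated multiplier parameter set with fit diagnostics.

    ``param_se`` holds delta-method standard errors of the free parameters
    (order as in ``free_names``), from which pointwise 95% bands on the
    response surface follow as prediction +/- 1.96 * sqrt(grad' Cov grad).
    """

    multipliers: MultiplierParams
    gopt: float
    rss: float
    r_squared: float
    free_names: list[str] = field(default_factory=list)
    param_values: np.ndarray | None = None
    param_se: np.ndarray | None = None
    param_cov: np.ndarray | None = None
    n_obs: int = 0


class DegenerateDesignError(ValueError):
    """A fitted covariate is (near) constant across plots."""


_SIGMOID_BOUNDS = {"a0": (0.0, 0.99), "d": (1e-3, 10.0), "tr": (1e-2, 500.0)}


def _pack_free(mp: MultiplierParams, gopt, components):
    """Build (names, x0, lo, hi, setter) for the requested free components."""
    names, x0, lo, hi = [], [], [], []
    for comp in components:
        if comp in ("salinity", "density"):
            p: SigmoidMultiplierParams = getattr(mp, comp)
            for f in ("a0", "d", "tr"):
                names.append(f"{comp}.{f}")
                x0.append(getattr(p, f))
                lo.append(_SIGMOID_BOUNDS[f][0])
                hi.append(_SIGMOID_BOUNDS[f][1])
        elif comp == "gopt":
            names.append("gopt")
            x0.append(float(gopt))
            lo.append(1.0)
            hi.append(5000.0)
        else:
            raise ValueError(f"unknown fit component {comp!r}")

    def setter(x):
        sal, dens, g = mp.salinity, mp.density, float(gopt)
        vals = dict(zip(names, x))
        if "salinity.a0" in vals:
            sal = SigmoidMultiplierParams(vals["salinity.a0"], vals["salinity.d"],
                                          vals["salinity.tr"])
        if "density.a0" in vals:
            dens = SigmoidMultiplierParams(vals["density.a0"], vals["density.d"],
                                           vals["density.tr"])
        if "gopt" in vals:
            g = vals["gopt"]
        return replace(mp, salinity=sal, density=dens), g

    return names, np.array(x0), np.array(lo), np.array(hi), setter


def fit_multipliers(
    plots: pd.DataFrame,
    sp: SpeciesParams,
    mp0: MultiplierParams,
    gopt: float | None = None,
    components: tuple[str, ...] = ("salinity", "density", "gopt"),
    n_starts: int = 8,
    seed: int = 0,
    g_column: str = "G_extracted",
) -> FitResult:
    """Estimate multiplier parameters from extracted plot growth rates.

    Minimises sum_i (G_i - Gopt * MUL(env_i; theta))^2 over the parameters of
    the requested ``components`` with a bounded trust-region least-squares
    solver, multi-started from ``n_starts`` seeded draws within the bounds to
    guard against local minima (ties broken by RSS, then parameter norm).
    Components not fitted (elevation, pollutants) are held at ``mp0``.
    ``gopt=None`` estimates Gopt jointly when "gopt" is in ``components``,
    otherwise Gopt must be supplied.
    """
    if gopt is None:
        if "gopt" not in components:
            raise ValueError("gopt must be given when not estimated")
        gopt = sp.Gopt
    g_obs = plots[g_column].to_numpy(dtype=float)
    n_free_check = 3 * sum(c in ("salinity", "density") for c in components) + (
        "gopt" in components)
    if len(plots) < n_free_check:
        raise ValueError(f"need at least {n_free_check} plots, got {len(plots)}")

    cov_of = {"salinity": "salinity", "density": "density"}
    for comp in components:
        if comp in cov_of:
            col = plots[cov_of[comp]].to_numpy(dtype=float)
            if np.ptp(col) < 1e-9 * max(1.0, np.abs(col).max()):
                raise DegenerateDesignError(
                    f"covariate {cov_of[comp]!r} is constant: cannot fit its response"
                )

    sal = plots["salinity"].to_numpy(dtype=float)
    dens = plots["density"].to_numpy(dtype=float)
    elev = plots["elevation"].to_numpy(dtype=float)
    names, x0, lo, hi, setter = _pack_free(mp0, gopt, components)

    def residuals(x):
        mp, g = setter(x)
        pred = g * combined_multiplier_fields(sal, dens, elev, mp)
        return pred - g_obs

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(0, n_starts - 1)):
        starts.append(lo + (hi - lo) * rng.random(len(x0)))

    best = None
    for s in starts:
        try:
            sol = least_squares(residuals, np.clip(s, lo, hi), bounds=(lo, hi),
                                method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        key = (round(rss, 12), float(np.linalg.norm(sol.x)))
        if best is None or key < best[0]:
            best = (key, sol, rss)
    if best is None:
        raise RuntimeError("all optimisation starts failed")
    _, sol, rss = best

    mp_hat, gopt_hat = setter(sol.x)
    tss = float(np.sum((g_obs - g_obs.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")

    # delta-method covariance: sigma^2 (J'J)^-1
    dof = max(len(g_obs) - len(sol.x), 1)
    sigma2 = rss / dof
    try:
        cov = sigma2 * np.linalg.pinv(sol.jac.T @ sol.jac)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        cov, se = None, None

    return FitResult(
        multipliers=mp_hat, gopt=gopt_hat, rss=rss, r_squared=r2,
        free_names=names, param_values=sol.x.copy(), param_se=se,
        param_cov=cov, n_obs=len(g_obs),
    )


def fit_pollutant(
    conc: np.ndarray,
    response: np.ndarray,
    metal: str,
    p0: PollutantMultiplierParams | None = None,
    n_starts: int = 8,
    seed: int = 0,
) -> PollutantMultiplierParams:
    """Fit the hormetic dose-response to (root concentration, relative G).

    ``response`` should be the growth rate normalised by the non-pollutant
    part of the multiplier product, i.e. an estimate of P(x) in [0, 1].
    Used with the (small) subset of plots where tissue metal concentrations
    were measured.
    """
    from .multipliers import pollutant_multiplier

    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    lo = np.array([1e-3, 1e-1, 1e-2, 1e-2])
    hi = np.array([100.0, 2000.0, 5.0, 10.0])
    if p0 is not None:
        x0 = np.array([p0.th1, p0.th2, p0.alpha1, p0.alpha2])
    else:
        x0 = np.array([1.0, 100.0, 0.5, 1.5])

    def resid(x):
        th1, th2, a1, a2 = x
        if th1 >= th2:
            return np.full_like(response, 1e3)
        p = PollutantMultiplierParams(metal, th1, th2, a1, a2)
        return pollutant_multiplier(conc, p) - response

    rng = np.random.default_rng(seed)
    starts = [x0] + [np.exp(np.log(lo) + (np.log(hi) - np.log(lo)) * rng.random(4))
                     for _ in range(n_starts - 1)]
    best = None
    for s in starts:
        try:
            sol = least_squares(resid, np.clip(s, lo, hi), bounds=(lo, hi), method="trf")
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise RuntimeError("pollutant fit failed for all starts")
    th1, th2, a1, a2 = best[1]
    if th1 >= th2:
        th2 = th1 * 1.001
    return PollutantMultiplierParams(metal, th1, th2, a1, a2)


# ---------------------------------------------------------------------------
# Validation


@dataclass
class ValidationResult:
    r_squared: float
    table: pd.DataFrame  # plot_id, age, dbh_observed, dbh_predicted


def predict_dbh(plots: pd.DataFrame, sp: SpeciesParams, mp: MultiplierParams,
                gopt: float, dbh0: float = 0.5, steps_per_year: int = 4) -> np.ndarray:
    """Forward-predict dbh at each plot's age under its static environment."""
    sal = plots["salinity"].to_numpy(dtype=float)
    dens = plots["density"].to_numpy(dtype=float)
    elev = plots["elevation"].to_numpy(dtype=float)
    mul = combined_multiplier_fields(sal, dens, elev, mp)
    G = gopt * mul
    ages = plots["age"].to_numpy(dtype=float)
    max_age = int(np.ceil(ages.max()))
    d = np.full(len(plots), float(dbh0))
    out = np.full(len(plots), float(dbh0))
    for yr in range(1, max_age + 1):
        d = step_dbh_rk4(d, G, sp, dt=1.0, n_steps=steps_per_year)
        hit = ages >= yr
        out[hit] = d[hit]
    return out


def validate(plots: pd.DataFrame, fit: FitResult, sp: SpeciesParams,
             dbh0: float = 0.5) -> ValidationResult:
    """Predicted-vs-observed dbh on a hold-out set; reports R^2.

    R^2 = 1 - RSS/TSS of predicted against observed mean dbh, the standard
    validation summary for the growth model.
    """
    if len(plots) == 0:
        raise ValueError("validation set is empty")
    pred = predict_dbh(plots, sp, fit.multipliers, fit.gopt, dbh0=dbh0)
    obs = plots["mean_dbh"].to_numpy(dtype=float)
    rss = float(np.sum((obs - pred) ** 2))
    tss = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    table = pd.DataFrame({
        "plot_id": plots.get("plot_id", pd.RangeIndex(len(plots))),
        "age": plots["age"].to_numpy(),
        "dbh_observed": obs,
        "dbh_predicted": pred,
    })
    return ValidationResult(r_squared=r2, table=table)


def stratified_split(plots: pd.DataFrame, n_fit: int, seed: int = 0,
                     covariates: tuple[str, ...] = ("salinity", "elevation", "density")):
    """Split an inventory into (fit, holdout) stratified over covariate terciles.

    Plots are binned into terciles of each available covariate; the fitting
    subset is drawn proportionally from every non-empty stratum so the fit
    sees the full environmental gradient, mirroring a survey design that
    selects estimation plots "according to ranging" covariates.
    """
    if not 0 < n_fit < len(plots):
        raise ValueError("n_fit must be strictly between 0 and len(plots)")
    usable = [c for c in covariates
              if c in plots.columns and plots[c].notna().all()
              and np.ptp(plots[c].to_numpy(dtype=float)) > 0]
    key = pd.Series(0, index=plots.index)
    for c in usable:
        terc = pd.qcut(plots[c].rank(method="first"), 3, labels=False)
        key = key * 3 + terc
    rng = np.random.default_rng(seed)
    fit_idx: list = []
    groups = list(plots.groupby(key.to_numpy()).groups.items())
    total = len(plots)
    for _, idx in groups:
        idx = list(idx)
        take = int(round(n_fit * len(idx) / total))
        take = min(take, len(idx))
        fit_idx.extend(rng.choice(idx, size=take, replace=False))
    # adjust to exactly n_fit
    fit_set = set(fit_idx)
    pool = [i for i in plots.index if i not in fit_set]
    rng.shuffle(pool)
    while len(fit_set) < n_fit and pool:
        fit_set.add(pool.pop())
    while len(fit_set) > n_fit:
        fit_set.pop()
    fit_mask = plots.index.isin(fit_set)
    return plots[fit_mask], plots[~fit_mask]
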