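"""Parameter containers and configuration I/O.

The growth model is parameterised at three levels: species constants
(maximum size, height allometry, optimal growth rate, biomass allometry),
environmental response ("multiplier") constants for salinity, tree density,
ground elevation and heavy-metal load, and the per-plot environment itself.
All parameters are plain dataclasses; the shipped defaults live in
``data/default_params.yaml`` and every value can be overridden from a user
config file.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "SpeciesParams",
    "SigmoidMultiplierParams",
    "ElevationMultiplierParams",
    "PollutantMultiplierParams",
    "MultiplierParams",
    "Environment",
    "ParameterError",
    "load_params",
    "save_params",
    "default_params_path",
]


class ParameterError(ValueError):
    """Raised when a parameter set violates its invariants."""


@dataclass(frozen=True)
class SpeciesParams:
    """Species constants for one mangrove species.

    Attributes
    ----------
    Hmax, Dmax:
        Maximum tree height [cm] and maximum diameter at breast height [cm].
    b1:
        Height at dbh = 0, conventionally breast height (137 cm).
    Gopt:
        Growth-rate constant under optimal conditions (Botkin units,
        cm-based; actual growth is ``Gopt * MUL`` with MUL in [0, 1]).
    a1_biom, c1_biom:
        Trunk dry-biomass allometry ``Biom = a1 * dbh**c1`` [kg, cm].
    """

    Hmax: float
    Dmax: float
    b1: float
    Gopt: float
    a1_biom: float
    c1_biom: float

    def __post_init__(self) -> None:
        if not (self.Hmax > self.b1 > 0):
            raise ParameterError(
                f"require Hmax > b1 > 0, got Hmax={self.Hmax}, b1={self.b1}"
            )
        if self.Dmax <= 0:
            raise ParameterError(f"Dmax must be positive, got {self.Dmax}")
        if self.Gopt <= 0:
            raise ParameterError(f"Gopt must be positive, got {self.Gopt}")
        if self.a1_biom <= 0 or self.c1_biom <= 0:
            raise ParameterError("biomass allometry coefficients must be positive")

    # Height-curve coefficients are fully determined by (Hmax, Dmax, b1):
    # H(Dmax) = Hmax and H'(Dmax) = 0 hold exactly by construction.
    @property
    def b2(self) -> float:
        """Linear height coefficient [cm/cm]: 2(Hmax - b1)/Dmax."""
        return 2.0 * (self.Hmax - self.b1) / self.Dmax

    @property
    def b3(self) -> float:
        """Quadratic height coefficient [cm/cm^2]: (Hmax - b1)/Dmax^2."""
        return (self.Hmax - self.b1) / self.Dmax**2


@dataclass(frozen=True)
class SigmoidMultiplierParams:
    """Decreasing sigmoid response g(x) = (1-a0)/(1+exp(d(x-tr))) + a0.

    Used for salinity [ppt] and tree density [trees/100 m^2].  ``a0`` is the
    asymptotic floor kept above zero so growth never stops entirely, ``tr``
    the threshold (midpoint) and ``d`` the (positive) steepness.  Both the
    salinity and the density response decrease with their covariate; a
    negative printed slope in a source table is interpreted as |d|.
    """

    a0: float
    d: float
    tr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.a0 < 1.0):
            raise ParameterError(f"a0 must be in [0, 1), got {self.a0}")
        if self.d <= 0:
            raise ParameterError(f"d must be positive (decreasing convention), got {self.d}")
        if self.tr <= 0:
            raise ParameterError(f"tr must be positive, got {self.tr}")


@dataclass(frozen=True)
class ElevationMultiplierParams:
    """Rise-plateau-fall elevation response.

    f(el) = (a1e + (amax-a1e) R(el)) * (a2e + (1-a2e) F(el)) with
    R(el) = 1 - exp(-((el-elmin)/el1)^alpha) rising and
    F(el) = exp(-((el-elmin)/el2)^beta) falling, and f = 0 below ``elmin``.
    The floor is ``a1e`` at el = elmin, the high-elevation limit ``amax*a2e``,
    with a plateau of near-optimal values in between.  Scale lengths el1,
    el2 are in metres (a negative configured el1 is read as |el1|).
    """

    a1e: float
    el1: float
    alpha: float
    el2: float
    beta: float
    a2e: float
    amax: float = 1.0
    elmin: float = -1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "el1", abs(self.el1))
        if not (0.0 <= self.a1e <= self.amax <= 1.0):
            raise ParameterError("require 0 <= a1e <= amax <= 1")
        if not (0.0 <= self.a2e <= self.amax):
            raise ParameterError("require 0 <= a2e <= amax")
        if self.alpha <= 0 or self.beta <= 0:
            raise ParameterError("shape exponents alpha, beta must be positive")
        if self.el1 == 0 or self.el2 <= 0:
            raise ParameterError("scale lengths el1, el2 must be nonzero/positive")


@dataclass(frozen=True)
class PollutantMultiplierParams:
    """Hormetic dose-response P(x) = (1 - exp(-(x/th1)^a1)) * exp(-(x/th2)^a2).

    ``x`` is the root-tissue metal concentration [mg/kg DW].  Below ``th1``
    the response rises (hormetic stimulation), beyond ``th2`` the decay term
    dominates and growth is suppressed towards zero.
    """

    metal: str
    th1: float
    th2: float
    alpha1: float
    alpha2: float

    def __post_init__(self) -> None:
        if not (0.0 < self.th1 < self.th2):
            raise ParameterError(f"require 0 < th1 < th2, got {self.th1}, {self.th2}")
        if self.alpha1 <= 0 or self.alpha2 <= 0:
            raise ParameterError("form factors alpha1, alpha2 must be positive")


@dataclass(frozen=True)
class MultiplierParams:
    """The full environmental response set entering the growth multiplier."""

    salinity: SigmoidMultiplierParams
    density: SigmoidMultiplierParams
    elevation: ElevationMultiplierParams
    pollutants: Mapping[str, PollutantMultiplierParams] = field(default_factory=dict)


@dataclass(frozen=True)
class Environment:
    """Environmental state of one plot or stand.

    ``pollutant_conc`` maps metal name to root concentration [mg/kg DW]; an
    absent metal contributes no growth reduction (unpolluted convention).
    """

    salinity: float
    density: float
    elevation: float
    pollutant_conc: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.salinity < 0 or self.density < 0:
            raise ParameterError("salinity and density must be non-negative")
        if self.pollutant_conc is not None:
            for metal, x in self.pollutant_conc.items():
                if x < 0:
                    raise ParameterError(f"negative {metal} concentration: {x}")


# ---------------------------------------------------------------------------
# Config I/O


def default_params_path() -> Path:
    """Path of the packaged default parameter file."""
    return Path(
        importlib.resources.files("mangrove_growth") / "data" / "default_params.yaml"
    )


def _multipliers_from_dict(raw: Mapping) -> MultiplierParams:
    pollutants = {
        metal: PollutantMultiplierParams(metal=metal, **p)
        for metal, p in raw.get("pollutant", {}).items()
    }
    return MultiplierParams(
        salinity=SigmoidMultiplierParams(**raw["salinity"]),
        density=SigmoidMultiplierParams(**raw["density"]),
        elevation=ElevationMultiplierParams(**raw["elevation"]),
        pollutants=pollutants,
    )


def load_params(path: str | Path | None = None):
    """Load (SpeciesParams, MultiplierParams, raw dict) from a YAML config.

    With ``path=None`` the packaged defaults are used.  The raw dict is
    returned as well so callers can reach sections (life cycle, background
    reference, generator settings) owned by other modules.
    """
    p = Path(path) if path is not None else default_params_path()
    with open(p) as fh:
        raw = yaml.safe_load(fh)
    sp = SpeciesParams(**raw["species"])
    mp = _multipliers_from_dict(raw["multipliers"])
    return sp, mp, raw


def _pyify(obj):
    """Recursively convert numpy scalars so YAML can represent them."""
    if isinstance(obj, dict):
        return {k: _pyify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pyify(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def save_params(path: str | Path, sp: SpeciesParams, mp: MultiplierParams,
                extra: Mapping | None = None) -> None:
    """Serialize a parameter set to YAML, round-trippable by :func:`load_params`."""
    pol = {}
    for metal, pp in mp.pollutants.items():
        d = asdict(pp)
        d.pop("metal")
        pol[metal] = d
    doc = {
        "species": asdict(sp),
        "multipliers": {
            "salinity": asdict(mp.salinity),
            "density": asdict(mp.density),
            "elevation": asdict(mp.elevation),
            "pollutant": pol,
        },
    }
    if extra:
        doc.update(dict(extra))
    with open(path, "w") as fh:
        yaml.safe_dump(_pyify(doc), fh, sort_keys=False)
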