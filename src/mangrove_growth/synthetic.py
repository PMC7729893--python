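"""Synthetic data with the statistical structure of the Can Gio survey.

Three generators make every pipeline stage testable without field data:

* :func:`generate_inventory` draws plot environments on the survey's
  covariate ranges, grows each plot's mean tree forward under a known
  ("true") parameter set and adds multiplicative lognormal observation
  noise - the basis of all parameter-recovery experiments.
* :func:`generate_hm_table` emulates the 11-site concentration table
  (including an Fe column, which the printed table lacks) with a built-in
  regional contrast.
* :func:`generate_rasters` produces smooth correlated elevation / salinity
  / root-Cr fields plus a forest mask at 100 m resolution for the scenario
  engine.

:func:`load_reference_tables` returns the two printed survey tables that
ship with the package as transcription fixtures.
"""

from __future__ import annotations

import hashlib
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .growth import step_dbh_rk4, height_from_dbh
from .io import RasterLayer
from .multipliers import combined_multiplier_fields
from .params import MultiplierParams, SpeciesParams, load_params

__all__ = [
    "SurveyGeneratorConfig",
    "RasterGeneratorConfig",
    "generate_inventory",
    "generate_hm_table",
    "generate_rasters",
    "load_reference_tables",
    "FixtureError",
]


@dataclass(frozen=True)
class SurveyGeneratorConfig:
    """Covariate ranges and noise level of the emulated survey.

    Defaults follow the field campaign this package models: 208 plots of
    10 x 10 m, ages 19-40 yr, pore-water salinity ~8-18 ppt, 10-115 trees
    per plot, and a 5% relative observation noise on dbh and height.
    """

    n_plots: int = 208
    salinity_range: tuple[float, float] = (8.0, 18.2)   # ppt
    elevation_range: tuple[float, float] = (-0.5, 0.5)  # m
    density_range: tuple[float, float] = (10.0, 115.0)  # trees / 100 m^2
    age_range: tuple[int, int] = (19, 40)               # yr
    sigma: float = 0.05        # relative lognormal noise on dbh and H
    dbh0: float = 0.5          # cm at planting
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plots < 1:
            raise ValueError("n_plots must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        for name in ("salinity_range", "elevation_range", "density_range", "age_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} is degenerate: {(lo, hi)}")


def generate_inventory(cfg: SurveyGeneratorConfig, sp: SpeciesParams,
                       mp: MultiplierParams) -> pd.DataFrame:
    """Draw a synthetic plot inventory under known true parameters.

    Covariates are uniform on their ranges; each plot's mean dbh results
    from growing a tree from ``dbh0`` for the plot's age at the constant
    rate G_true = Gopt * MUL(env), then applying median-unbiased lognormal
    noise exp(sigma * Z).  Height follows the height curve of the noisy dbh.
    ``G_true`` is retained for recovery experiments.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_plots
    sal = rng.uniform(*cfg.salinity_range, n)
    elev = rng.uniform(*cfg.elevation_range, n)
    dens = rng.uniform(*cfg.density_range, n)
    ages = rng.integers(cfg.age_range[0], cfg.age_range[1] + 1, n)

    mul = combined_multiplier_fields(sal, dens, elev, mp)
    G = sp.Gopt * mul
    dbh = np.full(n, cfg.dbh0)
    out = np.full(n, cfg.dbh0)
    for yr in range(1, int(ages.max()) + 1):
        dbh = step_dbh_rk4(dbh, G, sp, dt=1.0, n_steps=4)
        done = ages >= yr
        out[done] = dbh[done]

    noise_d = np.exp(cfg.sigma * rng.standard_normal(n))
    noise_h = np.exp(cfg.sigma * rng.standard_normal(n))
    dbh_obs = np.minimum(out * noise_d, sp.Dmax * 0.999)
    height_obs = height_from_dbh(np.clip(out, 0, sp.Dmax), sp) * noise_h

    return pd.DataFrame({
        "plot_id": [f"S{i:04d}" for i in range(n)],
        "region": "synthetic",
        "age": ages.astype(float),
        "mean_dbh": dbh_obs,
        "mean_height": height_obs,
        "density": dens,
        "salinity": sal,
        "elevation": elev,
        "G_true": G,
        "dbh_true": out,
    })


# ---------------------------------------------------------------------------
# Heavy-metal table generator

_HM_SOIL_MEDIANS = {  # mg/kg, roughly the observed regional levels
    "CanGio": {"Cu": 72.0, "Cr": 4.4, "Ni": 3.0, "Fe": 26000.0},
    "ThiVai": {"Cu": 84.0, "Cr": 16.0, "Ni": 9.0, "Fe": 36000.0},
}
_HM_TISSUE_FACTOR = {"root": 0.15, "leaf": 0.06}  # crude tissue/soil ratio scale


def generate_hm_table(n_sites: int, seed: int = 0,
                      sigma_log: float = 0.25) -> pd.DataFrame:
    """Emulate the 11-site heavy-metal table, Fe column included.

    Sites alternate between the two regions; concentrations are lognormal
    around region-specific medians so the observed contrast (higher Cr/Ni in
    the industrialised Thi Vai catchment) is built in.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_sites):
        region = "CanGio" if i % 2 == 0 else "ThiVai"
        position = "upstream" if (i // 2) % 2 == 0 else "downstream"
        site = f"Y{i:02d}"
        for metal, med in _HM_SOIL_MEDIANS[region].items():
            soil = med * np.exp(sigma_log * rng.standard_normal())
            rows.append((site, region, position, "soil", metal, soil))
            for tissue, f in _HM_TISSUE_FACTOR.items():
                if metal == "Fe":
                    continue
                conc = soil * f * np.exp(sigma_log * rng.standard_normal())
                rows.append((site, region, position, tissue, metal, conc))
    return pd.DataFrame(rows, columns=["site", "region", "position",
                                       "compartment", "metal", "conc"])


# ---------------------------------------------------------------------------
# Raster generator


@dataclass(frozen=True)
class RasterGeneratorConfig:
    """Smooth correlated raster stack emulating the scenario input maps.

    Fields are low-pass-filtered Gaussian noise rescaled to the given
    ranges; ``correlation_length`` is per-layer, in metres.  The root-Cr
    range is chosen so the observed load spans the hormetic plateau into
    the declining branch of the Cr dose-response, the regime the published
    scenario totals imply.
    """

    shape: tuple[int, int] = (30, 30)
    cellsize: float = 100.0  # m
    elevation_range: tuple[float, float] = (-1.0, 0.8)   # m
    salinity_range: tuple[float, float] = (8.0, 18.0)    # ppt
    root_cr_range: tuple[float, float] = (20.0, 150.0)   # mg/kg root DW
    correlation_length: dict = field(default_factory=lambda: {
        "elevation": 500.0, "salinity": 800.0, "root_cr": 400.0,
    })
    forest_fraction: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape[0] < 2 or self.shape[1] < 2:
            raise ValueError("shape must be at least 2 x 2")


def _smooth_field(rng, shape, corr_cells, lo, hi):
    noise = rng.standard_normal(shape)
    f = gaussian_filter(noise, sigma=max(corr_cells, 1e-6), mode="wrap")
    fmin, fmax = f.min(), f.max()
    if fmax - fmin < 1e-12:
        return np.full(shape, 0.5 * (lo + hi))
    return lo + (hi - lo) * (f - fmin) / (fmax - fmin)


def generate_rasters(cfg: RasterGeneratorConfig) -> dict[str, RasterLayer]:
    """Aligned elevation / salinity / root-Cr / forest-mask layers."""
    rng = np.random.default_rng(cfg.seed)
    layers: dict[str, RasterLayer] = {}
    ranges = {
        "elevation": cfg.elevation_range,
        "salinity": cfg.salinity_range,
        "root_cr": cfg.root_cr_range,
    }
    for kind, (lo, hi) in ranges.items():
        corr_cells = cfg.correlation_length.get(kind, 300.0) / cfg.cellsize
        vals = _smooth_field(rng, cfg.shape, corr_cells, lo, hi)
        layers[kind] = RasterLayer(values=vals, cellsize=cfg.cellsize, kind=kind)
    cover = _smooth_field(rng, cfg.shape, 300.0 / cfg.cellsize, 0.0, 1.0)
    mask = (cover <= np.quantile(cover, cfg.forest_fraction)).astype(float)
    if mask.sum() == 0:  # degenerate fraction: keep at least one cell
        mask.ravel()[0] = 1.0
    layers["forest_mask"] = RasterLayer(values=mask, cellsize=cfg.cellsize,
                                        kind="forest_mask")
    return layers


# ---------------------------------------------------------------------------
# Packaged survey-table fixtures


class FixtureError(RuntimeError):
    """A packaged fixture file is missing or corrupted."""


_FIXTURE_SHA256 = {
    # frozen at packaging time; verified on load
    "hm_concentrations_11_sites.csv":
        "08380a564291f8622b3f89f075672cde712c8fac710d86caa8085cb5e6434151",
    "plot_inventory_11_sites.csv":
        "4a5e3406f5abe43ceb1ccbb372d4780fbe4f7e7316c519f00c650bc167fa97a5",
    "fe_soil_synthetic.csv":
        "a363d738ff0485294f023c49fb8401f08950ed8a871dcff3d4c68b74a275e93f",
}


def _fixture_path(name: str) -> Path:
    return Path(importlib.resources.files("mangrove_growth") / "data" / name)


def _read_checked(name: str) -> pd.DataFrame:
    p = _fixture_path(name)
    if not p.exists():
        raise FixtureError(f"packaged fixture {name} is missing")
    blob = p.read_bytes()
    digest = hashlib.sha256(blob).hexdigest()
    expected = _FIXTURE_SHA256[name]
    if digest != expected:
        raise FixtureError(
            f"fixture {name} checksum mismatch (expected {expected[:12]}..., "
            f"got {digest[:12]}...)"
        )
    return pd.read_csv(p, dtype={"site": str, "plot_id": str})


def load_reference_tables(include_synthetic_fe: bool = False):
    """Packaged 11-site survey tables: (hm_table, plot_records).

    The heavy-metal table carries Cu/Cr/Ni in soil, root and leaf; Fe was
    not reported, so by default no Fe rows are present.  With
    ``include_synthetic_fe=True`` a clearly-labelled synthetic soil-Fe
    column (reverse-engineered from the published Cu enrichment factors) is
    appended so the enrichment-factor pipeline can run end to end.  The
    plot table carries the printed growth observations including the
    reported lifetime growth rate G.
    """
    hm = _read_checked("hm_concentrations_11_sites.csv")
    plots = _read_checked("plot_inventory_11_sites.csv")
    if include_synthetic_fe:
        fe = _read_checked("fe_soil_synthetic.csv")
        hm = pd.concat([hm, fe], ignore_index=True)
    return hm, plots


def default_true_params():
    """(SpeciesParams, MultiplierParams) of the packaged defaults - the
    generating truth for synthetic studies."""
    sp, mp, _ = load_params()
    return sp, mp
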