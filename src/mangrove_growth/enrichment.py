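"""Heavy-metal descriptive statistics and enrichment-factor analysis.

Concentration tables are long-format frames with one row per
(site, compartment, metal): soil, root and leaf concentrations in mg/kg dry
weight.  Sediment enrichment is judged by the Fe-normalised enrichment
factor EF = (Me/Fe)_sample / (Me/Fe)_background against continental-shale
background values; EF < 1.5 indicates a mainly natural source, EF >= 1.5
anthropogenic input and EF > 5 significant enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "HM_COLUMNS",
    "BackgroundReference",
    "CONTINENTAL_SHALE",
    "validate_hm_table",
    "summarize",
    "enrichment_factor",
    "classify_ef",
    "bioconcentration_ratio",
]

#: canonical column schema for long-format heavy-metal tables
HM_COLUMNS = ["site", "region", "position", "compartment", "metal", "conc"]

EF_NATURAL_MAX = 1.5     # EF below this: mainly natural source
EF_SIGNIFICANT_MIN = 5.0  # EF above this: significant enrichment


@dataclass(frozen=True)
class BackgroundReference:
    """Per-metal background concentrations [mg/kg] with an Fe reference."""

    values: Mapping[str, float]
    reference: str = "Fe"
    source: str = "unspecified"

    def __post_init__(self) -> None:
        if self.reference not in self.values:
            raise ValueError(f"reference element {self.reference!r} missing from values")
        if any(v <= 0 for v in self.values.values()):
            raise ValueError("background concentrations must be positive")


#: Continental-shale averages (Turekian & Wedepohl 1961); a conventional,
#: overridable default, not a measurement of the study region.
CONTINENTAL_SHALE = BackgroundReference(
    values={"Fe": 47200.0, "Cu": 45.0, "Cr": 90.0, "Ni": 68.0},
    reference="Fe",
    source="continental shale (Turekian & Wedepohl 1961)",
)


def validate_hm_table(table: pd.DataFrame) -> None:
    missing = [c for c in HM_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"heavy-metal table missing columns: {missing}")
    if (table["conc"] < 0).any():
        raise ValueError("negative concentration in heavy-metal table")
    dup = table.duplicated(subset=["site", "compartment", "metal"])
    if dup.any():
        raise ValueError("duplicate (site, compartment, metal) rows")


def summarize(table: pd.DataFrame, by: tuple[str, ...] = ("compartment",)) -> pd.DataFrame:
    """Mean / sample std / min / max of concentration per metal per group.

    ``by`` may include "region" and/or "compartment".  Sample (n-1) standard
    deviation; a single-row group reports std as NaN (not available).
    Values are returned at full precision - round only for presentation.
    """
    validate_hm_table(table)
    keys = list(by) + ["metal"]
    g = table.groupby(keys)["conc"]
    out = g.agg(n="count", mean="mean", std="std", min="min", max="max").reset_index()
    return out


def classify_ef(ef: float) -> str:
    """EF class: [0, 1.5) natural, [1.5, 5] anthropogenic, (5, inf) significant."""
    if ef < 0:
        raise ValueError("EF cannot be negative")
    if ef < EF_NATURAL_MAX:
        return "natural"
    if ef <= EF_SIGNIFICANT_MIN:
        return "anthropogenic"
    return "significant"


def enrichment_factor(table: pd.DataFrame, bg: BackgroundReference = CONTINENTAL_SHALE,
                      compartment: str = "soil") -> pd.DataFrame:
    """Per-site enrichment factors for every non-reference metal.

    EF = (Me/Fe)_sample / (Me/Fe)_background.  A site lacking the reference
    element yields per-site error records (``error`` column) rather than a
    global failure.  Output columns: site, metal, conc, ref_conc, EF,
    ef_class, error.
    """
    validate_hm_table(table)
    sub = table[table["compartment"] == compartment]
    records = []
    for site, grp in sub.groupby("site", sort=False):
        conc = dict(zip(grp["metal"], grp["conc"]))
        fe = conc.get(bg.reference)
        for metal, x in conc.items():
            if metal == bg.reference:
                continue
            if metal not in bg.values:
                continue
            rec = {"site": site, "metal": metal, "conc": x, "ref_conc": fe,
                   "EF": np.nan, "ef_class": None, "error": None}
            if fe is None or not np.isfinite(fe) or fe <= 0:
                rec["error"] = f"missing {bg.reference} at site {site}"
            else:
                ef = (x / fe) / (bg.values[metal] / bg.values[bg.reference])
                rec["EF"] = ef
                rec["ef_class"] = classify_ef(ef)
            records.append(rec)
    return pd.DataFrame.from_records(records)


def bioconcentration_ratio(table: pd.DataFrame,
                           tissues: tuple[str, ...] = ("root", "leaf")) -> pd.DataFrame:
    """Tissue/soil concentration ratios per site and metal.

    A zero (or missing) soil concentration flags the record as undefined
    instead of raising.  Output columns: site, metal, tissue, tissue_conc,
    soil_conc, ratio, undefined.
    """
    validate_hm_table(table)
    soil = table[table["compartment"] == "soil"].set_index(["site", "metal"])["conc"]
    records = []
    for tissue in tissues:
        sub = table[table["compartment"] == tissue]
        for row in sub.itertuples():
            key = (row.site, row.metal)
            s = soil.get(key, np.nan)
            undefined = not np.isfinite(s) or s == 0
            records.append({
                "site": row.site, "metal": row.metal, "tissue": tissue,
                "tissue_conc": row.conc, "soil_conc": s,
                "ratio": np.nan if undefined else row.conc / s,
                "undefined": undefined,
            })
    return pd.DataFrame.from_records(records)
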