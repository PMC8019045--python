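"""Monthly ecological covariates: food availability indices and rainfall.

The food availability index (FAI) of a plant-part group in a month is

    FAI = sum over species of  mean phenology score  x  species basal area

where the mean is over that species' surveyed trees and the 0-4 phenology
score indexes the fraction of crown bearing the part. "fruit" pools ripe
and unripe fruit with equal weight; "young_leaf" uses young leaves only.
A species-month with no phenology records is flagged missing and
contributes 0 to the FAI with a warning (an additive index treats a
non-bearing tree the same way), rather than propagating missingness.

Covariates are standardized to z-scores (population SD) over the analyzed
months before modeling.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import PhenologyRecord, RainfallRecord, SpeciesBasalArea

log = logging.getLogger("multisoc")

PART_GROUPS = {
    "fruit": frozenset({"ripe_fruit", "unripe_fruit"}),
    "ripe_fruit": frozenset({"ripe_fruit"}),
    "young_leaf": frozenset({"young_leaf"}),
}

__all__ = ["PART_GROUPS", "monthly_species_score", "food_availability_index", "build_covariates"]


def monthly_species_score(
    phenology: Iterable[PhenologyRecord],
    species: str,
    month: str,
    part_group: str = "fruit",
) -> float:
    """Mean phenology score of a species' trees for a month and part group;
    NaN flags a species-month with no records (absence of data, not a 0)."""
    parts = PART_GROUPS[part_group]
    scores = [
        r.score
        for r in phenology
        if r.species == species and r.month == month and r.plant_part in parts
    ]
    if not scores:
        return float("nan")
    return float(np.mean(scores))


def food_availability_index(
    phenology: Sequence[PhenologyRecord],
    basal_areas: Sequence[SpeciesBasalArea],
    part_group: str,
    month: str,
    strict: bool = False,
) -> float:
    """FAI for one month: sum of mean species score x species basal area.

    In strict mode a species scored that month but absent from the
    basal-area table raises; otherwise it is skipped with a warning.
    """
    ba = {b.species: b.basal_area for b in basal_areas}
    species_this_month = sorted(
        {r.species for r in phenology if r.month == month and r.plant_part in PART_GROUPS[part_group]}
    )
    total = 0.0
    for sp in ba:
        score = monthly_species_score(phenology, sp, month, part_group)
        if np.isnan(score):
            log.warning("no %s phenology for %s in %s; contributes 0", part_group, sp, month)
            continue
        total += score * ba[sp]
    missing_ba = [sp for sp in species_this_month if sp not in ba]
    if missing_ba:
        msg = f"species scored in {month} but missing basal area: {missing_ba}"
        if strict:
            raise ValueError(msg)
        log.warning(msg)
    return total


def build_covariates(
    fai_fruit: dict,
    fai_leaf: dict,
    rainfall: Sequence[RainfallRecord] | dict,
    months: Sequence[str],
    interpolate: bool = False,
) -> pd.DataFrame:
    """Join the three monthly series and standardize them.

    Returns a frame with columns month, fruit_fai, leaf_fai, rainfall_mm
    and z_fruit, z_leaf, z_rain (population-SD z-scores over the included
    months; a constant series gets NaN z-scores with a warning). Month gaps
    raise unless ``interpolate=True`` (linear). Pairwise predictor
    correlations above |r| = 0.7 trigger a multicollinearity warning.
    """
    if not isinstance(rainfall, dict):
        rainfall = {r.month: r.rainfall for r in rainfall}
    months = list(months)
    data = {"fruit_fai": fai_fruit, "leaf_fai": fai_leaf, "rainfall_mm": rainfall}
    cols = {}
    for name, series in data.items():
        vals = np.array([series.get(m, np.nan) for m in months], dtype=float)
        if np.isnan(vals).any():
            gaps = [m for m, v in zip(months, vals) if np.isnan(v)]
            if not interpolate:
                raise ValueError(f"{name} missing for months {gaps}")
            vals = (
                pd.Series(vals).interpolate(limit_direction="both").to_numpy()
            )
        cols[name] = vals
    frame = pd.DataFrame({"month": months, **cols})
    zmap = {"fruit_fai": "z_fruit", "leaf_fai": "z_leaf", "rainfall_mm": "z_rain"}
    for raw, z in zmap.items():
        vals = frame[raw].to_numpy()
        sd = vals.std()  # population SD
        if sd == 0:
            log.warning("%s is constant over the study months; z-score undefined", raw)
            frame[z] = np.nan
        else:
            frame[z] = (vals - vals.mean()) / sd
    for i, a in enumerate(zmap):
        for b in list(zmap)[i + 1 :]:
            va, vb = frame[a].to_numpy(), frame[b].to_numpy()
            if va.std() == 0 or vb.std() == 0:
                continue
            r = float(np.corrcoef(va, vb)[0, 1])
            if abs(r) > 0.7:
                log.warning(
                    "predictors %s and %s strongly correlated (r = %.2f > 0.7): "
                    "multicollinearity risk",
                    a,
                    b,
                    r,
                )
    return frame
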