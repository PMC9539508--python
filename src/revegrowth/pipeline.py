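"""End-to-end assembly: plant inventory tables to a model-ready frame.

This is the analysis path a user runs on real (or simulated) inventory
CSVs: estimate biomass from stem diameters through the allometry table,
derive relative growth rates, drop focal plants under 0.1 kg, compute the
per-focal neighborhood metrics, merge planting/plot/trait predictors,
apply the linearizing transforms and z-standardize over the pooled focal
set.  The stored standardizer is what later maps fixed raw moisture values
(e.g. dry = 0.27, mesic = 0.76) onto the modeled z-scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import growth as growth_mod
from . import neighborhood as nbh
from .design import CONTINUOUS_PREDICTORS, Standardizer, transform_predictors
from .simulate import Dataset, _assemble_predictors, complete_traits

__all__ = ["ModelFrame", "build_model_frame"]


@dataclass
class ModelFrame:
    """Standardized modeling data plus the bookkeeping around it."""

    data: pd.DataFrame  # standardized predictors + genus + random-factor columns + rgr
    standardizer: Standardizer
    n_excluded_small: int  # focals dropped by the < 0.1 kg biomass filter
    n_incomplete: int  # candidates dropped for missing neighborhood metrics
    raw: pd.DataFrame  # same rows, untransformed predictor scale

    @property
    def y(self) -> np.ndarray:
        return self.data["rgr"].to_numpy()


def build_model_frame(
    dataset: Dataset,
    allometry: growth_mod.AllometryTable | None = None,
    min_biomass_kg: float = 0.1,
    rarefaction_n: int = 9,
) -> ModelFrame:
    """Run the measurement pipeline and return the model-ready frame.

    Focal candidates are Acacia/Eucalyptus plants; a candidate enters the
    model only with complete neighborhood metrics (its plot holds at least
    ``rarefaction_n + 1`` plants and enough trait-complete neighbor
    species) and estimated biomass of at least ``min_biomass_kg``.
    """
    if allometry is None:
        allometry = growth_mod.synthetic_allometry()
    plants = dataset.plants.copy()
    plants["biomass_kg"] = growth_mod.estimate_biomass(
        plants["diameter_cm"],
        plants["species"],
        growth_mod.lifeform_key(plants["genus"]),
        plants["measure_height_cm"],
        allometry,
    )
    plants["is_focal"] = plants["genus"].isin(["Acacia", "Eucalyptus"])
    plants, n_small = growth_mod.filter_focals(plants, min_biomass_kg)

    ages = dataset.plantings.set_index("planting_id")["age_yr"]
    plants["rgr"] = np.nan
    foc = plants["is_focal"]
    plants.loc[foc, "rgr"] = growth_mod.compute_rgr(
        plants.loc[foc, "biomass_kg"].to_numpy(),
        ages.loc[plants.loc[foc, "planting_id"]].to_numpy(),
    )

    plants["is_focal_candidate"] = plants["is_focal"]
    traits = complete_traits(dataset)
    metrics = nbh.neighborhood_table(plants, dataset.plots, traits, rarefaction_n=rarefaction_n)
    df = _assemble_predictors(dataset, metrics)
    df = df.merge(plants[["plant_id", "rgr"]], on="plant_id")
    complete = df[list(CONTINUOUS_PREDICTORS)].notna().all(axis=1)
    n_incomplete = int((~complete).sum())
    raw = df[complete].reset_index(drop=True)

    transformed = transform_predictors(raw)
    std = Standardizer()
    data = std.fit_transform(transformed, CONTINUOUS_PREDICTORS)
    return ModelFrame(
        data=data,
        standardizer=std,
        n_excluded_small=n_small,
        n_incomplete=n_incomplete,
        raw=raw,
    )
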