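"""Model covariates: day of year, z-scores, and GLM design matrices.

All numeric predictors are z-score standardized (sample standard deviation,
n−1 denominator) so fitted effects are comparable across predictors; day of
year in multi-species models is standardized within species (group-centered)
because the five species' flowering seasons are offset. The fruiting flag is
a raw 0/1 indicator, not standardized.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

GEO_MODELS = ("geo_binary", "geo_count")
SPECIES_MODELS = ("species_binary", "species_count")
#: species indicator reference level in multi-species designs
REFERENCE_SPECIES = "inflata"


class CovariateError(ValueError):
    pass


@dataclass(slots=True)
class StandardizationParams:
    """Mean/SD used to standardize one variable, reusable on new data.

    ``scope`` is "global" (scalar mean/sd) or "by_species" (per-group dicts).
    ``raw_min``/``raw_max`` record the fitting-subset range so downstream
    prediction grids can flag extrapolation.
    """

    variable: str
    scope: str = "global"
    mean: Union[float, dict[str, float]] = 0.0
    sd: Union[float, dict[str, float]] = 1.0
    raw_min: Optional[float] = None
    raw_max: Optional[float] = None

    def apply(self, values, groups=None) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.scope == "global":
            return (values - self.mean) / self.sd
        if groups is None:
            raise CovariateError(
                f"{self.variable}: group labels required for by-species params")
        groups = np.asarray(groups)
        out = np.empty_like(values)
        for g in np.unique(groups):
            if g not in self.mean:
                raise CovariateError(f"{self.variable}: no params for group {g!r}")
            mask = groups == g
            out[mask] = (values[mask] - self.mean[g]) / self.sd[g]
        return out

    def invert(self, z, groups=None) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if self.scope == "global":
            return z * self.sd + self.mean
        groups = np.asarray(groups)
        out = np.empty_like(z)
        for g in np.unique(groups):
            mask = groups == g
            out[mask] = z[mask] * self.sd[g] + self.mean[g]
        return out

    def to_dict(self) -> dict:
        return {
            "variable": self.variable, "scope": self.scope,
            "mean": self.mean, "sd": self.sd,
            "raw_min": self.raw_min, "raw_max": self.raw_max,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StandardizationParams":
        return cls(**dict(d))


@dataclass(slots=True)
class DesignMatrix:
    """Response + predictor matrix for one model, aligned to record ids."""

    model: str
    response: np.ndarray
    X: pd.DataFrame  # includes the 'const' intercept column
    record_ids: list[str]
    fruit_mean: float  # fitting-subset fruiting proportion
    species: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.X.isna().any().any() or np.any(np.isnan(self.response)):
            raise CovariateError("design matrix contains missing values")


def day_of_year(date: _dt.date) -> int:
    """1-based ordinal day within the year (366 possible in leap years)."""
    return date.timetuple().tm_yday


def zscore(values, params: Optional[StandardizationParams] = None,
           variable: str = "x") -> tuple[np.ndarray, StandardizationParams]:
    """Standardize to mean 0, sample SD 1; or apply stored parameters."""
    values = np.asarray(values, dtype=float)
    if params is not None:
        return params.apply(values), params
    if values.size < 2:
        raise CovariateError(f"{variable}: need at least 2 values to standardize")
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        raise CovariateError(f"{variable}: zero standard deviation")
    params = StandardizationParams(
        variable=variable, scope="global", mean=float(values.mean()), sd=sd,
        raw_min=float(values.min()), raw_max=float(values.max()),
    )
    return params.apply(values), params


def group_zscore(values, groups, variable: str = "x",
                 ) -> tuple[np.ndarray, StandardizationParams]:
    """Z-score within each group independently (group-centered z-score)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for g in np.unique(groups):
        sub = values[groups == g]
        if sub.size < 2:
            raise CovariateError(f"{variable}: group {g!r} has fewer than 2 values")
        sd = float(sub.std(ddof=1))
        if sd == 0.0:
            raise CovariateError(f"{variable}: zero standard deviation in group {g!r}")
        means[str(g)] = float(sub.mean())
        sds[str(g)] = sd
    params = StandardizationParams(
        variable=variable, scope="by_species", mean=means, sd=sds,
        raw_min=float(values.min()), raw_max=float(values.max()),
    )
    return params.apply(values, groups=[str(g) for g in groups]), params


def build_design(
    records: Sequence,
    model: str,
    marginalities: Optional[Mapping[str, float]] = None,
) -> tuple[DesignMatrix, dict[str, StandardizationParams]]:
    """Assemble the design matrix for one of the four fitted models.

    Models
    ------
    geo_binary
        Response 1{exsertion present}; predictors z_latitude,
        z_marginality, z_longitude, z_elevation, z_day_of_year, fruit.
    geo_count
        Response n_exserted_flowers on present records; geo_binary
        predictors plus z_total_visible_flowers.
    species_binary
        Response as geo_binary; species indicators (reference
        *L. inflata*), group-centered z_day_of_year, fruit.
    species_count
        species_binary predictors plus z_total_visible_flowers.

    ``marginalities`` maps record_id to the marginality value r and is
    required for the geographic models. Standardization parameters are
    estimated on the model's own fitting subset and returned for reuse on
    prediction grids.
    """
    if model not in GEO_MODELS + SPECIES_MODELS:
        raise CovariateError(f"unknown model {model!r}")
    records = list(records)
    if not records:
        raise CovariateError("no records to build a design from")

    ids = [r.record_id for r in records]
    doy = np.array([day_of_year(r.observation_date) for r in records], dtype=float)
    fruit = np.array([1.0 if r.fruit_present == "yes" else 0.0 for r in records])
    params: dict[str, StandardizationParams] = {}
    cols: dict[str, np.ndarray] = {}

    if model in GEO_MODELS:
        if marginalities is None:
            raise CovariateError(f"{model}: per-record marginalities are required")
        missing = [i for i in ids if i not in marginalities]
        if missing:
            raise CovariateError(
                f"{model}: no marginality for record(s) {missing[:3]}...")
        lat = np.array([r.latitude for r in records], dtype=float)
        lon = np.array([r.longitude for r in records], dtype=float)
        if any(r.elevation is None for r in records):
            raise CovariateError(
                f"{model}: records lack elevation; re-run the filter cascade "
                "with require_elevation=True"
            )
        elev = np.array([r.elevation for r in records], dtype=float)
        marg = np.array([marginalities[i] for i in ids], dtype=float)
        for name, vals in (("z_latitude", lat), ("z_marginality", marg),
                           ("z_longitude", lon), ("z_elevation", elev)):
            cols[name], params[name] = zscore(vals, variable=name)
        # one species: group-centering reduces to the plain z-score
        cols["z_day_of_year"], params["z_day_of_year"] = zscore(
            doy, variable="z_day_of_year")
        cols["fruit"] = fruit
    else:
        species = np.array([r.species for r in records])
        for sp in sorted(set(species) - {REFERENCE_SPECIES}):
            cols[f"species_{sp}"] = (species == sp).astype(float)
        cols["z_day_of_year"], params["z_day_of_year"] = group_zscore(
            doy, species, variable="z_day_of_year")
        cols["fruit"] = fruit

    if model.endswith("_count"):
        bad = [r.record_id for r in records
               if r.exsertion_score != "present" or r.n_exserted_flowers is None]
        if bad:
            raise CovariateError(
                f"{model}: records not eligible for the count model "
                f"(first: {bad[0]!r}); filter with which_model='count'"
            )
        visible = np.array([r.n_visible_flowers for r in records], dtype=float)
        cols["z_total_visible_flowers"], params["z_total_visible_flowers"] = zscore(
            visible, variable="z_total_visible_flowers")
        response = np.array([r.n_exserted_flowers for r in records], dtype=float)
    else:
        response = np.array(
            [1.0 if r.exsertion_score == "present" else 0.0 for r in records])

    X = pd.DataFrame(cols, index=ids)
    X.insert(0, "const", 1.0)
    design = DesignMatrix(
        model=model, response=response, X=X, record_ids=ids,
        fruit_mean=float(fruit.mean()),
        species=(np.array([r.species for r in records])
                 if model in SPECIES_MODELS else None),
    )
    return design, params
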