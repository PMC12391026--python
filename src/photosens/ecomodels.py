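"""Association models between photoperiod sensitivity and species traits.

Two model families, one predictor per model:

* a Gamma GLM with log link for the continuous (strictly positive)
  germination sensitivity metric, weighted by the inverse squared bootstrap
  standard error of each species' metric, and
* a binomial logit GLM for categorical flowering photoperiodism from the
  literature, binarised to sensitive (long-day, short-day, other) versus
  insensitive (day-neutral).

Each model is reported with its coefficients, a deviance pseudo-R²
(1 − residual/null deviance) and a likelihood-ratio chi-square p-value
against the intercept-only model with the same weights.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from .germdata import SpeciesTraits
from .psmetric import PSMResult

__all__ = [
    "AssociationSummary",
    "FloweringCategory",
    "FloweringRecord",
    "GAMMA_PREDICTORS",
    "FLOWERING_PREDICTORS",
    "fit_weighted_gamma_glm",
    "fit_flowering_binomial_glm",
    "read_flowering_table",
]

GAMMA_PREDICTORS = ("seed_mass", "growth_form", "latitude", "lai", "alpine")
FLOWERING_PREDICTORS = ("latitude", "lai", "seed_mass")


@dataclass(frozen=True)
class AssociationSummary:
    predictor: str
    family: str  # "gamma_log" or "binomial_logit"
    coefficients: Mapping[str, float]
    pseudo_r2: float
    lr_statistic: float
    p_value: float
    n_used: int
    weights_used: bool


class FloweringCategory(enum.Enum):
    LONG_DAY = "long_day"
    SHORT_DAY = "short_day"
    DAY_NEUTRAL = "day_neutral"
    OTHER = "other"

    @property
    def sensitive(self) -> bool:
        """Day-neutral species are photoperiod-insensitive; all others sensitive."""
        return self is not FloweringCategory.DAY_NEUTRAL


_CATEGORY_DIALECTS = {
    "long_day": FloweringCategory.LONG_DAY,
    "long day": FloweringCategory.LONG_DAY,
    "short_day": FloweringCategory.SHORT_DAY,
    "short day": FloweringCategory.SHORT_DAY,
    "day_neutral": FloweringCategory.DAY_NEUTRAL,
    "day neutral": FloweringCategory.DAY_NEUTRAL,
    "no_photoperiodism": FloweringCategory.DAY_NEUTRAL,
    "no photoperiodism": FloweringCategory.DAY_NEUTRAL,
    "other": FloweringCategory.OTHER,
    "other_photoperiod": FloweringCategory.OTHER,
    "other photoperiod": FloweringCategory.OTHER,
}


@dataclass(frozen=True)
class FloweringRecord:
    species: str
    category: FloweringCategory
    latitude_deg: float | None = None
    lai: float | None = None
    seed_mass_mg: float | None = None


def read_flowering_table(path) -> list[FloweringRecord]:
    """Read a flowering-photoperiodism CSV
    (columns species, category, latitude_deg, lai, seed_mass_mg)."""
    df = pd.read_csv(path, dtype={"species": str, "category": str})
    records = []
    for i, row in df.iterrows():
        key = str(row["category"]).strip().lower()
        if key not in _CATEGORY_DIALECTS:
            raise ValueError(f"row {int(i)+1}: unknown flowering category {row['category']!r}")

        def _opt(col: str) -> float | None:
            return None if col not in row or pd.isna(row[col]) else float(row[col])

        records.append(
            FloweringRecord(
                species=str(row["species"]),
                category=_CATEGORY_DIALECTS[key],
                latitude_deg=_opt("latitude_deg"),
                lai=_opt("lai"),
                seed_mass_mg=_opt("seed_mass_mg"),
            )
        )
    return records


def _predictor_frame(
    predictor: str, traits: Mapping[str, SpeciesTraits], species: Sequence[str]
) -> pd.DataFrame:
    """Design columns for one predictor, NaN where the trait is missing."""
    rows = []
    for name in species:
        t = traits.get(name)
        value: float | str | None = None
        if t is not None:
            if predictor == "seed_mass":
                value = np.log10(t.seed_mass_mg) if t.seed_mass_mg else None
            elif predictor == "latitude":
                value = abs(t.latitude_deg) if t.latitude_deg is not None else None
            elif predictor == "lai":
                value = t.lai
            elif predictor == "alpine":
                value = None if t.alpine is None else float(t.alpine)
            elif predictor == "growth_form":
                value = t.growth_form
        rows.append({"species": name, predictor: value})
    return pd.DataFrame(rows)


def _exog_for(predictor: str, frame: pd.DataFrame) -> pd.DataFrame:
    if predictor == "growth_form":
        dummies = pd.get_dummies(frame[predictor], prefix="growth_form", dtype=float)
        # Stable reference level: drop the first level alphabetically.
        dummies = dummies.drop(columns=dummies.columns[0])
        exog = dummies
    else:
        exog = frame[[predictor]].astype(float)
    return sm.add_constant(exog, has_constant="add")


def fit_weighted_gamma_glm(
    psm_results: Sequence[PSMResult],
    traits: Sequence[SpeciesTraits],
    predictor: str,
    zero_offset: float | None = None,
) -> AssociationSummary:
    """Inverse-variance-weighted Gamma GLM of the sensitivity metric on one trait.

    The response is the non-negative metric itself; seed mass enters
    log10-transformed and latitude as absolute degrees; climber species are
    dropped before a growth-form fit (too few to estimate).  Species whose
    metric is exactly zero are incompatible with a Gamma response and raise
    unless ``zero_offset`` (a small constant added to every response) is
    explicitly supplied.
    """
    if predictor not in GAMMA_PREDICTORS:
        raise ValueError(f"predictor must be one of {GAMMA_PREDICTORS}, got {predictor!r}")
    usable = [r for r in psm_results if np.isfinite(r.weight) and r.se > 0]
    zero_species = [r.species for r in usable if r.psm <= 0]
    if zero_species and zero_offset is None:
        raise ValueError(
            "Gamma response requires strictly positive sensitivity values; "
            f"zero-valued species: {', '.join(sorted(zero_species))}. "
            "Pass zero_offset (e.g. 1e-6) to add a small constant to all responses."
        )
    offset = float(zero_offset) if zero_offset is not None else 0.0

    trait_map = {t.species: t for t in traits}
    species = [r.species for r in usable]
    frame = _predictor_frame(predictor, trait_map, species)
    frame["psm"] = [r.psm + offset for r in usable]
    frame["weight"] = [r.weight for r in usable]
    if predictor == "growth_form":
        frame = frame[frame[predictor] != "climber"]
    frame = frame.dropna(subset=[predictor, "psm", "weight"])
    if len(frame) < 3:
        raise ValueError(
            f"fewer than 3 usable species for predictor {predictor!r} (got {len(frame)})"
        )

    endog = frame["psm"].to_numpy()
    weights = frame["weight"].to_numpy()
    exog = _exog_for(predictor, frame)
    family = sm.families.Gamma(link=sm.families.links.Log())
    full = sm.GLM(endog, exog, family=family, var_weights=weights).fit()
    null = sm.GLM(
        endog, np.ones((len(endog), 1)), family=family, var_weights=weights
    ).fit()

    df_added = full.df_model
    # Scaled-deviance LRT: twice the weighted log-likelihood difference when
    # both deviances are evaluated at the full model's dispersion.
    lr = max(0.0, float((null.deviance - full.deviance) / full.scale))
    p_value = float(chi2.sf(lr, df_added)) if df_added > 0 else 1.0
    pseudo_r2 = float(np.clip(1.0 - full.deviance / null.deviance, 0.0, 1.0))
    return AssociationSummary(
        predictor=predictor,
        family="gamma_log",
        coefficients=dict(zip(exog.columns if hasattr(exog, "columns") else [], full.params)),
        pseudo_r2=pseudo_r2,
        lr_statistic=lr,
        p_value=p_value,
        n_used=int(len(frame)),
        weights_used=True,
    )


def fit_flowering_binomial_glm(
    records: Sequence[FloweringRecord],
    predictor: str,
) -> AssociationSummary:
    """Binomial logit GLM of flowering photoperiod sensitivity on one trait."""
    if predictor not in FLOWERING_PREDICTORS:
        raise ValueError(
            f"predictor must be one of {FLOWERING_PREDICTORS}, got {predictor!r}"
        )
    rows = []
    for r in records:
        if predictor == "seed_mass":
            value = np.log10(r.seed_mass_mg) if r.seed_mass_mg else None
        elif predictor == "latitude":
            value = abs(r.latitude_deg) if r.latitude_deg is not None else None
        else:
            value = r.lai
        rows.append({"sensitive": float(r.category.sensitive), predictor: value})
    frame = pd.DataFrame(rows).dropna()
    if frame.empty or frame["sensitive"].nunique() < 2:
        raise ValueError(
            "flowering response has a single class; the model is unidentifiable"
        )
    exog = sm.add_constant(frame[[predictor]].astype(float), has_constant="add")
    family = sm.families.Binomial()
    full = sm.GLM(frame["sensitive"].to_numpy(), exog, family=family).fit()
    null = sm.GLM(
        frame["sensitive"].to_numpy(), np.ones((len(frame), 1)), family=family
    ).fit()
    lr = max(0.0, 2.0 * float(full.llf - null.llf))
    p_value = float(chi2.sf(lr, full.df_model)) if full.df_model > 0 else 1.0
    pseudo_r2 = float(np.clip(1.0 - full.deviance / null.deviance, 0.0, 1.0))
    return AssociationSummary(
        predictor=predictor,
        family="binomial_logit",
        coefficients=dict(zip(exog.columns, full.params)),
        pseudo_r2=pseudo_r2,
        lr_statistic=lr,
        p_value=p_value,
        n_used=int(len(frame)),
        weights_used=False,
    )
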