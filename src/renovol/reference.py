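"""Normal kidney-volume reference models for dogs.

Packages the published regression equations relating CT kidney volume
(cm^3, both kidneys summed by the voxel-count method) to body weight (BW,
kg), body condition score (BCS, 1-9) and age (years) in normal dogs:

    volume = 3.701 * BW + 11.962                      (R^2 = 0.74)
    volume = 19.823 * BW/BCS + 10.705                 (R^2 = 0.72)
    volume = 3.740 * BW - 1.071 * BCS + 17.181        (R^2 = 0.74)
    volume = 3.697 * BW - 0.054 * age + 12.497        (R^2 = 0.74)

The BW/BCS index is body weight divided by body condition score, used to
normalize for body condition; the volume/BW index (volume divided by BW)
normalizes kidney volume across dog sizes. New reference models can be
fitted to cohort tables by ordinary least squares; fitted models carry R^2,
residual SD and coefficient p-values, and can report a 95% prediction
interval (an extension beyond the packaged equations, which ship with their
printed coefficients and R^2 only).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ParameterError

__all__ = [
    "DogRecord",
    "ReferenceModel",
    "packaged_models",
    "predict_reference_volume",
    "volume_bw_index",
    "fit_reference_model",
    "COVARIATES",
]

COVARIATES = ("BW", "BCS", "age", "BW_BCS")


@dataclass(frozen=True)
class DogRecord:
    """One dog's clinical record; ``measured_volume`` (cm^3) is optional."""

    id: str
    sex: str = "female"
    neutered: bool = True
    age: float | None = None
    bw: float | None = None
    bcs: int | None = None
    measured_volume: float | None = None

    def __post_init__(self):
        if self.bw is not None and self.bw <= 0:
            raise ParameterError("body weight must be positive")
        if self.bcs is not None and not (1 <= self.bcs <= 9):
            raise ParameterError("BCS must lie in [1, 9]")
        if self.age is not None and self.age < 0:
            raise ParameterError("age must be >= 0")

    def covariate(self, name: str) -> float:
        if name == "BW":
            value = self.bw
        elif name == "BCS":
            value = self.bcs
        elif name == "age":
            value = self.age
        elif name == "BW_BCS":
            value = None if (self.bw is None or self.bcs is None) else self.bw / self.bcs
        else:
            raise ParameterError(f"unknown covariate {name!r}")
        if value is None:
            raise ParameterError(f"record {self.id!r} is missing covariate {name!r}")
        return float(value)


@dataclass(frozen=True)
class ReferenceModel:
    """Linear model predicting total kidney volume in cm^3."""

    name: str
    covariates: tuple[str, ...]
    coefficients: dict  # covariate -> slope
    intercept: float
    r_squared: float | None = None
    residual_sd: float | None = None
    n: int | None = None
    p_values: dict | None = None

    def predict(self, record: DogRecord) -> float:
        value = self.intercept
        for cov in self.covariates:
            value += self.coefficients[cov] * record.covariate(cov)
        return float(value)

    def prediction_interval(self, record: DogRecord, level: float = 0.95):
        """Approximate prediction interval from the residual SD (fitted models only)."""
        if self.residual_sd is None:
            raise ParameterError(f"model {self.name!r} carries no residual SD")
        from scipy import stats

        center = self.predict(record)
        q = stats.norm.ppf(0.5 + level / 2)
        return (center - q * self.residual_sd, center + q * self.residual_sd)


def packaged_models() -> dict[str, ReferenceModel]:
    """The four published reference equations, at printed precision."""
    return {
        "bw": ReferenceModel(
            name="bw", covariates=("BW",), coefficients={"BW": 3.701},
            intercept=11.962, r_squared=0.74,
        ),
        "bw_bcs_index": ReferenceModel(
            name="bw_bcs_index", covariates=("BW_BCS",), coefficients={"BW_BCS": 19.823},
            intercept=10.705, r_squared=0.72,
        ),
        "bw_bcs": ReferenceModel(
            name="bw_bcs", covariates=("BW", "BCS"),
            coefficients={"BW": 3.740, "BCS": -1.071}, intercept=17.181, r_squared=0.74,
        ),
        "bw_age": ReferenceModel(
            name="bw_age", covariates=("BW", "age"),
            coefficients={"BW": 3.697, "age": -0.054}, intercept=12.497, r_squared=0.74,
        ),
    }


def predict_reference_volume(dog: DogRecord, model: ReferenceModel):
    """Expected volume for a dog; adds measured/expected when a measurement exists.

    Returns ``(expected_cm3, ratio_or_None)``.
    """
    expected = model.predict(dog)
    ratio = None
    if dog.measured_volume is not None:
        ratio = float(dog.measured_volume / expected)
    return expected, ratio


def volume_bw_index(volume_cm3: float, bw_kg: float) -> float:
    """Kidney volume normalized by body weight (cm^3 per kg)."""
    if bw_kg <= 0:
        raise ParameterError("body weight must be positive")
    return float(volume_cm3) / float(bw_kg)


def fit_reference_model(cohort: pd.DataFrame, covariates, volume_column: str = "true_volume",
                        name: str = "fitted") -> ReferenceModel:
    """Fit a new reference model by OLS on a cohort table.

    ``cohort`` needs columns BW, BCS, age (as applicable) and the volume
    column; ``BW_BCS`` is derived on the fly. Raises on missing values,
    insufficient sample size or a rank-deficient design.
    """
    covariates = tuple(covariates)
    unknown = set(covariates) - set(COVARIATES)
    if unknown:
        raise ParameterError(f"unknown covariates {sorted(unknown)}")
    df = cohort.copy()
    if "BW_BCS" in covariates and "BW_BCS" not in df.columns:
        df["BW_BCS"] = df["BW"] / df["BCS"]
    cols = list(covariates) + [volume_column]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParameterError(f"cohort table lacks columns {missing}")
    if df[cols].isna().any().any():
        raise ParameterError("cohort table contains missing values")
    n = len(df)
    if n <= len(covariates) + 1:
        raise ParameterError("need n > #covariates + 1 observations")
    X = sm.add_constant(df[list(covariates)].astype(float).to_numpy(), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ParameterError("rank-deficient design matrix (collinear covariates)")
    y = df[volume_column].astype(float).to_numpy()
    fit = sm.OLS(y, X).fit()
    resid_sd = float(np.sqrt(fit.scale))
    return ReferenceModel(
        name=name,
        covariates=covariates,
        coefficients={c: float(b) for c, b in zip(covariates, fit.params[1:])},
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        residual_sd=resid_sd,
        n=n,
        p_values={c: float(p) for c, p in zip(("intercept",) + covariates, fit.pvalues)},
    )
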