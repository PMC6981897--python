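"""The six published MET-prediction equations, encoded as immutable models.

Two model families were fitted on the 40-subject pooled dataset: two with
absolute heart rate (HR, HR+RHR) and four with percent heart-rate reserve
(HRR, HRR+RHR, HRR+RHR+SEX, HRR+RHR+HT).  Each carries its printed
unstandardized coefficients, standardized betas, and fit statistics
(r, R^2, SEE in METs).

Units matter: ``pct_hrr`` is in percentage points, ``resting_hr`` and ``hr``
in bpm, ``height`` in **cm** (a metres input silently corrupts the
prediction by two orders of magnitude in the height term), and ``sex`` is
coded male = 1, female = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

__all__ = ["PublishedEquation", "PUBLISHED_MODELS", "predict_mets", "mets_to_ee"]


@dataclass(frozen=True)
class PublishedEquation:
    """An affine MET predictor with its published fit statistics (read-only)."""

    model_id: str
    intercept: float
    coefficients: Mapping[str, float]
    standardized_betas: Mapping[str, float]
    r: float
    r2: float
    see: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", MappingProxyType(dict(self.coefficients)))
        object.__setattr__(
            self, "standardized_betas", MappingProxyType(dict(self.standardized_betas))
        )

    @property
    def predictors(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def predict(self, features: Mapping[str, float]) -> float:
        """intercept + sum(coef * feature); exact feature set required."""
        missing = set(self.coefficients) - set(features)
        extra = set(features) - set(self.coefficients)
        if missing:
            raise ValueError(f"model {self.model_id}: missing features {sorted(missing)}")
        if extra:
            raise ValueError(f"model {self.model_id}: unexpected features {sorted(extra)}")
        return self.intercept + sum(c * features[name] for name, c in self.coefficients.items())


def _eq(model_id, intercept, coefs, betas, r, r2, see) -> PublishedEquation:
    return PublishedEquation(model_id, intercept, coefs, betas, r, r2, see)


PUBLISHED_MODELS: Mapping[str, PublishedEquation] = MappingProxyType({
    "HR": _eq("HR", -4.030, {"hr": 0.080}, {"hr": 0.852}, 0.852, 0.725, 0.983),
    "HR+RHR": _eq(
        "HR+RHR",
        0.679,
        {"hr": 0.095, "resting_hr": -0.089},
        {"hr": 1.009, "resting_hr": -0.415},
        0.934, 0.873, 0.669,
    ),
    "HRR": _eq("HRR", 1.053, {"pct_hrr": 0.105}, {"pct_hrr": 0.938}, 0.938, 0.880, 0.648),
    "HRR+RHR": _eq(
        "HRR+RHR",
        2.123,
        {"pct_hrr": 0.105, "resting_hr": -0.016},
        {"pct_hrr": 0.942, "resting_hr": -0.074},
        0.941, 0.886, 0.634,
    ),
    "HRR+RHR+SEX": _eq(
        "HRR+RHR+SEX",
        2.046,
        {"pct_hrr": 0.106, "resting_hr": -0.016, "sex": 0.184},
        {"pct_hrr": 0.944, "resting_hr": -0.075, "sex": 0.049},
        0.942, 0.888, 0.628,
    ),
    "HRR+RHR+HT": _eq(
        "HRR+RHR+HT",
        -0.176,
        {"pct_hrr": 0.106, "resting_hr": -0.017, "height": 0.014},
        {"pct_hrr": 0.944, "resting_hr": -0.078, "height": 0.065},
        0.943, 0.890, 0.623,
    ),
})


def predict_mets(model_id: str, features: Mapping[str, float]) -> float:
    """Evaluate a published equation.

    Predictions are *not* clamped below at 1 MET: the published equations
    apply no clamp, and values slightly below 1 can occur at negative %HRR.
    """
    try:
        model = PUBLISHED_MODELS[model_id]
    except KeyError:
        raise ValueError(
            f"unknown model_id {model_id!r}; choose from {sorted(PUBLISHED_MODELS)}"
        ) from None
    return model.predict(features)


def mets_to_ee(mets: float, ee_rest_sitting: float) -> float:
    """Convert METs back to absolute energy expenditure, kcal/min."""
    if mets <= 0:
        raise ValueError("mets must be positive")
    if ee_rest_sitting <= 0:
        raise ValueError("ee_rest_sitting must be positive")
    return mets * ee_rest_sitting
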