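"""All-subsets regression with AIC selection for MET prediction.

Candidate models always contain exactly one heart-rate variable (absolute HR
or %HRR — the two are nearly collinear, r ~ 0.93, so they never co-occur)
plus any subset of the family's covariates.  Two families keep BMI apart from
its components:

* family A: covariates from {age, height, resting_hr, sex, weight} (BMI excluded)
* family B: covariates from {age, bmi, resting_hr, sex} (weight, height excluded)

Every candidate is fitted by OLS; the winner minimises AIC among candidates
that pass a sign-consistency screen (each coefficient's sign must agree with
the predictor's marginal correlation with METs) and a VIF screen.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CandidateSpec",
    "RegressionModel",
    "FAMILY_COVARIATES",
    "HR_VARIABLE_COLUMNS",
    "enumerate_candidates",
    "fit_ols",
    "sign_consistency_check",
    "select_best",
    "fit_family",
    "aic_least_squares",
    "aic_gaussian",
]

FAMILY_COVARIATES: Mapping[str, tuple[str, ...]] = {
    "A": ("age", "height", "resting_hr", "sex", "weight"),
    "B": ("age", "bmi", "resting_hr", "sex"),
}

HR_VARIABLE_COLUMNS: Mapping[str, str] = {"HR": "mean_hr", "HRR": "pct_hrr"}

# VIF >= this excludes a candidate outright; the report-only flag below marks
# even mild collinearity (the study observed all VIFs under 1.1).
VIF_EXCLUDE_DEFAULT = 10.0
VIF_FLAG_DEFAULT = 1.1


@dataclass(frozen=True)
class CandidateSpec:
    """One candidate model: a mandatory HR variable plus covariates."""

    hr_variable: str
    covariates: tuple[str, ...]
    family: str

    def __post_init__(self) -> None:
        if self.hr_variable not in HR_VARIABLE_COLUMNS:
            raise ValueError(f"hr_variable must be one of {sorted(HR_VARIABLE_COLUMNS)}")
        if self.family not in FAMILY_COVARIATES:
            raise ValueError(f"unknown family {self.family!r}")
        allowed = set(FAMILY_COVARIATES[self.family])
        bad = set(self.covariates) - allowed
        if bad:
            raise ValueError(f"covariates {sorted(bad)} not allowed in family {self.family}")
        object.__setattr__(self, "covariates", tuple(sorted(set(self.covariates))))

    @property
    def predictors(self) -> tuple[str, ...]:
        """Design-matrix columns: HR variable first, covariates alphabetical."""
        return (HR_VARIABLE_COLUMNS[self.hr_variable],) + self.covariates

    @property
    def label(self) -> str:
        return "+".join((self.hr_variable,) + self.covariates)


@dataclass(frozen=True)
class RegressionModel:
    """A fitted OLS candidate with the full published-table statistics."""

    spec: CandidateSpec
    intercept: float
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    p_values: dict[str, float]
    standardized_betas: dict[str, float]
    r: float
    r2: float
    adj_r2: float
    see: float
    aic: float
    vif: dict[str, float]
    n_obs: int
    rss: float
    sign_consistent: dict[str, bool]

    @property
    def n_predictors(self) -> int:
        return len(self.coefficients)

    @property
    def max_vif(self) -> float:
        return max(self.vif.values())

    @property
    def all_signs_consistent(self) -> bool:
        return all(self.sign_consistent.values())

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        X = data[list(self.coefficients)].to_numpy(float)
        beta = np.array(list(self.coefficients.values()))
        return self.intercept + X @ beta


def enumerate_candidates(hr_variable: str, family: str,
                         require_hr: bool = True) -> list[CandidateSpec]:
    """All 2^k covariate subsets of a family, each with the HR variable.

    With ``require_hr=False`` the covariate-only subsets (no HR variable) are
    not produced — the HR variable is structural to every published model —
    but the flag is accepted for forward compatibility and currently must be
    True.
    """
    if family not in FAMILY_COVARIATES:
        raise ValueError(f"unknown family {family!r}; choose from {sorted(FAMILY_COVARIATES)}")
    if hr_variable not in HR_VARIABLE_COLUMNS:
        raise ValueError(f"unknown hr_variable {hr_variable!r}")
    if not require_hr:
        raise NotImplementedError("HR-variable-free candidates are not part of the design")
    covs = FAMILY_COVARIATES[family]
    specs = []
    for r in range(len(covs) + 1):
        for subset in itertools.combinations(covs, r):
            specs.append(CandidateSpec(hr_variable=hr_variable, covariates=subset, family=family))
    return specs


def aic_least_squares(rss: float, n: int, k: int) -> float:
    """Gaussian profile-likelihood AIC: n ln(RSS/n) + 2 (k + 2).

    k counts slope parameters; +2 covers the intercept and the error
    variance.  Additive constants differ from the full-likelihood form but
    rankings are identical.
    """
    if rss <= 0:
        return -math.inf
    return n * math.log(rss / n) + 2 * (k + 2)


def aic_gaussian(rss: float, n: int, k: int) -> float:
    """Full Gaussian log-likelihood AIC (rank-equivalent alternative form)."""
    if rss <= 0:
        return -math.inf
    return n * math.log(2 * math.pi * rss / n) + n + 2 * (k + 2)


def _find_deficient_column(X: np.ndarray, names: Sequence[str]) -> str:
    full_rank = np.linalg.matrix_rank(X)
    for j, name in enumerate(names):
        if np.linalg.matrix_rank(np.delete(X, j + 1, axis=1)) == full_rank:
            return name
    return names[-1]


def _vif(X: np.ndarray, names: Sequence[str]) -> dict[str, float]:
    """VIF per predictor from auxiliary regressions x_j ~ other predictors."""
    if len(names) == 1:
        return {names[0]: 1.0}
    out = {}
    for j, name in enumerate(names):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(len(y)), others])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2_aux = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        out[name] = 1.0 / (1.0 - r2_aux) if r2_aux < 1.0 else math.inf
    return out


def fit_ols(observations: pd.DataFrame, spec: CandidateSpec) -> RegressionModel:
    """Fit one candidate by ordinary least squares on pooled observations.

    ``observations`` is the tidy subject-activity frame (one row per
    observation, predictor columns merged in, ``mets`` as the response).
    Returns the model with coefficients, standard errors, p-values,
    standardized betas (coef x SD(x)/SD(y)), r = sqrt(R^2), adjusted R^2,
    SEE = sqrt(RSS/(n-k-1)), AIC and per-predictor VIF.
    """
    names = list(spec.predictors)
    missing = [c for c in names + ["mets"] if c not in observations.columns]
    if missing:
        raise ValueError(f"observations lack columns {missing}")
    df = observations.dropna(subset=names + ["mets"])
    y = df["mets"].to_numpy(float)
    X = df[names].to_numpy(float)
    n, k = X.shape
    if n < k + 2:  # at least one residual degree of freedom for the SEE
        raise ValueError(f"need at least {k + 2} observations to fit {spec.label}; got {n}")
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < k + 1:
        bad = _find_deficient_column(design, names)
        raise ValueError(f"design matrix is rank deficient (predictor {bad!r})")

    res = sm.OLS(y, design).fit()
    coefs = dict(zip(names, res.params[1:]))
    rss = float(res.ssr)
    see = math.sqrt(rss / (n - k - 1))
    sd_y = float(np.std(y, ddof=1))
    std_betas = {
        name: coefs[name] * float(np.std(X[:, j], ddof=1)) / sd_y
        for j, name in enumerate(names)
    }
    r2 = float(res.rsquared)

    marginal = {}
    for j, name in enumerate(names):
        x = X[:, j]
        if np.std(x) == 0 or np.std(y) == 0:
            marginal[name] = 0.0
        else:
            marginal[name] = float(np.corrcoef(x, y)[0, 1])
    consistent = {
        name: coefs[name] == 0 or marginal[name] == 0
        or math.copysign(1, coefs[name]) == math.copysign(1, marginal[name])
        for name in names
    }

    return RegressionModel(
        spec=spec,
        intercept=float(res.params[0]),
        coefficients={k_: float(v) for k_, v in coefs.items()},
        standard_errors=dict(zip(names, map(float, res.bse[1:]))),
        p_values=dict(zip(names, map(float, res.pvalues[1:]))),
        standardized_betas=std_betas,
        r=math.sqrt(max(r2, 0.0)),
        r2=r2,
        adj_r2=float(res.rsquared_adj),
        see=see,
        aic=aic_least_squares(rss, n, k),
        vif=_vif(X, names),
        n_obs=n,
        rss=rss,
        sign_consistent=consistent,
    )


def sign_consistency_check(model: RegressionModel,
                           observations: pd.DataFrame) -> dict[str, bool]:
    """Per-predictor screen: coefficient sign must match the predictor's
    marginal Pearson correlation with METs (zero coefficient or zero
    correlation passes)."""
    out = {}
    y = observations["mets"].to_numpy(float)
    for name, coef in model.coefficients.items():
        x = observations[name].to_numpy(float)
        r = 0.0 if np.std(x) == 0 or np.std(y) == 0 else float(np.corrcoef(x, y)[0, 1])
        out[name] = coef == 0 or r == 0 or math.copysign(1, coef) == math.copysign(1, r)
    return out


def select_best(models: Sequence[RegressionModel],
                vif_exclude: float = VIF_EXCLUDE_DEFAULT) -> RegressionModel:
    """Minimum-AIC winner among screened candidates.

    Candidates failing sign consistency or with any VIF >= ``vif_exclude``
    are dropped first.  Ties on AIC break toward fewer predictors, then
    lexicographically by predictor names.  Zero-RSS candidates (AIC -inf)
    resolve the same way: fewest predictors among the perfect fits.
    """
    if not models:
        raise ValueError("no candidate models supplied")
    screened = [m for m in models
                if m.all_signs_consistent and m.max_vif < vif_exclude]
    if not screened:
        diag = "; ".join(
            f"{m.spec.label}: signs_ok={m.all_signs_consistent}, max_vif={m.max_vif:.2f}"
            for m in models
        )
        raise ValueError(f"all candidates excluded by screening ({diag})")
    return min(screened, key=lambda m: (m.aic, m.n_predictors, m.spec.predictors))


def fit_family(observations: pd.DataFrame, hr_variable: str, family: str) -> list[RegressionModel]:
    """Fit every candidate of one (HR variable, family) run."""
    return [fit_ols(observations, spec)
            for spec in enumerate_candidates(hr_variable, family)]


def models_to_frame(models: Iterable[RegressionModel],
                    selected: RegressionModel | None = None) -> pd.DataFrame:
    """One row per candidate with all fit statistics, for CSV export."""
    rows = []
    for m in models:
        rows.append({
            "model": m.spec.label,
            "family": m.spec.family,
            "n_predictors": m.n_predictors,
            "n_obs": m.n_obs,
            "intercept": m.intercept,
            "r": m.r,
            "r2": m.r2,
            "adj_r2": m.adj_r2,
            "see": m.see,
            "aic": m.aic,
            "max_vif": m.max_vif,
            "vif_flag_1.1": m.max_vif >= VIF_FLAG_DEFAULT,
            "signs_consistent": m.all_signs_consistent,
            "selected": selected is not None and m.spec == selected.spec,
            "coefficients": ";".join(f"{k}={v:.6g}" for k, v in m.coefficients.items()),
            "standardized_betas": ";".join(
                f"{k}={v:.4g}" for k, v in m.standardized_betas.items()),
        })
    return pd.DataFrame(rows)
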