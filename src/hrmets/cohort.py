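"""Synthetic cohort generator.

Emulates the study dataset the downstream analyses assume: 40 adults (20 male,
20 female) stratified over four 10-year age decades, each performing 20 daily
activities (5 exercise, 15 household/daily) while heart rate and expired gas
are recorded.  Subjects are drawn from per-cell (sex x decade) Gaussians
matching the published anthropometric means/SDs; each subject-activity
observation draws a %HRR from the activity's Gaussian, back-computes the
absolute heart rate from the subject's own resting HR and predicted HRmax, and
sets METs from a configurable linear truth (default: the published
three-predictor equation %HRR + resting HR + height, residual SD equal to its
published SEE of 0.623 METs).

Every output is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .physiology import hr_from_percent_hrr, predict_hrmax
from .preprocessing import RRIntervalSeries

__all__ = [
    "SubjectProfile",
    "ActivityCatalogEntry",
    "TrueModelSpec",
    "CELL_STATS",
    "ACTIVITY_CATALOG",
    "DEFAULT_TRUTH",
    "SINGLE_PREDICTOR_TRUTH",
    "generate_subjects",
    "generate_observations",
    "generate_rr_series",
    "subjects_to_frame",
    "observations_to_frame",
    "population_predictor_moments",
    "population_r2",
]

DECADES = (20, 30, 40, 50)

# %HRR draws are truncated below at -5: heart rates meaningfully under resting
# do not occur in seated/standing task data, but mildly negative %HRR does.
PCT_HRR_FLOOR = -5.0


@dataclass(frozen=True)
class SubjectProfile:
    """Anthropometrics and resting HR for one participant.

    sex is coded male = 1, female = 0.  BMI (kg/m^2) and age-predicted HRmax
    (Tanaka, 208 - 0.7 age) are derived, never stored independently.
    """

    subject_id: str
    age: float
    sex: int
    height: float
    weight: float
    resting_hr: float

    def __post_init__(self) -> None:
        if self.sex not in (0, 1):
            raise ValueError("sex must be coded 1 (male) or 0 (female)")
        if self.resting_hr >= self.predicted_hrmax:
            raise ValueError("resting_hr must be below predicted HRmax")

    @property
    def bmi(self) -> float:
        return self.weight / (self.height / 100.0) ** 2

    @property
    def predicted_hrmax(self) -> float:
        return predict_hrmax(self.age)

    @property
    def decade(self) -> int:
        return int(self.age // 10) * 10


@dataclass(frozen=True)
class ActivityCatalogEntry:
    """Target distribution for one activity.

    n_observed is the number of subjects with usable data for the activity
    (the published per-activity N; missing data came from sensor failures).
    outlier_k is the SD multiplier for epoch cleaning: 4 for radio
    calisthenics (a jumpy whole-body routine), 3 for everything else.
    """

    activity_name: str
    classification: Literal["exercise", "household/daily"]
    n_observed: int
    minutes_activity: float
    minutes_measured: float
    target_mets_mean: float
    target_mets_sd: float
    target_pct_hrr_mean: float
    target_pct_hrr_sd: float
    outlier_k: int = 3

    def __post_init__(self) -> None:
        if self.outlier_k not in (3, 4):
            raise ValueError("outlier_k must be 3 or 4")


@dataclass(frozen=True)
class TrueModelSpec:
    """Generating truth: METs = affine(predictors) + N(0, residual_sd)."""

    intercept: float
    coef_pct_hrr: float
    coef_resting_hr: float = 0.0
    coef_height: float = 0.0
    coef_sex: float = 0.0
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")

    def linear_predictor(
        self,
        pct_hrr: np.ndarray,
        resting_hr: np.ndarray,
        height: np.ndarray,
        sex: np.ndarray,
    ) -> np.ndarray:
        return (
            self.intercept
            + self.coef_pct_hrr * np.asarray(pct_hrr)
            + self.coef_resting_hr * np.asarray(resting_hr)
            + self.coef_height * np.asarray(height)
            + self.coef_sex * np.asarray(sex)
        )


# Published three-predictor equation (%HRR, resting HR, height), residual SD =
# its SEE.  Sex is absent from that model, so its effect defaults to 0.
DEFAULT_TRUTH = TrueModelSpec(
    intercept=-0.176,
    coef_pct_hrr=0.106,
    coef_resting_hr=-0.017,
    coef_height=0.014,
    coef_sex=0.0,
    residual_sd=0.623,
)

# Published single-predictor (%HRR only) equation at its SEE.
SINGLE_PREDICTOR_TRUTH = TrueModelSpec(
    intercept=1.053, coef_pct_hrr=0.105, residual_sd=0.648
)


# Per-cell anthropometric targets, mean and SD by (sex, decade):
# (age yr, height cm, weight kg, resting HR bpm).
CELL_STATS: dict[tuple[int, int], dict[str, tuple[float, float]]] = {
    (1, 20): {"age": (26.2, 3.1), "height": (169.0, 7.2), "weight": (66.3, 10.6), "resting_hr": (67.0, 5.9)},
    (1, 30): {"age": (37.3, 2.1), "height": (171.2, 3.8), "weight": (65.1, 18.6), "resting_hr": (61.4, 5.4)},
    (1, 40): {"age": (43.2, 3.9), "height": (173.1, 6.2), "weight": (73.1, 12.1), "resting_hr": (72.8, 6.1)},
    (1, 50): {"age": (52.2, 1.8), "height": (171.5, 2.3), "weight": (68.4, 13.1), "resting_hr": (67.3, 5.9)},
    (0, 20): {"age": (23.0, 2.3), "height": (157.3, 4.5), "weight": (49.1, 5.1), "resting_hr": (64.0, 12.8)},
    (0, 30): {"age": (33.0, 3.5), "height": (165.3, 10.6), "weight": (62.2, 14.1), "resting_hr": (70.8, 5.8)},
    (0, 40): {"age": (43.0, 4.2), "height": (155.9, 5.7), "weight": (52.8, 17.1), "resting_hr": (66.8, 13.7)},
    (0, 50): {"age": (52.8, 1.3), "height": (158.1, 2.2), "weight": (59.4, 8.0), "resting_hr": (67.6, 12.1)},
}


def _entry(name, cls, n, mins, meas, mets, hrr, k=3):
    return ActivityCatalogEntry(
        activity_name=name,
        classification=cls,
        n_observed=n,
        minutes_activity=mins,
        minutes_measured=meas,
        target_mets_mean=mets[0],
        target_mets_sd=mets[1],
        target_pct_hrr_mean=hrr[0],
        target_pct_hrr_sd=hrr[1],
        outlier_k=k,
    )


# The 20-activity catalog: per-activity usable N, minutes performed
# (measured), measured METs mean+-SD and %HRR mean+-SD.  N sums to 673.
ACTIVITY_CATALOG: tuple[ActivityCatalogEntry, ...] = (
    _entry("radio calisthenics", "exercise", 25, 8, 3.0, (3.1, 0.4), (21.6, 5.3), k=4),
    _entry("walking (55 m/min)", "exercise", 33, 5, 2.0, (3.3, 0.5), (21.8, 8.0)),
    _entry("walking (70 m/min)", "exercise", 29, 5, 2.0, (3.7, 0.5), (26.0, 8.0)),
    _entry("walking (100 m/min)", "exercise", 30, 5, 2.0, (5.1, 0.9), (36.5, 10.8)),
    _entry("jogging (130 m/min)", "exercise", 21, 4, 1.0, (9.5, 1.5), (73.4, 12.6)),
    _entry("operating a mobile phone", "household/daily", 36, 7, 5.0, (1.1, 0.1), (1.1, 3.7)),
    _entry("PC work", "household/daily", 38, 7, 5.0, (1.1, 0.1), (2.3, 3.4)),
    _entry("document arrangement while sitting", "household/daily", 39, 5, 3.0, (1.5, 0.3), (6.5, 3.4)),
    _entry("stretch exercising", "household/daily", 30, 12, 5.0, (2.1, 0.3), (8.0, 4.5)),
    _entry("document arrangement while standing", "household/daily", 40, 5, 3.0, (2.1, 0.4), (10.2, 4.6)),
    _entry("washing dishes", "household/daily", 37, 5, 3.0, (2.1, 0.4), (11.7, 5.5)),
    _entry("hanging and bringing in clothes", "household/daily", 38, 5, 2.0, (2.4, 0.4), (14.5, 5.7)),
    _entry("repeated sitting and standing", "household/daily", 38, 4, 2.0, (2.5, 0.3), (12.9, 5.1)),
    _entry("wiping tables", "household/daily", 39, 5, 2.0, (2.6, 0.5), (15.0, 5.8)),
    _entry("descending stairs", "household/daily", 36, 5, 1.5, (2.7, 0.4), (17.8, 6.3)),
    _entry("vacuuming the room", "household/daily", 35, 3, 2.0, (2.9, 0.6), (17.7, 6.4)),
    _entry("moving load (5 kg bag of rice)", "household/daily", 37, 5, 2.0, (3.7, 0.6), (25.4, 8.2)),
    _entry("walking with load (5 kg for 55 m/min)", "household/daily", 33, 5, 2.0, (4.0, 0.5), (29.7, 8.3)),
    _entry("walking with load (3 kg for 70 m/min)", "household/daily", 29, 5, 2.0, (4.2, 0.6), (30.1, 9.5)),
    _entry("ascending stairs", "household/daily", 30, 5, 1.0, (7.4, 0.9), (54.0, 7.7)),
)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float,
               size: int | None = None) -> np.ndarray | float:
    if sd == 0:
        return np.full(size, mean) if size is not None else mean
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _cell_counts(rng: np.random.Generator, lo: int, hi: int) -> list[int]:
    """Counts for the 4 decade cells of one sex, each in [lo, hi], summing to
    the range's natural per-sex total (20 for the default 4-6)."""
    target = round(4 * (lo + hi) / 2)
    counts = rng.integers(lo, hi + 1, size=4)
    while counts.sum() != target:
        i = rng.integers(0, 4)
        if counts.sum() > target and counts[i] > lo:
            counts[i] -= 1
        elif counts.sum() < target and counts[i] < hi:
            counts[i] += 1
    return counts.tolist()


def generate_subjects(
    n_per_cell_range: tuple[int, int] = (4, 6),
    seed: int | np.random.Generator = 0,
) -> list[SubjectProfile]:
    """Draw a stratified cohort: sex x decade cells of 4-6 subjects each.

    Anthropometrics and resting HR come from per-cell Gaussians truncated at
    +-3 SD (ages additionally clipped to the decade).  With the default range
    the cohort has exactly 20 male and 20 female subjects.
    """
    lo, hi = n_per_cell_range
    if not (1 <= lo <= hi <= 20):
        raise ValueError(f"n_per_cell_range {n_per_cell_range} must satisfy 1 <= lo <= hi <= 20")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    subjects: list[SubjectProfile] = []
    idx = 1
    for sex in (1, 0):
        counts = _cell_counts(rng, lo, hi)
        for decade, n in zip(DECADES, counts):
            cell = CELL_STATS[(sex, decade)]
            for _ in range(n):
                am, asd = cell["age"]
                age = float(_truncnorm(rng, am, asd, max(decade, am - 3 * asd),
                                       min(decade + 10 - 1e-9, am + 3 * asd)))
                hm, hsd = cell["height"]
                height = float(_truncnorm(rng, hm, hsd, hm - 3 * hsd, hm + 3 * hsd))
                wm, wsd = cell["weight"]
                weight = float(_truncnorm(rng, wm, wsd, max(wm - 3 * wsd, 35.0), wm + 3 * wsd))
                rm, rsd = cell["resting_hr"]
                resting = float(_truncnorm(rng, rm, rsd, rm - 3 * rsd, rm + 3 * rsd))
                subjects.append(SubjectProfile(
                    subject_id=f"S{idx:02d}", age=age, sex=sex,
                    height=height, weight=weight, resting_hr=resting,
                ))
                idx += 1
    return subjects


def population_predictor_moments(
    catalog: Sequence[ActivityCatalogEntry] = ACTIVITY_CATALOG,
    cell_stats: dict | None = None,
    weighting: Literal["table2", "uniform"] = "table2",
) -> dict[str, tuple[float, float]]:
    """Analytic population mean/variance of each generator predictor.

    %HRR moments come from the mixture of activity Gaussians — weighted by
    the published per-activity usable N ("table2") or equally ("uniform",
    matching a no-missingness grid); resting HR and height from the
    equal-weight mixture of the sex x decade cells; sex is Bernoulli(1/2).
    Predictors are treated as independent (the generator draws them
    independently within sex).
    """
    cells = cell_stats or CELL_STATS
    if weighting == "table2":
        w = np.array([e.n_observed for e in catalog], dtype=float)
    elif weighting == "uniform":
        w = np.ones(len(catalog))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    w /= w.sum()
    mu = np.array([e.target_pct_hrr_mean for e in catalog])
    sd = np.array([e.target_pct_hrr_sd for e in catalog])
    m_hrr = float(w @ mu)
    v_hrr = float(w @ (sd**2 + mu**2) - m_hrr**2)

    out = {"pct_hrr": (m_hrr, v_hrr)}
    for var in ("resting_hr", "height"):
        means = np.array([cells[k][var][0] for k in cells])
        sds = np.array([cells[k][var][1] for k in cells])
        m = float(means.mean())
        v = float(np.mean(sds**2 + means**2) - m**2)
        out[var] = (m, v)
    out["sex"] = (0.5, 0.25)
    return out


def population_r2(
    truth: TrueModelSpec,
    catalog: Sequence[ActivityCatalogEntry] = ACTIVITY_CATALOG,
    weighting: Literal["table2", "uniform"] = "table2",
) -> float:
    """Analytic population R^2 of the generating model: Var(LP)/(Var(LP)+sd^2)."""
    mom = population_predictor_moments(catalog, weighting=weighting)
    coefs = {
        "pct_hrr": truth.coef_pct_hrr,
        "resting_hr": truth.coef_resting_hr,
        "height": truth.coef_height,
        "sex": truth.coef_sex,
    }
    var_lp = sum(c**2 * mom[name][1] for name, c in coefs.items())
    if truth.residual_sd == 0:
        return 1.0
    return var_lp / (var_lp + truth.residual_sd**2)


def generate_observations(
    subjects: Sequence[SubjectProfile],
    catalog: Sequence[ActivityCatalogEntry] = ACTIVITY_CATALOG,
    truth: TrueModelSpec = DEFAULT_TRUTH,
    missing_pattern: Literal["none", "table2"] = "table2",
    seed: int | np.random.Generator = 0,
    target_r2: float | None = None,
) -> pd.DataFrame:
    """Simulate the pooled subject-activity MET observations.

    For each activity, the retained subjects' %HRR values are drawn from the
    activity's Gaussian (truncated below at -5%), the absolute heart rate is
    back-computed from each subject's own resting HR and predicted HRmax, and
    METs = truth linear predictor + N(0, residual_sd).  The residual is a
    plain Gaussian — untruncated, so coefficient and SEE recovery stay
    unbiased; at the default residual SD a few observations per thousand in
    the lowest-intensity activities come out non-positive, and percent-error
    summaries exclude those (see :func:`hrmets.validation.activity_report`).

    missing_pattern
        "none"   — every subject contributes every activity.
        "table2" — per-activity retention equals the published usable-N
                   column (673 pooled observations for a 40-subject cohort);
                   dropped subjects are chosen uniformly at random, since the
                   study does not identify which recordings failed.
    target_r2
        Calibrated mode: rescales the spread of the linear predictor around
        its analytic population mean so the expected R^2 equals this target
        (used for fit-statistic recovery checks where the real predictor
        covariances are unknown).

    Returns a tidy DataFrame with one row per retained subject-activity pair:
    subject_id, activity, mean_hr, pct_hrr, mets plus the subject's predictor
    columns (resting_hr, height, sex, age, weight, bmi).
    """
    if len(subjects) == 0:
        raise ValueError("subjects must be non-empty")
    if len(catalog) == 0:
        raise ValueError("catalog must be non-empty")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    scale, lp_mean = 1.0, 0.0
    if target_r2 is not None:
        if not (0.0 < target_r2 < 1.0):
            raise ValueError("target_r2 must be in (0, 1)")
        if truth.residual_sd == 0:
            raise ValueError("target_r2 requires residual_sd > 0")
        mom = population_predictor_moments(
            catalog, weighting="table2" if missing_pattern == "table2" else "uniform")
        coefs = {"pct_hrr": truth.coef_pct_hrr, "resting_hr": truth.coef_resting_hr,
                 "height": truth.coef_height, "sex": truth.coef_sex}
        var_lp = sum(c**2 * mom[n][1] for n, c in coefs.items())
        lp_mean = truth.intercept + sum(c * mom[n][0] for n, c in coefs.items())
        want = truth.residual_sd**2 * target_r2 / (1.0 - target_r2)
        scale = float(np.sqrt(want / var_lp))

    if missing_pattern not in ("none", "table2"):
        raise ValueError(f"unknown missing_pattern {missing_pattern!r}")

    sub = subjects_to_frame(subjects)
    parts = []
    for entry in catalog:
        keep = np.arange(len(subjects))
        if missing_pattern == "table2":
            n_keep = min(entry.n_observed, len(subjects))
            keep = np.sort(rng.choice(len(subjects), size=n_keep, replace=False))
        block = sub.iloc[keep].reset_index(drop=True)
        pct = np.asarray(_truncnorm(rng, entry.target_pct_hrr_mean,
                                    entry.target_pct_hrr_sd, PCT_HRR_FLOOR, np.inf,
                                    size=len(block)))
        hr = block["resting_hr"].to_numpy() + pct / 100.0 * (
            block["predicted_hrmax"].to_numpy() - block["resting_hr"].to_numpy())
        lp = truth.linear_predictor(pct, block["resting_hr"].to_numpy(),
                                    block["height"].to_numpy(), block["sex"].to_numpy())
        if target_r2 is not None:
            lp = lp_mean + scale * (lp - lp_mean)
        mets = lp + rng.normal(0.0, truth.residual_sd, size=len(block))
        parts.append(pd.DataFrame({
            "subject_id": block["subject_id"], "activity": entry.activity_name,
            "mean_hr": hr, "pct_hrr": pct, "mets": mets,
            "resting_hr": block["resting_hr"], "height": block["height"],
            "sex": block["sex"], "age": block["age"],
            "weight": block["weight"], "bmi": block["bmi"],
        }))
    return pd.concat(parts, ignore_index=True)


def generate_rr_series(
    subject: SubjectProfile,
    target_hr: float,
    duration: float,
    artifact_rate: float = 0.0,
    jitter_cv: float = 0.03,
    seed: int | np.random.Generator = 0,
    activity_name: str = "synthetic",
) -> RRIntervalSeries:
    """Emulate a beat-to-beat R-R recording around a target heart rate.

    Intervals fluctuate around 60/target_hr s with multiplicative Gaussian
    jitter (coefficient of variation ``jitter_cv``).  Artifacts — the kinds a
    patch ECG sensor produces — are inserted per beat at ``artifact_rate``:
    half are dropouts (a missed QRS doubles the interval), half are spurious
    detections (a split interval).  Beats accumulate until they span
    ``duration`` seconds.
    """
    if not (30.0 < target_hr < 220.0):
        raise ValueError("target_hr must lie in (30, 220) bpm")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not (0.0 <= artifact_rate <= 0.2):
        raise ValueError("artifact_rate must lie in [0, 0.2]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    base = 60.0 / target_hr
    n_est = int(np.ceil(duration / base * 1.5)) + 10
    rr = base * (1.0 + jitter_cv * rng.standard_normal(n_est))
    rr = np.clip(rr, 0.25 * base, 4.0 * base)
    if artifact_rate > 0:
        hit = rng.random(n_est) < artifact_rate
        kind = rng.random(n_est) < 0.5
        rr = np.where(hit & kind, rr * 2.2, rr)    # dropout: missed beat
        rr = np.where(hit & ~kind, rr * 0.35, rr)  # spike: spurious detection
    t = np.cumsum(rr)
    while t[-1] < duration:  # artifacts can shorten the span; top up
        extra = base * (1.0 + jitter_cv * rng.standard_normal(16))
        rr = np.concatenate([rr, np.clip(extra, 0.25 * base, 4.0 * base)])
        t = np.cumsum(rr)
    n = int(np.searchsorted(t, duration)) + 1
    n = min(n, len(rr))
    return RRIntervalSeries(
        subject_id=subject.subject_id,
        activity_name=activity_name,
        timestamps=t[:n],
        rr=rr[:n],
    )


def subjects_to_frame(subjects: Sequence[SubjectProfile]) -> pd.DataFrame:
    """Cohort table with derived columns, suitable for CSV export."""
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "age": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
            "height": [s.height for s in subjects],
            "weight": [s.weight for s in subjects],
            "bmi": [s.bmi for s in subjects],
            "resting_hr": [s.resting_hr for s in subjects],
            "predicted_hrmax": [s.predicted_hrmax for s in subjects],
        }
    )


def observations_to_frame(observations: pd.DataFrame) -> pd.DataFrame:
    """Identity passthrough kept for symmetry with subjects_to_frame."""
    return observations.copy()
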