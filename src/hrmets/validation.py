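"""Subject-level validation: leave-one-subject-out, repeated hold-out,
mean percent error / RMSE reports, and modified Bland-Altman agreement.

Cross-validation operates on *subjects*, never single observations: all 20
activities of the held-out subject leave the development set together, which
is what protects the error estimates from within-subject leakage (each
subject's resting HR, height and sex repeat across their activities).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import CandidateSpec

__all__ = [
    "ValidationReport",
    "BlandAltmanResult",
    "HoldoutReport",
    "loso_predict",
    "mpe",
    "rmse",
    "activity_report",
    "bland_altman",
    "holdout_rmse",
]

TOTAL_LABEL = "Total activities"


def _ols_fit_predict(train: pd.DataFrame, test: pd.DataFrame,
                     predictors: Sequence[str]) -> np.ndarray:
    """Plain least-squares fit on train, affine prediction on test."""
    Xtr = np.column_stack([np.ones(len(train)), train[list(predictors)].to_numpy(float)])
    beta, *_ = np.linalg.lstsq(Xtr, train["mets"].to_numpy(float), rcond=None)
    Xte = np.column_stack([np.ones(len(test)), test[list(predictors)].to_numpy(float)])
    return Xte @ beta


def loso_predict(observations: pd.DataFrame, spec: CandidateSpec) -> pd.DataFrame:
    """Leave-one-subject-out predictions.

    For each subject, the candidate is refitted on every other subject's
    observations and applied to the held-out subject's.  Returns a frame with
    one row per observation: subject_id, activity, measured, estimated.
    """
    subjects = observations["subject_id"].unique()
    if len(subjects) < 3:
        raise ValueError("leave-one-subject-out needs at least 3 subjects")
    parts = []
    for sid in subjects:
        test = observations[observations["subject_id"] == sid]
        train = observations[observations["subject_id"] != sid]
        try:
            est = _ols_fit_predict(train, test, spec.predictors)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"fit failed on fold holding out {sid!r}: {exc}") from exc
        parts.append(pd.DataFrame({
            "subject_id": test["subject_id"].to_numpy(),
            "activity": test["activity"].to_numpy(),
            "measured": test["mets"].to_numpy(float),
            "estimated": est,
        }))
    return pd.concat(parts, ignore_index=True)


def mpe(measured, estimated):
    """Mean percent error: (estimated - measured) / measured x 100.

    Elementwise on arrays; scalar on scalars.  Requires measured > 0.
    """
    m = np.asarray(measured, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if np.any(m <= 0):
        raise ValueError("measured METs must be positive")
    out = (e - m) / m * 100.0
    return float(out) if out.ndim == 0 else out


def rmse(measured, estimated) -> float:
    """Root mean square error, METs."""
    m = np.asarray(measured, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if m.size == 0:
        raise ValueError("rmse of an empty set is undefined")
    return float(np.sqrt(np.mean((e - m) ** 2)))


@dataclass(frozen=True)
class ValidationReport:
    """Per-activity and total MPE / RMSE / Wilcoxon table for one model."""

    model_label: str
    per_activity: pd.DataFrame  # activity, n, mpe_mean, mpe_sd, rmse, wilcoxon_p, flag
    total: pd.Series

    def to_frame(self) -> pd.DataFrame:
        total_row = self.total.to_frame().T
        total_row.insert(0, "activity", TOTAL_LABEL)
        out = pd.concat([self.per_activity, total_row], ignore_index=True)
        return out.astype({c: float for c in ("mpe_mean", "mpe_sd", "rmse", "wilcoxon_p")}
                          | {"n": int})


def _wilcoxon_p(measured: np.ndarray, estimated: np.ndarray) -> tuple[float, str]:
    if len(measured) < 2:
        return math.nan, "too_few_pairs"
    d = estimated - measured
    if np.allclose(d, 0):
        return math.nan, "degenerate_zero_differences"
    # exact null distribution for small n, normal approximation above 25
    method = "exact" if np.count_nonzero(d) <= 25 else "approx"
    p = float(stats.wilcoxon(measured, estimated, method=method).pvalue)
    return p, ""


def activity_report(pairs: pd.DataFrame, model_label: str = "") -> ValidationReport:
    """Summarise (measured, estimated) pairs per activity and overall.

    MPE is aggregated as mean and SD over the pooled leave-out predictions of
    each activity; the two-sided Wilcoxon signed-rank test compares measured
    with estimated METs per activity (omitted, with a flag, for degenerate
    groups).  Percent error is undefined for a non-positive measured value
    (possible only for rare synthetic draws, never for calorimetry data):
    such pairs are excluded from the MPE columns, flagged, and retained for
    RMSE and the signed-rank test.
    """

    def _summary(grp: pd.DataFrame) -> dict:
        m = grp["measured"].to_numpy(float)
        e = grp["estimated"].to_numpy(float)
        pos = m > 0
        p, flag = _wilcoxon_p(m, e)
        if not pos.all():
            flag = (flag + ";" if flag else "") + f"mpe_excludes_{int((~pos).sum())}_nonpositive"
        errs = mpe(m[pos], e[pos]) if pos.any() else np.array([])
        return {
            "n": len(grp),
            "mpe_mean": float(np.mean(errs)) if errs.size else math.nan,
            "mpe_sd": float(np.std(errs, ddof=1)) if errs.size > 1 else 0.0,
            "rmse": rmse(m, e),
            "wilcoxon_p": p, "flag": flag,
        }

    rows = [{"activity": activity, **_summary(grp)}
            for activity, grp in pairs.groupby("activity", sort=False)]
    per_activity = pd.DataFrame(rows)
    total = pd.Series(_summary(pairs))
    return ValidationReport(model_label=model_label, per_activity=per_activity, total=total)


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement summary: bias, 95% limits of agreement, proportional trend.

    loa_half_width = 1.96 x SD of the differences; limits of agreement are
    bias +- loa_half_width.  trend_r correlates the differences with the
    magnitude axis (modified form: measured METs; classic form: pair means).
    """

    bias: float
    loa_half_width: float
    trend_r: float
    trend_p: float
    n: int
    axis: str
    flag: str = ""

    @property
    def loa(self) -> tuple[float, float]:
        return (self.bias - self.loa_half_width, self.bias + self.loa_half_width)


def bland_altman(pairs: pd.DataFrame,
                 axis: Literal["measured", "mean"] = "measured") -> BlandAltmanResult:
    """Modified Bland-Altman analysis of estimated vs measured METs.

    Differences are estimated - measured.  The modified form plots them
    against the reference method (measured METs) rather than the pair mean,
    appropriate because indirect calorimetry is the criterion measure.
    """
    if len(pairs) < 3:
        raise ValueError("Bland-Altman needs at least 3 pairs")
    m = pairs["measured"].to_numpy(float)
    e = pairs["estimated"].to_numpy(float)
    d = e - m
    x = m if axis == "measured" else (m + e) / 2.0
    bias = float(np.mean(d))
    half = 1.96 * float(np.std(d, ddof=1))
    if np.std(x) == 0:
        return BlandAltmanResult(bias, half, math.nan, math.nan, len(d), axis,
                                 flag="zero_variance_axis")
    if np.std(d) == 0:
        return BlandAltmanResult(bias, half, math.nan, math.nan, len(d), axis,
                                 flag="zero_variance_differences")
    r, p = stats.pearsonr(x, d)
    return BlandAltmanResult(bias, half, float(r), float(p), len(d), axis)


@dataclass(frozen=True)
class HoldoutReport:
    """Average per-activity RMSE over repeated 2:1 subject-level splits."""

    per_activity_rmse: pd.Series
    total_rmse: float
    n_reps: int
    split_ratio: str
    seed: int
    n_dev_subjects: int = 0
    n_val_subjects: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = self.per_activity_rmse.rename("rmse").reset_index()
        total = pd.DataFrame({"activity": [TOTAL_LABEL], "rmse": [self.total_rmse]})
        return pd.concat([df, total], ignore_index=True)


def holdout_rmse(observations: pd.DataFrame, spec: CandidateSpec,
                 n_reps: int = 10_000, seed: int = 0) -> HoldoutReport:
    """Repeated hold-out: split subjects 2:1, fit on the development group,
    score per-activity RMSE on the validation group; average over repetitions.

    The development group holds round(2n/3) subjects.  An activity absent
    from a repetition's validation split contributes nothing to that
    repetition's average for the activity (the mean is over contributing
    repetitions only).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    subjects = np.array(sorted(observations["subject_id"].unique()))
    n = len(subjects)
    n_dev = round(2 * n / 3)
    if n_dev < 2 or n - n_dev < 1:
        raise ValueError(f"{n} subjects cannot support a 2:1 split")

    activities = list(observations["activity"].unique())
    sums = {a: 0.0 for a in activities}
    counts = {a: 0 for a in activities}
    total_sum, total_count = 0.0, 0
    by_subject = observations["subject_id"].to_numpy()

    for _ in range(n_reps):
        dev_ids = rng.choice(subjects, size=n_dev, replace=False)
        mask = np.isin(by_subject, dev_ids)
        train, test = observations[mask], observations[~mask]
        est = _ols_fit_predict(train, test, spec.predictors)
        diffs2 = (est - test["mets"].to_numpy(float)) ** 2
        grp = pd.Series(diffs2).groupby(test["activity"].to_numpy()).mean()
        for a, v in grp.items():
            sums[a] += math.sqrt(v)
            counts[a] += 1
        total_sum += math.sqrt(float(np.mean(diffs2)))
        total_count += 1

    per_activity = pd.Series(
        {a: sums[a] / counts[a] if counts[a] else math.nan for a in activities},
        name="rmse",
    )
    per_activity.index.name = "activity"
    return HoldoutReport(
        per_activity_rmse=per_activity,
        total_rmse=total_sum / total_count,
        n_reps=n_reps,
        split_ratio="2:1",
        seed=seed,
        n_dev_subjects=n_dev,
        n_val_subjects=n - n_dev,
    )
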