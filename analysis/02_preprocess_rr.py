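#!/usr/bin/env python
"""R-R preprocessing round trip on synthetic beat-to-beat recordings.

For a few subjects and activity intensities, emulates a patch-ECG R-R series
(with artifacts), runs the epoch/outlier/minute-averaging pipeline, and
reports how closely the cleaned activity HR recovers the target.  Writes
hr_summary.csv (subject_id, activity, target_hr, mean_hr_bpm, n_minutes,
n_epochs_removed).
"""

import argparse
from pathlib import Path

import pandas as pd

from hrmets.cohort import generate_rr_series, generate_subjects
from hrmets.physiology import hr_from_percent_hrr
from hrmets.preprocessing import (
    activity_mean_hr,
    remove_epoch_outliers,
    rr_to_epoch_hr,
)

DEMO_ACTIVITIES = [  # (name, %HRR level, minutes, outlier k)
    ("PC work", 2.3, 5, 3),
    ("walking (70 m/min)", 26.0, 2, 3),
    ("radio calisthenics", 21.6, 3, 4),
    ("jogging (130 m/min)", 73.4, 1, 3),
]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--artifact-rate", type=float, default=0.02)
    ap.add_argument("--epoch", type=float, default=0.4)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    subjects = generate_subjects(seed=args.seed)[:5]
    rows = []
    for i, subject in enumerate(subjects):
        for j, (name, pct, minutes, k_sd) in enumerate(DEMO_ACTIVITIES):
            target = hr_from_percent_hrr(pct, subject.resting_hr, subject.predicted_hrmax)
            series = generate_rr_series(subject, target_hr=target,
                                        duration=60.0 * minutes,
                                        artifact_rate=args.artifact_rate,
                                        seed=args.seed + 97 * i + j)
            epochs = rr_to_epoch_hr(series, args.epoch)
            cleaned, removed = remove_epoch_outliers(epochs, k_sd=k_sd)
            mean_hr = activity_mean_hr(cleaned, minutes=minutes)
            rows.append({
                "subject_id": subject.subject_id, "activity": name,
                "target_hr": target, "mean_hr_bpm": mean_hr,
                "n_minutes": minutes, "n_epochs_removed": removed,
            })

    df = pd.DataFrame(rows)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out_dir / "hr_summary.csv", index=False)
    err = (df["mean_hr_bpm"] - df["target_hr"]).abs()
    print(df.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
    print(f"\nmean |recovered - target| = {err.mean():.2f} bpm over {len(df)} recordings"
          f" (artifact rate {args.artifact_rate:.0%})")
    print(f"wrote {args.out_dir / 'hr_summary.csv'}")


if __name__ == "__main__":
    main()
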