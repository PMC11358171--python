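"""Signal-detection scoring of violence-likelihood ratings.

A fight clip rated 4 or more is a hit (3 or less, a miss); a non-fight
clip rated 3 or less is a correct rejection (4 or more, a false alarm).
d' and criterion C come from inverse-normal transforms of hit and
false-alarm rates, with the log-linear correction (add 0.5 to each cell,
1 to each denominator) guarding the extremes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

VIOLENT_THRESHOLD = 4  # rating >= 4 counts as a "violent" call


@dataclass
class SDTScores:
    hit_rate: float
    fa_rate: float
    d_prime: float
    criterion_c: float


def score_outcomes(table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant hit/miss/false-alarm/correct-rejection counts."""
    required = {"participant_id", "group", "clip_id", "category", "rating"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"ratings table missing columns: {sorted(missing)}")
    ratings = table["rating"].to_numpy()
    if not np.all((ratings >= 1) & (ratings <= 6) & (ratings == ratings.astype(int))):
        raise ValueError("ratings must be integers in 1..6")
    df = table.copy()
    df["violent_call"] = df["rating"] >= VIOLENT_THRESHOLD
    df["is_fight"] = df["category"] == "fight"
    rows = []
    for (pid, group), sub in df.groupby(["participant_id", "group"], sort=False):
        fight = sub[sub["is_fight"]]
        nonfight = sub[~sub["is_fight"]]
        rows.append(
            {
                "participant_id": pid,
                "group": group,
                "hits": int(fight["violent_call"].sum()),
                "misses": int((~fight["violent_call"]).sum()),
                "false_alarms": int(nonfight["violent_call"].sum()),
                "correct_rejections": int((~nonfight["violent_call"]).sum()),
            }
        )
    return pd.DataFrame(rows)


def dprime_criterion(
    hits: int, misses: int, false_alarms: int, correct_rejections: int
) -> SDTScores:
    """d' and criterion C from outcome counts with log-linear correction."""
    for name, v in (
        ("hits", hits),
        ("misses", misses),
        ("false_alarms", false_alarms),
        ("correct_rejections", correct_rejections),
    ):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    n_signal = hits + misses
    n_noise = false_alarms + correct_rejections
    if n_signal == 0 or n_noise == 0:
        raise ValueError("both signal and noise trials are required")
    h = (hits + 0.5) / (n_signal + 1)
    f = (false_alarms + 0.5) / (n_noise + 1)
    zh, zf = norm.ppf(h), norm.ppf(f)
    return SDTScores(
        hit_rate=float(h),
        fa_rate=float(f),
        d_prime=float(zh - zf),
        criterion_c=float(-(zh + zf) / 2.0),
    )


def score_table(table: pd.DataFrame) -> pd.DataFrame:
    """Ratings table -> per-participant rates, d', and C."""
    counts = score_outcomes(table)
    scored = counts.apply(
        lambda r: dprime_criterion(
            r["hits"], r["misses"], r["false_alarms"], r["correct_rejections"]
        ),
        axis=1,
    )
    counts["hit_rate"] = [s.hit_rate for s in scored]
    counts["fa_rate"] = [s.fa_rate for s in scored]
    counts["d_prime"] = [s.d_prime for s in scored]
    counts["criterion_c"] = [s.criterion_c for s in scored]
    return counts
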