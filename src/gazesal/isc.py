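"""Inter-subject correlation of time-concatenated feature streams.

Within-group ISC for a clip is the mean Pearson correlation over all
participant pairs of their concatenated feature vectors. Channels are
z-scored (population sd) over the pooled participant x clip x frame axis
before concatenation. A time-resolved variant computes the same per
disjoint time chunk; an inter-group variant correlates each participant
with the (leave-self-out) mean vector of their own group and with the
mean of the other group.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd


def znorm_channels(features: np.ndarray) -> np.ndarray:
    """Z-score each trailing-axis channel over all other axes (population sd)."""
    x = np.asarray(features, dtype=float)
    if x.ndim < 2:
        raise ValueError("features must have a trailing channel axis")
    flat = x.reshape(-1, x.shape[-1])
    constant = np.ptp(flat, axis=0) == 0
    for c in np.nonzero(constant)[0]:
        raise ValueError(f"channel {c} is constant; cannot z-score")
    mu = flat.mean(axis=0)
    sd = flat.std(axis=0)  # population convention (divide by N)
    return (x - mu) / sd


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return np.nan
    return float((a @ b) / denom)


def pairwise_isc(rows: np.ndarray, groups) -> dict[str, float]:
    """Mean within-group pairwise correlation of per-participant rows.

    ``rows`` is (n_participants, length); zero-variance rows make their
    pairs undefined — those pairs are excluded with a warning.
    """
    rows = np.asarray(rows, dtype=float)
    groups = np.asarray(groups)
    if rows.ndim != 2:
        raise ValueError("rows must be 2-D (participants x length)")
    if len(groups) != rows.shape[0]:
        raise ValueError("groups length must match number of rows")
    out: dict[str, float] = {}
    for g in dict.fromkeys(groups):
        idx = np.nonzero(groups == g)[0]
        if len(idx) < 2:
            raise ValueError(f"group {g!r} needs >= 2 participants")
        vals = []
        dropped = 0
        for i, j in combinations(idx, 2):
            r = _pearson(rows[i], rows[j])
            if np.isnan(r):
                dropped += 1
            else:
                vals.append(r)
        if dropped:
            warnings.warn(
                f"group {g!r}: excluded {dropped} pair(s) with zero-variance rows",
                stacklevel=2,
            )
        out[g] = float(np.mean(vals)) if vals else np.nan
    return out


def time_resolved_isc(
    features: np.ndarray,
    groups,
    chunk_s: float = 2.0,
    fps: float = 25.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Within-group ISC per disjoint time chunk.

    ``features`` is (participants, frames, channels). Returns one row per
    chunk x group with the chunk's frame range, the group ISC, and the
    Bonferroni-adjusted alpha (0.05 / n_chunks) for group comparisons.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 3:
        raise ValueError("features must be (participants, frames, channels)")
    chunk_frames = int(round(chunk_s * fps))
    if chunk_frames < 2:
        raise ValueError("chunk must span at least 2 frames")
    n_frames = x.shape[1]
    starts = list(range(0, n_frames, chunk_frames))
    n_chunks = len(starts)
    rows = []
    for ci, s in enumerate(starts):
        e = min(s + chunk_frames, n_frames)
        chunk_rows = x[:, s:e, :].reshape(x.shape[0], -1)
        isc = pairwise_isc(chunk_rows, groups)
        for g, r in isc.items():
            rows.append(
                {
                    "chunk": ci,
                    "start_frame": s,
                    "end_frame": e,
                    "group": g,
                    "isc": r,
                    "adjusted_alpha": alpha / n_chunks,
                }
            )
    return pd.DataFrame(rows)


def intergroup_correlation(
    rows: np.ndarray, groups, leave_self_out: bool = True
) -> pd.DataFrame:
    """Correlate each participant with own-group and other-group mean vectors.

    With ``leave_self_out`` the participant's own row is excluded from
    their group mean (avoids self-correlation inflation); this requires
    every group to have >= 2 members.
    """
    rows = np.asarray(rows, dtype=float)
    groups = np.asarray(groups)
    unique = list(dict.fromkeys(groups))
    if len(unique) != 2:
        raise ValueError("exactly two groups are required")
    sizes = {g: int(np.sum(groups == g)) for g in unique}
    if leave_self_out and min(sizes.values()) < 2:
        raise ValueError("leave-self-out needs >= 2 participants per group")
    means = {g: rows[groups == g].mean(axis=0) for g in unique}
    out = []
    for i in range(rows.shape[0]):
        g = groups[i]
        other = unique[0] if g == unique[1] else unique[1]
        if leave_self_out:
            n = sizes[g]
            own_mean = (means[g] * n - rows[i]) / (n - 1)
        else:
            own_mean = means[g]
        out.append(
            {
                "participant": i,
                "group": g,
                "own_r": _pearson(rows[i], own_mean),
                "other_r": _pearson(rows[i], means[other]),
            }
        )
    return pd.DataFrame(out)
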