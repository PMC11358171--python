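"""Elastic-net group and action decoding over temporal feature windows.

Group decoding (group "a" vs group "b") trains an elastic-net-penalized
binomial GLM per clip and temporal window in a leave-one-participant-out
loop; the per-clip score is the maximum accuracy over cumulative windows.
Significance is assessed by one-sample t-tests against chance with a
Bonferroni-adjusted alpha, and by a permutation test that shuffles the
channel identities of the features. Action decoding (fight vs the rest)
runs frame-by-frame per participant with leave-one-clip-out and balanced
class weights, taking the maximum accuracy in each fixed-length chunk.

Regularization strength is chosen by inner cross-validation on each
training fold over a fixed logarithmic grid (pass a float to fix it
instead); features are z-scored with statistics fit on the training fold
only. Held-out probabilities are thresholded at 0.5 with ties going to
the negative (first-sorted) class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

REG_GRID = np.logspace(-2.0, 2.0, 5)  # inverse regularization strengths (C)


@dataclass
class LOODecodeResult:
    """One leave-one-out decoding run on a single feature matrix."""

    accuracy: float
    correct: np.ndarray  # (n_samples,) bool
    coefs: np.ndarray  # (n_iterations, n_features)
    chosen_c: np.ndarray  # (n_iterations,)
    classes: tuple  # (negative, positive)

    @property
    def n_iterations(self) -> int:
        return len(self.correct)


@dataclass
class DecodingResult:
    """Group decoding across clips and cumulative windows."""

    per_clip_window_accuracy: np.ndarray  # (n_clips, n_windows)
    per_clip_max: np.ndarray  # (n_clips,)
    per_clip_max_window: np.ndarray  # (n_clips,) first window index attaining max
    windows: list[tuple[int, int]]
    fits: list[list[LOODecodeResult]]  # [clip][window]
    elastic_net_alpha: float


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p_value: float


def build_windows(n_frames: int, step: int, mode: str = "cumulative") -> list[tuple[int, int]]:
    """Temporal windows as half-open (start, end) frame ranges.

    Cumulative windows all start at frame 0 and end at step, 2*step, ...,
    n_frames; chunked windows are the disjoint blocks between those
    endpoints.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if step > n_frames:
        raise ValueError("step must not exceed n_frames")
    ends = list(range(step, n_frames + 1, step))
    if ends[-1] != n_frames:
        ends.append(n_frames)
    if mode == "cumulative":
        return [(0, e) for e in ends]
    if mode == "chunked":
        starts = [0] + ends[:-1]
        return list(zip(starts, ends))
    raise ValueError("mode must be 'cumulative' or 'chunked'")


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def _fit_enet(
    X: np.ndarray,
    y: np.ndarray,
    mixing_alpha: float,
    c_value: float,
    seed: int,
    class_weight=None,
) -> LogisticRegression:
    model = LogisticRegression(
        solver="saga",
        l1_ratio=mixing_alpha,
        C=c_value,
        max_iter=2000,
        tol=1e-4,
        class_weight=class_weight,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model


def _choose_c(
    X: np.ndarray,
    y: np.ndarray,
    mixing_alpha: float,
    seed: int,
    class_weight=None,
    grid: np.ndarray = REG_GRID,
) -> float:
    """Inner stratified CV over the C grid; ties prefer stronger regularization."""
    _, counts = np.unique(y, return_counts=True)
    n_splits = int(min(5, counts.min()))
    if n_splits < 2:
        return float(grid[len(grid) // 2])
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    scores = np.zeros(len(grid))
    for tr, te in cv.split(X, y):
        Xtr, Xte = _standardize(X[tr], X[te])
        for i, c in enumerate(grid):
            model = _fit_enet(Xtr, y[tr], mixing_alpha, c, seed, class_weight)
            scores[i] += float(np.mean(model.predict(Xte) == y[te]))
    return float(grid[int(np.argmax(scores))])


def loo_group_decode(
    X: np.ndarray,
    labels,
    mixing_alpha: float = 1.0,
    reg: float | str = "cv",
    seed: int = 0,
    class_weight="balanced",
) -> LOODecodeResult:
    """Leave-one-sample-out elastic-net decoding of binary labels.

    ``reg`` is either "cv" (inner cross-validated strength per training
    fold) or a fixed inverse regularization strength C. Iteration count
    equals the number of samples. Training folds are imbalanced by
    construction (the held-out sample's class is one short), which biases
    null accuracy below chance; balanced class weights are therefore the
    default.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    labels = np.asarray(labels)
    if len(labels) != X.shape[0]:
        raise ValueError("labels length must match rows of X")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    if counts.min() < 2:
        raise ValueError("each class needs >= 2 samples for leave-one-out training")
    if not 0 < mixing_alpha <= 1:
        raise ValueError("mixing_alpha must lie in (0, 1]")

    neg, pos = classes[0], classes[1]
    y = (labels == pos).astype(int)
    n = X.shape[0]
    correct = np.zeros(n, dtype=bool)
    coefs = np.zeros((n, X.shape[1]))
    chosen = np.zeros(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr_raw, ytr = X[mask], y[mask]
        if reg == "cv":
            c_value = _choose_c(Xtr_raw, ytr, mixing_alpha, seed, class_weight)
        else:
            c_value = float(reg)
        Xtr, Xte = _standardize(Xtr_raw, X[i : i + 1])
        model = _fit_enet(Xtr, ytr, mixing_alpha, c_value, seed, class_weight)
        p_pos = model.predict_proba(Xte)[0, list(model.classes_).index(1)]
        pred = 1 if p_pos > 0.5 else 0  # ties go to the negative class
        correct[i] = pred == y[i]
        coefs[i] = model.coef_[0]
        chosen[i] = c_value
    return LOODecodeResult(
        accuracy=float(correct.mean()),
        correct=correct,
        coefs=coefs,
        chosen_c=chosen,
        classes=(neg, pos),
    )


def decode_clip_windows(
    tensor: np.ndarray,
    labels,
    step: int,
    mode: str = "cumulative",
    mixing_alpha: float = 1.0,
    reg: float | str = "cv",
    seed: int = 0,
) -> tuple[np.ndarray, list[LOODecodeResult], list[tuple[int, int]]]:
    """Decode one clip's (participants, frames, dim) tensor per temporal window."""
    tensor = np.asarray(tensor, dtype=float)
    if tensor.ndim != 3:
        raise ValueError("tensor must be (participants, frames, dim)")
    windows = build_windows(tensor.shape[1], step, mode)
    accs = np.zeros(len(windows))
    fits = []
    for wi, (s, e) in enumerate(windows):
        Xw = tensor[:, s:e, :].reshape(tensor.shape[0], -1)
        res = loo_group_decode(Xw, labels, mixing_alpha, reg, seed)
        accs[wi] = res.accuracy
        fits.append(res)
    return accs, fits, windows


def summarize_max_accuracy(per_window: np.ndarray) -> tuple[float, int]:
    """Maximum over windows; ties keep the earliest window index."""
    per_window = np.asarray(per_window, dtype=float)
    if per_window.size == 0:
        raise ValueError("per-window accuracies are empty")
    idx = int(np.argmax(per_window))  # argmax returns the first maximum
    return float(per_window[idx]), idx


def group_decode(
    clip_tensors: list[np.ndarray],
    labels,
    step: int,
    mode: str = "cumulative",
    mixing_alpha: float = 1.0,
    reg: float | str = "cv",
    seed: int = 0,
) -> DecodingResult:
    """Per-clip windowed decoding with max-over-windows summarization."""
    if not clip_tensors:
        raise ValueError("clip list is empty")
    all_accs, all_fits, windows = [], [], None
    for tensor in clip_tensors:
        accs, fits, windows = decode_clip_windows(
            tensor, labels, step, mode, mixing_alpha, reg, seed
        )
        all_accs.append(accs)
        all_fits.append(fits)
    per_clip = np.stack(all_accs)
    maxes = np.array([summarize_max_accuracy(a) for a in per_clip])
    return DecodingResult(
        per_clip_window_accuracy=per_clip,
        per_clip_max=maxes[:, 0],
        per_clip_max_window=maxes[:, 1].astype(int),
        windows=windows,
        fits=all_fits,
        elastic_net_alpha=mixing_alpha,
    )


def test_vs_chance(
    per_clip_max: np.ndarray,
    categories,
    chance: float = 0.5,
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """One-sample t-test per category against chance, Bonferroni-adjusted."""
    per_clip_max = np.asarray(per_clip_max, dtype=float)
    categories = np.asarray(categories)
    cats = list(dict.fromkeys(categories))  # preserve first-seen order
    if n_tests is None:
        n_tests = len(cats)
    adjusted = alpha / n_tests
    rows = []
    for cat in cats:
        vals = per_clip_max[categories == cat]
        if len(vals) < 2:
            raise ValueError(f"category {cat!r} needs >= 2 clips")
        degenerate = bool(np.std(vals) == 0)
        if degenerate:
            t, p = (0.0, 1.0) if np.isclose(vals[0], chance) else (np.inf, 0.0)
        else:
            t, p = stats.ttest_1samp(vals, chance)
        rows.append(
            {
                "category": cat,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "t": float(t),
                "p": float(p),
                "adjusted_alpha": adjusted,
                "significant": bool(p < adjusted),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def permutation_null(
    clip_tensors: list[np.ndarray],
    labels,
    n_iter: int = 100,
    seed: int = 0,
    step: int | None = None,
    mixing_alpha: float = 1.0,
    reg: float | str = "cv",
) -> PermutationResult:
    """Channel-identity permutation test for saliency-stream decoding.

    Per iteration and participant, one random permutation of the channel
    axis is applied consistently across frames (and clips); the full
    windowed decoding pipeline is re-run. The p-value is the fraction of
    null statistics >= the observed mean max-window accuracy.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    tensors = [np.asarray(t, dtype=float) for t in clip_tensors]
    n_participants = tensors[0].shape[0]
    n_channels = tensors[0].shape[2]
    if step is None:
        step = tensors[0].shape[1]

    def _stat(ts: list[np.ndarray]) -> float:
        res = group_decode(ts, labels, step=step, mixing_alpha=mixing_alpha, reg=reg, seed=seed)
        return float(res.per_clip_max.mean())

    observed = _stat(tensors)
    rng = np.random.default_rng(seed)
    null = np.zeros(n_iter)
    for it in range(n_iter):
        perms = [rng.permutation(n_channels) for _ in range(n_participants)]
        shuffled = [
            np.stack([t[p_idx][:, perms[p_idx]] for p_idx in range(n_participants)])
            for t in tensors
        ]
        null[it] = _stat(shuffled)
    p = float(np.mean(null >= observed))
    return PermutationResult(observed=observed, null=null, p_value=p)


def selection_proportions(fits, n_channels: int = 6) -> np.ndarray:
    """Per-channel fraction of LOO fits with any nonzero coefficient.

    ``fits`` is any nesting of LOODecodeResult objects whose feature
    layout is frame-major (channel index = column index mod n_channels).
    """

    def _iter(obj):
        if isinstance(obj, LOODecodeResult):
            yield obj
        else:
            for item in obj:
                yield from _iter(item)

    counts = np.zeros(n_channels)
    total = 0
    for res in _iter(fits):
        per_fit = res.coefs.reshape(res.coefs.shape[0], -1, n_channels)
        counts += (np.abs(per_fit) > 0).any(axis=1).sum(axis=0)
        total += res.coefs.shape[0]
    if total == 0:
        return counts
    return counts / total


@dataclass
class FightDecodeResult:
    per_frame_accuracy: np.ndarray
    per_chunk_max: np.ndarray
    accuracy: float  # mean of per-chunk maxima
    baseline: float  # majority-class prior


def decode_fight_vs_rest(
    clip_features: np.ndarray,
    fight_labels,
    chunk_frames: int = 100,
    mixing_alpha: float = 1.0,
    reg: float | str = "cv",
    seed: int = 0,
) -> FightDecodeResult:
    """Frame-by-frame fight/non-fight decoding for one participant.

    ``clip_features`` is (n_clips, n_frames, dim); per frame a classifier
    with balanced class weights is trained leave-one-clip-out. The
    maximum per-frame accuracy within each ``chunk_frames`` block is
    averaged into the participant's score.
    """
    X = np.asarray(clip_features, dtype=float)
    if X.ndim != 3:
        raise ValueError("clip_features must be (clips, frames, dim)")
    y = np.asarray(fight_labels).astype(bool)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need >= 2 clips in each of the fight and non-fight classes")
    n_clips, n_frames, _ = X.shape
    per_frame = np.zeros(n_frames)
    for t in range(n_frames):
        res = loo_group_decode(
            X[:, t, :], y, mixing_alpha, reg, seed, class_weight="balanced"
        )
        per_frame[t] = res.accuracy
    chunks = build_windows(n_frames, chunk_frames, "chunked")
    per_chunk = np.array([per_frame[s:e].max() for s, e in chunks])
    baseline = float(max(y.mean(), 1 - y.mean()))
    return FightDecodeResult(
        per_frame_accuracy=per_frame,
        per_chunk_max=per_chunk,
        accuracy=float(per_chunk.mean()),
        baseline=baseline,
    )


def combine_streams(saliency_row: np.ndarray, embedding_row: np.ndarray) -> np.ndarray:
    """Concatenate two per-frame feature streams after per-stream standardization.

    Rows are (n_frames, dim) on a common frame grid (the saliency stream
    is expected to be subsampled to the embedding frames beforehand).
    Each stream is centered and scaled by its pooled mean/sd; an all-zero
    (zero-variance) stream is left as zeros so it cannot perturb the
    other stream's decoding.
    """
    a = np.asarray(saliency_row, dtype=float)
    b = np.asarray(embedding_row, dtype=float)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("stream rows must be 2-D (frames x dim)")
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"frame grids differ: {a.shape[0]} vs {b.shape[0]}")

    def _z(x: np.ndarray) -> np.ndarray:
        if x.size == 0:
            return x
        sd = x.std()
        if sd == 0:
            return x - x.mean()
        return (x - x.mean()) / sd

    return np.concatenate([_z(a), _z(b)], axis=1)


def correlate_behavior(accuracies: pd.DataFrame, sdt: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations of per-participant accuracies with d' and C.

    ``accuracies`` has a participant_id column plus one column per
    feature stream; ``sdt`` has participant_id, d_prime, criterion_c.
    Zero-variance pairs are flagged with undefined r.
    """
    merged = accuracies.merge(sdt, on="participant_id", validate="one_to_one")
    streams = [c for c in accuracies.columns if c != "participant_id"]
    rows = []
    for stream in streams:
        for measure in ("d_prime", "criterion_c"):
            x = merged[stream].to_numpy(dtype=float)
            yv = merged[measure].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(yv) == 0:
                rows.append(
                    {"stream": stream, "measure": measure, "r": np.nan, "p": np.nan,
                     "undefined": True}
                )
                continue
            r, p = stats.pearsonr(x, yv)
            rows.append(
                {"stream": stream, "measure": measure, "r": float(r), "p": float(p),
                 "undefined": False}
            )
    return pd.DataFrame(rows)
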