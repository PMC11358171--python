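"""Synthetic stimulus clips, two-group gaze traces, and behavioral ratings.

Clips are rendered as moving Gaussian "agent" blobs over a uniform
background, with optional static/flickering colored distractor blobs.
Agent motion depends on the action category (fight/confrontation agents
converge on an interaction locus, playful agents orbit it, neutral agents
wander independently). Ground-truth agent tracks and distractor positions
are recorded so that gaze simulation and tests can reference them.

Gaze traces follow a group-shared target policy: group "a" tracks the
agent that ends up nearest the interaction locus, with per-participant
noise scaled by ``1 - within_group_consistency``; group "b" follows the
same policy but is captured by distractors on short segments with a
probability controlled by ``strategy_gap``. With ``strategy_gap == 0`` and
equal consistencies both groups are drawn from the identical generative
policy.

Ratings come from an equal-variance Gaussian signal-detection model
(fight clips are the signal class) mapped onto six ordinal bins by
equal-width criterion cuts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CATEGORIES = ("fight", "confrontation", "playful", "neutral")

GROUP_A = "a"
GROUP_B = "b"


@dataclass(frozen=True)
class ClipSpec:
    """Parameters of one synthetic clip."""

    clip_id: str = "clip-000"
    category: str = "neutral"
    duration_s: float = 16.0
    fps: float = 25.0
    width: int = 576
    height: int = 480
    n_agents: int = 3
    n_distractors: int = 2
    agent_motion_scale: float = 1.5
    distractor_salience: float = 0.8

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}; expected one of {CATEGORIES}")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("width and height must be positive")
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValueError("fps and duration_s must be positive")
        n = self.duration_s * self.fps
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"duration_s * fps must be an integer frame count, got {n}")
        if self.n_agents < 0 or self.n_distractors < 0:
            raise ValueError("agent and distractor counts must be non-negative")
        if not 0.0 <= self.distractor_salience <= 1.0:
            raise ValueError("distractor_salience must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a two-group synthetic cohort."""

    n_group_a: int = 11
    n_group_b: int = 10
    strategy_gap: float = 0.0
    within_group_consistency_a: float = 0.8
    within_group_consistency_b: float = 0.8
    missing_rate: float = 0.011
    gaze_noise_px: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a + self.n_group_b < 2:
            raise ValueError("cohort must have at least two participants")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.strategy_gap < 0:
            raise ValueError("strategy_gap must be non-negative")
        for c in (self.within_group_consistency_a, self.within_group_consistency_b):
            if not 0.0 <= c <= 1.0:
                raise ValueError("within-group consistencies must lie in [0, 1]")

    @property
    def participant_ids(self) -> list[str]:
        return [f"a{i + 1:02d}" for i in range(self.n_group_a)] + [
            f"b{i + 1:02d}" for i in range(self.n_group_b)
        ]

    @property
    def groups(self) -> list[str]:
        return [GROUP_A] * self.n_group_a + [GROUP_B] * self.n_group_b


@dataclass
class VideoClip:
    """Rendered clip plus the ground truth used to generate it.

    ``frames`` is a ``(T, H, W, 3)`` float32 array of RGB intensities in
    [0, 1]. ``agent_tracks`` is ``(n_agents, T, 2)`` of (x, y) pixel
    positions; ``distractor_points`` is ``(n_distractors, 2)``.
    """

    frames: np.ndarray
    spec: ClipSpec
    agent_tracks: np.ndarray
    distractor_points: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def interaction_locus(self) -> np.ndarray:
        """Centroid of the agents' final positions (frame center if no agents)."""
        if self.agent_tracks.shape[0] == 0:
            return np.array([(self.spec.width - 1) / 2.0, (self.spec.height - 1) / 2.0])
        return self.agent_tracks[:, -1, :].mean(axis=0)


@dataclass
class GazeTrace:
    """Per participant x clip gaze sample sequence at frame rate."""

    participant_id: str
    group: str
    clip_id: str
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.x)


BACKGROUND = 0.5
AGENT_AMPLITUDE = -0.4
AGENT_SIGMA_FRAC = 1 / 40  # of min(width, height)

# fixed palette for distractors: saturated colored offsets from background
_DISTRACTOR_COLORS = np.array(
    [[0.5, -0.4, -0.4], [-0.4, -0.4, 0.5], [0.5, 0.4, -0.4], [-0.4, 0.5, -0.4]]
)


def _stamp_blob(frame: np.ndarray, x: float, y: float, sigma: float, amp: np.ndarray) -> None:
    """Add a Gaussian blob in place, evaluated only on a local window."""
    h, w = frame.shape[:2]
    r = int(3 * sigma + 0.5)
    x0, x1 = int(np.floor(x)) - r, int(np.floor(x)) + r + 1
    y0, y1 = int(np.floor(y)) - r, int(np.floor(y)) + r + 1
    x0, x1 = max(x0, 0), min(x1, w)
    y0, y1 = max(y0, 0), min(y1, h)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - x
    ys = np.arange(y0, y1) - y
    g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma**2))
    frame[y0:y1, x0:x1] += g[:, :, None] * amp[None, None, :]


def _agent_tracks(spec: ClipSpec, rng: np.random.Generator) -> np.ndarray:
    """Category-dependent agent trajectories, shape (n_agents, T, 2)."""
    T = spec.n_frames
    w, h = spec.width, spec.height
    margin = 0.15
    locus = np.array([w, h]) * rng.uniform(0.35, 0.65, size=2)
    start = np.stack(
        [
            rng.uniform(margin * w, (1 - margin) * w, size=spec.n_agents),
            rng.uniform(margin * h, (1 - margin) * h, size=spec.n_agents),
        ],
        axis=1,
    )
    tracks = np.zeros((spec.n_agents, T, 2))
    t = np.arange(T) / max(T - 1, 1)
    scale = spec.agent_motion_scale
    for i in range(spec.n_agents):
        p0 = start[i]
        to_locus = locus - p0
        dist = np.linalg.norm(to_locus) + 1e-9
        direction = to_locus / dist
        if spec.category == "fight":
            # converge with increasing speed: quadratic progress toward locus
            progress = np.minimum(t**2 * scale * T / dist * 1.5, 1.0)
            tracks[i] = p0 + progress[:, None] * to_locus[None, :]
        elif spec.category == "confrontation":
            # constant moderate speed, stop short of the locus
            stop = max(dist - 8 * AGENT_SIGMA_FRAC * min(w, h), 0.0)
            progress = np.minimum(t * scale * T / dist, stop / dist)
            tracks[i] = p0 + progress[:, None] * to_locus[None, :]
        elif spec.category == "playful":
            # orbit the locus at the starting radius
            phase0 = np.arctan2(p0[1] - locus[1], p0[0] - locus[0])
            omega = scale / max(dist, 1.0)
            phase = phase0 + omega * np.arange(T)
            tracks[i, :, 0] = locus[0] + dist * np.cos(phase)
            tracks[i, :, 1] = locus[1] + dist * np.sin(phase)
        else:  # neutral: independent slow smoothed random walk
            steps = rng.normal(scale=0.5 * scale, size=(T, 2))
            drift = rng.normal(scale=0.3 * scale, size=2)
            path = np.cumsum(steps + drift, axis=0)
            tracks[i] = p0 + path - path[0]
        np.clip(tracks[i, :, 0], 2.0, w - 3.0, out=tracks[i, :, 0])
        np.clip(tracks[i, :, 1], 2.0, h - 3.0, out=tracks[i, :, 1])
    return tracks


def generate_clip(spec: ClipSpec, seed: int) -> VideoClip:
    """Render one synthetic clip; deterministic given (spec, seed)."""
    rng = np.random.default_rng(seed)
    T = spec.n_frames
    sigma = AGENT_SIGMA_FRAC * min(spec.width, spec.height)
    tracks = _agent_tracks(spec, rng)
    margin = 0.1
    dist_xy = np.stack(
        [
            rng.uniform(margin * spec.width, (1 - margin) * spec.width, size=spec.n_distractors),
            rng.uniform(margin * spec.height, (1 - margin) * spec.height, size=spec.n_distractors),
        ],
        axis=1,
    )
    colors = _DISTRACTOR_COLORS[rng.integers(0, len(_DISTRACTOR_COLORS), size=spec.n_distractors)]
    tints = rng.uniform(-0.05, 0.05, size=(spec.n_agents, 3))

    frames = np.empty((T, spec.height, spec.width, 3), dtype=np.float32)
    base = np.full((spec.height, spec.width, 3), BACKGROUND, dtype=np.float64)
    for t in range(T):
        frame = base.copy()
        for d in range(spec.n_distractors):
            amp = colors[d] * spec.distractor_salience
            if d % 2 == 1:  # periodic flicker at ~1 Hz
                amp = amp * (0.75 + 0.25 * np.sin(2 * np.pi * t / spec.fps))
            _stamp_blob(frame, dist_xy[d, 0], dist_xy[d, 1], 1.5 * sigma, amp)
        for i in range(spec.n_agents):
            amp = AGENT_AMPLITUDE + tints[i]
            _stamp_blob(frame, tracks[i, t, 0], tracks[i, t, 1], sigma, amp)
        frames[t] = np.clip(frame, 0.0, 1.0)
    return VideoClip(frames=frames, spec=spec, agent_tracks=tracks, distractor_points=dist_xy)


def generate_stimulus_set(
    n_per_category: int, base_spec: ClipSpec | None = None, seed: int = 0
) -> list[VideoClip]:
    """Balanced clip set: ``n_per_category`` clips for each of the 4 categories."""
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    base = base_spec if base_spec is not None else ClipSpec()
    child_seeds = np.random.SeedSequence(seed).generate_state(4 * n_per_category)
    clips = []
    k = 0
    for cat in CATEGORIES:
        for i in range(n_per_category):
            spec = replace(base, clip_id=f"{cat}-{i + 1:02d}", category=cat)
            clips.append(generate_clip(spec, int(child_seeds[k])))
            k += 1
    return clips


def _target_agent(clip: VideoClip) -> np.ndarray:
    """Per-frame (x, y) of the agent whose final position is nearest the locus."""
    if clip.agent_tracks.shape[0] == 0:
        locus = clip.interaction_locus()
        return np.tile(locus, (clip.n_frames, 1))
    locus = clip.interaction_locus()
    final = clip.agent_tracks[:, -1, :]
    idx = int(np.argmin(np.linalg.norm(final - locus, axis=1)))
    return clip.agent_tracks[idx]


def generate_cohort_gaze(clips: list[VideoClip], cohort: CohortSpec) -> list[GazeTrace]:
    """Simulate one gaze trace per participant x clip.

    Returns traces ordered participant-major (all clips of participant 1,
    then participant 2, ...).
    """
    if not clips:
        raise ValueError("clip list must be non-empty")
    rng = np.random.default_rng(cohort.seed)
    traces: list[GazeTrace] = []
    for pid, group in zip(cohort.participant_ids, cohort.groups):
        consistency = (
            cohort.within_group_consistency_a
            if group == GROUP_A
            else cohort.within_group_consistency_b
        )
        noise_sd = cohort.gaze_noise_px * (1.0 - consistency)
        for clip in clips:
            T = clip.n_frames
            target = _target_agent(clip).copy()
            if group == GROUP_B and cohort.strategy_gap > 0:
                # distractor capture on ~0.5 s segments
                seg = max(int(round(clip.spec.fps / 2)), 1)
                p_capture = min(cohort.strategy_gap, 1.0)
                for s0 in range(0, T, seg):
                    if rng.random() >= p_capture:
                        continue
                    if clip.distractor_points.shape[0] > 0:
                        j = rng.integers(0, clip.distractor_points.shape[0])
                        point = clip.distractor_points[j]
                    else:  # consistent fallback: a fixed off-locus point
                        point = np.array([clip.spec.width * 0.2, clip.spec.height * 0.2])
                    target[s0 : s0 + seg] = point
            xy = target + rng.normal(scale=noise_sd, size=(T, 2))
            x = np.clip(xy[:, 0], 0.0, clip.spec.width - 1.0)
            y = np.clip(xy[:, 1], 0.0, clip.spec.height - 1.0)
            valid = rng.random(T) >= cohort.missing_rate
            traces.append(
                GazeTrace(
                    participant_id=pid,
                    group=group,
                    clip_id=clip.spec.clip_id,
                    x=x,
                    y=y,
                    valid=valid,
                )
            )
    return traces


def generate_ratings(
    cohort: CohortSpec,
    clips: list[VideoClip],
    sensitivity_a: float = 1.5,
    sensitivity_b: float = 1.0,
    criterion: float = 0.0,
    seed: int = 0,
    bin_width: float = 1.0,
) -> pd.DataFrame:
    """Ordinal 1-6 ratings from an equal-variance signal-detection model.

    Fight clips carry a signal of strength ``sensitivity`` (per group);
    the decision axis is cut into six equal-width bins centered on the
    decision threshold, so a rating >= 4 corresponds to a "violent" call.
    """
    if sensitivity_a < 0 or sensitivity_b < 0:
        raise ValueError("sensitivities must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for pid, group in zip(cohort.participant_ids, cohort.groups):
        d = sensitivity_a if group == GROUP_A else sensitivity_b
        k = criterion + d / 2.0  # threshold giving criterion C on the SDT axis
        cuts = k + bin_width * np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        for clip in clips:
            signal = clip.spec.category == "fight"
            x = rng.normal(loc=d if signal else 0.0, scale=1.0)
            rating = 1 + int(np.sum(x > cuts))
            rows.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "clip_id": clip.spec.clip_id,
                    "category": clip.spec.category,
                    "rating": rating,
                }
            )
    return pd.DataFrame(rows)
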