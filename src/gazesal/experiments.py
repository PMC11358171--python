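"""Scaled-down end-to-end simulation runs for calibration and validation.

The full-scale configuration (576x480 clips, 400 frames, 75-px patches,
21 participants) is too heavy to repeat hundreds of times on one CPU, so
calibration experiments (null decoding, permutation rejection rate,
effect-recovery curves) run the identical pipeline at a reduced scale:
smaller clips, shorter durations, smaller patch windows, fewer
participants. Only sizes change — every stage is the production code
path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gazesal import pipeline
from gazesal.synth import (
    CATEGORIES,
    ClipSpec,
    CohortSpec,
    generate_clip,
    generate_cohort_gaze,
)


@dataclass(frozen=True)
class SmallScale:
    """Reduced-scale pipeline geometry for repeated simulation."""

    n_clips: int = 4
    frames: int = 10
    fps: float = 10.0
    clip_px: int = 64
    window_px: int = 16
    n_agents: int = 2
    n_distractors: int = 2
    n_group_a: int = 4
    n_group_b: int = 4
    strategy_gap: float = 0.0
    consistency_a: float = 0.8
    consistency_b: float = 0.8
    gaze_noise_px: float = 20.0
    missing_rate: float = 0.011


def simulate_saliency_features(
    scale: SmallScale, seed: int
) -> tuple[list[np.ndarray], np.ndarray, list[str]]:
    """Synthetic clips -> cohort gaze -> patches -> saliency feature tensors.

    Returns per-clip (participants, frames, 6) tensors, the group label
    array, and the clip categories.
    """
    state = np.random.SeedSequence(seed).generate_state(scale.n_clips + 1)
    clips = []
    for i in range(scale.n_clips):
        cat = CATEGORIES[i % len(CATEGORIES)]
        spec = ClipSpec(
            clip_id=f"{cat}-{i:03d}",
            category=cat,
            duration_s=scale.frames / scale.fps,
            fps=scale.fps,
            width=scale.clip_px,
            height=scale.clip_px,
            n_agents=scale.n_agents,
            n_distractors=scale.n_distractors,
        )
        clips.append(generate_clip(spec, int(state[i])))
    cohort = CohortSpec(
        n_group_a=scale.n_group_a,
        n_group_b=scale.n_group_b,
        strategy_gap=scale.strategy_gap,
        within_group_consistency_a=scale.consistency_a,
        within_group_consistency_b=scale.consistency_b,
        gaze_noise_px=scale.gaze_noise_px,
        missing_rate=scale.missing_rate,
        seed=int(state[-1]),
    )
    traces = generate_cohort_gaze(clips, cohort)
    feats = pipeline.saliency_features(clips, traces, window_px=scale.window_px)
    tensors = [f.tensor for f in feats]
    labels = np.asarray(feats[0].groups)
    categories = [f.category for f in feats]
    return tensors, labels, categories
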