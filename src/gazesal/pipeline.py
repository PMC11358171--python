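"""End-to-end plumbing from clips + gaze traces to per-clip feature tensors.

Used by the CLI and by calibration/acceptance runs; keeps the stage
wiring (patches -> saliency / embedding -> participant-stacked tensors)
in one place.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from gazesal import saliency as sal
from gazesal.embed import EmbeddingBackend, embed_sequence
from gazesal.patches import extract_patch_sequence, downsample_frames
from gazesal.synth import GazeTrace, VideoClip


@dataclass
class ClipFeatures:
    """Per-clip feature tensor stacked over participants."""

    clip_id: str
    category: str
    participant_ids: list[str]
    groups: list[str]
    tensor: np.ndarray  # (participants, frames, dim)


def _traces_by_clip(traces: list[GazeTrace]) -> dict[str, list[GazeTrace]]:
    by_clip: dict[str, list[GazeTrace]] = defaultdict(list)
    for tr in traces:
        by_clip[tr.clip_id].append(tr)
    return by_clip


def saliency_features(
    clips: list[VideoClip],
    traces: list[GazeTrace],
    window_px: int = 75,
    config: sal.SaliencyConfig = sal.DEFAULT_CONFIG,
) -> list[ClipFeatures]:
    """(participants, frames, 6) exported-factor tensor per clip."""
    by_clip = _traces_by_clip(traces)
    out = []
    for clip in clips:
        cid = clip.spec.clip_id
        rows, pids, groups = [], [], []
        for tr in by_clip[cid]:
            seq = extract_patch_sequence(clip, tr, window_px=window_px)
            feats = sal.run_saliency_sequence(seq, config)
            rows.append(sal.features_to_matrix(feats))
            pids.append(tr.participant_id)
            groups.append(tr.group)
        out.append(
            ClipFeatures(
                clip_id=cid,
                category=clip.spec.category,
                participant_ids=pids,
                groups=groups,
                tensor=np.stack(rows),
            )
        )
    return out


def embedding_features(
    clips: list[VideoClip],
    traces: list[GazeTrace],
    backend: EmbeddingBackend,
    window_px: int = 75,
    downsample: int = 10,
) -> list[ClipFeatures]:
    """(participants, frames, dim) embedding tensor per clip (frame-subsampled)."""
    by_clip = _traces_by_clip(traces)
    out = []
    for clip in clips:
        cid = clip.spec.clip_id
        rows, pids, groups = [], [], []
        for tr in by_clip[cid]:
            seq = downsample_frames(
                extract_patch_sequence(clip, tr, window_px=window_px), downsample
            )
            row = embed_sequence(seq, backend)
            rows.append(row.reshape(len(seq), backend.output_dim))
            pids.append(tr.participant_id)
            groups.append(tr.group)
        out.append(
            ClipFeatures(
                clip_id=cid,
                category=clip.spec.category,
                participant_ids=pids,
                groups=groups,
                tensor=np.stack(rows),
            )
        )
    return out
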