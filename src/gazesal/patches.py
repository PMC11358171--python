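"""Gaze-centered patch extraction and frame downsampling.

Coordinate convention: 0-based, ``x`` is the column, ``y`` the row,
origin at the top-left. Gaze coordinates are rounded to the nearest
integer pixel; a window of side ``w`` is the half-open crop
``[c - w//2, c - w//2 + w)`` in each axis, so the gaze pixel sits at
index ``w//2`` of the patch. Crops that extend past the frame are
zero-padded to full size by default (``boundary="clamp"`` shifts the
window inside the frame instead). Frames with missing gaze are all-zero
patches flagged invalid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gazesal.synth import GazeTrace, VideoClip

DEFAULT_WINDOW = 75


@dataclass
class PatchSequence:
    """Sequence of gaze-centered square patches for one participant x clip."""

    patches: np.ndarray  # (T, w, w, 3), float32
    valid: np.ndarray  # (T,), bool
    clip_id: str
    participant_id: str

    @property
    def window(self) -> int:
        return self.patches.shape[1]

    def __len__(self) -> int:
        return self.patches.shape[0]


def extract_patch_sequence(
    clip: VideoClip,
    trace: GazeTrace,
    window_px: int = DEFAULT_WINDOW,
    boundary: str = "zero",
) -> PatchSequence:
    if window_px <= 0:
        raise ValueError("window_px must be positive")
    h, w = clip.frames.shape[1:3]
    if window_px > h or window_px > w:
        raise ValueError(f"window_px={window_px} exceeds frame size {w}x{h}")
    if trace.clip_id != clip.spec.clip_id:
        raise ValueError(f"trace clip_id {trace.clip_id!r} != clip id {clip.spec.clip_id!r}")
    if len(trace) != clip.n_frames:
        raise ValueError("trace length must equal clip frame count")
    if boundary not in ("zero", "clamp"):
        raise ValueError("boundary must be 'zero' or 'clamp'")

    T = clip.n_frames
    half = window_px // 2
    patches = np.zeros((T, window_px, window_px, 3), dtype=np.float32)
    valid = np.asarray(trace.valid, dtype=bool).copy()
    for t in range(T):
        if not valid[t]:
            continue
        cx = int(round(float(trace.x[t])))
        cy = int(round(float(trace.y[t])))
        x0, y0 = cx - half, cy - half
        if boundary == "clamp":
            x0 = min(max(x0, 0), w - window_px)
            y0 = min(max(y0, 0), h - window_px)
        sx0, sy0 = max(x0, 0), max(y0, 0)
        sx1, sy1 = min(x0 + window_px, w), min(y0 + window_px, h)
        if sx0 >= sx1 or sy0 >= sy1:
            continue  # fully outside: stays zero
        patches[t, sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = clip.frames[t, sy0:sy1, sx0:sx1]
    return PatchSequence(
        patches=patches,
        valid=valid,
        clip_id=clip.spec.clip_id,
        participant_id=trace.participant_id,
    )


def downsample_frames(seq: PatchSequence, factor: int = 10) -> PatchSequence:
    """Keep frames at indices 0, factor, 2*factor, ...; validity subsampled identically."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    return PatchSequence(
        patches=seq.patches[::factor].copy(),
        valid=seq.valid[::factor].copy(),
        clip_id=seq.clip_id,
        participant_id=seq.participant_id,
    )
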